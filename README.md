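# clonotrack

Clonal tracking of T-cell receptor (TCR) repertoires across tissues.

`clonotrack` is for immunologists following the fate of a defined T-cell
population — typically an in vitro expanded donor regulatory T-cell
(Treg) product — after adoptive transfer, by comparing the clonotype
composition of the infused product with repertoires re-isolated from
host organs (spleen, liver, colon) of one or several recipients. It
ingests bulk UMI-based clonotype tables (AIRR Rearrangement TSV or
MiXCR-style export) and 10x-style paired-chain single-cell contig
tables, and provides:

- **Diversity** — inverse Simpson index `iSI = 1/Σp²` after rarefaction
  to a common depth (sampling UMIs without replacement), the effective
  number of equally sized clones.
- **Overlap** — Morisita–Horn `2Σpq/(Σp²+Σq²)` and classical Morisita
  similarity, plus directional UMI-overlap fractions for circos-style
  sharing plots.
- **Barycentric clone geometry** — each clone detected in three
  compartments maps to triangle weights `w_X = f_X/Σf` (per-compartment
  frequencies `f_X = count_X/depth_X`), with a normalized size; clones
  are classified organ-restricted, biased or ubiquitous.
- **TSEA** (TCR set enrichment analysis) — tests whether clones
  re-detected in an organ concentrate among the top frequency ranks of
  the graft, via the standardized mean rank
  `z = (E₀ − mean rank)/SD₀` with closed-form null moments and a
  permutation p-value, plus GSEA-style running-sum scores and windowed
  "worm" densities on a fixed scale.
- **Vβ segment usage** — per-sample segment frequencies
  (clone- or UMI-weighted, ambiguous calls excluded and counted) and
  enrichment of designated segment sets across organs or clusters by
  two-sided Fisher exact tests with Benjamini–Hochberg correction.
- **A synthetic experiment generator** — heavy-tailed donor repertoire,
  polyclonal vs allo-selective expansion, three-organ seeding in
  multiple recipients with ground-truth clone classes, and paired-chain
  single-cell fixtures, so every stage can be validated end to end.

See `docs/methods.md` for the statistical model and defaults.

## Worked example

Simulate the default experiment and run the core analyses:

```python
import clonotrack as ct

exp = ct.simulate_experiment(ct.SimulationConfig(seed=1))

# diversity of the fresh donor repertoire and the two cell products
prof = ct.diversity_profile(
    [exp.donor, exp.products["poly"], exp.products["allo"]],
    n_reps=10, seed=1,
)
print(prof[["sample_id", "depth", "isi", "isi_sd"]].round(1).to_string(index=False))

# pool each organ over the three recipients of the polyclonal arm
pool = {
    organ: ct.pool_samples(
        [exp.seeded["poly"][(f"r{r}", organ)] for r in (1, 2, 3)], organ
    )
    for organ in ("spleen", "liver", "colon")
}
print(ct.pairwise_overlap(list(pool.values()), "morisita_horn").values.round(3))

tri = ct.barycentric_table([pool["spleen"], pool["liver"], pool["colon"]])
print(tri["class"].value_counts())

enr = ct.segment_set_enrichment(pool)   # TRBV12-1/12-2/26 by default
print(enr[["group", "odds_ratio", "p", "p_adj"]].round(4).to_string(index=False))
```

Output:

```
   sample_id  depth   isi  isi_sd
 donor_fresh  30000 390.4     0.0
product_poly  30000 235.3     0.0
product_allo  30000 148.8     0.0
        spleen  liver  colon
spleen   1.000  0.999  0.951
liver    0.999  1.000  0.953
colon    0.951  0.953  1.000
class
ubiquitous       4726
restricted(C)     132
restricted(A)      53
restricted(B)      41
biased(C)          33
 group  odds_ratio      p  p_adj
spleen      0.9162 0.0808 0.1212
 liver      0.9648 0.4749 0.4749
 colon      1.1287 0.0137 0.0412
```

Reading the numbers: allo-selective expansion narrows the repertoire
(iSI 148.8 vs 235.3 for the polyclonal product and 390.4 fresh, at a
common depth of 30 000 UMIs; the SD is 0 here because that depth equals
the full table, making the rarefaction draw exhaustive). Spleen and
liver repertoires are nearly identical (Morisita–Horn 0.999) while the
colon stands apart (0.95), carrying its own restricted clones: most
clones are organ-spanning ("ubiquitous"), but the colon vertex holds
the largest restricted group (132 clones plus 33 biased), and the
planted colon-tropic Vβ set (TRBV12-1, TRBV12-2, TRBV26) is enriched
only there (odds ratio 1.13, BH-adjusted p = 0.041).

## Command line

Each stage is also a subcommand of the `clonotrack` CLI; `run` drives a
whole configured pipeline and writes a checksummed manifest:

```bash
clonotrack simulate --seed 1 --out sim/
clonotrack diversity sim/product_poly.airr.tsv sim/product_allo.airr.tsv \
    --seed 1 --out diversity.tsv
clonotrack run --config run.yaml --seed 1 --out results/
```

Reruns with the same configuration and seed reproduce byte-identical
outputs.

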