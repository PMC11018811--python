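# Methods

`clonotrack` analyzes the clonal composition of T-cell receptor (TCR)
repertoires sampled from multiple body compartments — the setting of an
adoptive-transfer experiment in which an in vitro expanded donor
regulatory T-cell (Treg) product seeds spleen, liver and colon of
several transplant recipients. This note documents the statistical
model behind each stage, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the
numerical conventions.

## Clonotype model

A bulk clonotype is keyed by `(chain, v_call, j_call, cdr3_nt)` — the
nucleotide-level identity produced by UMI-consensus pipelines. Counts
are unique molecular identifiers (UMIs), each standing for one captured
mRNA molecule, so clone sizes are digital. V/J calls are reduced to
plain segment names (allele suffixes such as `*01` and alignment scores
are stripped); ambiguous multi-hit calls are kept as comma-joined lists
and resolved only where a single segment is needed. Amino-acid-level
keying (`level="aa"`) is available everywhere a key is used but is
never the default, since nucleotide keys are what distinguishes
convergent rearrangements. Single-cell clones are keyed by the full
alpha/beta pair; only barcodes with exactly one productive,
high-confidence TRA and one TRB contig are retained — cells with two
alpha chains are dropped rather than disambiguated.

## Diversity

The inverse Simpson index (iSI) `1/Σ p_i²` is the effective number of
equally sized clones. Because iSI estimates depend on sequencing depth,
samples are compared after rarefaction to a common depth — by default
the smallest total among the compared samples, since the true depths
per comparison are a property of the data, not the method. Rarefaction
draws UMIs *without replacement* (multivariate hypergeometric): each
UMI is a distinct molecule, so sampling with replacement would
understate the tail. The reported iSI is the mean over `n_reps = 25`
independent downsamples with its SD; a single draw would be an unstable
estimate and untestable. Each sample's random stream is seeded by
`global_seed + crc32(sample_id)`, so adding samples to an analysis
never changes existing numbers.

## Overlap

Morisita–Horn, `2Σp_i q_i / (Σp_i² + Σq_i²)` over the union of
clonotype keys, is the default pairwise similarity: bounded in [0, 1],
defined for proportions, equal to 1 only for identical composition.
Classical Morisita (unbiased Simpson terms `Σn(n−1)/(N(N−1))`) is also
provided; it can exceed 1 in small samples, which triggers a warning
rather than clipping. Circos-style sharing is summarized by directional
UMI-overlap fractions — the share of a sample's molecules whose
clonotype is also seen in the partner — plus a pooled variant for
printed totals; both are emitted because a band has two endpoints with
different denominators.

## Barycentric clone geometry

Every clone detected in up to three compartments maps to a triangle
point. Default normalization is *frequency* mode: per-compartment
frequencies `f_X = count_X / depth_X` are computed first and weights
are `w_X = f_X / Σf`, so a compartment sequenced ten times deeper does
not pull points toward its vertex; *raw* mode (`w_X = count_X /
Σcounts`) suits replicate triangles of comparable depth. Bubble size is
the mean per-compartment frequency — one of several defensible
normalizations; it is stated in the output so downstream plots are
unambiguous. Clones are labeled `restricted(X)` when all weight sits on
one vertex, `biased(X)` when a weight reaches the dominance threshold
(default 0.9, a reporting convention only), else `ubiquitous`.

## TCR set enrichment (TSEA)

TSEA asks whether a clonotype set (e.g. the clones re-detected in one
organ) concentrates among the high-frequency ranks of a reference
repertoire (the graft). The reference is ranked by descending UMI
count, ties broken lexicographically so ranking is deterministic. The
primary statistic is the standardized mean rank of the hits: drawing
`k` of `N` ranks without replacement has mean `(N+1)/2` and variance of
the mean `(N+1)(N−k)/(12k)`, giving a closed-form z-score that is
positive for top-of-list concentration. Significance comes from a
permutation null over random same-size key sets with the add-one
estimator `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`, which cannot return
zero. Query keys absent from the reference carry no rank; they are
reported as `missing`, never silently dropped. A GSEA-style running-sum
enrichment score (+1/k per hit, −1/(N−k) per miss, maximal deviation)
and a windowed "worm" density — hits per window relative to the
expected density `k/N`, so 1 is neutral and `N/window` the ceiling, on
a scale fixed by `(N, window)` alone — are emitted for barcode-plot
style display. The permutation layer is this package's own inferential
addition to what is otherwise a visualization.

## V-segment usage and set enrichment

Per-sample Vβ usage is reported clone-weighted and UMI-weighted
(figures in the field use either; both are emitted). Records with
ambiguous V calls are excluded by default and counted. Enrichment of a
designated segment set — default the colon-associated trio TRBV12-1,
TRBV12-2, TRBV26 — across groups uses, per group, the 2×2 table
(in-set vs out) × (group vs all other groups), a two-sided Fisher exact
test (p = total probability of all fixed-margin tables no more likely
than the observed one, the standard convention), and
Benjamini–Hochberg correction across groups. The sample odds ratio
gets a Haldane 0.5 correction when a margin cell is zero, and the row
is flagged. Segment names are matched case-insensitively with `.`/`-`
separators unified.

## The synthetic experiment

The generator produces the full study design with per-clone ground
truth, so every stage can be tested for parameter recovery.

1. **Donor repertoire.** `n_clones = 5000` clones with sizes from a
   power law with tail index `α = 1.5` (`1 + Pareto(1.5)`), the
   heavy-tailed shape of antigen-experienced repertoires; a lognormal
   law is available. Each clone gets unique beta and alpha chains
   (random V/J from murine segment lists, collision-checked in-frame
   CDR3s). 5 % of clones are *alloreactive*; 3 % of the remainder are
   *tissue-restricted*: colon-tropic, preferentially (80 %) carrying
   the designated Vβ trio, and entering the graft at a quarter of the
   usual size — they are low-frequency clones responding to local
   gut antigens, not culture-expanded ones. The rest are bystanders.
2. **Expansion.** Polyclonal culture multiplies each proportion by
   `exp(N(0, 0.2))` — growth-rate noise that largely preserves breadth.
   Allo-selective culture adds a per-clone expansion advantage
   `LogNormal(ln 8, 1.5)` for alloreactive clones and depletes
   tissue-restricted clones by 1/8. The gains are heterogeneous
   because antigen-driven selection compounds exponentially over a
   culture; a constant gain applied to a random subset provably leaves
   the inverse Simpson index nearly unchanged and cannot reproduce the
   repertoire narrowing that defines the allo arm.
3. **Seeding.** Clone weights per organ are the product proportion
   times class-specific organ weights: alloreactive uniform across
   organs with an additional shared in-vivo expansion
   `LogNormal(ln 8, 1.5)` (allo-antigens are ubiquitous in the
   mismatched host — this is what makes re-isolated repertoires less
   diverse than their graft and dominant clones organ-spanning);
   tissue-restricted 0.05/0.05/0.90 toward the colon with a local
   colon expansion of the same form; bystanders depth-proportional.
   Recipients share all selection weights and differ only by
   independent multinomial draws of exactly the configured depth
   (2×10⁴ UMIs per organ); optional per-recipient weight jitter exists
   for robustness studies.
4. **Single cell.** Cells are drawn from a sample's clone proportions;
   each intact cell emits one TRA and one TRB contig consistent with
   the bulk beta chain. A configurable defect fraction (default 0.1,
   split evenly among missing-alpha, missing-beta, doublet-alpha)
   exercises the pairing filter.

All randomness flows from one integer seed through named
`numpy.random.default_rng` streams, so a configuration reproduces
byte-identical tables across platforms.

**What the generator does not emulate.** Real repertoires have
10⁴–10⁶ clones and organ samples far shallower than the repertoire; at
the desk scale used here, 6×10⁴ pooled organ UMIs against 5×10³ graft
clones mean clonotype detection is nearly saturated for the broad
polyclonal product. Redetection fractions of the graft in host organs
are therefore near 100 % for the poly arm and do not reproduce the
lower seeding proportions real polyclonal products show. Sequence
content is random (no V(D)J recombination model, no convergent
recombination), there is no cross-contamination or PCR noise, and
expression phenotypes are out of scope. Passing recovery tests shows
the *statistics* behave correctly under the assumed sampling model,
not that the biology of any particular study is re-derived.

## Problem sizes and numerical choices

Module tests run the generator at 800 clones / 5–8×10³ UMIs; the
acceptance layer uses the default configuration above plus
2000-replicate null calibrations (TSEA type-I error at α = 0.05 within
two Monte-Carlo SDs; segment-set false-positive rate at or below
nominal). The TSEA arm comparison uses matched random sub-queries of
8 detected clones averaged over 40 draws, a size chosen so the
permutation p-value is informative rather than floored at
`1/(n_perm+1)` for both arms. Barycentric weight sums are enforced to
1 within 1e−12; proportions renormalize after every reweighting step;
ties anywhere resolve by lexicographic key order. Degenerate inputs
(empty tables, all-zero counts, saturated or disjoint queries) raise
typed errors rather than returning sentinel values.

## Known limitations

- Exactly three compartments for barycentric geometry; no simplex
  generalization.
- Classical Morisita's small-sample excess over 1 is reported, not
  corrected.
- The TSEA permutation null treats the query size as fixed and keys as
  exchangeable; it does not model detection-probability differences
  between clones.
- BH correction is applied per segment-set analysis (across groups),
  not across multiple segment sets.
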