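"""Shared fixtures: hand-built micro-repertoires and one desk-scale
synthetic experiment reused across module tests."""

from __future__ import annotations

import pandas as pd
import pytest

from clonotrack import (
    RepertoireTable,
    SampleMeta,
    SimulationConfig,
    pool_samples,
    simulate_experiment,
)

_B4 = "ACGT"


def label_to_cdr3(label: str) -> str:
    """Deterministic, collision-free mapping of an arbitrary label to a
    valid CDR3 nucleotide string (each byte -> 4 base-4 digits)."""
    out = []
    for byte in label.encode("utf-8"):
        for shift in (6, 4, 2, 0):
            out.append(_B4[(byte >> shift) & 3])
    return "".join(out)


def make_table(
    counts: dict,
    sample_id: str = "s1",
    chain: str = "TRB",
    v_call: str = "TRBV1",
    j_call: str = "TRBJ1-1",
    organ: str = "other",
    **meta,
) -> RepertoireTable:
    """Build a table from ``{label: count}`` (or ``{(v, label): count}``
    to control the V segment). Labels are encoded into CDR3s, so equal
    labels across tables mean shared clonotypes."""
    rows = []
    for key, count in counts.items():
        v, label = key if isinstance(key, tuple) else (v_call, key)
        rows.append(
            {
                "chain": chain,
                "v_call": v,
                "j_call": j_call,
                "cdr3_nt": label_to_cdr3(str(label)),
                "cdr3_aa": "",
                "umi_count": count,
            }
        )
    return RepertoireTable.from_records(
        pd.DataFrame(rows), SampleMeta(sample_id=sample_id, organ=organ, **meta)
    )


#: desk-scale generator settings used by the module tests (the default
#: configuration is exercised by the acceptance tests)
SMALL_CONFIG = dict(
    n_clones=800,
    donor_depth=8000,
    product_depth=8000,
    organ_depths={"spleen": 5000, "liver": 5000, "colon": 5000},
)


@pytest.fixture(scope="session")
def small_exp():
    return simulate_experiment(SimulationConfig(seed=1, **SMALL_CONFIG))


def pooled_organs(exp, mode: str) -> dict:
    """Pool each organ over recipients for one expansion arm."""
    n = exp.config.n_recipients
    return {
        organ: pool_samples(
            [exp.seeded[mode][(f"r{r + 1}", organ)] for r in range(n)],
            label=f"{mode}_pooled_{organ}",
        )
        for organ in ("spleen", "liver", "colon")
    }
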