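"""Reading, validating, pooling and writing clonotype tables.

Bulk repertoires arrive as AIRR Rearrangement TSV or MiXCR-style export
TSV; single-cell repertoires arrive as 10x ``filtered_contig_annotations``
style CSV. All readers return validated containers keyed on
``(chain, v_call, j_call, cdr3_nt)`` — the nucleotide-level clonotype key
of UMI-consensus pipelines. Amino-acid keying is available downstream via
``counts_by_key(..., level="aa")`` but is never the default.

V/J calls are normalized to plain segment names: allele suffixes
(``*01``) and alignment-score annotations (``(1234)``) are stripped.
Multi-hit (ambiguous) calls are preserved as comma-joined segment lists,
so ambiguity survives a round-trip; downstream segment-usage code decides
how to treat them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ChainMismatchError, EmptyTableError, FormatError

ORGANS = ("donor", "spleen", "liver", "colon", "other")
TREATMENTS = ("fresh", "allo", "poly")
SETTINGS = ("donor_product", "GvHD", "noGvHD", "noBMT")
CHAINS = ("TRA", "TRB")

#: columns that define a bulk clonotype within one sample
KEY_COLUMNS = ["chain", "v_call", "j_call", "cdr3_nt"]

#: columns that define a paired single-cell clone
PAIRED_KEY_COLUMNS = ["tra_v", "tra_j", "cdr3a_nt", "trb_v", "trb_j", "cdr3b_nt"]

RECORD_COLUMNS = KEY_COLUMNS + ["cdr3_aa", "umi_count"]

_CDR3_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata attached to one repertoire sample (or pooled group)."""

    sample_id: str
    organ: str = "other"
    recipient_id: str | None = None
    treatment: str = "fresh"
    setting: str = "noBMT"
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise FormatError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
        if self.treatment not in TREATMENTS:
            raise FormatError(f"unknown treatment {self.treatment!r}")
        if self.setting not in SETTINGS:
            raise FormatError(f"unknown setting {self.setting!r}")
        if (self.organ == "donor") != (self.setting == "donor_product"):
            raise FormatError(
                "organ='donor' and setting='donor_product' must be used together "
                f"(got organ={self.organ!r}, setting={self.setting!r})"
            )


@dataclass
class RepertoireTable:
    """One sample's clonotype records plus metadata.

    ``records`` is a DataFrame with columns ``chain, v_call, j_call,
    cdr3_nt, cdr3_aa, umi_count``; the clonotype key is unique within the
    table and every ``umi_count`` is positive. Use :meth:`from_records`
    to construct from unvalidated rows.
    """

    meta: SampleMeta
    records: pd.DataFrame
    drops: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"record frame lacks columns {missing}")
        self.records = self.records[RECORD_COLUMNS].reset_index(drop=True)
        if (self.records["umi_count"] <= 0).any():
            raise FormatError("records with umi_count <= 0 are not allowed")
        if self.records.duplicated(KEY_COLUMNS).any():
            raise FormatError("duplicate clonotype keys in record frame")

    # -- derived quantities -------------------------------------------------
    @property
    def total_umis(self) -> int:
        return int(self.records["umi_count"].sum())

    @property
    def n_clonotypes(self) -> int:
        return len(self.records)

    @property
    def chains(self) -> set[str]:
        return set(self.records["chain"].unique())

    def __len__(self) -> int:  # number of clonotypes
        return len(self.records)

    @classmethod
    def from_records(
        cls, rows: pd.DataFrame, meta: SampleMeta, drops: dict[str, int] | None = None
    ) -> "RepertoireTable":
        """Validate raw rows: drop zero counts and malformed CDR3s, merge
        duplicate keys by summing counts. Drop reasons are tallied in
        ``drops``."""
        drops = dict(drops or {})
        rows = rows.copy()
        for col in ("chain", "v_call", "j_call", "cdr3_nt"):
            if col not in rows.columns:
                raise FormatError(f"missing mandatory column {col!r}")
        if "cdr3_aa" not in rows.columns:
            rows["cdr3_aa"] = ""
        rows["cdr3_aa"] = rows["cdr3_aa"].fillna("")
        rows["umi_count"] = pd.to_numeric(rows["umi_count"], errors="coerce")

        bad_count = rows["umi_count"].isna() | (rows["umi_count"] <= 0)
        if bad_count.any():
            drops["nonpositive_count"] = drops.get("nonpositive_count", 0) + int(
                bad_count.sum()
            )
            rows = rows[~bad_count]
        cdr3 = rows["cdr3_nt"].astype(str).str.upper()
        bad_cdr3 = ~cdr3.str.match(_CDR3_RE)
        if bad_cdr3.any():
            drops["invalid_cdr3"] = drops.get("invalid_cdr3", 0) + int(bad_cdr3.sum())
            rows = rows[~bad_cdr3]
            cdr3 = cdr3[~bad_cdr3]
        rows = rows.assign(cdr3_nt=cdr3, umi_count=rows["umi_count"].astype(np.int64))
        bad_chain = ~rows["chain"].isin(CHAINS)
        if bad_chain.any():
            drops["unknown_chain"] = drops.get("unknown_chain", 0) + int(bad_chain.sum())
            rows = rows[~bad_chain]

        merged = (
            rows.groupby(KEY_COLUMNS, as_index=False, sort=True)
            .agg(cdr3_aa=("cdr3_aa", "first"), umi_count=("umi_count", "sum"))
        )
        return cls(meta=meta, records=merged[RECORD_COLUMNS], drops=drops)


@dataclass
class PairedCloneTable:
    """Paired-chain single-cell clones for one sample.

    ``clones`` columns: ``tra_v, tra_j, cdr3a_nt, trb_v, trb_j, cdr3b_nt,
    cell_count``. Each row is one clone, defined by exactly one productive
    alpha and one productive beta chain; ``cell_count`` is the number of
    retained barcodes carrying that pair.
    """

    sample_id: str
    clones: pd.DataFrame
    drops: dict[str, int] = field(default_factory=dict)

    @property
    def total_cells(self) -> int:
        return int(self.clones["cell_count"].sum())


# ---------------------------------------------------------------------------
# gene-call normalization
# ---------------------------------------------------------------------------

def normalize_gene_call(raw: str) -> str:
    """Reduce a V/J call to plain segment names.

    Strips allele suffixes (``*01``) and score annotations (``(1234)``)
    from each hit; multiple hits stay comma-joined (marking ambiguity).
    Returns '' if nothing parsable remains.
    """
    hits = []
    for part in str(raw).split(","):
        name = part.split("*")[0].split("(")[0].strip()
        if name and name not in hits:
            hits.append(name)
    return ",".join(hits)


def primary_segment(call: str) -> str:
    """First segment of a (possibly ambiguous, comma-joined) call."""
    return str(call).split(",")[0]


def is_ambiguous_call(call: str) -> bool:
    return "," in str(call)


def _chain_from_v(v_call: str) -> str:
    head = primary_segment(v_call)[:3].upper()
    return head if head in CHAINS else ""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_airr(path, meta: SampleMeta) -> RepertoireTable:
    """Read an AIRR Rearrangement TSV into a validated table.

    Requires at least ``v_call, j_call, junction, duplicate_count``;
    ``locus`` and ``junction_aa`` are used when present. Duplicate
    clonotype keys are merged by summing counts; rows failing validation
    are dropped and counted in ``table.drops``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise EmptyTableError(f"{path}: no rearrangement rows")
    for col in ("v_call", "j_call", "junction", "duplicate_count"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    v = df["v_call"].map(normalize_gene_call)
    rows = pd.DataFrame(
        {
            "chain": df["locus"].str.upper() if "locus" in df.columns else v.map(_chain_from_v),
            "v_call": v,
            "j_call": df["j_call"].map(normalize_gene_call),
            "cdr3_nt": df["junction"],
            "cdr3_aa": df.get("junction_aa", ""),
            "umi_count": df["duplicate_count"],
        }
    )
    table = RepertoireTable.from_records(rows, meta)
    if table.n_clonotypes == 0:
        raise EmptyTableError(f"{path}: all rows failed validation ({table.drops})")
    return table


#: column aliases across MiXCR export versions
_MIXCR_ALIASES = {
    "count": ["cloneCount", "clonecount", "readCount"],
    "v": ["allVHitsWithScore", "bestVHit", "allVHits"],
    "j": ["allJHitsWithScore", "bestJHit", "allJHits"],
    "cdr3_nt": ["nSeqCDR3", "nSeqImputedCDR3"],
    "cdr3_aa": ["aaSeqCDR3"],
}


def _pick(df: pd.DataFrame, role: str, required: bool = True) -> str | None:
    for name in _MIXCR_ALIASES[role]:
        if name in df.columns:
            return name
    if required:
        raise FormatError(f"MiXCR table lacks a recognizable {role} column "
                          f"(tried {_MIXCR_ALIASES[role]})")
    return None


def read_mixcr_tsv(path, meta: SampleMeta) -> RepertoireTable:
    """Read a MiXCR-style clone export TSV.

    V/J hit strings like ``TRBV12-1*00(1200)`` are truncated to plain
    segment names; comma-separated multi-hit fields stay comma-joined and
    are therefore flagged ambiguous downstream. Rows whose V field yields
    no parsable segment are excluded and counted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise EmptyTableError(f"{path}: no clone rows")
    count_col = _pick(df, "count")
    v_col, j_col = _pick(df, "v"), _pick(df, "j")
    nt_col = _pick(df, "cdr3_nt")
    aa_col = _pick(df, "cdr3_aa", required=False)

    v = df[v_col].map(normalize_gene_call)
    drops: dict[str, int] = {}
    unparsable = v == ""
    if unparsable.any():
        drops["unparsable_v_call"] = int(unparsable.sum())
        df, v = df[~unparsable], v[~unparsable]
    rows = pd.DataFrame(
        {
            "chain": v.map(_chain_from_v),
            "v_call": v,
            "j_call": df[j_col].map(normalize_gene_call),
            "cdr3_nt": df[nt_col],
            "cdr3_aa": df[aa_col] if aa_col else "",
            "umi_count": df[count_col],
        }
    )
    table = RepertoireTable.from_records(rows, meta, drops=drops)
    if table.n_clonotypes == 0:
        raise EmptyTableError(f"{path}: all rows excluded ({table.drops})")
    return table


def read_sc_contigs(path, sample_id: str | None = None) -> PairedCloneTable:
    """Reduce a 10x filtered-contig CSV to paired-chain clones.

    Keeps only barcodes with exactly one productive, high-confidence TRA
    contig and exactly one productive, high-confidence TRB contig
    (cells with two alpha chains are dropped, not disambiguated).
    Identical alpha/beta pairs are aggregated into one clone with a cell
    count; per-reason drop counts are reported.
    """
    df = pd.read_csv(path, dtype=str)
    needed = ["barcode", "chain", "v_gene", "j_gene", "cdr3_nt", "productive",
              "high_confidence"]
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"{path}: missing contig column {col!r}")
    if sample_id is None:
        sample_id = str(path)

    truthy = {"true", "t", "1", "yes"}
    ok = (
        df["productive"].str.strip().str.lower().isin(truthy)
        & df["high_confidence"].str.strip().str.lower().isin(truthy)
        & df["chain"].isin(CHAINS)
    )
    usable = df[ok]
    drops = {"non_informative_contigs": int((~ok).sum())}

    counts = usable.groupby(["barcode", "chain"]).size().unstack(fill_value=0)
    for chain in CHAINS:
        if chain not in counts.columns:
            counts[chain] = 0
    keep = (counts["TRA"] == 1) & (counts["TRB"] == 1)
    drops["missing_tra"] = int((counts["TRA"] == 0).sum())
    drops["multiple_tra"] = int((counts["TRA"] > 1).sum())
    drops["missing_trb"] = int(((counts["TRB"] == 0) & (counts["TRA"] == 1)).sum())
    drops["multiple_trb"] = int(((counts["TRB"] > 1) & (counts["TRA"] == 1)).sum())
    kept_barcodes = counts.index[keep]
    if len(kept_barcodes) == 0:
        raise EmptyTableError(f"{path}: no cells with a single alpha/beta pair "
                              f"({drops})")

    cells = usable[usable["barcode"].isin(kept_barcodes)].copy()
    cells["v_gene"] = cells["v_gene"].map(normalize_gene_call)
    cells["j_gene"] = cells["j_gene"].map(normalize_gene_call)
    tra = cells[cells["chain"] == "TRA"].set_index("barcode")
    trb = cells[cells["chain"] == "TRB"].set_index("barcode")
    paired = pd.DataFrame(
        {
            "tra_v": tra["v_gene"],
            "tra_j": tra["j_gene"],
            "cdr3a_nt": tra["cdr3_nt"],
            "trb_v": trb["v_gene"],
            "trb_j": trb["j_gene"],
            "cdr3b_nt": trb["cdr3_nt"],
        }
    )
    clones = (
        paired.groupby(PAIRED_KEY_COLUMNS, sort=True)
        .size()
        .rename("cell_count")
        .reset_index()
    )
    return PairedCloneTable(sample_id=sample_id, clones=clones, drops=drops)


def read_sample_sheet(path) -> list[tuple[str, SampleMeta, str]]:
    """Read a sample-sheet TSV mapping files to metadata.

    Columns: ``path, format, sample_id, organ, recipient_id, treatment,
    setting, replicate`` (missing metadata columns fall back to defaults).
    Returns ``(path, SampleMeta, format)`` triples; format is one of
    ``airr``, ``mixcr``, ``sc_contigs``.
    """
    sheet = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("path", "format", "sample_id"):
        if col not in sheet.columns:
            raise FormatError(f"{path}: sample sheet missing column {col!r}")
    out = []
    for _, row in sheet.iterrows():
        meta = SampleMeta(
            sample_id=row["sample_id"],
            organ=row.get("organ") or "other",
            recipient_id=row.get("recipient_id") or None,
            treatment=row.get("treatment") or "fresh",
            setting=row.get("setting") or "noBMT",
            replicate=row.get("replicate") or "",
        )
        out.append((row["path"], meta, row["format"]))
    return out


# ---------------------------------------------------------------------------
# pooling and writing
# ---------------------------------------------------------------------------

def pool_samples(tables: list[RepertoireTable], label: str,
                 meta: SampleMeta | None = None) -> RepertoireTable:
    """Clonotype-keyed union of several tables with summed UMI counts."""
    if not tables:
        raise EmptyTableError("pool_samples needs at least one table")
    chains = set().union(*(t.chains for t in tables))
    if len(chains) > 1:
        raise ChainMismatchError(f"cannot pool mixed chains {sorted(chains)}")
    if meta is None:
        first = tables[0].meta
        organs = {t.meta.organ for t in tables}
        settings = {t.meta.setting for t in tables}
        meta = replace(
            first,
            sample_id=label,
            organ=organs.pop() if len(organs) == 1 else "other",
            setting=settings.pop() if len(settings) == 1 else first.setting,
            recipient_id=None,
            replicate="",
        )
    rows = pd.concat([t.records for t in tables], ignore_index=True)
    pooled = RepertoireTable.from_records(rows, meta)
    assert pooled.total_umis == sum(t.total_umis for t in tables)
    return pooled


def write_clonotype_table(table: RepertoireTable, path) -> None:
    """Write an AIRR-style TSV that round-trips losslessly through
    :func:`read_airr` (up to record order)."""
    df = pd.DataFrame(
        {
            "sequence_id": [f"{table.meta.sample_id}-{i}" for i in range(len(table))],
            "locus": table.records["chain"],
            "v_call": table.records["v_call"],
            "j_call": table.records["j_call"],
            "junction": table.records["cdr3_nt"],
            "junction_aa": table.records["cdr3_aa"],
            "duplicate_count": table.records["umi_count"],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# keyed count vectors (shared by every downstream module)
# ---------------------------------------------------------------------------

def counts_by_key(table: RepertoireTable, level: str = "nt") -> pd.Series:
    """Clone counts indexed by clonotype key.

    ``level='nt'`` keys on ``chain|v|j|cdr3_nt`` (default); ``level='aa'``
    keys on the amino-acid CDR3 instead, aggregating nucleotide variants.
    """
    r = table.records
    if level == "nt":
        key = r["chain"] + "|" + r["v_call"] + "|" + r["j_call"] + "|" + r["cdr3_nt"]
    elif level == "aa":
        key = r["chain"] + "|" + r["v_call"] + "|" + r["j_call"] + "|" + r["cdr3_aa"]
    else:
        raise FormatError(f"unknown key level {level!r}")
    return r.groupby(key.rename("clone_key"))["umi_count"].sum().sort_index()


def paired_counts_by_key(table: PairedCloneTable) -> pd.Series:
    """Cell counts indexed by the paired alpha/beta clone key."""
    c = table.clones
    key = c[PAIRED_KEY_COLUMNS].agg("|".join, axis=1)
    return c.groupby(key.rename("clone_key"))["cell_count"].sum().sort_index()
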