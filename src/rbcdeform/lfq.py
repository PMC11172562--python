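"""Containers and IO for membrane-bound hemoglobin LFQ abundance tables.

Label-free quantification (LFQ) intensities for the six globin chains found
on the red-cell membrane are analysed throughout on the natural-log scale,
Ln(LFQ).  Samples belong to one of two groups: freshly drawn donor blood or
blood-bank units stored in SAGM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "SUBUNIT_GENES",
    "GENE_TO_SUBUNIT",
    "GENES",
    "LFQTable",
    "ln_transform",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_maxquant",
]

# canonical column order: (greek subunit name, gene symbol)
SUBUNIT_GENES: tuple[tuple[str, str], ...] = (
    ("beta", "HBB"),
    ("alpha", "HBA1"),
    ("delta", "HBD"),
    ("mu", "HBM"),
    ("gamma", "HBG2"),
    ("theta", "HBQ1"),
)
GENES: tuple[str, ...] = tuple(g for _, g in SUBUNIT_GENES)
GENE_TO_SUBUNIT: dict[str, str] = {g: s for s, g in SUBUNIT_GENES}

GROUPS = ("fresh", "stored")

# heuristic ceiling: raw MS intensities are ~1e9-1e15, Ln values ~20-40
_LN_SCALE_CEILING = 100.0


@dataclass
class LFQTable:
    """Samples x six-subunit Ln(LFQ) matrix with group labels.

    ``data`` is indexed by sample id with gene-symbol columns in canonical
    order (HBB, HBA1, HBD, HBM, HBG2, HBQ1); missing values (non-detections)
    are NaN.  ``group`` is an aligned Series of "fresh"/"stored" labels.
    """

    data: pd.DataFrame
    group: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = [g for g in GENES if g not in self.data.columns]
        if missing:
            raise InputError(f"LFQ table missing subunit columns: {missing}")
        self.data = self.data.loc[:, list(GENES)].astype(float)
        if self.group is None:
            self.group = pd.Series("fresh", index=self.data.index, name="group")
        else:
            self.group = pd.Series(self.group, index=self.data.index, name="group")
            bad = set(self.group.dropna()) - set(GROUPS)
            if bad:
                raise InputError(f"unknown group labels: {sorted(bad)}")
        if self.n_samples < 2:
            raise InputError("LFQ table needs at least 2 samples")
        vals = self.data.to_numpy()
        if not np.isfinite(vals[~np.isnan(vals)]).all():
            raise InputError("LFQ table contains non-finite values")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def column(self, gene: str) -> pd.Series:
        if gene not in GENES:
            raise InputError(f"unknown subunit gene {gene!r}; expected one of {GENES}")
        return self.data[gene]


def ln_transform(raw: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform of raw LFQ intensities.

    Zeros mark non-detection and become NaN.  A table whose values are all
    below 100 is assumed to already be on the Ln scale and is rejected
    (idempotence guard); negative intensities are an input error.
    """
    values = raw.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if (finite < 0).any():
        raise InputError("raw LFQ intensities must be non-negative")
    nonzero = finite[finite > 0]
    if nonzero.size and np.nanmax(nonzero) < _LN_SCALE_CEILING:
        raise InputError(
            "input appears to be on the Ln scale already "
            f"(all values < {_LN_SCALE_CEILING:g}); refusing to log twice"
        )
    out = raw.astype(float).where(raw > 0)
    return np.log(out)


COHORT_COLUMNS = ["sample_id", "group", *GENES, "AER"]


def write_cohort_csv(path, table: LFQTable, aer: pd.Series | None = None) -> None:
    """Write a cohort CSV (sample_id, group, six Ln(LFQ) columns, AER)."""
    out = table.data.copy()
    out.insert(0, "group", table.group)
    if aer is not None:
        out["AER"] = pd.Series(aer, index=out.index)
    out.index.name = "sample_id"
    out.to_csv(path)


def read_cohort_csv(path) -> tuple[LFQTable, pd.Series | None]:
    """Read a cohort CSV; returns the table and the AER column if present."""
    df = pd.read_csv(path, index_col="sample_id")
    group = df["group"] if "group" in df.columns else None
    aer = df["AER"] if "AER" in df.columns else None
    return LFQTable(data=df, group=group), aer


def read_maxquant(path, sep: str = "\t") -> pd.DataFrame:
    """Extract the six Hb genes from a MaxQuant proteinGroups-style table.

    Expects rows keyed by a ``Gene names`` column and one ``LFQ intensity
    <sample>`` column per sample; returns a samples x genes DataFrame of raw
    (not yet log-transformed) intensities.
    """
    df = pd.read_csv(path, sep=sep)
    gene_col = next(
        (c for c in ("Gene names", "Gene Names", "gene_names") if c in df.columns), None
    )
    if gene_col is None:
        raise InputError("no 'Gene names' column in proteinGroups table")
    lfq_cols = [c for c in df.columns if c.startswith("LFQ intensity ")]
    if not lfq_cols:
        raise InputError("no 'LFQ intensity <sample>' columns found")
    # a protein group may list several gene names separated by ';'
    genes = df[gene_col].fillna("").str.split(";")
    rows = {}
    for target in GENES:
        hit = df[genes.apply(lambda gs: target in gs)]
        if len(hit) == 0:
            rows[target] = pd.Series(np.nan, index=lfq_cols)
        else:
            rows[target] = hit.iloc[0][lfq_cols]
    wide = pd.DataFrame(rows)
    wide.index = [c[len("LFQ intensity "):] for c in lfq_cols]
    wide.index.name = "sample_id"
    return wide.astype(float)
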