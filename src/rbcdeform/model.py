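"""Model/results facade over the membrane-bound hemoglobin analysis.

``MembraneHbDeformability`` bundles an LFQ cohort and its per-sample AER
values; ``fit()`` runs the full statistical layer — abundance summaries,
the inter-subunit correlation matrix, the subunit-vs-AER screen, the
fresh-vs-stored contrast, per-column normality checks and the delta/alpha
intensity ratio — into a results object with tidy frames and a text
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .hbstats import (
    CorrelationMatrix,
    CorrelationResult,
    GroupComparison,
    compare_groups,
    correlation_matrix,
    deformability_screen,
    normality_check,
    subunit_ratio,
)
from .lfq import GENE_TO_SUBUNIT, GENES, LFQTable, read_cohort_csv

__all__ = ["MembraneHbDeformability", "MembraneHbResults"]


class MembraneHbDeformability:
    """Joint model of membrane-bound Hb subunit levels and cell deformability.

    Parameters
    ----------
    lfq : LFQTable
        Samples x six-subunit Ln(LFQ) table with fresh/stored labels.
    aer : Series, optional
        Per-sample average elongation ratio aligned to the table's sample
        ids; without it the deformability screen is skipped.
    """

    def __init__(self, lfq: LFQTable, aer: pd.Series | None = None):
        self.lfq = lfq
        self.aer = None if aer is None else pd.Series(aer).astype(float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col: str = "group",
                       aer_col: str = "AER") -> "MembraneHbDeformability":
        """Build from one wide DataFrame (index = sample id)."""
        group = df[group_col] if group_col in df.columns else None
        aer = df[aer_col] if aer_col in df.columns else None
        return cls(LFQTable(data=df, group=group), aer)

    @classmethod
    def from_cohort_csv(cls, path) -> "MembraneHbDeformability":
        table, aer = read_cohort_csv(path)
        return cls(table, aer)

    def fit(self, group_test: str = "welch", holm: bool = False) -> "MembraneHbResults":
        lfq = self.lfq
        abundance = pd.DataFrame(
            {
                "subunit": [GENE_TO_SUBUNIT[g] for g in GENES],
                "mean": lfq.data.mean().to_numpy(),
                "sd": lfq.data.std(ddof=1).to_numpy(),
                "n": lfq.data.notna().sum().to_numpy(),
            },
            index=pd.Index(GENES, name="gene"),
        )
        normality = {}
        for g in GENES:
            vals = lfq.data[g].dropna()
            if 3 <= len(vals) <= 2000 and vals.nunique() > 1:
                normality[g] = normality_check(vals)
        corr = correlation_matrix(lfq)
        screen = (
            deformability_screen(lfq, self.aer, holm=holm)
            if self.aer is not None
            else None
        )
        groups = None
        if set(lfq.group) == {"fresh", "stored"}:
            groups = compare_groups(lfq, test=group_test)
        _, ratio_mean, ratio_sd, _ = subunit_ratio(lfq, "HBD", "HBA1")
        return MembraneHbResults(
            model=self, abundance=abundance, normality=normality,
            subunit_corr=corr, screen=screen, groups=groups,
            delta_alpha_ratio=(ratio_mean, ratio_sd),
        )


@dataclass
class MembraneHbResults:
    """Fitted results of :class:`MembraneHbDeformability`."""

    model: MembraneHbDeformability
    abundance: pd.DataFrame
    normality: dict[str, tuple[float, float]]
    subunit_corr: CorrelationMatrix
    screen: list[CorrelationResult] | None
    groups: list[GroupComparison] | None
    delta_alpha_ratio: tuple[float, float] = field(default=(np.nan, np.nan))

    def screen_frame(self) -> pd.DataFrame:
        if self.screen is None:
            raise InputError("no AER values were supplied; screen not fitted")
        return pd.DataFrame(
            {
                "subunit": [GENE_TO_SUBUNIT[res.pair[0]] for res in self.screen],
                "r": [res.r for res in self.screen],
                "n": [res.n for res in self.screen],
                "p": [res.p for res in self.screen],
                "tier": [res.tier for res in self.screen],
            },
            index=pd.Index([res.pair[0] for res in self.screen], name="gene"),
        )

    def groups_frame(self) -> pd.DataFrame:
        if self.groups is None:
            raise InputError("cohort has a single group; contrast not fitted")
        return pd.DataFrame(
            {
                "subunit": [g.subunit for g in self.groups],
                "mean_fresh": [g.mean_fresh for g in self.groups],
                "sd_fresh": [g.sd_fresh for g in self.groups],
                "mean_stored": [g.mean_stored for g in self.groups],
                "sd_stored": [g.sd_stored for g in self.groups],
                "test": [g.test_name for g in self.groups],
                "p": [g.p for g in self.groups],
            },
            index=pd.Index([g.gene for g in self.groups], name="gene"),
        )

    def summary(self) -> str:
        """Human-readable report mirroring the conventional table layout."""
        lines = ["Membrane-bound hemoglobin / deformability analysis",
                 "=" * 50, ""]
        lines.append("Subunit abundance, Ln(LFQ) [mean +/- SD]")
        for gene, row in self.abundance.iterrows():
            lines.append(
                f"  {row['subunit']:>5s} {gene:<5s} "
                f"{row['mean']:6.1f} +/- {row['sd']:.1f}  (n={int(row['n'])})"
            )
        lines.append("")
        lines.append("Inter-subunit correlation matrix (r, significance)")
        genes = list(self.subunit_corr.r.columns)
        lines.append("        " + "".join(f"{g:>8s}" for g in genes))
        for ga in genes:
            cells = []
            for gb in genes:
                if ga == gb:
                    cells.append(f"{'1.00':>8s}")
                else:
                    t = self.subunit_corr.tier.loc[ga, gb]
                    star = t if t != "ns" else ""
                    cells.append(f"{self.subunit_corr.r.loc[ga, gb]:6.2f}{star:<2s}")
            lines.append(f"  {ga:<6s}" + "".join(cells))
        lines.append("")
        if self.screen is not None:
            lines.append("Deformability screen: subunit Ln(LFQ) vs AER")
            for res in self.screen:
                lines.append(
                    f"  {GENE_TO_SUBUNIT[res.pair[0]]:>5s} "
                    f"r={res.r:+.3f}  n={res.n}  p={res.p:.4f}  [{res.tier}]"
                )
            lines.append("")
        if self.groups is not None:
            lines.append("Fresh vs stored contrast")
            for g in self.groups:
                lines.append(
                    f"  {g.subunit:>5s} fresh {g.mean_fresh:5.1f}+/-{g.sd_fresh:.1f} "
                    f"stored {g.mean_stored:5.1f}+/-{g.sd_stored:.1f} "
                    f"({g.test_name}) p={g.p:.3f}"
                )
            lines.append("")
        m, s = self.delta_alpha_ratio
        lines.append(f"delta/alpha intensity ratio: {m:.4f} +/- {s:.4f}")
        return "\n".join(lines)
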