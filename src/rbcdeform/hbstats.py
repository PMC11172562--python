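"""Statistical layer for the membrane-bound hemoglobin analysis.

Pearson correlation with t-distribution p-values on pairwise-complete
observations, the 6x6 inter-subunit correlation matrix, the subunit-vs-AER
deformability screen, fresh-vs-stored group contrasts, Shapiro-Wilk
normality checks and the delta/alpha intensity ratio.

Significance tiers follow the two-star convention: "*" for p < 0.05 and
"**" for p <= 0.001, "ns" otherwise.  No multiple-testing correction is
applied by default; a Holm adjustment is available but off, matching the
way these screens are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError, ZeroVarianceError
from .lfq import GENE_TO_SUBUNIT, GENES, LFQTable

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "pearson",
    "p_from_r",
    "tier_from_p",
    "correlation_matrix",
    "CorrelationMatrix",
    "deformability_screen",
    "compare_groups",
    "normality_check",
    "subunit_ratio",
    "holm_adjust",
]

# output order of the deformability screen (beta, alpha, delta, gamma, mu, theta)
SCREEN_ORDER = ("HBB", "HBA1", "HBD", "HBG2", "HBM", "HBQ1")


def tier_from_p(p: float) -> str:
    if p <= 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def p_from_r(r, n):
    """Two-sided p for a Pearson r from the t-distribution with n-2 df.

    Vectorised over ``r``; |r| = 1 maps to p = 0.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    return p if p.shape else float(p)


@dataclass(frozen=True)
class CorrelationResult:
    """One entry of a correlation screen."""

    pair: tuple[str, str]
    r: float
    n: int
    p: float
    tier: str

    @property
    def significant(self) -> bool:
        return self.tier != "ns"


@dataclass(frozen=True)
class GroupComparison:
    """Fresh-vs-stored contrast for one subunit."""

    subunit: str
    gene: str
    mean_fresh: float
    sd_fresh: float
    n_fresh: int
    mean_stored: float
    sd_stored: float
    n_stored: int
    test_name: str
    p: float


def pearson(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson correlation on pairwise-complete observations.

    r is the standard product-moment coefficient; p is two-sided from
    t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise InputError(f"need >= 3 pairwise-complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError(
            f"correlation undefined for pair {pair}: a variable is constant"
        )
    r = float(stats.pearsonr(x, y).statistic)
    p = float(p_from_r(r, n))
    return CorrelationResult(pair=pair, r=r, n=n, p=p, tier=tier_from_p(p))


@dataclass
class CorrelationMatrix:
    """Symmetric 6x6 correlation screen with per-cell n and significance."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    tier: pd.DataFrame

    def result(self, gene_a: str, gene_b: str) -> CorrelationResult:
        return CorrelationResult(
            pair=(gene_a, gene_b),
            r=float(self.r.loc[gene_a, gene_b]),
            n=int(self.n.loc[gene_a, gene_b]),
            p=float(self.p.loc[gene_a, gene_b]),
            tier=str(self.tier.loc[gene_a, gene_b]),
        )


def correlation_matrix(table: LFQTable) -> CorrelationMatrix:
    """Inter-subunit Pearson matrix on pairwise-complete observations.

    The per-cell n may differ between cells when values are missing and is
    reported alongside r and p.  Diagonal: r = 1 with no tier.
    """
    genes = list(GENES)
    r = pd.DataFrame(np.eye(6), index=genes, columns=genes)
    p = pd.DataFrame(np.nan, index=genes, columns=genes)
    n = pd.DataFrame(0, index=genes, columns=genes, dtype=int)
    tier = pd.DataFrame("", index=genes, columns=genes)
    for i, ga in enumerate(genes):
        n.loc[ga, ga] = int(table.data[ga].notna().sum())
        for gb in genes[i + 1:]:
            res = pearson(table.data[ga], table.data[gb], pair=(ga, gb))
            r.loc[ga, gb] = r.loc[gb, ga] = res.r
            p.loc[ga, gb] = p.loc[gb, ga] = res.p
            n.loc[ga, gb] = n.loc[gb, ga] = res.n
            tier.loc[ga, gb] = tier.loc[gb, ga] = res.tier
    return CorrelationMatrix(r=r, p=p, n=n, tier=tier)


def deformability_screen(table: LFQTable, aer: pd.Series,
                         holm: bool = False) -> list[CorrelationResult]:
    """Correlate each subunit's Ln(LFQ) level with per-sample AER.

    Returns six results in conventional reporting order (beta, alpha,
    delta, gamma, mu, theta); non-significant subunits keep their computed
    r with tier "ns".
    """
    aer = pd.Series(aer)
    orphans_t = [s for s in table.sample_ids if s not in aer.index]
    orphans_a = [s for s in aer.index if s not in table.data.index]
    if orphans_t or orphans_a:
        raise InputError(
            "sample ids misaligned between LFQ table and AER: "
            f"missing AER for {orphans_t}; AER without LFQ row {orphans_a}"
        )
    aer = aer.loc[table.sample_ids].astype(float)
    results = [
        pearson(table.data[g], aer, pair=(g, "AER")) for g in SCREEN_ORDER
    ]
    if holm:
        results = holm_adjust(results)
    return results


def holm_adjust(results: list[CorrelationResult]) -> list[CorrelationResult]:
    """Holm step-down adjustment of a list of correlation results."""
    m = len(results)
    order = np.argsort([res.p for res in results])
    adjusted = [None] * m
    running = 0.0
    for rank, idx in enumerate(order):
        p_adj = min(1.0, (m - rank) * results[idx].p)
        running = max(running, p_adj)
        adjusted[idx] = replace(
            results[idx], p=running, tier=tier_from_p(running)
        )
    return adjusted


def compare_groups(table: LFQTable, test: str = "welch") -> list[GroupComparison]:
    """Fresh-vs-stored contrast per subunit.

    Default is Welch's unequal-variance t test; ``test="ranksum"`` uses the
    Mann-Whitney U.  The test name is always recorded with the result.
    """
    if test not in ("welch", "ranksum"):
        raise ParameterError(f"unknown test {test!r}; use 'welch' or 'ranksum'")
    fresh = table.data[table.group == "fresh"]
    stored = table.data[table.group == "stored"]
    if len(fresh) < 2 or len(stored) < 2:
        raise InputError(
            f"both groups need >= 2 samples (fresh={len(fresh)}, stored={len(stored)})"
        )
    out = []
    for gene in GENES:
        xf = fresh[gene].dropna().to_numpy()
        xs = stored[gene].dropna().to_numpy()
        if test == "welch":
            p = float(stats.ttest_ind(xf, xs, equal_var=False).pvalue)
            name = "Welch t"
        else:
            p = float(stats.mannwhitneyu(xf, xs, alternative="two-sided").pvalue)
            name = "Mann-Whitney U"
        out.append(
            GroupComparison(
                subunit=GENE_TO_SUBUNIT[gene], gene=gene,
                mean_fresh=float(xf.mean()), sd_fresh=float(xf.std(ddof=1)),
                n_fresh=len(xf),
                mean_stored=float(xs.mean()), sd_stored=float(xs.std(ddof=1)),
                n_stored=len(xs),
                test_name=name, p=p,
            )
        )
    return out


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk test of normality; returns (W, p).  Valid for 3<=n<=2000."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= x.size <= 2000:
        raise InputError(f"Shapiro-Wilk needs 3 <= n <= 2000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("normality undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def subunit_ratio(table: LFQTable, numerator: str = "HBD",
                  denominator: str = "HBA1"):
    """Per-sample intensity-scale ratio of two subunits.

    Ln values are differenced and exponentiated per sample,
    exp(Ln_num - Ln_den); samples missing either value are skipped.
    Returns ``(ratios, mean, sd, n_skipped)``.
    """
    num = table.column(numerator)
    den = table.column(denominator)
    diff = num - den
    ratios = np.exp(diff.dropna())
    n_skipped = int(diff.isna().sum())
    if len(ratios) == 0:
        raise InputError("no sample has both subunits quantified")
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    return ratios, float(ratios.mean()), sd, n_skipped
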