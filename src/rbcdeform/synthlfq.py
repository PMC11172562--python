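"""Synthetic LFQ + AER cohorts with a controlled joint correlation structure.

The generator draws one joint Gaussian vector per sample: six Ln(LFQ)
subunit coordinates plus a latent deformability coordinate that is shifted
and scaled into the sample's average elongation ratio (AER).  Target
correlations are therefore hit exactly in expectation, and stored-unit
samples receive an additive shift of the fetal gamma-subunit mean, the one
storage effect the cohort design carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .lfq import GENES, LFQTable

__all__ = [
    "LFQCohortSpec",
    "generate_lfq_cohort",
    "nearest_correlation_matrix",
    "scale_counts",
]


def nearest_correlation_matrix(corr: np.ndarray, tol: float = 1e-10,
                               max_iter: int = 500) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation matrix.

    Higham's alternating projections between the PSD cone and the
    unit-diagonal affine set, in the Frobenius norm.
    """
    a = np.asarray(corr, dtype=float)
    y = a.copy()
    ds = np.zeros_like(a)
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh(r)
        x = (v * np.clip(w, 0.0, None)) @ v.T
        ds = x - r
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        if np.linalg.eigvalsh(y).min() > -tol and np.abs(y - x).max() < tol:
            break
    return (y + y.T) / 2.0


@dataclass(frozen=True)
class LFQCohortSpec:
    """Design of one synthetic donor cohort.

    ``mu``/``sigma`` are Ln(LFQ) means and SDs in canonical gene order
    (HBB, HBA1, HBD, HBM, HBG2, HBQ1); ``subunit_corr`` is the 6x6
    inter-subunit correlation target and ``aer_corr`` the six subunit-AER
    correlation targets.  ``stored_gamma_shift`` is added to the HBG2 mean
    of stored-unit samples.  ``psd_repair`` permits projecting a target
    joint correlation matrix that is not positive semidefinite (as printed
    summary tables often are) to the nearest valid one; with it off, a
    non-PSD target is an error.
    """

    n_fresh: int = 9
    n_stored: int = 6
    mu: tuple[float, ...] = (34.4, 34.0, 29.1, 25.7, 24.4, 23.3)
    sigma: tuple[float, ...] = (0.5, 0.4, 0.9, 1.1, 0.65, 1.1)
    subunit_corr: tuple[tuple[float, ...], ...] = tuple(
        tuple(row)
        for row in (
            (1.00, 0.82, 0.76, 0.25, 0.37, 0.42),
            (0.82, 1.00, 0.76, 0.07, 0.08, 0.46),
            (0.76, 0.76, 1.00, 0.63, 0.43, 0.39),
            (0.25, 0.07, 0.63, 1.00, 0.21, 0.54),
            (0.37, 0.08, 0.43, 0.21, 1.00, 0.26),
            (0.42, 0.46, 0.39, 0.54, 0.26, 1.00),
        )
    )
    aer_corr: tuple[float, ...] = (-0.606, -0.722, -0.687, 0.0, 0.0, 0.0)
    aer_mean: float = 1.56
    aer_sd: float = 0.10
    stored_gamma_shift: float = 2.3
    psd_repair: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_fresh < 0 or self.n_stored < 0:
            raise ParameterError("group sizes must be non-negative")
        if len(self.mu) != 6 or len(self.sigma) != 6 or len(self.aer_corr) != 6:
            raise ParameterError("mu, sigma and aer_corr must have 6 entries")
        if any(s <= 0 for s in self.sigma) or self.aer_sd <= 0:
            raise ParameterError("sigma and aer_sd must be positive")
        c = np.asarray(self.subunit_corr, dtype=float)
        if c.shape != (6, 6) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ParameterError(
                "subunit_corr must be a symmetric 6x6 matrix with unit diagonal"
            )
        if np.abs(np.asarray(self.aer_corr)).max() > 1:
            raise ParameterError("aer_corr entries must be in [-1, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_fresh + self.n_stored

    def joint_correlation(self) -> np.ndarray:
        """The 7x7 joint target (six subunits + AER), PSD-repaired if allowed."""
        c = np.eye(7)
        c[:6, :6] = np.asarray(self.subunit_corr, dtype=float)
        c[6, :6] = c[:6, 6] = np.asarray(self.aer_corr, dtype=float)
        eigmin = float(np.linalg.eigvalsh(c).min())
        if eigmin < -1e-10:
            if not self.psd_repair:
                raise ParameterError(
                    "joint subunit+AER correlation target is not positive "
                    f"semidefinite (smallest eigenvalue {eigmin:.4f}); enable "
                    "psd_repair to project to the nearest correlation matrix"
                )
            c = nearest_correlation_matrix(c)
        return c


def scale_counts(spec: LFQCohortSpec, n_total: int) -> LFQCohortSpec:
    """Rescale the cohort to ``n_total`` samples keeping the group ratio."""
    if n_total < 2:
        raise ParameterError("n_total must be >= 2")
    if spec.n_samples == 0:
        raise ParameterError("cannot scale a cohort with zero samples")
    frac_fresh = spec.n_fresh / spec.n_samples
    n_fresh = int(round(n_total * frac_fresh))
    return replace(spec, n_fresh=n_fresh, n_stored=n_total - n_fresh)


def generate_lfq_cohort(spec: LFQCohortSpec,
                        seed: int | None = None) -> tuple[LFQTable, pd.Series]:
    """Draw one cohort: an Ln(LFQ) table plus aligned per-sample AER values.

    Returns ``(table, aer)``.  Fresh samples are ids F01.. and stored S01..;
    the HBG2 (gamma) mean of stored samples is shifted by
    ``spec.stored_gamma_shift``.  Identical spec + seed reproduce the cohort
    bit for bit.
    """
    n = spec.n_samples
    if n < 2:
        raise ParameterError("cohort needs at least 2 samples")
    use_seed = seed if seed is not None else spec.seed
    rng = np.random.default_rng(use_seed)
    corr = spec.joint_correlation()
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))  # corr = root @ root.T
    z = rng.standard_normal((n, 7)) @ root.T

    sigma = np.asarray(spec.sigma)
    mu = np.asarray(spec.mu)
    values = mu + sigma * z[:, :6]
    aer_values = spec.aer_mean + spec.aer_sd * z[:, 6]

    groups = ["fresh"] * spec.n_fresh + ["stored"] * spec.n_stored
    ids = [f"F{i + 1:02d}" for i in range(spec.n_fresh)] + [
        f"S{i + 1:02d}" for i in range(spec.n_stored)
    ]
    gamma_ix = GENES.index("HBG2")
    values[spec.n_fresh:, gamma_ix] += spec.stored_gamma_shift

    data = pd.DataFrame(values, index=pd.Index(ids, name="sample_id"), columns=GENES)
    table = LFQTable(data=data, group=pd.Series(groups, index=data.index, name="group"))
    aer = pd.Series(aer_values, index=data.index, name="AER")
    return table, aer
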