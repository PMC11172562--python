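"""Correlation screen, group contrasts, normality and ratio statistics."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbcdeform import (
    InputError,
    LFQTable,
    ZeroVarianceError,
    compare_groups,
    correlation_matrix,
    deformability_screen,
    generate_lfq_cohort,
    normality_check,
    pearson,
    subunit_ratio,
)
from rbcdeform.hbstats import SCREEN_ORDER, holm_adjust, p_from_r, tier_from_p
from rbcdeform.lfq import GENES
from rbcdeform.synthlfq import LFQCohortSpec, scale_counts

from test_synthlfq import IDENTITY, null_spec, two_pass_corr


def brute_force_pearson(x, y):
    """Two-pass covariance oracle, no library calls."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(5.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-9

    @pytest.mark.parametrize("r,n,expected", [(-0.606, 15, 0.017), (-0.687, 15, 0.0047)])
    def test_printed_significance_values(self, r, n, expected):
        assert p_from_r(r, n) == pytest.approx(expected, abs=5e-4)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.normal(size=rng.integers(5, 40))
            y = rng.normal(size=x.size) + 0.5 * x
            res = pearson(x, y)
            assert abs(res.r - brute_force_pearson(list(x), list(y))) < 1e-12

    def test_p_monotone_in_r_and_n(self):
        rs = np.linspace(0.05, 0.95, 20)
        ps = [p_from_r(r, 15) for r in rs]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        ns = np.arange(5, 100, 5)
        ps_n = [p_from_r(0.4, n) for n in ns]
        assert all(a > b for a, b in zip(ps_n, ps_n[1:]))

    def test_pairwise_complete_n_reported(self):
        x = np.array([1.0, 2, 3, np.nan, 5, 6])
        y = np.array([1.1, 2.1, np.nan, 4, 5.2, 6.1])
        res = pearson(x, y)
        assert res.n == 4

    def test_degenerate_inputs(self):
        with pytest.raises(ZeroVarianceError):
            pearson([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(InputError):
            pearson([1.0, 2.0], [1.0, 2.0])

    def test_tier_convention(self):
        assert tier_from_p(0.0005) == "**"
        assert tier_from_p(0.001) == "**"
        assert tier_from_p(0.01) == "*"
        assert tier_from_p(0.05) == "ns"
        assert tier_from_p(0.5) == "ns"


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, study_preset):
        table, _ = generate_lfq_cohort(study_preset.cohort, seed=1)
        m = correlation_matrix(table)
        assert np.allclose(m.r, m.r.T)
        assert np.allclose(np.diag(m.r), 1.0)

    def test_preset_beta_alpha_recovered(self, study_preset):
        spec = scale_counts(study_preset.cohort, 2000)
        table, _ = generate_lfq_cohort(spec, seed=8)
        m = correlation_matrix(table)
        assert m.r.loc["HBB", "HBA1"] == pytest.approx(0.82, abs=0.05)

    def test_independent_columns_near_zero(self):
        table, _ = generate_lfq_cohort(null_spec(2000), seed=2)
        m = correlation_matrix(table)
        off = m.r.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.07


class TestDeformabilityScreen:
    def test_constant_aer_undefined(self, study_preset):
        table, aer = generate_lfq_cohort(study_preset.cohort, seed=0)
        with pytest.raises(ZeroVarianceError):
            deformability_screen(table, pd.Series(1.5, index=aer.index))

    def test_misaligned_ids_listed(self, study_preset):
        table, aer = generate_lfq_cohort(study_preset.cohort, seed=0)
        bad = aer.rename(index={"F01": "ghost"})
        with pytest.raises(InputError, match="F01"):
            deformability_screen(table, bad)

    def test_output_order_is_reporting_order(self, study_preset):
        table, aer = generate_lfq_cohort(study_preset.cohort, seed=0)
        results = deformability_screen(table, aer)
        assert [r.pair[0] for r in results] == list(SCREEN_ORDER)

    def test_alpha_target_recovered_at_large_n(self, study_preset):
        spec = scale_counts(study_preset.cohort, 2000)
        target = spec.joint_correlation()[6, GENES.index("HBA1")]
        table, aer = generate_lfq_cohort(spec, seed=6)
        res = next(r for r in deformability_screen(table, aer)
                   if r.pair[0] == "HBA1")
        assert res.r == pytest.approx(target, abs=0.05)
        assert abs(res.r - two_pass_corr(table.data["HBA1"], aer)) < 1e-12

    def test_majority_concordance_at_n300(self, study_preset):
        spec = scale_counts(study_preset.cohort, 300)
        hits = 0
        for seed in range(5):
            table, aer = generate_lfq_cohort(spec, seed=seed)
            sig = {r.pair[0] for r in deformability_screen(table, aer)
                   if r.p < 0.01}
            hits += sig == {"HBB", "HBA1", "HBD"}
        assert hits >= 3

    def test_holm_adjustment_is_conservative(self, study_preset):
        table, aer = generate_lfq_cohort(study_preset.cohort, seed=3)
        plain = deformability_screen(table, aer)
        adj = holm_adjust(plain)
        for a, b in zip(plain, adj):
            assert b.p >= a.p


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        vals = np.tile(np.array([[34.0], [35.0], [33.5]]), (2, 6))
        df = pd.DataFrame(vals, columns=GENES,
                          index=[f"S{i}" for i in range(6)])
        table = LFQTable(data=df, group=pd.Series(["fresh"] * 3 + ["stored"] * 3,
                                                  index=df.index))
        for comp in compare_groups(table):
            assert comp.p == pytest.approx(1.0)
            assert comp.test_name == "Welch t"

    def test_gamma_storage_shift_detected(self, study_preset):
        flagged = 0
        for seed in range(100):
            table, _ = generate_lfq_cohort(study_preset.cohort, seed=seed)
            comps = {c.gene: c for c in compare_groups(table)}
            flagged += comps["HBG2"].p < 0.05
        assert flagged >= 95

    def test_beta_type_one_error_calibrated(self, study_preset):
        # no shift on beta: ~5% false positives at alpha = 0.05
        flagged = 0
        n_rep = 400
        for seed in range(n_rep):
            table, _ = generate_lfq_cohort(study_preset.cohort, seed=seed)
            comps = {c.gene: c for c in compare_groups(table)}
            flagged += comps["HBB"].p < 0.05
        assert 0.02 <= flagged / n_rep <= 0.09

    def test_single_group_rejected(self, fresh_preset):
        table, _ = generate_lfq_cohort(fresh_preset.cohort, seed=0)
        with pytest.raises(InputError, match="groups"):
            compare_groups(table)

    def test_ranksum_alternative_recorded(self, study_preset):
        table, _ = generate_lfq_cohort(study_preset.cohort, seed=0)
        comps = compare_groups(table, test="ranksum")
        assert all(c.test_name == "Mann-Whitney U" for c in comps)


class TestNormality:
    def test_p_uniform_under_null(self):
        rng = np.random.default_rng(12)
        ps = [normality_check(rng.normal(size=100))[1] for _ in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-4, 0.3, 25), rng.normal(4, 0.3, 25)])
        _, p = normality_check(x)
        assert p < 0.01

    def test_degenerate_and_out_of_range(self):
        with pytest.raises(ZeroVarianceError):
            normality_check(np.ones(50))
        with pytest.raises(InputError):
            normality_check([1.0, 2.0])
        with pytest.raises(InputError):
            normality_check(np.random.default_rng(0).normal(size=2001))


class TestSubunitRatio:
    def test_identical_columns_ratio_one(self, study_preset):
        table, _ = generate_lfq_cohort(study_preset.cohort, seed=0)
        table.data["HBD"] = table.data["HBA1"]
        ratios, mean, sd, skipped = subunit_ratio(table, "HBD", "HBA1")
        assert np.allclose(ratios, 1.0)
        assert mean == pytest.approx(1.0)
        assert skipped == 0

    def test_closed_form_difference(self, study_preset):
        table, _ = generate_lfq_cohort(study_preset.cohort, seed=0)
        table.data.loc[:, "HBD"] = 30.0
        table.data.loc[:, "HBA1"] = 32.0
        _, mean, _, _ = subunit_ratio(table, "HBD", "HBA1")
        assert mean == pytest.approx(np.exp(-2.0))

    def test_lognormal_mean_identity(self):
        # delta/alpha Ln-difference: mean ratio obeys exp(mu_d + var_d/2)
        spec = replace(
            LFQCohortSpec(n_fresh=50_000, n_stored=0, subunit_corr=IDENTITY,
                          aer_corr=(0.0,) * 6, stored_gamma_shift=0.0),
            mu=(34.0, 34.0, 29.1, 25.7, 25.1, 23.3),
            sigma=(0.5, 0.4, 0.9, 1.1, 1.6, 1.1),
        )
        table, _ = generate_lfq_cohort(spec, seed=21)
        _, mean, _, _ = subunit_ratio(table, "HBD", "HBA1")
        var_d = 0.9**2 + 0.4**2  # independent columns
        expected = np.exp((29.1 - 34.0) + var_d / 2)
        assert mean == pytest.approx(expected, rel=0.05)

    def test_missing_samples_skipped_and_counted(self, study_preset):
        table, _ = generate_lfq_cohort(study_preset.cohort, seed=0)
        table.data.iloc[0, GENES.index("HBD")] = np.nan
        ratios, _, _, skipped = subunit_ratio(table, "HBD", "HBA1")
        assert skipped == 1
        assert len(ratios) == table.n_samples - 1
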