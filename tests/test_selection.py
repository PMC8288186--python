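import numpy as np
import pandas as pd
import pytest

from cohortsel import (binomial_sign_test, cohort_allele_freq, make_panel,
                       scan_panel, selection_coefficient,
                       simulate_allele_trajectory, trend_test,
                       trend_test_matrix)
from cohortsel.selection import control_scan, sample_matched_controls
from cohortsel.simulate import DEFAULT_COHORTS, SimulationConfig


def _cohort_study(rng, n_per_cohort, trajectory=None, p=0.5):
    """Birth years over the six default cohorts + dosages, optionally drawn
    from a planted per-year frequency trajectory."""
    years = np.concatenate([rng.integers(a, b + 1, n_per_cohort)
                            for a, b in DEFAULT_COHORTS])
    if trajectory is None:
        d = rng.binomial(2, p, len(years)).astype(float)
    else:
        d = rng.binomial(2, trajectory[years - 1940]).astype(float)
    return years, d


class TestCohortAlleleFreq:
    @pytest.mark.parametrize("dosages,expected", [
        ([1, 1, 1, 1], 0.5),
        ([2, 2, 2], 1.0),
        ([0, 1, 2, 2], 0.625),
    ])
    def test_arithmetic(self, dosages, expected):
        d = np.asarray(dosages, dtype=float)
        assert cohort_allele_freq(d, np.ones(len(d), bool)) == expected

    def test_missing_excluded_from_denominator(self):
        d = np.array([2.0, np.nan, 0.0, np.nan])
        assert cohort_allele_freq(d, np.ones(4, bool)) == 0.5

    def test_all_missing_is_nan(self):
        assert np.isnan(cohort_allele_freq(np.array([np.nan]), np.array([True])))


class TestTrendTest:
    def test_null_rejection_rate(self):
        rng = np.random.default_rng(0)
        years, _ = _cohort_study(rng, 300)
        mat = rng.binomial(2, 0.5, (len(years), 1000)).astype(float)
        res = trend_test_matrix(mat, years)
        rate = float((res["p"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(1)
        traj = simulate_allele_trajectory(0.375, 0.04, 29)  # slope 6e-4/yr
        years, d = _cohort_study(rng, 10_000, trajectory=traj)
        res = trend_test_matrix(d, years)
        slope, se = res["slope_per_year"].iloc[0], res["se"].iloc[0]
        assert abs(slope - 0.0006) < 2 * se

    def test_single_birth_year_errors(self):
        with pytest.raises(ValueError):
            trend_test(np.array([0.0, 1.0, 2.0]), np.array([1950, 1950, 1950]))

    def test_constant_dosage_flagged(self):
        slope, p = trend_test(np.ones(100), np.repeat([1941, 1961], 50))
        assert slope == 0.0 and np.isnan(p)

    def test_allele_flip_antisymmetry(self):
        rng = np.random.default_rng(2)
        traj = simulate_allele_trajectory(0.4, 0.05, 29)
        years, d = _cohort_study(rng, 1000, trajectory=traj)
        a = trend_test_matrix(d, years)
        b = trend_test_matrix(2.0 - d, years)
        assert a["slope_per_year"].iloc[0] == pytest.approx(
            -b["slope_per_year"].iloc[0], rel=1e-12)
        assert a["p"].iloc[0] == pytest.approx(b["p"].iloc[0], rel=1e-12)


class TestSelectionCoefficient:
    def test_zero_slope(self):
        assert selection_coefficient(0.0, 0.5) == 0.0

    def test_formula(self):
        assert selection_coefficient(0.001, 0.5, 25) == pytest.approx(0.05)

    @pytest.mark.parametrize("p0", [0.0, 1.0])
    def test_degenerate_p0(self, p0):
        with pytest.raises(ValueError):
            selection_coefficient(0.001, p0)

    def test_estimator_bias_shrinks_with_n(self):
        """Under the linearized generator, the s estimate tightens as n grows."""
        rng = np.random.default_rng(3)
        traj = simulate_allele_trajectory(0.4, 0.05, 29)
        errs = []
        for n_pc in (500, 8000):
            reps = []
            for _ in range(8):
                years, d = _cohort_study(rng, n_pc, trajectory=traj)
                res = trend_test_matrix(d, years)
                mid1 = 1942.0
                p0 = res["intercept"].iloc[0] + res["slope_per_year"].iloc[0] * mid1
                reps.append(selection_coefficient(res["slope_per_year"].iloc[0], p0))
            errs.append(abs(np.median(reps) - 0.05))
        assert errs[1] < errs[0]


class TestBinomialSignTest:
    @pytest.mark.parametrize("up,down,expected,tol", [
        (26, 6, 0.00054, 5e-6),
        (25, 5, 0.00032, 5e-6),
        (20, 4, 0.0015, 5e-5),
        (16, 16, 1.0, 0.0),
    ])
    def test_printed_values(self, up, down, expected, tol):
        assert binomial_sign_test(up, down) == pytest.approx(expected, abs=tol)

    def test_matches_scipy_binomtest(self):
        from scipy.stats import binomtest
        for up, down in [(26, 6), (7, 3), (1, 0), (10, 10)]:
            assert binomial_sign_test(up, down) == pytest.approx(
                binomtest(up, up + down, 0.5).pvalue, rel=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            binomial_sign_test(0, 0)


class TestMatchedControls:
    def _panel_and_pool(self, seed=4):
        rng = np.random.default_rng(seed)
        m = 10
        cfg = SimulationConfig(baseline_freqs=rng.uniform(0.2, 0.8, m),
                               s_true=np.zeros(m), u_true=np.zeros(m),
                               beta_afb=np.zeros(m), beta_neb=np.zeros(m),
                               beta_lifespan=np.zeros(m), pool_size=150, seed=seed)
        panel = make_panel(cfg)
        from cohortsel import simulate_control_pool
        return panel, simulate_control_pool(cfg, panel)

    def test_identical_pool_matches_trivially(self):
        panel, _ = self._panel_and_pool()
        pool = panel.copy()
        pool["snp_id"] = ["c" + s for s in pool["snp_id"]]
        sets = sample_matched_controls(panel, pool, n_sets=2, rng=0)
        assert all(len(set(s)) == len(panel) for s in sets)

    def test_tolerances_audited(self):
        panel, pool = self._panel_and_pool()
        sets = sample_matched_controls(panel, pool, n_sets=5, rng=1)
        for chosen in sets:
            assert np.all(np.abs(pool["baseline_freq"].to_numpy()[chosen]
                                 - panel["baseline_freq"]) <= 0.01)
            assert np.all(np.abs(pool["recomb_rate"].to_numpy()[chosen]
                                 - panel["recomb_rate"]) <= 0.05)

    def test_null_control_scan_calibrated(self):
        """On null data, significant-per-set ~= alpha*m, split near-symmetric."""
        rng = np.random.default_rng(5)
        panel, pool = self._panel_and_pool()
        years = np.concatenate([rng.integers(a, b + 1, 500)
                                for a, b in DEFAULT_COHORTS])
        sets = sample_matched_controls(panel, pool, n_sets=60, rng=2)
        summary = control_scan(pool, sets, years, rng=3)
        mean_sig = summary["n_significant"].mean()
        assert abs(mean_sig - 0.05 * len(panel)) < 0.35
        assert (summary["n_sig_increase"] + summary["n_sig_decrease"]
                == summary["n_significant"]).all()
        # symmetry over distinct sampled SNPs (sets share pool SNPs, so
        # pooled per-set counts are dependent trials)
        union = np.unique(np.concatenate(sets))
        pf = pool["baseline_freq"].to_numpy()[union]
        du = rng.binomial(2, pf[None, :], (len(years), len(union))).astype(float)
        from cohortsel import trend_test_matrix
        res = trend_test_matrix(du, years)
        sig = res["p"].to_numpy() < 0.05
        up = int((sig & (res["slope_per_year"].to_numpy() > 0)).sum())
        down = int((sig & (res["slope_per_year"].to_numpy() < 0)).sum())
        assert binomial_sign_test(up, down) > 0.01


class TestScanPanel:
    def test_empty_panel(self):
        est, summary = scan_panel(pd.DataFrame(columns=["snp_id"]),
                                  np.empty((10, 0)), np.repeat([1941, 1961], 5),
                                  DEFAULT_COHORTS)
        assert len(est) == 0 and summary.n_snps == 0

    def test_planted_26_up_6_down_recovers_sign_test(self):
        """Strong planted signals: 26 rising and 6 falling risk alleles give
        the expected direction counts and their exact binomial p."""
        rng = np.random.default_rng(6)
        m = 48
        s = np.zeros(m)
        s[:26], s[26:32] = 0.12, -0.12
        freqs = np.full(m, 0.5)
        years = np.concatenate([rng.integers(a, b + 1, 3000)
                                for a, b in DEFAULT_COHORTS])
        d = np.empty((len(years), m))
        for j in range(m):
            traj = simulate_allele_trajectory(freqs[j], s[j], 29)
            d[:, j] = rng.binomial(2, traj[years - 1940])
        panel = pd.DataFrame({"snp_id": [f"s{j}" for j in range(m)]})
        est, summary = scan_panel(panel, d, years, DEFAULT_COHORTS)
        assert summary.n_up == 26 and summary.n_down == 6
        assert summary.sign_test_p == pytest.approx(0.00054, abs=5e-6)
        # s estimates oriented with the slope
        sig = est[est["direction"] != "0"]
        assert ((sig["s"] > 0) == (sig["direction"] == "+")).all()

    def test_all_null_panel_few_significant(self):
        rng = np.random.default_rng(7)
        years = np.concatenate([rng.integers(a, b + 1, 400)
                                for a, b in DEFAULT_COHORTS])
        d = rng.binomial(2, 0.5, (len(years), 60)).astype(float)
        panel = pd.DataFrame({"snp_id": [f"s{j}" for j in range(60)]})
        est, summary = scan_panel(panel, d, years, DEFAULT_COHORTS)
        assert (est["trend_p"] < 0.05).sum() <= 8   # ~alpha*m before FDR
        assert summary.n_significant <= 1           # ~0 after FDR

    def test_per_cohort_frequencies_reported(self, null_dataset):
        ds, panel = null_dataset
        years = ds.phenotypes["birth_year"].to_numpy()
        est, _ = scan_panel(panel, ds.genotypes, years, DEFAULT_COHORTS)
        freq_cols = [f"freq_c{k}" for k in range(1, 7)]
        assert est[freq_cols].notna().all().all()
        assert ((est[freq_cols] >= 0) & (est[freq_cols] <= 1)).all().all()
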