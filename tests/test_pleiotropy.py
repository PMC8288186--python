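import numpy as np
import pandas as pd
import pytest

from cohortsel import (association_proportion_chisq, correlation_pvalue,
                       direction_consistency, group_t_test, lifespan_screen,
                       s_effect_correlation)


class TestLifespanScreen:
    def _dataset(self, beta=-0.8, n=20_000, seed=0):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, 0.4, (n, 6)).astype(float)
        ls_mother = 78 + beta * d[:, 0] + rng.normal(0, 10, n)
        ls_father = 72 + beta * d[:, 1] + rng.normal(0, 10, n)
        pheno = pd.DataFrame({"mother_lifespan": ls_mother,
                              "father_lifespan": ls_father})
        return d, pheno

    def test_planted_effects_flagged(self):
        d, pheno = self._dataset()
        table, flagged = lifespan_screen(d, pheno)
        assert flagged[0] and flagged[1]
        assert not flagged[2:].any()

    def test_null_flagged_fraction_near_zero(self):
        rng = np.random.default_rng(1)
        hits = 0
        for rep in range(10):
            d = rng.binomial(2, 0.5, (2000, 20)).astype(float)
            pheno = pd.DataFrame({
                "mother_lifespan": rng.normal(78, 10, 2000),
                "father_lifespan": rng.normal(72, 10, 2000)})
            _, flagged = lifespan_screen(d, pheno)
            hits += flagged.sum()
        # BH on a null family rejects with probability ~alpha per family:
        # expect ~1 flagged SNP over 10 families of 20; allow 3x that
        assert hits / 200 <= 0.03

    def test_mothers_only_degraded_mode(self):
        d, pheno = self._dataset(n=20_000)
        pheno["father_lifespan"] = np.nan
        table, flagged = lifespan_screen(d, pheno)
        assert flagged[0] and not flagged[1]
        assert "father_beta" not in table.columns

    def test_no_lifespan_data_warns(self):
        d = np.random.default_rng(2).binomial(2, 0.5, (100, 3)).astype(float)
        with pytest.warns(UserWarning):
            _, flagged = lifespan_screen(d, pd.DataFrame({"x": np.zeros(100)}))
        assert not flagged.any()


class TestDirectionConsistency:
    def _frames(self, direction, afb_beta=np.nan, neb_beta=np.nan,
                afb_sig=False, neb_sig=False):
        sel = pd.DataFrame({"snp_id": ["a"], "direction": [direction], "s": [0.05]})
        rep = pd.DataFrame({"snp_id": ["a"],
                            "afb_beta": [afb_beta], "afb_q": [0.01],
                            "afb_significant": [afb_sig],
                            "neb_beta": [neb_beta], "neb_q": [0.01],
                            "neb_significant": [neb_sig]})
        return sel, rep

    def test_positive_selection_lower_afb_consistent(self):
        table, _ = direction_consistency(*self._frames("+", afb_beta=-0.2, afb_sig=True))
        assert table.loc[table["trait"] == "afb", "consistent"].iloc[0] is True

    def test_positive_selection_lower_neb_inconsistent(self):
        table, _ = direction_consistency(*self._frames("+", neb_beta=-0.1, neb_sig=True))
        assert table.loc[table["trait"] == "neb", "consistent"].iloc[0] is False

    def test_negative_selection_mirrors(self):
        table, _ = direction_consistency(*self._frames("-", afb_beta=0.2, afb_sig=True))
        assert table.loc[table["trait"] == "afb", "consistent"].iloc[0] is True

    def test_nonsignificant_traits_undefined(self):
        table, p = direction_consistency(*self._frames("+", afb_beta=-0.2))
        assert table["consistent"].isna().all() and np.isnan(p)

    def test_antisymmetry(self):
        """Negating both the selection direction and the trait effect
        preserves the consistency verdict."""
        t1, _ = direction_consistency(*self._frames("+", neb_beta=0.1, neb_sig=True))
        t2, _ = direction_consistency(*self._frames("-", neb_beta=-0.1, neb_sig=True))
        assert (t1.loc[t1["trait"] == "neb", "consistent"].iloc[0]
                == t2.loc[t2["trait"] == "neb", "consistent"].iloc[0])

    def test_fifteen_consistent_binomial(self):
        sel = pd.DataFrame({"snp_id": [f"s{i}" for i in range(15)],
                            "direction": ["+"] * 15, "s": [0.05] * 15})
        rep = pd.DataFrame({"snp_id": sel["snp_id"],
                            "afb_beta": [-0.2] * 15, "afb_q": [0.01] * 15,
                            "afb_significant": [True] * 15,
                            "neb_beta": [np.nan] * 15, "neb_q": [1.0] * 15,
                            "neb_significant": [False] * 15})
        _, p = direction_consistency(sel, rep)
        assert p == pytest.approx(2 * 0.5 ** 15, rel=1e-9)
        assert p < 1e-4


class TestCorrelation:
    def test_printed_afb_value(self):
        # the published r is rounded, so the reported 0.049 differs in the
        # third decimal from the t-transform of r=-0.67 exactly (0.0483)
        assert correlation_pvalue(-0.67, 9) == pytest.approx(0.049, abs=0.0015)

    def test_zero_r_gives_p_one(self):
        assert correlation_pvalue(0.0, 20) == pytest.approx(1.0)

    def test_matches_scipy_pearsonr(self):
        from scipy.stats import pearsonr
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 15)
        y = 0.5 * x + rng.normal(0, 1, 15)
        r, p, n = s_effect_correlation(x, y)
        r_sp, p_sp = pearsonr(x, y)
        assert r == pytest.approx(r_sp, rel=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-9)

    def test_permutation_cross_check(self):
        """t-transform p agrees with a permutation p within Monte Carlo error."""
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 12)
        y = 0.6 * x + rng.normal(0, 1, 12)
        r, p, n = s_effect_correlation(x, y)
        perm_r = np.empty(10_000)
        for i in range(10_000):
            perm_r[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = float(np.mean(np.abs(perm_r) >= abs(r)))
        assert abs(p - p_perm) < 3 * np.sqrt(p * (1 - p) / 10_000) + 0.005

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            s_effect_correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            s_effect_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupTTest:
    def test_identical_groups(self):
        x = np.arange(10.0)
        res = group_t_test(x, x)
        assert res["t"] == pytest.approx(0.0) and res["p"] == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        """AFB shifted +0.5 yr in one group, n=10,000/group, sd=4: the Welch
        test power at alpha=0.001 is essentially 1 (effect/se ~= 8.8)."""
        rng = np.random.default_rng(5)
        a = rng.normal(25.5, 4, 10_000)
        b = rng.normal(25.0, 4, 10_000)
        res = group_t_test(a, b)
        assert res["p"] < 1e-3
        assert res["mean_a"] - res["mean_b"] == pytest.approx(0.5, abs=0.2)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 50), rng.normal(0.3, 1, 60)
        r1, r2 = group_t_test(a, b), group_t_test(b, a)
        assert r1["p"] == pytest.approx(r2["p"], rel=1e-12)
        assert r1["mean_a"] - r1["mean_b"] == pytest.approx(
            -(r2["mean_a"] - r2["mean_b"]), rel=1e-12)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            group_t_test([1.0], [1.0, 2.0])


class TestProportionChisq:
    def test_printed_contrast(self):
        chi2, p = association_proportion_chisq(15, 30, 3, 30)
        assert chi2 == pytest.approx(11.4, abs=0.05)
        assert p == pytest.approx(0.0007, abs=5e-5)

    def test_equal_proportions(self):
        chi2, p = association_proportion_chisq(5, 10, 5, 10)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_direct_formula_oracle(self):
        k1, n1, k2, n2 = 8, 10, 2, 10
        chi2, _ = association_proportion_chisq(k1, n1, k2, n2)
        obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
        row, col = obs.sum(1), obs.sum(0)
        exp = np.outer(row, col) / obs.sum()
        assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)

    def test_swap_invariances(self):
        base, _ = association_proportion_chisq(15, 30, 3, 30)
        swapped_groups, _ = association_proportion_chisq(3, 30, 15, 30)
        swapped_outcome, _ = association_proportion_chisq(15, 30, 27, 30)
        assert base == pytest.approx(swapped_groups, rel=1e-12)
        # swapping success/failure within one group changes the table; the
        # invariant swap is success<->failure in both groups
        both, _ = association_proportion_chisq(30 - 15, 30, 30 - 3, 30)
        assert base == pytest.approx(both, rel=1e-12)

    def test_zero_expected_cell(self):
        with pytest.raises(ValueError):
            association_proportion_chisq(0, 10, 0, 10)
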