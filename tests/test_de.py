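import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from lfqde import de
from lfqde.de import (DEError, EBHyperparams, bh_adjust, classify_testability,
                      effect_and_variance, fit_eb_hyperparams, moderated_t,
                      run_contrast)
from lfqde.simulate import SimConfig, generate_dataset

from conftest import make_matrix


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_stepped_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_fatal(self):
        with pytest.raises(DEError):
            bh_adjust([0.5, 1.2])

    def test_matches_double_loop_bruteforce(self, rng):
        p = rng.random(1000)
        q = bh_adjust(p)
        order = np.argsort(p)
        m = len(p)
        for i in [0, 1, 17, 500, 998, 999]:  # spot-check ranks
            rank = np.nonzero(order == i)[0][0] + 1
            expected = min(min(p[j] * m / (np.nonzero(order == j)[0][0] + 1)
                               for j in order[rank - 1:]), 1.0)
            assert q[i] == pytest.approx(expected)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_q_at_least_p(self, rng):
        p = rng.random(300)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestEffectAndVariance:
    def matrix(self, a_vals, b_vals):
        vals = np.array([list(a_vals) + list(b_vals)], dtype=float)
        n = len(a_vals)
        return make_matrix(vals, ["A"] * n + ["B"] * len(b_vals),
                           [f"c{i + 1}" for i in range(n)]
                           + [f"c{i + 1}" for i in range(len(b_vals))])

    def test_constant_paired_differences(self):
        sm = self.matrix([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        fc, s2, dg, c = effect_and_variance(sm, "P000", ("A", "B"), True,
                                            ["c1", "c2", "c3"])
        assert (fc, s2, dg, c) == (1.0, 0.0, 2, pytest.approx(1 / 3))

    def test_identical_unpaired_groups(self):
        sm = self.matrix([5.0, 7.0], [5.0, 7.0])
        fc, s2, dg, c = effect_and_variance(
            sm, "P000", ("A", "B"), False, list(sm.values.columns))
        assert fc == 0.0
        assert dg == 2
        assert c == pytest.approx(1.0)

    def test_matches_hand_arithmetic(self, rng):
        a = rng.normal(10, 1, 3)
        b = rng.normal(9, 1, 3)
        sm = self.matrix(a, b)
        fc, s2, dg, c = effect_and_variance(sm, "P000", ("A", "B"), True,
                                            ["c1", "c2", "c3"])
        d = a - b
        assert fc == pytest.approx(d.mean(), abs=1e-12)
        assert s2 == pytest.approx(((d - d.mean()) ** 2).sum() / 2, abs=1e-12)
        fc_u, s2_u, dg_u, c_u = effect_and_variance(
            sm, "P000", ("A", "B"), False, list(sm.values.columns))
        assert fc_u == pytest.approx(a.mean() - b.mean(), abs=1e-12)
        pooled = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 4
        assert s2_u == pytest.approx(pooled, abs=1e-12)
        assert dg_u == 4 and c_u == pytest.approx(2 / 3)


class TestFitEBHyperparams:
    def test_identical_variances_give_complete_shrinkage(self):
        hyper = fit_eb_hyperparams(np.full(50, 0.7), np.full(50, 2.0))
        assert np.isinf(hyper.d0)
        # with d0 = inf every moderated variance equals s0_sq
        _, p = moderated_t(np.zeros(3), np.full(3, 0.7), np.full(3, 2.0),
                           np.full(3, 1 / 3), hyper)
        np.testing.assert_allclose(p, 1.0)

    def test_parameter_recovery_from_scaled_chi2(self):
        rng = np.random.default_rng(42)
        d0_true, s0_true, G, dg = 4.0, 1.0, 5000, 2
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, G)
        s2 = sigma2 * rng.chisquare(dg, G) / dg
        hyper = fit_eb_hyperparams(s2, np.full(G, float(dg)))
        assert hyper.d0 == pytest.approx(d0_true, rel=0.25)
        assert hyper.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_null_p_values_uniform(self):
        # moderated p-values on pure-null data are approximately uniform
        rng = np.random.default_rng(7)
        d0_true, s0_true, G, n = 6.0, 0.5, 2000, 3
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, G)
        x = rng.normal(0, np.sqrt(sigma2)[:, None], size=(G, n))
        fc = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        dg = np.full(G, n - 1.0)
        hyper = fit_eb_hyperparams(s2, dg)
        _, p = moderated_t(fc, s2, dg, np.full(G, 1 / n), hyper)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_zero_variances_floored(self):
        s2 = np.concatenate([np.zeros(5), np.full(20, 1.0)])
        hyper = fit_eb_hyperparams(s2, np.full(25, 2.0))
        assert np.isfinite(hyper.s0_sq) and hyper.s0_sq > 0


class TestModeratedT:
    def test_small_d0_limit_is_ordinary_t(self):
        fc, s2, dg, c = 1.2, 0.4, 4.0, 1 / 3
        hyper = EBHyperparams(d0=1e-9, s0_sq=5.0)
        t, p = moderated_t([fc], [s2], [dg], [c], hyper)
        t_ord = fc / math.sqrt(s2 * c)
        assert t[0] == pytest.approx(t_ord, rel=1e-6)
        assert p[0] == pytest.approx(2 * stats.t.sf(abs(t_ord), dg), rel=1e-4)

    def test_zero_effect_gives_p_one(self):
        hyper = EBHyperparams(d0=4.0, s0_sq=0.5)
        t, p = moderated_t([0.0], [0.25], [2.0], [1 / 3], hyper)
        assert t[0] == 0.0 and p[0] == 1.0

    def test_p_matches_numeric_integration_of_t_density(self):
        # toy case: log2fc=1, sg_sq=0.25, dg=2, d0=4, s0_sq=0.5, c=1/3
        hyper = EBHyperparams(d0=4.0, s0_sq=0.5)
        t, p = moderated_t([1.0], [0.25], [2.0], [1 / 3], hyper)
        df = 6.0
        s2_tilde = (4 * 0.5 + 2 * 0.25) / 6
        t_expect = 1.0 / math.sqrt(s2_tilde / 3)
        assert t[0] == pytest.approx(t_expect)

        def density(x):
            norm = special.gamma((df + 1) / 2) / (
                math.sqrt(df * math.pi) * special.gamma(df / 2))
            return norm * (1 + x * x / df) ** (-(df + 1) / 2)

        tail, _ = integrate.quad(density, t_expect, np.inf)
        assert p[0] == pytest.approx(2 * tail, rel=1e-8)

    def test_monotone_in_effect_and_variance(self):
        hyper = EBHyperparams(d0=4.0, s0_sq=0.5)
        fcs = np.array([0.1, 0.5, 1.0, 2.0])
        t1, _ = moderated_t(fcs, np.full(4, 0.3), np.full(4, 2.0),
                            np.full(4, 1 / 3), hyper)
        assert (np.diff(t1) > 0).all()
        s2s = np.array([0.1, 0.5, 1.0, 3.0])
        t2, _ = moderated_t(np.ones(4), s2s, np.full(4, 2.0),
                            np.full(4, 1 / 3), hyper)
        assert (np.diff(np.abs(t2)) < 0).all()

    def test_limits_of_shrinkage(self):
        s2 = np.array([0.1, 1.0, 4.0])
        dg = np.full(3, 2.0)
        big = EBHyperparams(d0=np.inf, s0_sq=0.5)
        t_inf, _ = moderated_t(np.ones(3), s2, dg, np.full(3, 1 / 3), big)
        np.testing.assert_allclose(t_inf, t_inf[0])  # all variances -> s0


class TestClassifyTestability:
    def matrix(self, det_a, det_b):
        det = np.array([list(det_a) + list(det_b)])
        return make_matrix(np.ones((1, 6)), ["A"] * 3 + ["B"] * 3,
                           ["c1", "c2", "c3"] * 2, detected=det)

    def test_selective_pattern(self):
        sm = self.matrix([True] * 3, [False] * 3)
        out = classify_testability(sm, ("A", "B"), paired=True)
        assert out.loc["P000", "status"] == "selective_in_A"

    def test_complete_case(self):
        sm = self.matrix([True] * 3, [True] * 3)
        out = classify_testability(sm, ("A", "B"), paired=True)
        assert out.loc["P000", "status"] == "tested"
        assert out.loc["P000", "tier"] == "complete"
        assert out.loc["P000", "usable"] == ["c1", "c2", "c3"]

    def test_single_shared_pair_not_testable(self):
        # detected cultures {1,2} in A and {2,3} in B -> only pair c2 usable
        sm = self.matrix([True, True, False], [False, True, True])
        out = classify_testability(sm, ("A", "B"), paired=True)
        assert out.loc["P000", "status"] == "not_testable"
        assert out.loc["P000", "usable"] == ["c2"]

    def test_partial_tier_excludes_unpaired_cultures(self):
        sm = self.matrix([True, True, True], [True, True, False])
        out = classify_testability(sm, ("A", "B"), paired=True)
        assert out.loc["P000", "status"] == "tested"
        assert out.loc["P000", "tier"] == "partial"
        assert out.loc["P000", "usable"] == ["c1", "c2"]

    def test_unknown_condition_fatal(self):
        sm = self.matrix([True] * 3, [True] * 3)
        with pytest.raises(DEError, match="unknown condition"):
            classify_testability(sm, ("A", "Z"), paired=False)

    def test_every_protein_gets_exactly_one_status(self, rng):
        det = rng.random((40, 6)) < 0.6
        sm = make_matrix(np.ones((40, 6)), ["A"] * 3 + ["B"] * 3,
                         ["c1", "c2", "c3"] * 2, detected=det)
        out = classify_testability(sm, ("A", "B"), paired=True)
        assert len(out) == 40
        valid = {"tested", "not_testable", "selective_in_A", "selective_in_B"}
        assert set(out["status"]) <= valid
        # tiers partition the tested set
        tested = out[out["status"] == "tested"]
        assert tested["tier"].isin(["complete", "partial"]).all()
        assert out.loc[out["status"] != "tested", "tier"].isna().all()


class TestRunContrast:
    def test_no_missingness_single_tier(self, rng):
        vals = rng.normal(20, 2, size=(30, 6))
        sm = make_matrix(vals, ["A"] * 3 + ["B"] * 3, ["c1", "c2", "c3"] * 2)
        res = run_contrast(sm, ("A", "B"), paired=True)
        assert (res["status"] == "tested").all()
        assert (res["tier"] == "complete").all()

    def test_selective_protein_passes_through_without_p(self, rng):
        vals = np.vstack([rng.normal(20, 1, size=(1, 6)),
                          [[18, 19, 20, 10, 10, 10]],
                          rng.normal(21, 1, size=(28, 6))])
        det = np.ones((30, 6), dtype=bool)
        det[1, 3:] = False
        sm = make_matrix(vals, ["A"] * 3 + ["B"] * 3, ["c1", "c2", "c3"] * 2,
                         detected=det)
        res = run_contrast(sm, ("A", "B"), paired=True)
        assert res.iloc[1]["status"] == "selective_in_A"
        assert np.isnan(res.iloc[1]["p"])
        assert res.iloc[1]["log2fc"] > 0

    def test_true_positives_enriched_among_calls(self):
        cfg = SimConfig(seed=1, n_proteins=800)
        table, design, _, truth = generate_dataset(cfg)
        from lfqde.preprocess import preprocess
        sm = preprocess(table, design)
        res = run_contrast(sm, ("Th17", "Th0"), paired=True)
        tested = res[res["status"] == "tested"]
        true_fc = truth.true_log2fc(("Th17", "Th0")).loc[tested.index]
        called = tested["q"] < 0.05
        assert called.sum() > 10
        frac_de_called = (true_fc[called] != 0).mean()
        frac_de_overall = (true_fc != 0).mean()
        assert frac_de_called > 3 * frac_de_overall


def test_moderated_t_null_matches_t_distribution():
    """On null data the moderated t follows Student t with d0+dg df."""
    rng = np.random.default_rng(11)
    G, n = 2000, 3
    sigma2 = 0.5 * 6 / rng.chisquare(6.0, G)
    x = rng.normal(0, np.sqrt(sigma2)[:, None], size=(G, n))
    s2 = x.var(axis=1, ddof=1)
    dg = np.full(G, n - 1.0)
    hyper = fit_eb_hyperparams(s2, dg)
    t, _ = moderated_t(x.mean(axis=1), s2, dg, np.full(G, 1 / n), hyper)
    ks = stats.kstest(t, stats.t(df=hyper.d0 + n - 1).cdf)
    assert ks.pvalue > 0.01
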