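import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from relapse_delta.matrix_io import ExpressionMatrix, MatrixIOError
from relapse_delta.survival import (
    MetageneSet,
    association_tests,
    build_metagene,
    cox_fit,
    kaplan_scan,
    km_estimate,
    logrank_test,
    two_group_logrank,
)


def _records(times, events, index=None, **covs):
    df = pd.DataFrame({"time": times, "event": events, **covs})
    if index is not None:
        df.index = index
    return df


class TestKaplanMeier:
    def test_single_event(self):
        km = km_estimate(_records([5.0], [1]))
        assert km[km["time"] == 5.0]["survival"].iloc[0] == 0.0
        assert km[km["time"] < 5.0]["survival"].iloc[0] == 1.0

    def test_all_censored_flat_curve(self):
        km = km_estimate(_records([1.0, 2.0, 3.0], [0, 0, 0]))
        assert (km["survival"] == 1.0).all()

    def test_matches_hand_computed_product_limit(self):
        """10-record worked example against an independent product-limit loop."""
        times = [1, 2, 2, 3, 4, 4, 5, 6, 7, 8]
        events = [1, 1, 0, 1, 1, 1, 0, 1, 0, 1]
        km = km_estimate(_records(times, events))
        # independent oracle
        s = 1.0
        oracle = {}
        records = sorted(zip(times, events))
        distinct = sorted({t for t, e in records if e == 1})
        for t in distinct:
            n_at_risk = sum(1 for tt, _ in records if tt >= t)
            d = sum(1 for tt, e in records if tt == t and e == 1)
            s *= 1 - d / n_at_risk
            oracle[t] = s
        for t, s_exp in oracle.items():
            got = km[km["time"] == t]["survival"].iloc[0]
            assert got == pytest.approx(s_exp, abs=1e-12)

    def test_record_order_invariance(self, rng):
        times = rng.exponential(10, 30)
        events = rng.integers(0, 2, 30)
        km1 = km_estimate(_records(times, events))
        perm = rng.permutation(30)
        km2 = km_estimate(_records(times[perm], events[perm]))
        pd.testing.assert_frame_equal(km1, km2)

    def test_negative_time_rejected(self):
        with pytest.raises(MatrixIOError):
            km_estimate(_records([-1.0], [1]))


class TestLogrank:
    def _example(self):
        times = [2, 3, 3, 5, 6, 7, 8, 9, 10, 11, 12, 13]
        events = [1, 1, 0, 1, 1, 1, 0, 1, 1, 0, 1, 1]
        groups = ["A"] * 6 + ["B"] * 6
        return _records(times, events), pd.Series(groups)

    def test_matches_brute_force_risk_table(self):
        rec, groups = self._example()
        res = logrank_test(rec, groups)
        chi2, p, _ = two_group_logrank(
            rec["time"].to_numpy(float),
            rec["event"].to_numpy(int),
            (groups == "A").to_numpy(),
        )
        assert res["chi2"] == pytest.approx(chi2, abs=1e-8)
        assert res["p"] == pytest.approx(p, abs=1e-8)
        assert res["df"] == 1

    def test_label_swap_invariance(self):
        rec, groups = self._example()
        res1 = logrank_test(rec, groups)
        res2 = logrank_test(rec, groups.map({"A": "B", "B": "A"}))
        assert res1["chi2"] == pytest.approx(res2["chi2"])

    def test_duplicated_groups_give_zero(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        res = logrank_test(_records(times, events), pd.Series(list("AAAABBBB")))
        assert res["chi2"] == pytest.approx(0.0, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(MatrixIOError):
            logrank_test(_records([1, 2], [1, 1]), pd.Series(["A", "A"]))

    def test_internal_statistic_agrees_with_lifelines(self, rng):
        """Dual route: the scan's fast log-rank vs the lifelines statistic."""
        from lifelines.statistics import multivariate_logrank_test

        for _ in range(10):
            n = 40
            t = rng.exponential(10, n).round(1)  # induce ties
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n).astype(bool)
            if e.sum() == 0 or g.all() or not g.any():
                continue
            chi2, p, _ = two_group_logrank(t, e, g)
            ref = multivariate_logrank_test(t, g, e)
            assert chi2 == pytest.approx(float(ref.test_statistic), abs=1e-8)


class TestKaplanScan:
    def test_constant_expression_flagged(self):
        rec = _records(list(range(1, 13)), [1] * 12, index=[f"s{i}" for i in range(12)])
        expr = pd.Series(np.ones(12), index=rec.index, name="flat")
        res = kaplan_scan(expr, rec)
        assert not res.valid

    def test_monotone_transform_invariance(self, rng):
        n = 40
        idx = [f"s{i}" for i in range(n)]
        rec = _records(rng.exponential(10, n), rng.integers(0, 2, n), index=idx)
        expr = pd.Series(rng.normal(size=n), index=idx, name="g")
        r1 = kaplan_scan(expr, rec)
        r2 = kaplan_scan(np.exp(expr * 3), rec)
        assert r1.p_raw == pytest.approx(r2.p_raw, abs=1e-12)
        assert r1.n_cutoffs_tested == r2.n_cutoffs_tested
        assert r1.direction == r2.direction

    def test_bonferroni_identity(self, rng):
        n = 30
        idx = [f"s{i}" for i in range(n)]
        rec = _records(rng.exponential(10, n), rng.integers(0, 2, n), index=idx)
        expr = pd.Series(rng.normal(size=n), index=idx, name="g")
        res = kaplan_scan(expr, rec)
        assert res.p_bonferroni == pytest.approx(
            min(1.0, res.p_raw * res.n_cutoffs_tested)
        )

    def test_null_calibration(self):
        """Corrected type-I error of the scan stays at or below nominal."""
        rng = np.random.default_rng(42)
        n, reps, alpha = 60, 200, 0.05
        hits = 0
        for _ in range(reps):
            idx = [f"s{i}" for i in range(n)]
            rec = _records(
                rng.exponential(10, n), rng.integers(0, 2, n), index=idx
            )
            expr = pd.Series(rng.normal(size=n), index=idx, name="g")
            res = kaplan_scan(expr, rec)
            if res.valid and res.p_bonferroni < alpha:
                hits += 1
        # Bonferroni is conservative: rate must not exceed alpha + MC error
        assert hits / reps <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_power_for_programmed_hazard_gene(self):
        """logHR 0.8 per SD recovered with corrected p < 0.05 at n=196."""
        rng = np.random.default_rng(5)
        n, reps, hits = 196, 20, 0
        for _ in range(reps):
            idx = [f"s{i}" for i in range(n)]
            x = rng.normal(size=n)
            t = rng.exponential(36 * np.exp(-0.8 * x))
            c = rng.uniform(0, 120, n)
            rec = _records(np.minimum(t, c), (t <= c).astype(int), index=idx)
            expr = pd.Series(x, index=idx, name="g")
            res = kaplan_scan(expr, rec)
            if res.valid and res.p_bonferroni < 0.05 and res.direction == 1:
                hits += 1
        assert hits / reps >= 0.8


class TestMetagene:
    def test_no_significant_scans_empty_sets(self, rng):
        n = 30
        idx = [f"s{i}" for i in range(n)]
        rec = _records(rng.exponential(10, n), rng.integers(0, 2, n), index=idx)
        mat = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(10, n)),
                index=[f"g{i}" for i in range(10)],
                columns=idx,
            ),
            scale="log2rpkm",
        )
        unfav, fav, _ = build_metagene(mat, rec, ["g0", "g1"], ["g2", "g3"])
        assert unfav.genes == [] and fav.genes == []

    def test_single_gene_score_is_z_score(self, rng):
        vals = rng.normal(size=(1, 12))
        mat = ExpressionMatrix(
            pd.DataFrame(vals, index=["gX"], columns=[f"s{i}" for i in range(12)]),
            scale="log2rpkm",
        )
        score = MetageneSet("unfavorable", ["gX"]).score(mat)
        z = (vals[0] - vals[0].mean()) / vals[0].std(ddof=1)
        np.testing.assert_allclose(score.to_numpy(), z, atol=1e-12)

    def test_unfavorable_score_positive_cox_beta(self):
        """Programmed risk genes: higher metagene score => fitted beta > 0."""
        rng = np.random.default_rng(9)
        n, n_genes = 196, 5
        idx = [f"s{i}" for i in range(n)]
        latent = rng.normal(size=n)
        expr = latent[None, :] + rng.normal(0, 0.5, size=(n_genes, n))
        mat = ExpressionMatrix(
            pd.DataFrame(expr, index=[f"g{i}" for i in range(n_genes)], columns=idx),
            scale="log2rpkm",
        )
        t = rng.exponential(36 * np.exp(-0.8 * latent))
        c = rng.uniform(0, 120, n)
        rec = _records(np.minimum(t, c), (t <= c).astype(int), index=idx)
        mset = MetageneSet("unfavorable", [f"g{i}" for i in range(n_genes)])
        rec2 = rec.copy()
        rec2["score"] = mset.score(mat)
        fit = cox_fit(rec2, ["score"])
        assert fit.loc["score", "beta"] > 0
        assert fit.loc["score", "p"] < 0.01


def efron_partial_loglik(beta, times, events, x):
    """Independent Efron-tie partial log-likelihood (brute-force risk sets)."""
    ll = 0.0
    for t in sorted({tt for tt, e in zip(times, events) if e == 1}):
        D = [i for i in range(len(times)) if times[i] == t and events[i] == 1]
        R = [i for i in range(len(times)) if times[i] >= t]
        sum_risk = sum(np.exp(beta * x[i]) for i in R)
        sum_tie = sum(np.exp(beta * x[i]) for i in D)
        d = len(D)
        ll += beta * sum(x[i] for i in D)
        for ell in range(d):
            ll -= np.log(sum_risk - ell / d * sum_tie)
    return ll


class TestCox:
    def test_identical_groups_beta_zero(self):
        times = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        events = [1, 1, 0, 1, 1, 1, 1, 0, 1, 1]
        x = [0.0] * 5 + [1.0] * 5
        fit = cox_fit(_records(times, events, arm=x))
        assert abs(fit.loc["arm", "beta"]) < 1e-6

    def test_matches_efron_oracle_on_tied_example(self):
        """8-record tied example: fitted beta maximizes the brute-force
        Efron partial likelihood."""
        times = np.array([2.0, 2.0, 3.0, 3.0, 5.0, 5.0, 7.0, 9.0])
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        fit = cox_fit(_records(times, events, arm=x))
        beta_hat = fit.loc["arm", "beta"]
        res = optimize.minimize_scalar(
            lambda b: -efron_partial_loglik(b, times, events, x), bounds=(-5, 5), method="bounded"
        )
        assert beta_hat == pytest.approx(res.x, abs=1e-4)
        assert fit.attrs["loglik"] == pytest.approx(
            efron_partial_loglik(beta_hat, times, events, x), abs=1e-6
        )

    def test_hr_recovery_two_arm(self):
        """True HR=2 at n=400: mean estimate within 10% over seeds."""
        hrs = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            x = rng.binomial(1, 0.5, 400).astype(float)
            t = rng.exponential(np.exp(-np.log(2.0) * x))
            c = rng.uniform(0, 3, 400)
            fit = cox_fit(
                _records(np.minimum(t, c), (t <= c).astype(int), arm=x)
            )
            hrs.append(fit.loc["arm", "HR"])
        assert 1.8 <= np.mean(hrs) <= 2.2

    def test_group_swap_flips_beta(self):
        rng = np.random.default_rng(3)
        x = rng.binomial(1, 0.5, 60).astype(float)
        t = rng.exponential(np.exp(-0.7 * x))
        rec1 = _records(t, np.ones(60, dtype=int), arm=x)
        rec2 = _records(t, np.ones(60, dtype=int), arm=1.0 - x)
        f1, f2 = cox_fit(rec1), cox_fit(rec2)
        assert f1.loc["arm", "beta"] == pytest.approx(-f2.loc["arm", "beta"], abs=1e-6)

    def test_separation_raises(self):
        # perfectly separating covariate: monotone likelihood
        times = np.concatenate([np.arange(1, 11), np.arange(100, 110)]).astype(float)
        events = np.ones(20, dtype=int)
        x = np.array([1.0] * 10 + [0.0] * 10)
        with pytest.raises(MatrixIOError):
            cox_fit(_records(times, events, arm=x))


class TestAssociations:
    def test_independent_table_p_one(self):
        df = pd.DataFrame(
            {
                "f1": ["a"] * 20 + ["b"] * 20,
                "f2": (["x"] * 10 + ["y"] * 10) * 2,
            }
        )
        res = association_tests(df, [("f1", "f2")])
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_fisher_matches_enumeration(self):
        """Fisher on [[8,2],[1,5]] vs exhaustive hypergeometric enumeration."""
        table = np.array([[8, 2], [1, 5]])
        df = pd.DataFrame(
            {
                "f1": ["a"] * 10 + ["b"] * 6,
                "f2": ["x"] * 8 + ["y"] * 2 + ["x"] * 1 + ["y"] * 5,
            }
        )
        res = association_tests(df, [("f1", "f2")])
        # enumerate all tables with the same margins
        row1, col1, n = 10, 9, 16
        probs = {}
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
            probs[k] = stats.hypergeom.pmf(k, n, row1, col1)
        p_obs = probs[8]
        p_oracle = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        assert res.loc[0, "method"] == "fisher"
        assert res.loc[0, "p"] == pytest.approx(p_oracle, abs=1e-10)

    def test_transpose_symmetry(self, rng):
        df = pd.DataFrame(
            {
                "f1": rng.choice(["a", "b"], 60),
                "f2": rng.choice(["x", "y", "z"], 60),
            }
        )
        res1 = association_tests(df, [("f1", "f2")])
        res2 = association_tests(df, [("f2", "f1")])
        assert res1.loc[0, "p"] == pytest.approx(res2.loc[0, "p"], abs=1e-12)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"f1": ["a"] * 10, "f2": ["x", "y"] * 5})
        with pytest.raises(MatrixIOError):
            association_tests(df, [("f1", "f2")])
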