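"""Thought-probe statistics: contrasts, BH, partial correlations, PA, EFA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dreamcue.probes import (
    LIKERT_ITEMS,
    ProbeResponse,
    bh_adjust,
    binary_item_contrast,
    contrast_table,
    efa,
    multinomial_item_contrast,
    paired_contrast,
    parallel_analysis,
    partial_correlations,
    read_probe_table,
    substantial_loadings,
)
from dreamcue import synthgen


def bh_oracle(p):
    """Definition-based step-up adjustment: adjusted_(k) = min over j >= k
    of p_(j) * m / j, clipped at 1, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank_idx in range(m):
        tail = [p[order[j]] * m / (j + 1) for j in range(rank_idx, m)]
        adj_sorted[rank_idx] = min(1.0, min(tail))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_monotone_and_never_below_raw(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 40))
    def test_matches_definition_oracle(self, seed, m):
        p = np.random.default_rng(seed).random(m)
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestPairedContrast:
    def _long(self, hyp, fmt, item="novelty"):
        n = len(hyp)
        rows = []
        for i in range(n):
            rows.append({"participant_id": f"p{i}", "condition": "hypnagogia", item: hyp[i]})
            rows.append({"participant_id": f"p{i}", "condition": "fmt", item: fmt[i]})
        return pd.DataFrame(rows)

    def test_identical_conditions(self):
        vals = [1, 2, 3, 4, 5]
        res = paired_contrast("novelty", self._long(vals, vals))
        assert res.estimate == 0.0
        assert res.raw_p == 1.0

    def test_sign_flip_symmetry(self, rng):
        hyp = rng.integers(1, 6, 30)
        fmt = rng.integers(1, 6, 30)
        a = paired_contrast("novelty", self._long(hyp, fmt))
        b = paired_contrast("novelty", self._long(fmt, hyp))
        assert a.estimate == pytest.approx(-b.estimate)
        assert a.raw_p == pytest.approx(b.raw_p)

    def test_planted_shift_detected_in_majority(self, rng):
        # shift +0.31 on a 1-5 item with sd_diff ~ 1.2 at n = 80
        hits = 0
        reps = 100
        for _ in range(reps):
            diff = rng.normal(0.31, 1.2, 80)
            base = rng.normal(3, 0.8, 80)
            res = paired_contrast("novelty", self._long(base + diff, base))
            hits += res.raw_p < 0.05
        assert hits > reps / 2


class TestCategoricalContrasts:
    def _binary_frame(self, n11, n10, n01, n00):
        # condition=hypnagogia rows then fmt rows
        rows = []
        for _ in range(n11):
            rows.append({"condition": "hypnagogia", "intentionality": "spontaneous"})
        for _ in range(n10):
            rows.append({"condition": "hypnagogia", "intentionality": "deliberate"})
        for _ in range(n01):
            rows.append({"condition": "fmt", "intentionality": "spontaneous"})
        for _ in range(n00):
            rows.append({"condition": "fmt", "intentionality": "deliberate"})
        return pd.DataFrame(rows)

    def test_identical_distributions_null(self):
        res = binary_item_contrast(self._binary_frame(30, 20, 30, 20))
        assert res["chi2"] == pytest.approx(0.0, abs=1e-8)
        assert res["odds_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_odds_ratio_closed_form(self):
        res = binary_item_contrast(self._binary_frame(30, 50, 50, 30))
        assert res["odds_ratio"] == pytest.approx((30 * 30) / (50 * 50), rel=1e-4)

    def test_separation_flagged(self):
        res = binary_item_contrast(self._binary_frame(40, 0, 10, 30))
        assert res["separated"]
        assert np.isfinite(res["chi2"]) and np.isfinite(res["odds_ratio"])

    def test_planted_log_odds_power(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            p_fmt = 0.4
            p_hyp = 1 / (1 + np.exp(-(np.log(p_fmt / (1 - p_fmt)) + 1.0)))
            rows = []
            for i in range(80):
                rows.append(
                    {"condition": "hypnagogia",
                     "intentionality": "spontaneous" if rng.random() < p_hyp else "deliberate"}
                )
                rows.append(
                    {"condition": "fmt",
                     "intentionality": "spontaneous" if rng.random() < p_fmt else "deliberate"}
                )
            res = binary_item_contrast(pd.DataFrame(rows))
            hits += res["p"] < 0.05
        # analytic power at these settings (Wald SE ~ 0.34 for the log odds
        # ratio) is ~ 0.85; assert a 3-sigma lower band around it
        assert hits >= 0.75 * reps

    def test_multinomial_identical_distributions(self):
        rows = []
        for cond in ("hypnagogia", "fmt"):
            for cat, k in (("none", 30), ("past", 30), ("present", 20), ("future", 20)):
                rows += [{"condition": cond, "temporality": cat}] * k
        res = multinomial_item_contrast(pd.DataFrame(rows))
        for cat in ("past", "present", "future"):
            assert res["rrr"][cat]["rrr"] == pytest.approx(1.0, abs=1e-3)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-6)

    def test_multinomial_scale_invariance(self):
        def frame(scale):
            rows = []
            for cat, k_h, k_f in (("none", 3, 2), ("past", 4, 3), ("present", 2, 5), ("future", 1, 2)):
                rows += [{"condition": "hypnagogia", "temporality": cat}] * (k_h * scale)
                rows += [{"condition": "fmt", "temporality": cat}] * (k_f * scale)
            return pd.DataFrame(rows)

        r1 = multinomial_item_contrast(frame(10))
        r2 = multinomial_item_contrast(frame(100))
        for cat in ("past", "present", "future"):
            assert r1["rrr"][cat]["rrr"] == pytest.approx(r2["rrr"][cat]["rrr"], rel=1e-3)

    def test_planted_present_rrr_recovered(self, rng):
        # relative odds of present vs the atemporal reference 1.876x higher
        # in FMT than hypnagogia
        base = np.array([0.3, 0.3, 0.2, 0.2])  # none past present future (hyp)
        w = base.copy()
        w[2] *= 1.876
        fmt_p = w / w.sum()
        cats = np.array(["none", "past", "present", "future"])
        rows = []
        n = 20000
        rows += [
            {"condition": "hypnagogia", "temporality": c}
            for c in cats[rng.choice(4, n, p=base)]
        ]
        rows += [
            {"condition": "fmt", "temporality": c} for c in cats[rng.choice(4, n, p=fmt_p)]
        ]
        res = multinomial_item_contrast(
            pd.DataFrame(rows), reference_condition="hypnagogia"
        )
        assert res["rrr"]["present"]["rrr"] == pytest.approx(1.876, rel=0.10)


class TestPartialCorrelations:
    def test_independent_variables_near_zero(self, rng):
        data = pd.DataFrame(rng.normal(size=(5000, 4)), columns=list("abcd"))
        pc = partial_correlations(data)
        assert abs(pc.r.loc["a", "b"]) < 0.05

    def test_near_duplicate_near_one(self, rng):
        x = rng.normal(size=500)
        data = pd.DataFrame(
            {"x": x, "y": x + rng.normal(0, 0.01, 500), "z": rng.normal(size=500)}
        )
        pc = partial_correlations(data)
        assert pc.r.loc["x", "y"] > 0.99

    def test_matrix_structure(self, rng):
        data = pd.DataFrame(rng.normal(size=(100, 5)))
        data.columns = list("abcde")
        pc = partial_correlations(data)
        r = pc.r.to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1.0 + 1e-12).all()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_residual_regression_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 60, 4
        X = rng.normal(size=(n, k)) @ rng.normal(size=(k, k))  # correlated system
        data = pd.DataFrame(X, columns=[f"v{i}" for i in range(k)])
        pc = partial_correlations(data)
        for i in range(k):
            for j in range(i + 1, k):
                others = [c for c in range(k) if c not in (i, j)]
                Z = np.column_stack([np.ones(n), X[:, others]])
                ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
                rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
                oracle = np.corrcoef(ri, rj)[0, 1]
                assert pc.r.iloc[i, j] == pytest.approx(oracle, abs=1e-8)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        pc = partial_correlations(data)
        ref = pingouin.partial_corr(data, x="a", y="b", covar=["c", "d"])
        assert pc.r.loc["a", "b"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert pc.p.loc["a", "b"] == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_too_few_observations_rejected(self, rng):
        data = pd.DataFrame(rng.normal(size=(4, 5)))
        with pytest.raises(ValueError, match="observations"):
            partial_correlations(data)


class TestParallelAnalysis:
    def test_deterministic_given_seed(self, rng):
        data = rng.normal(size=(150, 8))
        a = parallel_analysis(data, n_iter=100, seed=5)
        b = parallel_analysis(data, n_iter=100, seed=5)
        assert a == b

    def test_min_iterations_enforced(self, rng):
        with pytest.raises(ValueError):
            parallel_analysis(rng.normal(size=(50, 5)), n_iter=10)

    def test_pure_noise_suggests_at_most_one(self):
        # the percentile criterion controls the pure-noise retention rate;
        # the mean criterion is anticonservative under the null by design
        # (each noise eigenvalue beats the mean reference with p ~ 1/2)
        hits = 0
        seeds = range(40)
        for s in seeds:
            data = np.random.default_rng(1000 + s).normal(size=(200, 11))
            hits += parallel_analysis(data, n_iter=100, seed=s, criterion="p95") <= 1
        assert hits >= 0.95 * len(seeds)

    def test_recovers_planted_four_factors(self):
        hits = 0
        seeds = range(15)
        for s in seeds:
            items, _ = synthgen.generate_probe_data(
                synthgen.CohortParams(seed=100 + s), n=300
            )
            hits += parallel_analysis(items, n_iter=100, seed=s) == 4
        assert hits >= 0.90 * len(seeds)


def _factor_data(rng, n, loadings):
    """Continuous data with planted orthogonal-factor structure; loadings is
    items x factors."""
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    f = rng.normal(size=(n, k))
    res_sd = np.sqrt(np.clip(1 - (L**2).sum(axis=1), 0.05, None))
    X = f @ L.T + rng.normal(size=(n, p)) * res_sd
    return pd.DataFrame(X, columns=[f"item{i}" for i in range(p)])


class TestEFA:
    def test_single_factor_closed_form(self, rng):
        lam = 0.8
        data = _factor_data(rng, 4000, np.full((6, 1), lam))
        fit = efa(data, n_factors=1)
        assert np.allclose(np.abs(fit.loadings.to_numpy().ravel()), lam, atol=0.05)
        assert np.allclose(fit.communalities, lam**2, atol=0.08)

    def test_orthogonal_two_factor_small_factor_correlation(self, rng):
        L = np.zeros((8, 2))
        L[:4, 0] = 0.75
        L[4:, 1] = 0.75
        fit = efa(_factor_data(rng, 2000, L), n_factors=2)
        phi = fit.factor_correlations.to_numpy()
        assert abs(phi[0, 1]) < 0.1

    def test_item_sign_flip_negates_its_loadings(self, rng):
        L = np.zeros((8, 2))
        L[:4, 0] = 0.75
        L[4:, 1] = 0.75
        L[0, 0] = 0.9  # keep item0 the dominant loader so the factor sign
        # convention is anchored by an unflipped item
        data = _factor_data(rng, 2000, L)
        fit = efa(data, n_factors=2)
        flipped = data.copy()
        flipped["item1"] = -flipped["item1"]  # not the max loader of its factor
        fit2 = efa(flipped, n_factors=2)
        assert np.allclose(
            fit2.loadings.loc["item1"], -fit.loadings.loc["item1"], atol=1e-4
        )
        assert fit2.communalities["item1"] == pytest.approx(
            fit.communalities["item1"], abs=1e-6
        )

    def test_variance_decomposition_consistency(self, rng):
        L = np.zeros((9, 3))
        L[:3, 0], L[3:6, 1], L[6:, 2] = 0.8, 0.7, 0.6
        data = _factor_data(rng, 1500, L)
        # orthogonal (unrotated) case: sum of h2 equals total SS loadings
        fit = efa(data, n_factors=3, rotation="none")
        assert fit.ss_loadings.sum() == pytest.approx(fit.communalities.sum(), rel=1e-8)
        for f in (fit, efa(data, n_factors=3)):
            assert ((f.proportion_var >= 0) & (f.proportion_var <= 1)).all()
            assert (np.diff(f.cumulative_var) >= -1e-12).all()
            assert f.cumulative_proportion.iloc[-1] == pytest.approx(1.0)

    def test_communalities_match_sklearn(self, rng):
        from sklearn.decomposition import FactorAnalysis

        L = np.zeros((8, 2))
        L[:4, 0] = 0.75
        L[4:, 1] = 0.75
        data = _factor_data(rng, 3000, L)
        fit = efa(data, n_factors=2, rotation="none")
        Z = (data - data.mean()) / data.std(ddof=0)
        sk = FactorAnalysis(n_components=2, svd_method="lapack").fit(Z.to_numpy())
        h2_sk = (sk.components_**2).sum(axis=0)
        assert np.allclose(fit.communalities.to_numpy(), h2_sk, atol=0.05)

    def test_recovers_planted_loadings_on_likert_battery(self):
        items, _ = synthgen.generate_probe_data(synthgen.CohortParams(seed=9), n=300)
        fit = efa(items, n_factors=4)
        planted = synthgen.default_loading_matrix().to_numpy()
        est = fit.loadings.to_numpy()
        # align estimated factors to planted ones by greatest absolute
        # column correlation, then compare
        from scipy.optimize import linear_sum_assignment

        cost = -np.abs(planted.T @ est)
        rows, cols = linear_sum_assignment(cost)
        err = []
        for r, c in zip(rows, cols):
            sign = np.sign(planted[:, r] @ est[:, c])
            err.append(np.abs(planted[:, r] - sign * est[:, c]))
        assert np.mean(np.concatenate(err)) < 0.10

    def test_inadmissible_factor_count_rejected(self, rng):
        data = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        with pytest.raises(ValueError, match="n_factors"):
            efa(data, n_factors=4)


class TestSubstantialLoadings:
    def _result_with(self, values):
        items, _ = synthgen.generate_probe_data(synthgen.CohortParams(seed=1), n=200)
        fit = efa(items, n_factors=2)
        L = pd.DataFrame(values, index=fit.loadings.index[: len(values)], columns=["Factor1", "Factor2"])
        object.__setattr__(fit, "loadings", L)
        return fit

    def test_threshold_inclusive_and_magnitude_based(self):
        fit = self._result_with([[0.40, 0.0], [-0.75, 0.0], [0.39, 0.39]])
        mask = substantial_loadings(fit)
        assert bool(mask.iloc[0, 0]) is True  # 0.40 inclusive
        assert bool(mask.iloc[1, 0]) is True  # |-0.75|
        assert not mask.iloc[2, :2].any()  # 0.39 below threshold

    def test_cross_loading_reported(self):
        fit = self._result_with([[0.5, 0.6], [0.5, 0.1], [0.1, 0.1]])
        mask = substantial_loadings(fit)
        assert mask["cross_loading"].tolist() == [True, False, False]


class TestProbeResponseValidation:
    def test_out_of_scale_rejected(self):
        likert = {k: 3 for k in LIKERT_ITEMS}
        likert["novelty"] = 6
        with pytest.raises(ValueError, match="Likert"):
            ProbeResponse("p", "fmt", likert, "deliberate", "past")

    def test_probe_table_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "probes.csv"
        small_cohort.probes.to_csv(path, index=False)
        back = read_probe_table(path)
        pd.testing.assert_frame_equal(back, small_cohort.probes)


class TestContrastTable:
    def test_family_of_thirteen_with_bh(self, default_cohort):
        table = contrast_table(default_cohort.probes)
        assert len(table) == 13
        assert set(table["item"]) == set(LIKERT_ITEMS) | {"intentionality", "temporality"}
        assert (table["bh_p"] >= table["raw_p"] - 1e-15).all()
        assert np.allclose(table["bh_p"], bh_oracle(table["raw_p"].to_numpy()))
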