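"""Survival machinery vs hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test as _ll_logrank

from epimmune.survival import (
    concordance_index,
    cox_fit,
    decision_curve,
    encode_clinical_covariates,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    prognostic_screen,
    time_dependent_auc,
)


def _km_at(km: pd.DataFrame, t: float) -> float:
    eligible = km[km["time"] <= t]
    return float(eligible["survival"].iloc[-1]) if len(eligible) else 1.0


class TestKaplanMeier:
    def test_single_subject_event(self):
        km = km_estimate([5.0], [1])
        assert _km_at(km, 4.99) == pytest.approx(1.0)
        assert _km_at(km, 5.0) == pytest.approx(0.0)

    def test_all_censored_curve_is_flat_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.allclose(km["survival"], 1.0)

    def test_three_events_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert _km_at(km, 1.0) == pytest.approx(2 / 3)
        assert _km_at(km, 2.0) == pytest.approx(1 / 3)
        assert _km_at(km, 3.0) == pytest.approx(0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.1, 50), st.integers(0, 1)),
                    min_size=2, max_size=30))
    def test_curve_nonincreasing_and_starts_at_one(self, subjects):
        time, event = zip(*subjects)
        km = km_estimate(np.array(time), np.array(event))
        s = km["survival"].to_numpy()
        assert s[0] <= 1.0 + 1e-12 and _km_at(km, 0.0) == pytest.approx(1.0)
        assert (np.diff(s) <= 1e-12).all()


def _hand_two_group_logrank(time, event, group):
    """Risk-set tabulation oracle: chi2 = (O - E)^2 / V for group 1."""
    time, event, group = map(np.asarray, (time, event, group))
    o = e = v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n, n1 = at_risk.sum(), (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v


class TestLogrank:
    def test_duplicated_groups_give_zero_statistic(self):
        time = [3.0, 5.0, 7.0, 3.0, 5.0, 7.0]
        event = [1, 0, 1, 1, 0, 1]
        labels = ["a"] * 3 + ["b"] * 3
        chi2, df, p = logrank_test(labels, time, event)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and 0.0 <= p <= 1.0

    def test_six_subject_hand_tabulated_statistic(self):
        time = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        event = [1, 1, 1, 1, 1, 1]
        group = [0, 0, 0, 1, 1, 1]
        chi2, df, _ = logrank_test(group, time, event)
        assert chi2 == pytest.approx(_hand_two_group_logrank(time, event, group))

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(0)
        time = rng.exponential(10, 40)
        event = rng.integers(0, 2, 40)
        labels = rng.integers(0, 2, 40)
        chi2_a, *_ = logrank_test(labels, time, event)
        perm = rng.permutation(40)
        chi2_b, *_ = logrank_test(labels[perm], time[perm], event[perm])
        assert chi2_a == pytest.approx(chi2_b)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(["a"] * 5, np.arange(1.0, 6.0), np.ones(5, int))


def _brute_force_cutpoint(marker, time, event, minprop):
    """Exhaustive enumeration with an independent log-rank implementation."""
    n = len(marker)
    min_side = int(np.ceil(minprop * n))
    best_thr, best_chi2 = None, -1.0
    for lo, hi in zip(np.unique(marker)[:-1], np.unique(marker)[1:]):
        thr = 0.5 * (lo + hi)
        high = marker > thr
        if high.sum() < min_side or (~high).sum() < min_side:
            continue
        res = _ll_logrank(time[high], time[~high], event[high], event[~high])
        if res.test_statistic > best_chi2 + 1e-12:
            best_thr, best_chi2 = thr, res.test_statistic
    return best_thr, best_chi2


class TestOptimalCutpoint:
    def test_matches_exhaustive_search_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(15):
            n = int(rng.integers(20, 50))
            marker = rng.normal(size=n)
            time = rng.exponential(10, n)
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            cut = optimal_cutpoint(marker, time, event, minprop=0.1)
            thr, chi2 = _brute_force_cutpoint(marker, time, event, 0.1)
            assert cut.threshold == pytest.approx(thr)
            assert cut.statistic**2 == pytest.approx(chi2, abs=1e-8)

    def test_perfectly_separating_bimodal_marker(self):
        marker = np.array([0.0] * 10 + [1.0] * 10)
        time = np.r_[np.linspace(1, 2, 10), np.linspace(20, 30, 10)]
        event = np.r_[np.ones(10, int), np.zeros(10, int)]
        cut = optimal_cutpoint(marker, time, event)
        assert 0.0 < cut.threshold < 1.0

    def test_minprop_constrains_group_sizes(self):
        rng = np.random.default_rng(3)
        marker = rng.normal(size=20)
        cut = optimal_cutpoint(marker, rng.exponential(5, 20),
                               rng.integers(0, 2, 20), minprop=0.1)
        assert min(cut.n_low, cut.n_high) >= 2

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutpoint(np.ones(10), np.arange(1.0, 11.0), np.ones(10, int))


def _grid_search_cox_beta(x, time, event):
    """Maximize the explicit partial likelihood over a beta grid (no ties)."""
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]
    betas = np.arange(-4.0, 4.0, 1e-4)
    ll = np.zeros_like(betas)
    for i in np.where(event == 1)[0]:
        at_risk = x[time >= time[i]]
        ll += betas * x[i] - np.log(np.exp(betas[:, None] * at_risk[None, :]).sum(axis=1))
    return betas[np.argmax(ll)]


class TestCox:
    def test_six_subject_beta_matches_partial_likelihood_grid(self):
        time = np.array([2.0, 5.0, 7.0, 11.0, 13.0, 17.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        fit = cox_fit(pd.DataFrame({"x": x}), time, event)
        assert fit.beta("x") == pytest.approx(_grid_search_cox_beta(x, time, event), abs=1e-4)

    def test_negating_covariate_negates_beta(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=60)
        time = rng.exponential(np.exp(-0.5 * x))
        event = np.ones(60, int)
        f1 = cox_fit(pd.DataFrame({"x": x}), time, event)
        f2 = cox_fit(pd.DataFrame({"x": -x}), time, event)
        assert f1.beta("x") == pytest.approx(-f2.beta("x"), abs=1e-8)
        assert f1.summary.at["x", "ci_low"] <= f1.hr("x") <= f1.summary.at["x", "ci_high"]

    def test_null_binary_covariate_ci_covers_zero(self):
        covered = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 120).astype(float)
            time = rng.exponential(10, 120)
            event = (rng.random(120) < 0.8).astype(int)
            fit = cox_fit(pd.DataFrame({"x": x}), time, event)
            lo = np.log(fit.summary.at["x", "ci_low"])
            hi = np.log(fit.summary.at["x", "ci_high"])
            covered += lo <= 0.0 <= hi
        assert covered >= 42  # ~95% nominal coverage over 50 replicates

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=30), "c": 1.0})
        with pytest.warns(UserWarning):
            fit = cox_fit(df, rng.exponential(5, 30), np.ones(30, int))
        assert list(fit.summary.index) == ["x"]


def _brute_force_cindex(risk, time, event):
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # usable: the earlier time is an observed event
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_and_constant_risk(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, int)
        assert concordance_index([4, 3, 2, 1], time, event) == pytest.approx(1.0)
        assert concordance_index([1, 1, 1, 1], time, event) == pytest.approx(0.5)

    def test_equals_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 10
            risk = rng.normal(size=n)
            time = rng.exponential(10, n)
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            assert concordance_index(risk, time, event) == pytest.approx(
                _brute_force_cindex(risk, time, event))


class TestTimeDependentAuc:
    def test_perfect_ranking_marker(self):
        time = np.arange(1.0, 21.0)
        event = np.ones(20, int)
        marker = -time  # higher marker = earlier failure
        auc = time_dependent_auc(marker, time, event, horizons=[10.5])
        assert auc[10.5] == pytest.approx(1.0)

    def test_no_censoring_equals_binary_auc_oracle(self):
        rng = np.random.default_rng(3)
        n = 80
        marker = rng.normal(size=n)
        time = rng.exponential(np.exp(-marker), n)
        event = np.ones(n, int)
        t = float(np.median(time))
        auc = time_dependent_auc(marker, time, event, horizons=[t])[t]
        cases, controls = marker[time <= t], marker[time > t]
        u = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
        assert auc == pytest.approx(u / (len(cases) * len(controls)), abs=1e-10)

    def test_horizon_beyond_followup_rejected(self):
        with pytest.raises(ValueError):
            time_dependent_auc([1.0, 2.0], [1.0, 2.0], [1, 1], horizons=[5.0])


class TestDecisionCurve:
    def test_reference_strategies(self):
        rng = np.random.default_rng(0)
        outcome = (rng.random(200) < 0.3).astype(int)
        dc = decision_curve(rng.random(200), outcome, thresholds=[0.2])
        prevalence = outcome.mean()
        assert dc["treat_none"].iloc[0] == 0.0
        assert dc["treat_all"].iloc[0] == pytest.approx(prevalence - (1 - prevalence) * 0.25)

    def test_treat_all_closed_form_at_known_prevalence(self):
        outcome = np.r_[np.ones(30, int), np.zeros(70, int)]
        dc = decision_curve(np.ones(100), outcome, thresholds=[0.2])
        assert dc["treat_all"].iloc[0] == pytest.approx(0.3 - 0.7 * 0.25)

    def test_perfect_predictor_net_benefit_is_prevalence(self):
        outcome = np.r_[np.ones(40, int), np.zeros(60, int)]
        prob = outcome.astype(float)
        dc = decision_curve(prob, outcome, thresholds=[0.1, 0.5, 0.9])
        assert np.allclose(dc["net_benefit"], 0.4)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=[1.0])


def _clinical_frame(rng, n, time, event):
    return pd.DataFrame(
        {"OS_time": time, "OS_event": event,
         "age": rng.normal(65, 8, n).round(),
         "gender": rng.choice(["male", "female"], n),
         "stage": rng.choice(["I", "II", "III", "IV"], n)},
        index=[f"s{i}" for i in range(n)])


class TestPrognosticScreen:
    def test_empty_pair_list_yields_empty_report(self):
        rng = np.random.default_rng(0)
        clinical = _clinical_frame(rng, 20, rng.exponential(10, 20), np.ones(20, int))
        out = prognostic_screen(pd.DataFrame(columns=["probe", "gene"]),
                                pd.DataFrame(), pd.DataFrame(), clinical)
        assert len(out) == 0

    def test_planted_prognostic_pair_detected_with_correct_direction(self):
        rng = np.random.default_rng(42)
        n = 300
        samples = [f"s{i}" for i in range(n)]
        marker = rng.normal(size=n)
        time = rng.exponential(30 * np.exp(-0.8 * marker))
        clinical = _clinical_frame(rng, n, time, np.ones(n, int))
        expr = pd.DataFrame([5 + marker], index=["G1"], columns=samples)
        beta = pd.DataFrame([1 / (1 + np.exp(-marker))], index=["cg1"], columns=samples)
        pairs = pd.DataFrame({"probe": ["cg1"], "gene": ["G1"]})
        out = prognostic_screen(pairs, expr, beta, clinical)
        assert bool(out["pair_prognostic"].iloc[0])
        assert out["gene_HR"].iloc[0] > 1.0  # high expression = high hazard here

    def test_per_marker_errors_recorded_without_aborting(self):
        rng = np.random.default_rng(1)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        marker = rng.normal(size=n)
        time = rng.exponential(10 * np.exp(-0.5 * marker))
        clinical = _clinical_frame(rng, n, time, np.ones(n, int))
        expr = pd.DataFrame([5 + marker], index=["G1"], columns=samples)
        beta = pd.DataFrame([np.full(n, 0.5)], index=["cg_const"], columns=samples)
        pairs = pd.DataFrame({"probe": ["cg_const"], "gene": ["G1"]})
        out = prognostic_screen(pairs, expr, beta, clinical)
        assert out["probe_error"].iloc[0] != ""
        assert np.isfinite(out["gene_p"].iloc[0])

    def test_covariate_encoding(self):
        rng = np.random.default_rng(2)
        clinical = _clinical_frame(rng, 10, rng.exponential(5, 10), np.ones(10, int))
        design = encode_clinical_covariates(clinical)
        assert set(design.columns) == {"age", "gender_male", "stage_ordinal"}
        assert design["stage_ordinal"].isin([1, 2, 3, 4]).all()
        clinical.loc[clinical.index[0], "age"] = np.nan
        with pytest.raises(ValueError):
            encode_clinical_covariates(clinical)
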