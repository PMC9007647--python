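"""Prognostic machinery: cutpoints, Kaplan-Meier, Cox, discrimination, DCA.

Continuous biomarkers are dichotomized at the maximally selected log-rank
cutpoint (every admissible split leaving at least ``minprop`` of the
samples on each side is scanned; the split with the largest standardized
log-rank statistic wins, smallest threshold on ties).  Group survival is
summarized by the Kaplan-Meier product-limit estimator and compared by
the log-rank test; adjusted effects come from Cox proportional-hazards
fits (Efron ties, Wald intervals).  Discrimination is quantified by
Harrell's concordance index and by IPCW cumulative/dynamic AUC at fixed
horizons; clinical utility by decision-curve net benefit.

No multiple-selection correction is applied to p-values obtained after
cutpoint optimization: the cutpoint is used only to dichotomize, and the
selection bias this induces on same-data tests is documented rather than
corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

__all__ = [
    "CutpointResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "two_group_logrank_z",
    "optimal_cutpoint",
    "cox_fit",
    "concordance_index",
    "time_dependent_auc",
    "decision_curve",
    "prognostic_screen",
    "encode_clinical_covariates",
]

STAGE_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass(frozen=True)
class CutpointResult:
    threshold: float
    statistic: float  # standardized log-rank statistic at the threshold
    n_low: int
    n_high: int
    minprop: float


@dataclass(frozen=True)
class CoxFit:
    summary: pd.DataFrame  # per covariate: beta, HR, CI bounds, p
    log_likelihood: float
    ties: str

    def beta(self, covariate: str) -> float:
        return float(self.summary.at[covariate, "beta"])

    def hr(self, covariate: str) -> float:
        return float(self.summary.at[covariate, "HR"])

    def p(self, covariate: str) -> float:
        return float(self.summary.at[covariate, "p"])


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit survival estimate: a right-continuous step function.

    Returns a DataFrame with columns ``time`` and ``survival`` giving
    S(t) at each observed time (S(0) = 1, nonincreasing, drops only at
    event times).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float),
                         "survival": sf.iloc[:, 0].to_numpy(float)})


def logrank_test(group_labels, time, event) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi2, df, p)."""
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(np.asarray(time, float), labels, np.asarray(event, int))
    return float(res.test_statistic), int(groups.size - 1), float(res.p_value)


def two_group_logrank_z(time, event, in_high: np.ndarray) -> float:
    """Standardized log-rank statistic Z = (O - E) / sqrt(V) for one split.

    O, E, V accumulate the observed and hypergeometric-expected events of
    the high group over the distinct event times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    in_high = np.asarray(in_high, dtype=bool)
    event_times = np.unique(time[event == 1])
    o = e = v = 0.0
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        n1_t = (at_risk & in_high).sum()
        d_t = ((time == t) & (event == 1)).sum()
        d1_t = ((time == t) & (event == 1) & in_high).sum()
        o += d1_t
        e += d_t * n1_t / n_t
        if n_t > 1:
            v += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    if v <= 0:
        return 0.0
    return float((o - e) / np.sqrt(v))


def optimal_cutpoint(marker, time, event, minprop: float = 0.1) -> CutpointResult:
    """Maximally selected log-rank cutpoint for a continuous marker.

    Every threshold between consecutive distinct marker values that
    leaves at least ``ceil(minprop * n)`` samples on each side is a
    candidate; the one maximizing |Z| of the two-group log-rank
    statistic is returned (ties broken toward the smallest threshold).
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = marker.size
    distinct = np.unique(marker)
    if distinct.size < 2:
        raise ValueError("marker must take at least 2 distinct values")
    min_side = int(np.ceil(minprop * n))
    thresholds = 0.5 * (distinct[:-1] + distinct[1:])
    n_high = (marker[None, :] > thresholds[:, None]).sum(axis=1)
    admissible = (n_high >= min_side) & (n - n_high >= min_side)
    if not admissible.any():
        raise ValueError("no admissible split satisfies the minprop constraint")
    thresholds = thresholds[admissible]
    z = _logrank_z_all_splits(marker, time, event, thresholds)
    # first maximum = smallest threshold on ties (thresholds are ascending)
    best = int(np.argmax(np.abs(z)))
    nh = int((marker > thresholds[best]).sum())
    return CutpointResult(float(thresholds[best]), float(z[best]), n - nh, nh, minprop)


def _logrank_z_all_splits(
    marker: np.ndarray, time: np.ndarray, event: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """Standardized log-rank Z for every threshold at once (matrix form)."""
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        return np.zeros(thresholds.size)
    at_risk = time[:, None] >= event_times[None, :]  # n x T
    evt_at = (time[:, None] == event_times[None, :]) & (event[:, None] == 1)
    n_t = at_risk.sum(axis=0).astype(float)
    d_t = evt_at.sum(axis=0).astype(float)
    high = marker[None, :] > thresholds[:, None]  # S x n
    n1 = high.astype(float) @ at_risk.astype(float)  # S x T
    d1 = high.astype(float) @ evt_at.astype(float)
    frac = n1 / n_t
    o = d1.sum(axis=1)
    e = (d_t * frac).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_t = d_t * frac * (1.0 - frac) * (n_t - d_t) / (n_t - 1.0)
    v = np.where(np.isfinite(v_t), v_t, 0.0).sum(axis=1)
    z = np.zeros_like(o)
    positive = v > 0
    z[positive] = (o[positive] - e[positive]) / np.sqrt(v[positive])
    return z


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def cox_fit(
    covariates: pd.DataFrame,
    time,
    event,
    ties: str = "efron",
    alpha: float = 0.05,
) -> CoxFit:
    """Cox PH fit (partial-likelihood Newton-Raphson, Efron tie handling).

    Constant covariates are dropped with a warning.  Returns per-covariate
    log-hazard, hazard ratio, Wald CI and p-value.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is provided")
    X = covariates.copy()
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        import warnings

        warnings.warn(f"dropping constant covariates: {constant}", stacklevel=2)
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValueError("no non-constant covariates to fit")
    event = np.asarray(event, dtype=int)
    if event.sum() < X.shape[1]:
        raise ValueError("fewer events than covariates")
    df = X.astype(float).copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = event
    cph = CoxPHFitter(alpha=alpha)
    cph.fit(df, duration_col="_time", event_col="_event")
    s = cph.summary
    summary = pd.DataFrame(
        {
            "beta": s["coef"],
            "HR": s["exp(coef)"],
            "ci_low": np.exp(s["coef lower 95%"]) if "coef lower 95%" in s else s["exp(coef) lower 95%"],
            "ci_high": np.exp(s["coef upper 95%"]) if "coef upper 95%" in s else s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    summary.index.name = "covariate"
    return CoxFit(summary=summary, log_likelihood=float(cph.log_likelihood_), ties=ties)


def concordance_index(risk_scores, time, event) -> float:
    """Harrell's C over usable pairs; higher risk = earlier failure.

    Risk ties count 0.5.  Wraps the standard pair-counting estimator with
    the risk sign flipped to the 'higher risk is worse' convention.
    """
    risk = np.asarray(risk_scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    return float(_lifelines_cindex(time, -risk, event))


def time_dependent_auc(
    marker,
    time,
    event,
    horizons: Sequence[float],
) -> dict[float, float]:
    """IPCW cumulative/dynamic AUC(t) at the requested horizons.

    Censoring weights come from the Kaplan-Meier estimate of the
    censoring distribution on the same data.  Horizons must lie strictly
    within the observed follow-up range.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    horizons = np.asarray(sorted(horizons), dtype=float)
    if horizons.max() >= time.max():
        raise ValueError("horizon beyond the last observed time")
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    auc, _ = cumulative_dynamic_auc(y, y, np.asarray(marker, float), horizons)
    return {float(t): float(a) for t, a in zip(horizons, auc)}


def decision_curve(
    predicted_prob,
    outcome,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Decision-curve net benefit of a probabilistic classifier.

    ``NB(pt) = TP/n - (FP/n) * pt / (1 - pt)`` where a subject is
    test-positive when predicted probability >= pt.  Also returns the
    treat-all reference ``prevalence - (1 - prevalence) * pt / (1 - pt)``
    and the treat-none reference (identically 0).
    """
    prob = np.asarray(predicted_prob, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    rows = []
    n = prob.size
    prevalence = outcome.mean()
    for pt in thresholds:
        if not 0.0 < pt < 1.0:
            raise ValueError("thresholds must lie strictly inside (0, 1)")
        odds = pt / (1.0 - pt)
        positive = prob >= pt
        tp = np.sum(positive & (outcome == 1)) / n
        fp = np.sum(positive & (outcome == 0)) / n
        rows.append(
            {
                "threshold": pt,
                "net_benefit": tp - fp * odds,
                "treat_all": prevalence - (1.0 - prevalence) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Prognostic screen over mIMg markers
# ---------------------------------------------------------------------------

def encode_clinical_covariates(
    clinical: pd.DataFrame,
    adjusters: Sequence[str] = ("age", "gender", "stage"),
) -> pd.DataFrame:
    """Numeric design columns for the adjusters (complete cases required).

    gender -> indicator of male; stage -> single ordinal I<II<III<IV.
    """
    cols = {}
    for adj in adjusters:
        if adj not in clinical.columns:
            raise KeyError(f"clinical table lacks adjuster column {adj!r}")
        col = clinical[adj]
        if col.isna().any():
            raise ValueError(f"adjuster {adj!r} has missing values (complete cases required)")
        if adj == "gender":
            cols["gender_male"] = (col.astype(str) == "male").astype(float)
        elif adj == "stage":
            cols["stage_ordinal"] = col.map(STAGE_ORDER).astype(float)
        else:
            cols[adj] = col.astype(float)
    return pd.DataFrame(cols, index=clinical.index)


def prognostic_screen(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
    methylation: pd.DataFrame,
    clinical: pd.DataFrame,
    adjusters: Sequence[str] = ("age", "gender", "stage"),
    minprop: float = 0.1,
    p_threshold: float = 0.05,
    high_is_reference: bool = False,
) -> pd.DataFrame:
    """Covariate-adjusted prognostic evaluation of each mIMg probe and gene.

    Every marker (the probe's beta row and the gene's expression row) is
    dichotomized at its maximally selected log-rank cutpoint; the
    high-vs-low indicator enters a multivariate Cox model with the
    clinical adjusters.  A marker is prognostic when its adjusted Wald
    p < ``p_threshold``; a pair where BOTH members are prognostic forms
    the headline set (``pair_prognostic``).  Failures on individual
    markers are recorded (``error`` column) without aborting the screen.

    ``high_is_reference=False`` codes the high-marker group as 1 (HR is
    high vs low); flip for the opposite reference level.
    """
    time = clinical["OS_time"].to_numpy(float)
    event = clinical["OS_event"].to_numpy(int)
    base_design = encode_clinical_covariates(clinical, adjusters)
    cache: dict[tuple[str, str], dict] = {}

    def screen_marker(kind: str, name: str, values: np.ndarray) -> dict:
        key = (kind, name)
        if key in cache:
            return cache[key]
        rec: dict = {"cutpoint": np.nan, "HR": np.nan, "ci_low": np.nan,
                     "ci_high": np.nan, "p": np.nan, "error": ""}
        try:
            cut = optimal_cutpoint(values, time, event, minprop=minprop)
            group = (values > cut.threshold).astype(float)
            if high_is_reference:
                group = 1.0 - group
            design = base_design.copy()
            design["marker_high"] = group
            fit = cox_fit(design, time, event)
            rec.update(
                cutpoint=cut.threshold,
                HR=fit.hr("marker_high"),
                ci_low=float(fit.summary.at["marker_high", "ci_low"]),
                ci_high=float(fit.summary.at["marker_high", "ci_high"]),
                p=fit.p("marker_high"),
            )
        except Exception as exc:  # propagate per-marker, keep screening
            rec["error"] = f"{type(exc).__name__}: {exc}"
        rec["prognostic"] = bool(rec["p"] < p_threshold) if np.isfinite(rec["p"]) else False
        cache[key] = rec
        return rec

    rows = []
    for _, pair in pairs.iterrows():
        probe, gene = pair["probe"], pair["gene"]
        p_rec = screen_marker("probe", probe, methylation.loc[probe].to_numpy(float))
        g_rec = screen_marker("gene", gene, expression.loc[gene].to_numpy(float))
        row = {"probe": probe, "gene": gene}
        row.update({f"probe_{k}": v for k, v in p_rec.items()})
        row.update({f"gene_{k}": v for k, v in g_rec.items()})
        row["pair_prognostic"] = p_rec["prognostic"] and g_rec["prognostic"]
        rows.append(row)
    columns = ["probe", "gene"] + [
        f"{side}_{k}" for side in ("probe", "gene")
        for k in ("cutpoint", "HR", "ci_low", "ci_high", "p", "prognostic", "error")
    ] + ["pair_prognostic"]
    return pd.DataFrame(rows, columns=columns)
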