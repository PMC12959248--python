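"""Survival-analysis primitives for biomarker evaluation.

The workflow these primitives support: unadjusted Kaplan–Meier curves over
biomarker quartiles with log-rank tests; Cox proportional-hazards models of
each log-transformed biomarker, unadjusted and adjusted for age, sex and
anatomical site; non-parametric bootstrap of the hazard ratio; Harrell's
concordance index; Schoenfeld-residual checks of proportional hazards;
logistic-regression / ROC comparison for 5-year melanoma-specific survival;
Spearman correlations and Wilcoxon rank-sum subgroup contrasts.

Cox, Kaplan–Meier, log-rank and the Schoenfeld test are delegated to
``lifelines`` (ties handled by Efron's method); logistic fits to
``statsmodels``; the concordance index is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FitError, SchemaError

__all__ = [
    "KMCurve",
    "CoxResult",
    "RocResult",
    "log_transform",
    "quartile_groups",
    "km_estimate",
    "logrank_test",
    "fit_cox",
    "bootstrap_cox",
    "harrells_c",
    "schoenfeld_ph_check",
    "logistic_5yr",
    "roc_auc",
    "spearman",
    "wilcoxon_subgroup",
]

ADJUST_COVARIATES = ("age", "sex", "site")
PARAMETERS = ("area", "perimeter", "major", "dbt", "ni")
ENDPOINTS = ("os", "mss")


# ---------------------------------------------------------------------------
# transforms and grouping

def log_transform(values, case_ids=None) -> np.ndarray:
    """Natural log of strictly positive values.

    Zero or negative entries raise :class:`FitError` listing the offending
    case identifiers — cases are never silently dropped at this stage.
    """
    v = np.asarray(values, dtype=float)
    bad = ~(v > 0)
    if bad.any():
        ids = (np.asarray(case_ids)[bad].tolist() if case_ids is not None
               else np.flatnonzero(bad).tolist())
        raise FitError(f"log transform requires positive values; offending cases: {ids}")
    return np.log(v)


def quartile_groups(values) -> np.ndarray:
    """Quartile labels Q1..Q4 by sample quartiles (type-7 quantiles).

    Values tied with a boundary all receive the lower group.  All-identical
    input cannot form quartiles and raises :class:`FitError`.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise FitError(f"need >=4 values to form quartiles, got {v.size}")
    qs = np.quantile(v, [0.25, 0.5, 0.75])  # numpy default = type 7
    if np.all(v == v[0]):
        raise FitError("cannot form quartiles: all values identical")
    # number of boundaries strictly below the value -> 0..3
    idx = (v[:, None] > qs[None, :]).sum(axis=1)
    return np.array([f"Q{i + 1}" for i in idx])


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank

@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan–Meier product-limit estimator under right censoring."""
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise FitError("times and events must have equal length")
    if (t < 0).any():
        raise FitError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e, label=label or None)
    grid = kmf.survival_function_
    times_out = grid.index.to_numpy(dtype=float)
    surv = grid.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([(t >= u).sum() for u in times_out])
    return KMCurve(times_out, surv, at_risk, label)


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi2, df, p)."""
    from lifelines.statistics import multivariate_logrank_test

    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise FitError("log-rank test needs >=2 groups")
    res = multivariate_logrank_test(np.asarray(times, float), g, np.asarray(events, int))
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


# ---------------------------------------------------------------------------
# Cox models

@dataclass
class CoxResult:
    """One fitted Cox model for one log-transformed biomarker."""

    parameter: str
    endpoint: str
    adjusted: bool
    hr: float
    ci_low: float
    ci_high: float
    p: float
    c_index: float
    coef: float
    se: float
    n: int
    n_events: int
    n_dropped: int
    covariates: tuple = ()
    ph_pvals: dict = field(default_factory=dict)
    bootstrap_ci: tuple | None = None
    fitter: object = None

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("parameter", "endpoint", "adjusted", "hr", "ci_low", "ci_high",
              "p", "c_index", "coef", "se", "n", "n_events", "n_dropped")}
        d["covariates"] = list(self.covariates)
        d["ph_pvals"] = self.ph_pvals
        d["bootstrap_ci"] = list(self.bootstrap_ci) if self.bootstrap_ci else None
        return d


def _model_frame(cohort: pd.DataFrame, parameter: str, endpoint: str,
                 adjusted: bool) -> tuple[pd.DataFrame, list[str], int]:
    for col in (parameter, f"time_{endpoint}", f"event_{endpoint}"):
        if col not in cohort.columns:
            raise SchemaError(f"cohort lacks column {col!r}")
    covs = list(ADJUST_COVARIATES) if adjusted else []
    df = cohort[[parameter, f"time_{endpoint}", f"event_{endpoint}", *covs]].copy()
    n0 = len(df)
    df = df.dropna()
    dropped = n0 - len(df)
    x = df[parameter].to_numpy(dtype=float)
    if (x <= 0).any():
        ids = cohort.loc[df.index[x <= 0], "case_id"].tolist() \
            if "case_id" in cohort.columns else df.index[x <= 0].tolist()
        raise FitError(f"non-positive {parameter!r} for cases {ids}")
    out = pd.DataFrame({
        "time": df[f"time_{endpoint}"].astype(float),
        "event": df[f"event_{endpoint}"].astype(int),
        f"log_{parameter}": np.log(x),
    }, index=df.index)
    names = [f"log_{parameter}"]
    for c in covs:
        col = df[c]
        if c == "sex":
            out["sex_male"] = _binary(col, "male")
            names.append("sex_male")
        elif c == "site":
            out["site_central"] = _binary(col, "central")
            names.append("site_central")
        else:
            out[c] = col.astype(float)
            names.append(c)
    return out, names, dropped


def _binary(col: pd.Series, positive: str) -> np.ndarray:
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        return (col.astype(str).str.lower() == positive).astype(float).to_numpy()
    return col.astype(float).to_numpy()


def fit_cox(cohort: pd.DataFrame, parameter: str, endpoint: str = "os",
            adjusted: bool = True, compute_c: bool = True) -> CoxResult:
    """Cox proportional-hazards fit of one log-transformed biomarker.

    ``adjusted=True`` adds age (continuous years), sex (male vs female) and
    site (central vs peripheral).  Ties are handled by Efron's method; the
    hazard ratio is ``exp(coef)`` of the log-biomarker, with Wald 95% CI and
    p-value, and Harrell's C of the model's linear predictor attached.
    Cases missing any model column are dropped and counted (complete-case).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df, names, dropped = _model_frame(cohort, parameter, endpoint, adjusted)
    if df["event"].sum() < 1:
        raise FitError(f"no events for endpoint {endpoint!r}")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as e:
        raise FitError(f"Cox fit failed for {parameter}/{endpoint}: {e}") from e
    cph._melmorph_train_df = df  # retained for Schoenfeld diagnostics
    key = f"log_{parameter}"
    s = cph.summary.loc[key]
    if compute_c:
        risk = cph.predict_partial_hazard(df).to_numpy(dtype=float)
        c = harrells_c(risk, df["time"].to_numpy(), df["event"].to_numpy())
    else:
        c = float("nan")
    return CoxResult(
        parameter=parameter,
        endpoint=endpoint,
        adjusted=adjusted,
        hr=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]),
        c_index=c,
        coef=float(s["coef"]),
        se=float(s["se(coef)"]),
        n=len(df),
        n_events=int(df["event"].sum()),
        n_dropped=dropped,
        covariates=tuple(n for n in names if n != key),
        fitter=cph,
    )


def bootstrap_cox(cohort: pd.DataFrame, parameter: str, endpoint: str = "os",
                  adjusted: bool = True, B: int = 1000,
                  seed: int | None = None) -> tuple[float, float]:
    """Percentile bootstrap CI for the hazard ratio.

    Case-level resampling with replacement, refit per replicate; replicates
    that fail to converge are dropped and counted, and more than 10% failures
    is an error.  Identical seeds give bitwise-identical CIs.
    """
    if B < 1:
        raise FitError("B must be >= 1")
    if seed is None:
        raise FitError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    hrs = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = cohort.iloc[idx].reset_index(drop=True)
        try:
            hrs.append(fit_cox(sample, parameter, endpoint, adjusted,
                               compute_c=False).hr)
        except FitError:
            failures += 1
    if failures > 0.1 * B:
        raise FitError(f"bootstrap unstable: {failures}/{B} replicates failed to converge")
    lo, hi = np.percentile(hrs, [2.5, 97.5])
    return float(lo), float(hi)


def harrells_c(risk_scores, times, events) -> float:
    """Harrell's concordance index over usable pairs.

    A pair is usable when the shorter observed time carries an event (ties in
    time with both events are unusable).  Concordant = higher risk score has
    the shorter time; tied scores count 1/2.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(r) == len(t) == len(e)):
        raise FitError("risk_scores, times, events must have equal length")
    # pair (i, j): usable iff t_i < t_j and e_i = 1  (role of i = earlier subject)
    ti, tj = t[:, None], t[None, :]
    usable = (ti < tj) & (e[:, None] == 1)
    ri, rj = r[:, None], r[None, :]
    conc = usable & (ri > rj)
    tied = usable & (ri == rj)
    n_usable = usable.sum()
    if n_usable == 0:
        raise FitError("no usable pairs for concordance")
    return float((conc.sum() + 0.5 * tied.sum()) / n_usable)


def schoenfeld_ph_check(cox: CoxResult) -> dict:
    """Proportional-hazards check via scaled Schoenfeld residuals.

    Per-covariate chi-square tests (rank-transformed event times) from
    ``lifelines.statistics.proportional_hazard_test``, plus an approximate
    omnibus "global" p summing the per-covariate statistics (df = number of
    covariates; cross-covariate correlation ignored).  Residual-vs-time
    points are exported for plotting.
    """
    from lifelines.statistics import proportional_hazard_test

    cph = cox.fitter
    if cph is None:
        raise FitError("CoxResult carries no fitter; refit with fit_cox")
    train_df = getattr(cph, "_melmorph_train_df", None)
    if train_df is None:
        raise FitError("fitter lacks its training frame; refit with fit_cox")
    events = int(train_df["event"].sum())
    k = len(cph.params_)
    if events < 2 or events < k:
        raise FitError(f"too few events ({events}) for a PH check on {k} covariates")
    res = proportional_hazard_test(cph, train_df, time_transform="rank")
    summ = res.summary
    pvals = {str(i[0]) if isinstance(i, tuple) else str(i): float(row["p"])
             for i, row in summ.iterrows()}
    stat = float(summ["test_statistic"].sum())
    pvals["global"] = float(sps.chi2.sf(stat, df=k))
    try:
        sched = cph.compute_residuals(train_df, "scaled_schoenfeld")
    except Exception:
        sched = None
    return {"p": pvals, "residuals": sched}


def _roc_points(y: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, score)
    return fpr, tpr


def roc_auc(y, score) -> float:
    """Trapezoidal area under the empirical ROC of a score."""
    y = np.asarray(y, dtype=int)
    s = np.asarray(score, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise FitError("AUC needs both cases and controls")
    if len(np.unique(s)) == 1:
        return 0.5
    fpr, tpr = _roc_points(y, s)
    return float(np.trapezoid(tpr, fpr))


@dataclass
class RocResult:
    """Logistic model of 5-year melanoma-specific death, with ROC/AUC."""

    predictors: tuple
    auc: float
    n_used: int
    n_events: int
    n_excluded: int
    fpr: np.ndarray
    tpr: np.ndarray
    coef: dict


def logistic_5yr(cohort: pd.DataFrame, predictors, horizon: float = 5.0,
                 log_morph: bool = True) -> RocResult:
    """Logistic regression for melanoma-specific death within ``horizon`` years.

    Outcome = melanoma death at or before the horizon.  Subjects censored
    alive before the horizon carry no 5-year status and are excluded; the
    exclusion count is reported.  The AUC is the trapezoidal area under the
    empirical ROC of the fitted probabilities.
    """
    import statsmodels.api as sm

    predictors = tuple(predictors)
    cols = [c for c in predictors]
    for c in cols + ["time_mss", "event_mss"]:
        if c not in cohort.columns:
            raise SchemaError(f"cohort lacks column {c!r}")
    df = cohort[cols + ["time_mss", "event_mss"]].dropna()
    t = df["time_mss"].to_numpy(float)
    e = df["event_mss"].to_numpy(int)
    event_by_h = (e == 1) & (t <= horizon)
    known = event_by_h | (t >= horizon)
    excluded = int((~known).sum()) + (len(cohort) - len(df))
    df = df[known]
    y = event_by_h[known].astype(int)
    if y.sum() < 10:
        raise FitError(f"too few 5-year events ({int(y.sum())}); need >=10")
    X = pd.DataFrame(index=df.index)
    for c in predictors:
        v = df[c].astype(float)
        if log_morph and c in ("area", "perimeter", "major", "dbt", "ni", "breslow"):
            if (v <= 0).any():
                raise FitError(f"non-positive {c!r} in logistic model")
            v = np.log(v)
        X[c] = v
    # a constant predictor is collinear with the intercept: drop it and let
    # the intercept-only model give the chance-level ROC
    X = X.loc[:, X.nunique() > 1]
    X = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0)
    except Exception as e:
        raise FitError(f"logistic fit failed ({predictors}): {e}") from e
    if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 50):
        raise FitError(f"complete separation suspected for predictors {predictors}")
    prob = np.asarray(fit.predict(X))
    if len(np.unique(prob)) == 1:
        fpr, tpr, auc = np.array([0, 1.0]), np.array([0, 1.0]), 0.5
    else:
        fpr, tpr = _roc_points(y, prob)
        auc = roc_auc(y, prob)
    return RocResult(
        predictors=predictors,
        auc=auc,
        n_used=int(len(y)),
        n_events=int(y.sum()),
        n_excluded=excluded,
        fpr=fpr,
        tpr=tpr,
        coef=dict(zip(X.columns, np.asarray(fit.params, dtype=float))),
    )


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise FitError("spearman needs two equal-length vectors of length >=3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise FitError("spearman undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def wilcoxon_subgroup(values, group) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two subgroups.

    Exact enumeration when both groups have n <= 10 and no ties span the
    groups; otherwise the normal approximation with tie correction.
    Returns (rank-sum statistic U of the first group, p).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise FitError(f"need exactly 2 groups, got {len(labels)}")
    a, b = v[g == labels[0]], v[g == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise FitError("empty subgroup")
    exact = len(a) <= 10 and len(b) <= 10 and len(np.unique(v)) == len(v)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=not exact)
    return float(res.statistic), float(res.pvalue)
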