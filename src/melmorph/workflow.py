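"""The full biomarker-evaluation workflow as a Model / Results pair.

``MelanomaSurvivalModel`` is built from a cohort table (five morphometric
biomarkers + covariates + OS/MSS endpoints); ``fit()`` runs the complete
workflow in the published order — quartile Kaplan–Meier curves with log-rank
tests, unadjusted and age/sex/site-adjusted Cox models per log-transformed
biomarker and endpoint, optional bootstrap CIs, Harrell's C, Schoenfeld
proportional-hazards checks, covariate collinearity (Spearman), 5-year
logistic/ROC model comparisons and Wilcoxon subgroup contrasts — and returns
a ``MelanomaSurvivalResults`` carrying every statistic, a ``summary()``
table, plotting helpers and a JSON report.

All p-values are reported raw; the family-wise threshold p <= 0.001 is
flagged alongside, never used to drop results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FitError, SchemaError
from . import survival as sv

__all__ = ["MelanomaSurvivalModel", "MelanomaSurvivalResults", "run_survival_analysis"]

#: Predictor sets compared in the 5-year logistic/ROC stage (run when the
#: needed columns are present).
ROC_SETS = (("breslow",), ("dbt",), ("ni",), ("dbt", "ni"),
            ("ajcc_stage",), ("ajcc_stage", "ni"))

#: Binary subgroup columns contrasted against each biomarker when present.
SUBGROUP_COLS = ("ulceration", "vascular_invasion", "subtype",
                 "mitotic_rate_ge1", "regression", "microsatellitosis",
                 "perineural", "sex", "site")


class MelanomaSurvivalModel:
    """Survival-evaluation model for the five morphometric biomarkers.

    Parameters
    ----------
    cohort : DataFrame
        Per-case table with the biomarker columns, ``age``, ``sex``,
        ``site`` and the ``time_os/event_os/time_mss/event_mss`` endpoints.
    parameters, endpoints : sequences
        Biomarkers and endpoints to evaluate (defaults: all five, OS + MSS).
    alpha : float
        Family-wise significance threshold used for flagging (0.001).
    age_as_binary : bool
        Enter age as the >=50-year indicator instead of continuous years.
    """

    def __init__(self, cohort: pd.DataFrame,
                 parameters=sv.PARAMETERS, endpoints=sv.ENDPOINTS,
                 alpha: float = 0.001, min_cases: int = 50,
                 age_as_binary: bool = False):
        if len(cohort) < min_cases:
            raise SchemaError(
                f"cohort has {len(cohort)} cases; >= {min_cases} required for "
                f"stable quartile groups")
        for p in parameters:
            if p not in cohort.columns:
                raise SchemaError(f"cohort lacks biomarker column {p!r}")
        self.cohort = cohort.copy()
        if age_as_binary and "age" in self.cohort:
            self.cohort["age"] = (self.cohort["age"] >= 50).astype(float)
        self.parameters = tuple(parameters)
        self.endpoints = tuple(endpoints)
        self.alpha = alpha

    @classmethod
    def from_cohort_file(cls, path, **kw) -> "MelanomaSurvivalModel":
        from .mask_io import read_cohort_table

        return cls(read_cohort_table(path), **kw)

    # -- fitting -----------------------------------------------------------

    def fit(self, bootstrap_reps: int = 0,
            seed: int = 20260304) -> "MelanomaSurvivalResults":
        cox = []
        km = {}
        logrank = {}
        errors = {}
        for param in self.parameters:
            groups = sv.quartile_groups(self.cohort[param].to_numpy(float))
            for ep in self.endpoints:
                t = self.cohort[f"time_{ep}"].to_numpy(float)
                e = self.cohort[f"event_{ep}"].to_numpy(int)
                curves = [sv.km_estimate(t[groups == q], e[groups == q], label=q)
                          for q in ("Q1", "Q2", "Q3", "Q4")]
                km[(param, ep)] = curves
                logrank[(param, ep)] = sv.logrank_test(t, e, groups)
                for adjusted in (False, True):
                    try:
                        res = sv.fit_cox(self.cohort, param, ep, adjusted)
                        if adjusted:
                            res.ph_pvals = sv.schoenfeld_ph_check(res)["p"]
                        if bootstrap_reps:
                            res.bootstrap_ci = sv.bootstrap_cox(
                                self.cohort, param, ep, adjusted,
                                B=bootstrap_reps, seed=seed)
                        cox.append(res)
                    except FitError as e_:
                        errors[f"cox:{param}:{ep}:{'adj' if adjusted else 'unadj'}"] = str(e_)

        collinearity = self._covariate_spearman()
        roc = []
        for preds in ROC_SETS:
            if all(p in self.cohort.columns and self.cohort[p].notna().any()
                   for p in preds):
                try:
                    roc.append(sv.logistic_5yr(self.cohort, preds))
                except FitError as e_:
                    errors[f"logistic:{'+'.join(preds)}"] = str(e_)

        subgroups = []
        for col in SUBGROUP_COLS:
            if col not in self.cohort.columns:
                continue
            sub = self.cohort[[col, *self.parameters]].dropna()
            if sub[col].nunique() != 2:
                continue
            for param in self.parameters:
                try:
                    stat, p = sv.wilcoxon_subgroup(
                        sub[param].to_numpy(float), sub[col].to_numpy())
                    subgroups.append({"feature": col, "parameter": param,
                                      "statistic": stat, "p": p,
                                      "significant": p <= self.alpha})
                except FitError as e_:
                    errors[f"wilcoxon:{col}:{param}"] = str(e_)

        return MelanomaSurvivalResults(
            model=self, cox=cox, km=km, logrank=logrank, roc=roc,
            subgroups=subgroups, collinearity=collinearity,
            errors=errors, seed=seed, bootstrap_reps=bootstrap_reps)

    def _covariate_spearman(self) -> dict:
        out = {}
        df = self.cohort
        enc = {
            "age": df["age"].astype(float) if "age" in df else None,
            "sex": (df["sex"].astype(str).str.lower() == "male").astype(float)
            if "sex" in df else None,
            "site": (df["site"].astype(str).str.lower() == "central").astype(float)
            if "site" in df else None,
        }
        names = [k for k, v in enc.items() if v is not None]
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                pair = pd.DataFrame({"a": enc[a], "b": enc[b]}).dropna()
                try:
                    out[f"{a}~{b}"] = sv.spearman(pair["a"], pair["b"])
                except FitError:
                    out[f"{a}~{b}"] = float("nan")
        return out


@dataclass
class MelanomaSurvivalResults:
    """Fitted workflow: every statistic of the evaluation, plus reporting."""

    model: MelanomaSurvivalModel
    cox: list
    km: dict
    logrank: dict
    roc: list
    subgroups: list
    collinearity: dict
    errors: dict
    seed: int
    bootstrap_reps: int
    alpha: float = field(init=False)

    def __post_init__(self) -> None:
        self.alpha = self.model.alpha

    # -- accessors ---------------------------------------------------------

    def cox_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.cox:
            d = r.as_dict()
            d["significant"] = d["p"] <= self.alpha
            rows.append(d)
        return pd.DataFrame(rows)

    def get_cox(self, parameter: str, endpoint: str = "os",
                adjusted: bool = True):
        for r in self.cox:
            if (r.parameter, r.endpoint, r.adjusted) == (parameter, endpoint, adjusted):
                return r
        raise KeyError(f"no Cox fit for ({parameter}, {endpoint}, adjusted={adjusted})")

    def summary(self) -> str:
        """Human-readable summary table of the Cox stage."""
        lines = [
            "Melanoma morphometric biomarker survival evaluation",
            f"cases: {len(self.model.cohort)}   "
            f"significance threshold: p <= {self.alpha}",
            "",
            f"{'parameter':<10}{'endpoint':<9}{'model':<11}"
            f"{'HR':>7}{'95% CI':>17}{'p':>11}{'C':>7}",
        ]
        for r in self.cox:
            flag = " *" if r.p <= self.alpha else ""
            lines.append(
                f"{r.parameter:<10}{r.endpoint.upper():<9}"
                f"{'adjusted' if r.adjusted else 'unadjusted':<11}"
                f"{r.hr:>7.2f}{f'({r.ci_low:.2f}-{r.ci_high:.2f})':>17}"
                f"{r.p:>11.2e}{r.c_index:>7.3f}{flag}")
        if self.roc:
            lines += ["", "5-year melanoma-specific survival (logistic/ROC):"]
            for r in self.roc:
                lines.append(f"  {'+'.join(r.predictors):<22} AUC {r.auc:.3f}  "
                             f"(n={r.n_used}, events={r.n_events}, "
                             f"excluded={r.n_excluded})")
        if self.errors:
            lines += ["", f"stages with errors: {sorted(self.errors)}"]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_report(self) -> dict:
        """Machine-readable report of every computed statistic."""
        return {
            "n_cases": int(len(self.model.cohort)),
            "alpha": self.alpha,
            "seed": self.seed,
            "bootstrap_reps": self.bootstrap_reps,
            "cox": [dict(r.as_dict(), significant=r.p <= self.alpha)
                    for r in self.cox],
            "logrank": {
                f"{p}:{ep}": {"chi2": c, "df": d, "p": pv,
                              "significant": pv <= self.alpha}
                for (p, ep), (c, d, pv) in self.logrank.items()},
            "km": {
                f"{p}:{ep}": [
                    {"label": c.label,
                     "times": c.times.tolist(),
                     "survival": c.survival.tolist(),
                     "at_risk": c.at_risk.tolist()} for c in curves]
                for (p, ep), curves in self.km.items()},
            "roc": [{"predictors": list(r.predictors), "auc": r.auc,
                     "n_used": r.n_used, "n_events": r.n_events,
                     "n_excluded": r.n_excluded} for r in self.roc],
            "subgroups": self.subgroups,
            "covariate_spearman": self.collinearity,
            "errors": self.errors,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_report(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    # -- plots -------------------------------------------------------------

    def plot_km(self, parameter: str, endpoint: str = "os", ax=None):
        """Step plot of the quartile Kaplan–Meier curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for curve in self.km[(parameter, endpoint)]:
            ax.step(np.r_[0, curve.times], np.r_[1.0, curve.survival],
                    where="post", label=curve.label)
        chi2, df, p = self.logrank[(parameter, endpoint)]
        ax.set_xlabel("years")
        ax.set_ylabel("survival probability")
        ax.set_title(f"{parameter} quartiles, {endpoint.upper()} "
                     f"(log-rank p={p:.2e})")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for r in self.roc:
            ax.plot(r.fpr, r.tpr, label=f"{'+'.join(r.predictors)} ({r.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title("Melanoma-specific survival at 5 years")
        ax.legend()
        return ax


def run_survival_analysis(cohort: pd.DataFrame, bootstrap_reps: int = 0,
                          seed: int = 20260304, **model_kw) -> MelanomaSurvivalResults:
    """One-call convenience wrapper: build the model and fit the workflow."""
    return MelanomaSurvivalModel(cohort, **model_kw).fit(
        bootstrap_reps=bootstrap_reps, seed=seed)
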