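"""Kaplan-Meier, log-rank, and Cox proportional-hazards recurrence analysis.

The headline analysis stratifies recurrence-free survival by the AGI
composite: within each stratum (AGI, NGI) it compares the three immune
classes by Kaplan-Meier curves and a log-rank test, then fits crude and
adjusted (age, race, stage, ER) Cox models with Adaptive-Enriched as the
referent. Stage IV and AGI-indeterminate samples are excluded first, and
follow-up is administratively censored at 5 years.

Cox models use Efron tie handling (lifelines' default). The proportionality
assumption is checked by refitting with a covariate x log(time) interaction
as a time-varying covariate (episodic expansion at the event times) and
reporting the interaction's Wald p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .data_io import DataError
from .synthetic import ADAPTIVE, IMMUNE_CLASSES

logger = logging.getLogger("gipipe")


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank
# ---------------------------------------------------------------------------


@dataclass
class KMResult:
    """Per-group product-limit curves and the k-sample log-rank test."""

    curves: dict[str, pd.DataFrame]  # group -> [time, survival, at_risk, censored]
    logrank_chi2: float | None
    logrank_p: float | None
    df: int | None
    skipped_reason: str | None = None


def km_fit(time, event, group) -> KMResult:
    """Product-limit estimator per group plus the log-rank test across groups.

    Groups with zero subjects are dropped with a warning; with fewer than two
    populated groups the log-rank test is skipped with a reason.
    """
    df = pd.DataFrame({"time": time, "event": event, "group": group}).dropna()
    if (df["time"] < 0).any():
        raise DataError("times must be >= 0")
    curves: dict[str, pd.DataFrame] = {}
    for g, sub in df.groupby("group", sort=True):
        if len(sub) == 0:
            logger.warning("km_fit: group %r has zero subjects; dropped", g)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        tab = kmf.event_table
        curve = pd.DataFrame(
            {
                "time": tab.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                "at_risk": tab["at_risk"].to_numpy(dtype=int),
                "censored": tab["censored"].to_numpy(dtype=int),
            }
        )
        curves[str(g)] = curve
    if len(curves) < 2:
        return KMResult(curves, None, None, None,
                        skipped_reason="fewer than 2 populated groups")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return KMResult(
        curves,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
        df=int(res.degrees_of_freedom),
    )


def score_test_at_zero(time, event, group) -> float:
    """Cox partial-likelihood score test chi-square at beta = 0 for a single
    binary covariate (hand-rolled U(0)^2 / I(0); with no tied event times the
    Efron and Breslow likelihoods coincide and this equals the log-rank
    chi-square — the classical identity).
    """
    df = pd.DataFrame({"t": time, "e": event, "x": group}).dropna()
    levels = sorted(df["x"].unique())
    if len(levels) != 2:
        raise DataError(f"score_test_at_zero needs a two-level group, got {levels}")
    x = (df["x"] == levels[1]).astype(float).to_numpy()
    t = df["t"].to_numpy(dtype=float)
    e = df["e"].to_numpy(dtype=int)
    u = 0.0
    info = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n = at_risk.sum()
        xbar = x[at_risk].mean()
        deaths = (t == et) & (e == 1)
        d = deaths.sum()
        u += x[deaths].sum() - d * xbar
        # hypergeometric variance of the number of deaths falling in group 1
        var_x = x[at_risk].var()  # population variance over the risk set
        if n > 1:
            info += d * var_x * (n - d) / (n - 1)
    if info == 0:
        raise DataError("score test undefined: no usable events")
    return float(u * u / info)


# ---------------------------------------------------------------------------
# Cox PH
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    """HR table (one row per covariate) plus optional proportionality p's."""

    table: pd.DataFrame  # index covariate; coef, hr, hr_ci_low, hr_ci_high, p, unstable
    n: int
    n_events: int
    proportionality_p: dict[str, float] = field(default_factory=dict)


def _encode(df: pd.DataFrame, covariates: list[str],
            referents: dict[str, str] | None) -> pd.DataFrame:
    """Numeric columns pass through; categoricals become indicator columns
    against a declared (or sorted-first) referent."""
    referents = referents or {}
    X = pd.DataFrame(index=df.index)
    for cov in covariates:
        col = df[cov]
        if np.issubdtype(col.dtype, np.number):
            X[cov] = col.astype(float)
            continue
        levels = sorted(col.dropna().unique())
        ref = referents.get(cov, levels[0])
        if ref not in levels:
            raise DataError(f"referent {ref!r} absent from {cov!r} levels {levels}")
        for lev in [l for l in levels if l != ref]:
            X[f"{cov}[{lev}]"] = (col == lev).astype(float)
    return X


def cox_fit(
    df: pd.DataFrame,
    *,
    duration_col: str = "recurrence_time",
    event_col: str = "recurrence_event",
    covariates: list[str],
    referents: dict[str, str] | None = None,
    check_proportionality: bool = False,
) -> CoxResult:
    """Cox PH fit (Efron ties) with Wald CIs.

    A categorical level with no events yields a monotone partial likelihood;
    the affected rows are flagged ``unstable`` rather than suppressed.
    """
    data = df[[duration_col, event_col] + covariates].dropna()
    if data[event_col].sum() < 1:
        raise DataError("cox_fit needs at least one event")
    X = _encode(data, covariates, referents)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DataError(f"covariate matrix not full rank: {X.columns.tolist()}")
    fit_df = pd.concat(
        [data[[duration_col, event_col]].astype(float), X], axis=1
    )
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col=duration_col, event_col=event_col)
    summ = cph.summary

    # monotone-likelihood flag: an indicator level whose carriers (or
    # non-carriers) have no events cannot have a finite MLE
    unstable = {}
    ev = data[event_col].to_numpy(dtype=bool)
    for col in X.columns:
        xv = X[col].to_numpy()
        if set(np.unique(xv)) <= {0.0, 1.0}:
            unstable[col] = not (ev[xv == 1].any() and ev[xv == 0].any())
        else:
            unstable[col] = False
        if unstable[col]:
            logger.warning("cox_fit: monotone likelihood for %r; CI unstable", col)

    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "hr_ci_low": summ["exp(coef) lower 95%"],
            "hr_ci_high": summ["exp(coef) upper 95%"],
            "se": summ["se(coef)"],
            "p": summ["p"],
            "unstable": pd.Series(unstable),
        }
    )
    prop: dict[str, float] = {}
    if check_proportionality:
        prop = _logtime_interaction_pvalues(
            fit_df, duration_col, event_col, list(X.columns)
        )
    return CoxResult(
        table=table,
        n=int(len(data)),
        n_events=int(data[event_col].sum()),
        proportionality_p=prop,
    )


def _episodic(fit_df: pd.DataFrame, duration_col: str, event_col: str) -> pd.DataFrame:
    """Counting-process expansion at the distinct event times, with a
    ``log_t`` column holding log(interval end) for time-interaction terms."""
    event_times = np.unique(
        fit_df.loc[fit_df[event_col] == 1, duration_col].to_numpy()
    )
    rows = []
    for rid, row in fit_df.iterrows():
        t = row[duration_col]
        cuts = event_times[event_times <= t]
        if len(cuts) == 0 or cuts[-1] < t:
            cuts = np.append(cuts, t)
        start = 0.0
        for stop in cuts:
            rows.append(
                {
                    "id": rid,
                    "start": start,
                    "stop": stop,
                    "ev": int(row[event_col] == 1 and stop == t),
                    "log_t": np.log(stop),
                    **{c: row[c] for c in fit_df.columns
                       if c not in (duration_col, event_col)},
                }
            )
            start = stop
    return pd.DataFrame(rows)


def _logtime_interaction_pvalues(
    fit_df: pd.DataFrame, duration_col: str, event_col: str, terms: list[str]
) -> dict[str, float]:
    """Wald p of each covariate x log(time) interaction, one refit per term."""
    episodic = _episodic(fit_df, duration_col, event_col)
    out = {}
    for term in terms:
        df = episodic.copy()
        inter = f"{term}:log_t"
        df[inter] = df[term] * df["log_t"]
        ctv = CoxTimeVaryingFitter()
        ctv.fit(
            df[["id", "start", "stop", "ev"] + terms + [inter]],
            id_col="id",
            start_col="start",
            stop_col="stop",
            event_col="ev",
        )
        out[term] = float(ctv.summary.loc[inter, "p"])
    return out


# ---------------------------------------------------------------------------
# AGI-stratified recurrence analysis
# ---------------------------------------------------------------------------


@dataclass
class SurvivalReport:
    """One AGI stratum: KM curves + log-rank + Table-2-shaped Cox rows."""

    stratum: str
    km: KMResult
    cox_rows: pd.DataFrame | None  # index immune class; events, n, crude/adjusted HR+CI
    proportionality_p: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


ADJUSTED_COVARIATES = ("age", "race", "stage", "er_status")


def recurrence_analysis(
    table: pd.DataFrame,
    *,
    referent_class: str = ADAPTIVE,
    admin_censor: float = 5.0,
    adjust: tuple[str, ...] = ADJUSTED_COVARIATES,
    fit_cox: bool = True,
    check_proportionality: bool = False,
) -> tuple[dict[str, SurvivalReport], dict[str, int]]:
    """AGI-stratified recurrence analysis on a merged sample table.

    ``table`` needs columns: sample_id, agi, immune_class, stage, er_status,
    race, age, recurrence_time, recurrence_event. Stage-IV samples,
    AGI-indeterminate samples, and samples missing ER or follow-up are
    excluded (counts returned). Follow-up is administratively censored at
    ``admin_censor`` years — no event after that horizon survives in any
    report. Both strata are always reported, however underpowered.
    """
    df = table.copy()
    exclusions = {"stage_iv": 0, "agi_indeterminate": 0, "missing_er": 0,
                  "missing_followup": 0, "missing_class": 0}

    def _drop(mask: pd.Series, reason: str):
        exclusions[reason] += int(mask.sum())
        if mask.sum():
            logger.info("recurrence_analysis: excluded %d sample(s) (reason=%s)",
                        int(mask.sum()), reason)
        return df.loc[~mask]

    df = _drop(df["stage"] == "IV", "stage_iv")
    df = _drop(~df["agi"].isin(["AGI", "NGI"]), "agi_indeterminate")
    df = _drop(df["er_status"].isna(), "missing_er")
    df = _drop(df["recurrence_time"].isna() | df["recurrence_event"].isna(),
               "missing_followup")
    df = _drop(~df["immune_class"].isin(IMMUNE_CLASSES), "missing_class")

    over = df["recurrence_time"] > admin_censor
    df.loc[over, "recurrence_event"] = 0
    df.loc[over, "recurrence_time"] = admin_censor

    reports: dict[str, SurvivalReport] = {}
    for stratum in ("AGI", "NGI"):
        sub = df[df["agi"] == stratum]
        notes: list[str] = []
        if len(sub) == 0:
            reports[stratum] = SurvivalReport(
                stratum, KMResult({}, None, None, None, "empty stratum"), None,
                notes=["empty stratum"],
            )
            continue
        km = km_fit(sub["recurrence_time"], sub["recurrence_event"],
                    sub["immune_class"])
        if km.skipped_reason:
            notes.append(f"log-rank skipped: {km.skipped_reason}")

        cox_rows = None
        prop: dict[str, float] = {}
        classes_present = [c for c in IMMUNE_CLASSES if (sub["immune_class"] == c).any()]
        if fit_cox and len(classes_present) >= 2 and sub["recurrence_event"].sum() >= 1 \
                and referent_class in classes_present:
            try:
                crude = cox_fit(
                    sub, covariates=["immune_class"],
                    referents={"immune_class": referent_class},
                )
                adjusted = cox_fit(
                    sub, covariates=["immune_class", *adjust],
                    referents={"immune_class": referent_class, "stage": "I"},
                    check_proportionality=check_proportionality,
                )
                prop = adjusted.proportionality_p
                rows = []
                for cls in classes_present:
                    n_cls = int((sub["immune_class"] == cls).sum())
                    ev_cls = int(sub.loc[sub["immune_class"] == cls,
                                         "recurrence_event"].sum())
                    if cls == referent_class:
                        rows.append({"immune_class": cls, "events": ev_cls, "n": n_cls,
                                     "crude_hr": 1.0, "crude_ci_low": np.nan,
                                     "crude_ci_high": np.nan, "adj_hr": 1.0,
                                     "adj_ci_low": np.nan, "adj_ci_high": np.nan,
                                     "unstable": False})
                        continue
                    key = f"immune_class[{cls}]"
                    rows.append({
                        "immune_class": cls, "events": ev_cls, "n": n_cls,
                        "crude_hr": crude.table.loc[key, "hr"],
                        "crude_ci_low": crude.table.loc[key, "hr_ci_low"],
                        "crude_ci_high": crude.table.loc[key, "hr_ci_high"],
                        "adj_hr": adjusted.table.loc[key, "hr"],
                        "adj_ci_low": adjusted.table.loc[key, "hr_ci_low"],
                        "adj_ci_high": adjusted.table.loc[key, "hr_ci_high"],
                        "unstable": bool(crude.table.loc[key, "unstable"]
                                         or adjusted.table.loc[key, "unstable"]),
                    })
                cox_rows = pd.DataFrame(rows).set_index("immune_class")
            except DataError as exc:
                notes.append(f"cox skipped: {exc}")
        elif fit_cox:
            notes.append("cox skipped: insufficient classes or events")
        reports[stratum] = SurvivalReport(stratum, km, cox_rows,
                                          proportionality_p=prop, notes=notes)
    return reports, exclusions
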