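"""Welch t tests, relative frequency differences, and differential scores.

The relative frequency difference (RFD) is the percentage-point difference in
outcome frequency between an index and a referent exposure group, estimated by
a binomial GLM with an *identity* link so the exposure coefficient is the
frequency difference itself (x100 for percentage points), optionally adjusted
for covariates (age + race in the defaults). Identity-link binomial models can
fail: iteration failure or fitted probabilities escaping [0, 1] is reported as
a first-class non-converged ("DNC") result — the link is never silently
swapped for a logit.

Differential immune-score analysis fits, per score, a linear model
score ~ group + covariates and corrects the family of scores tested within
one contrast by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data_io import DataError

DNC = "DNC"


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------


@dataclass
class WelchResult:
    t: float
    df: float  # Welch-Satterthwaite degrees of freedom
    p: float  # two-sided


def welch_t(x, y) -> WelchResult:
    """Welch two-sample t test (unequal variances), two-sided."""
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    y = np.asarray(pd.Series(y).dropna(), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("welch_t needs >=2 non-missing values per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) == np.mean(y):
        raise DataError("welch_t undefined: zero variance in both groups, equal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


# ---------------------------------------------------------------------------
# RFD via identity-link binomial GLM
# ---------------------------------------------------------------------------


@dataclass
class RFDResult:
    """One exposure-level contrast (index vs referent) for one binary outcome.

    ``rfd`` and the CI bounds are percentage points. When ``converged`` is
    False the estimate fields are None and ``reason`` says why (``DNC`` for
    iteration/feasibility failure, ``degenerate outcome`` for a constant
    outcome).
    """

    outcome_name: str
    index_level: str
    referent_level: str
    converged: bool
    rfd: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_index: int = 0
    n_referent: int = 0
    covariates: list[str] = field(default_factory=list)
    reason: str | None = None


def _design(exposure: pd.Series, referent: str, covariates: pd.DataFrame | None):
    levels = [referent] + sorted(set(exposure.dropna()) - {referent})
    X = pd.DataFrame(index=exposure.index)
    X["const"] = 1.0
    for lev in levels[1:]:
        X[f"exposure[{lev}]"] = (exposure == lev).astype(float)
    if covariates is not None and covariates.shape[1]:
        covs = covariates.copy()
        for col in covs.columns:
            if not np.issubdtype(covs[col].dtype, np.number):
                dummies = pd.get_dummies(covs[col], prefix=col, drop_first=True)
                covs = covs.drop(columns=[col]).join(dummies.astype(float))
        rank = np.linalg.matrix_rank(pd.concat([X, covs], axis=1).to_numpy())
        if rank < X.shape[1] + covs.shape[1]:
            raise DataError(
                f"collinear covariate set: {covs.columns.tolist()}"
            )
        X = pd.concat([X, covs], axis=1)
    return X, levels[1:]


def estimate_rfd(
    outcome: pd.Series,
    exposure: pd.Series,
    *,
    covariates: pd.DataFrame | None = None,
    referent: str | None = None,
    outcome_name: str = "outcome",
    method: str = "glm",
) -> list[RFDResult]:
    """Identity-link binomial GLM; one RFDResult per non-referent level.

    With no covariates and a single binary exposure the fit reproduces the raw
    difference in proportions exactly (the closed form of the linear
    probability model).

    ``method="lpm"`` requests the least-squares linear-probability model with
    heteroskedasticity-robust (HC1) standard errors instead. It must be asked
    for explicitly: a failed identity-link binomial fit is reported as DNC,
    never silently re-estimated.
    """
    data = pd.DataFrame({"y": outcome, "x": exposure})
    if covariates is not None:
        covariates = covariates.loc[data.index]
    keep = data.notna().all(axis=1)
    if covariates is not None:
        keep &= covariates.notna().all(axis=1)
    data = data[keep]
    covs = covariates[keep] if covariates is not None else None
    if referent is None:
        referent = sorted(data["x"].unique())[0]
    if referent not in set(data["x"]):
        raise DataError(f"referent level {referent!r} has no observations")

    X, index_levels = _design(data["x"], referent, covs)
    cov_names = [c for c in X.columns if not c.startswith(("const", "exposure["))]
    n_by_level = data["x"].value_counts()

    def _failure(reason: str) -> list[RFDResult]:
        return [
            RFDResult(
                outcome_name=outcome_name,
                index_level=lev,
                referent_level=referent,
                converged=False,
                reason=reason,
                n_index=int(n_by_level.get(lev, 0)),
                n_referent=int(n_by_level.get(referent, 0)),
                covariates=cov_names,
            )
            for lev in index_levels
        ]

    y = data["y"].astype(float)
    if y.nunique() < 2:
        return _failure("degenerate outcome")

    if method == "lpm":
        fit = sm.OLS(y, X).fit(cov_type="HC1")
        ci = fit.conf_int()
        return [
            RFDResult(
                outcome_name=outcome_name,
                index_level=lev,
                referent_level=referent,
                converged=True,
                rfd=100.0 * float(fit.params[f"exposure[{lev}]"]),
                ci_low=100.0 * float(ci.loc[f"exposure[{lev}]", 0]),
                ci_high=100.0 * float(ci.loc[f"exposure[{lev}]", 1]),
                n_index=int(n_by_level.get(lev, 0)),
                n_referent=int(n_by_level.get(referent, 0)),
                covariates=cov_names,
            )
            for lev in index_levels
        ]
    if method != "glm":
        raise DataError(f"method must be 'glm' or 'lpm', got {method!r}")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start = np.linalg.lstsq(X.to_numpy(), y.to_numpy(), rcond=None)[0]
            model = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Identity()))
            fit = model.fit(start_params=start, maxiter=200)
        mu = np.asarray(fit.fittedvalues, dtype=float)
        ok = (
            getattr(fit, "converged", True)
            and np.all(np.isfinite(fit.params))
            and np.all(np.isfinite(fit.bse))
            and np.all(mu > 0.0)
            and np.all(mu < 1.0)
        )
    except (PerfectSeparationError, ValueError, np.linalg.LinAlgError, FloatingPointError):
        ok = False
    if not ok:
        return _failure(DNC)

    ci = fit.conf_int()
    results = []
    for lev in index_levels:
        name = f"exposure[{lev}]"
        results.append(
            RFDResult(
                outcome_name=outcome_name,
                index_level=lev,
                referent_level=referent,
                converged=True,
                rfd=100.0 * float(fit.params[name]),
                ci_low=100.0 * float(ci.loc[name, 0]),
                ci_high=100.0 * float(ci.loc[name, 1]),
                n_index=int(n_by_level.get(lev, 0)),
                n_referent=int(n_by_level.get(referent, 0)),
                covariates=cov_names,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Differential immune-score analysis with BH correction
# ---------------------------------------------------------------------------


def differential_scores(
    score_table: pd.DataFrame,
    group: pd.Series,
    *,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-score linear model ``score ~ group + covariates``.

    ``group`` is a binary contrast (0 = referent, 1 = index, or a two-level
    categorical whose sorted second level is the index). Returns one row per
    score: beta (adjusted mean difference, expression units), se, p, and the
    Benjamini-Hochberg q over the family of scores in this contrast.
    """
    group = pd.Series(group)
    levels = sorted(group.dropna().unique())
    if len(levels) != 2:
        raise DataError(f"group must be binary, got levels {levels}")
    g = (group == levels[1]).astype(float)
    g[group.isna()] = np.nan

    rows = []
    for score in score_table.columns:
        df = pd.DataFrame({"score": score_table[score], "g": g})
        if covariates is not None:
            covariates = covariates.loc[score_table.index]
        keep = df.notna().all(axis=1)
        if covariates is not None:
            keep &= covariates.notna().all(axis=1)
        df = df[keep]
        for lev, n in ((0.0, (df["g"] == 0).sum()), (1.0, (df["g"] == 1).sum())):
            if n < 2:
                raise DataError(
                    f"score {score!r}: need >=2 samples per group, "
                    f"group {lev:g} has {n}"
                )
        X, _ = _design(
            df["g"].map({0.0: "ref", 1.0: "idx"}),
            "ref",
            covariates[keep] if covariates is not None else None,
        )
        fit = sm.OLS(df["score"].astype(float), X).fit()
        rows.append(
            {
                "score_name": score,
                "beta": float(fit.params["exposure[idx]"]),
                "se": float(fit.bse["exposure[idx]"]),
                "p": float(fit.pvalues["exposure[idx]"]),
                "n": int(len(df)),
            }
        )
    out = pd.DataFrame(rows).set_index("score_name")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
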