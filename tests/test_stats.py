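"""Welch tests, identity-link RFD models, differential scores, BH."""

import numpy as np
import pandas as pd
import pytest

import gipipe
from gipipe.data_io import DataError
from gipipe.stats import DNC


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------


def test_welch_identical_samples():
    res = gipipe.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == 0.0
    assert res.p == pytest.approx(1.0)


def test_welch_matches_hand_formulas():
    """Welch statistic and Satterthwaite df recomputed from first principles."""
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 3.0, 4.0, 5.0, 7.0])
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t_expected = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df_expected = (vx + vy) ** 2 / (
        vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1)
    )
    res = gipipe.welch_t(x, y)
    assert res.t == pytest.approx(t_expected, abs=1e-12)
    assert res.df == pytest.approx(df_expected, abs=1e-9)


def test_welch_preconditions():
    with pytest.raises(DataError):
        gipipe.welch_t([1.0], [1.0, 2.0])
    with pytest.raises(DataError):
        gipipe.welch_t([2.0, 2.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# RFD (identity-link binomial GLM)
# ---------------------------------------------------------------------------


def _binary_cohort(p_index, p_referent, n=200, seed=0):
    rng = np.random.default_rng(seed)
    exposure = pd.Series(["idx"] * n + ["ref"] * n)
    outcome = pd.Series(
        np.r_[rng.random(n) < p_index, rng.random(n) < p_referent].astype(float)
    )
    return outcome, exposure


def test_rfd_equals_proportion_difference_exactly():
    # constructed 2x2: index 60/100 vs referent 40/100 -> RFD 20.0
    outcome = pd.Series([1.0] * 60 + [0.0] * 40 + [1.0] * 40 + [0.0] * 60)
    exposure = pd.Series(["idx"] * 100 + ["ref"] * 100)
    (res,) = gipipe.estimate_rfd(outcome, exposure, referent="ref")
    assert res.converged
    assert res.rfd == pytest.approx(20.0, abs=1e-8)
    assert res.ci_low <= res.rfd <= res.ci_high
    assert (res.n_index, res.n_referent) == (100, 100)


@pytest.mark.parametrize("seed", range(5))
def test_unadjusted_rfd_is_proportion_difference_on_random_data(seed):
    rng = np.random.default_rng(seed)
    p_i, p_r = rng.uniform(0.2, 0.8, size=2)
    outcome, exposure = _binary_cohort(p_i, p_r, n=150, seed=seed + 100)
    (res,) = gipipe.estimate_rfd(outcome, exposure, referent="ref")
    expected = 100.0 * (
        outcome[exposure == "idx"].mean() - outcome[exposure == "ref"].mean()
    )
    assert res.rfd == pytest.approx(expected, abs=1e-8)


def test_rfd_degenerate_outcome():
    outcome = pd.Series([0.0] * 40)
    exposure = pd.Series(["idx"] * 20 + ["ref"] * 20)
    (res,) = gipipe.estimate_rfd(outcome, exposure, referent="ref")
    assert not res.converged
    assert res.reason == "degenerate outcome"
    assert res.rfd is None


def test_rfd_complete_separation_is_dnc():
    # outcome identical to exposure: fitted probabilities hit 0 and 1
    outcome = pd.Series([1.0] * 30 + [0.0] * 30)
    exposure = pd.Series(["idx"] * 30 + ["ref"] * 30)
    (res,) = gipipe.estimate_rfd(outcome, exposure, referent="ref")
    assert not res.converged
    assert res.reason == DNC


def test_rfd_missing_referent_errors():
    outcome, exposure = _binary_cohort(0.5, 0.5)
    with pytest.raises(DataError, match="referent"):
        gipipe.estimate_rfd(outcome, exposure, referent="nope")


def test_adjusted_rfd_close_to_crude_without_confounding(rng):
    outcome, exposure = _binary_cohort(0.6, 0.4, n=400, seed=1)
    covs = pd.DataFrame(
        {"age": rng.normal(50, 10, 800), "race": rng.choice(["Black", "non-Black"], 800)}
    )
    (crude,) = gipipe.estimate_rfd(outcome, exposure, referent="ref")
    (adj,) = gipipe.estimate_rfd(outcome, exposure, covariates=covs, referent="ref")
    assert adj.converged
    assert adj.covariates  # age + race indicator recorded
    assert adj.rfd == pytest.approx(crude.rfd, abs=5.0)


def test_adjusted_and_crude_diverge_under_constructed_confounding():
    """When race drives both exposure and outcome, the race-adjusted RFD
    must move away from the crude one (the crude estimate absorbs the
    confounding path)."""
    rng = np.random.default_rng(7)
    n = 4000
    race = rng.choice(["Black", "non-Black"], n)
    p_exposed = np.where(race == "Black", 0.8, 0.2)
    exposure = pd.Series(np.where(rng.random(n) < p_exposed, "idx", "ref"))
    p_outcome = 0.3 + 0.3 * (race == "Black")
    outcome = pd.Series((rng.random(n) < p_outcome).astype(float))
    covs = pd.DataFrame({"race": race})
    (crude,) = gipipe.estimate_rfd(outcome, exposure, referent="ref")
    (adj,) = gipipe.estimate_rfd(outcome, exposure, covariates=covs, referent="ref")
    assert abs(crude.rfd) > abs(adj.rfd) + 5.0  # confounding inflates the crude RFD


def test_multilevel_exposure_one_result_per_level():
    rng = np.random.default_rng(3)
    exposure = pd.Series(rng.choice(["quiet", "adaptive", "innate"], 300))
    outcome = pd.Series((rng.random(300) < 0.4).astype(float))
    results = gipipe.estimate_rfd(outcome, exposure, referent="quiet")
    assert sorted(r.index_level for r in results) == ["adaptive", "innate"]
    for r in results:
        assert r.referent_level == "quiet"


# ---------------------------------------------------------------------------
# Differential scores + BH
# ---------------------------------------------------------------------------


def _bh_oracle(pvals):
    """Step-up BH recomputed by hand."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        q[i] = prev
    return q


def test_beta_equals_group_mean_difference_without_covariates(rng):
    scores = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("wxyz"))
    group = pd.Series(rng.integers(0, 2, 80))
    res = gipipe.differential_scores(scores, group)
    for name in scores.columns:
        expected = scores.loc[group == 1, name].mean() - scores.loc[group == 0, name].mean()
        assert res.loc[name, "beta"] == pytest.approx(expected, abs=1e-10)


def test_q_values_match_hand_bh_and_invariants(rng):
    scores = pd.DataFrame(rng.normal(size=(60, 10)),
                          columns=[f"sc{i}" for i in range(10)])
    scores["sc0"] += rng.normal(0, 1, 60) + 2.0 * rng.integers(0, 2, 60)
    group = pd.Series(rng.integers(0, 2, 60))
    res = gipipe.differential_scores(scores, group)
    np.testing.assert_allclose(res["q"], _bh_oracle(res["p"]), atol=1e-12)
    assert (res["q"] >= res["p"] - 1e-12).all()
    # column order must not matter
    res2 = gipipe.differential_scores(scores[scores.columns[::-1]], group)
    pd.testing.assert_series_equal(
        res["q"].sort_index(), res2["q"].sort_index()
    )
    # BH never declares more discoveries than raw p at the same threshold
    assert (res["q"] < 0.05).sum() <= (res["p"] < 0.05).sum()


def test_differential_scores_on_synthetic_contrast():
    """Adaptive marker scores separate TP53 Mut-like from WT-like (elevation
    travels through the AGI-linked immune mix), while pure noise genes stay
    centered at zero."""
    cfg = gipipe.default_config(n_samples=1000, seed=17)
    cohort = gipipe.generate_cohort(cfg)
    panel = gipipe.default_marker_panel()
    noise_panel = gipipe.MarkerPanel(
        "noise", {f"noise{i}": [f"NOISE_{i:03d}"] for i in range(1, 11)}
    )
    truth = cohort.truth.set_index("sample_id")
    scores = gipipe.compute_scores(cohort.expression, panel)
    noise_scores = gipipe.compute_scores(cohort.expression, noise_panel)
    group = (truth["tp53"] == "Mut-like").astype(int)
    res = gipipe.differential_scores(scores[["adaptive", "overall-immune"]], group)
    assert (res["q"] < 0.05).all()
    assert (res["beta"] > 0).all()
    null_res = gipipe.differential_scores(noise_scores, group)
    assert null_res["beta"].abs().max() < 0.2


def test_collinear_covariates_named(rng):
    scores = pd.DataFrame({"sc": rng.normal(size=50)})
    group = pd.Series(rng.integers(0, 2, 50))
    covs = pd.DataFrame({"a": np.arange(50.0), "b": 2.0 * np.arange(50.0)})
    with pytest.raises(DataError, match="collinear"):
        gipipe.differential_scores(scores, group, covariates=covs)


def test_lpm_fallback_only_on_request():
    """The linear-probability fallback handles the complete-separation case
    the identity-link GLM reports as DNC, but only when asked for."""
    outcome = pd.Series([1.0] * 30 + [0.0] * 30)
    exposure = pd.Series(["idx"] * 30 + ["ref"] * 30)
    (dnc,) = gipipe.estimate_rfd(outcome, exposure, referent="ref")
    assert not dnc.converged
    (lpm,) = gipipe.estimate_rfd(outcome, exposure, referent="ref", method="lpm")
    assert lpm.converged
    assert lpm.rfd == pytest.approx(100.0, abs=1e-8)
    with pytest.raises(DataError, match="method"):
        gipipe.estimate_rfd(outcome, exposure, referent="ref", method="logit")
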