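"""Nearest-centroid training and classification against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import gipipe
from gipipe.data_io import DataError


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return gipipe.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _rank(v):
    """Average ranks, independent of scipy."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _spearman_oracle(x, y):
    rx, ry = _rank(x), _rank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def test_train_two_point_separation():
    expr = _expr([[1.0, 1.0, 0.0, 0.0]])
    labels = pd.Series({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
    cs = gipipe.train_centroids(expr, labels, class_order=["A", "B"])
    np.testing.assert_allclose(cs.centroid_values, [[1.0], [0.0]])


def test_train_matches_brute_force_class_means(rng):
    expr = _expr(rng.normal(size=(20, 30)))
    labels = pd.Series(rng.choice(["A", "B", "C"], size=30),
                       index=[f"s{j}" for j in range(30)])
    cs = gipipe.train_centroids(expr, labels)
    for ci, cls in enumerate(cs.class_labels):
        members = [s for s in labels.index if labels[s] == cls]
        expected = expr.df[members].to_numpy().mean(axis=1)
        np.testing.assert_allclose(cs.centroid_values[ci], expected, atol=1e-12)


def test_train_singleton_class_equals_its_sample(rng):
    expr = _expr(rng.normal(size=(6, 3)))
    labels = pd.Series({"s0": "A", "s1": "A", "s2": "lone"})
    cs = gipipe.train_centroids(expr, labels, class_order=["A", "lone"])
    np.testing.assert_allclose(cs.centroid_values[1], expr.df["s2"].to_numpy())


def test_train_empty_class_and_clamp(rng):
    expr = _expr(rng.normal(size=(4, 4)))
    labels = pd.Series({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
    with pytest.raises(DataError, match="ghost"):
        gipipe.train_centroids(expr, labels, class_order=["A", "B", "ghost"])
    with pytest.warns(UserWarning, match="clamp"):
        cs = gipipe.train_centroids(expr, labels, genes_per_class=10)
    assert len(cs.gene_ids) == 4


def test_train_gene_selection_prefers_separating_genes(rng):
    # one strongly separating gene among pure-noise genes
    noise = rng.normal(size=(9, 40))
    signal = np.r_[np.zeros(20), np.ones(20) * 5][None, :]
    expr = _expr(np.vstack([noise, signal]))
    labels = pd.Series(["A"] * 20 + ["B"] * 20, index=[f"s{j}" for j in range(40)])
    cs = gipipe.train_centroids(expr, labels, genes_per_class=1)
    assert cs.gene_ids == ["g9"]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def test_self_centroid_has_spearman_one(rng):
    profile = rng.normal(size=12)
    cs = gipipe.CentroidSet(
        "sig", ["A", "B"], [f"g{i}" for i in range(12)],
        np.vstack([profile, profile[::-1]]),
    )
    expr = _expr(profile[:, None], samples=["s0"])
    calls = gipipe.classify(expr, cs)
    assert calls.loc["s0", "label"] == "A"
    assert calls.loc["s0", "sim_A"] == pytest.approx(1.0)


@pytest.mark.parametrize("with_missing", [False, True])
def test_similarities_match_brute_force_rank_correlation(rng, with_missing):
    values = rng.normal(size=(25, 5))
    if with_missing:
        values[3, 2] = np.nan  # exercises the per-sample loop path
    expr = _expr(values)
    cents = rng.normal(size=(3, 25))
    cs = gipipe.CentroidSet("sig", ["A", "B", "C"],
                            [f"g{i}" for i in range(25)], cents)
    calls = gipipe.classify(expr, cs)
    for s in expr.sample_ids:
        x = expr.df[s].to_numpy()
        ok = ~np.isnan(x)
        for ci, cls in enumerate(cs.class_labels):
            expected = _spearman_oracle(x[ok], cents[ci][ok])
            assert calls.loc[s, f"sim_{cls}"] == pytest.approx(expected, abs=1e-10)
        best = max(cs.class_labels,
                   key=lambda c: calls.loc[s, f"sim_{c}"])
        assert calls.loc[s, "label"] == best


def test_all_missing_sample_is_uncallable(rng):
    values = rng.normal(size=(10, 2))
    values[:, 1] = np.nan
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(10)],
                      columns=["ok", "empty"])
    expr = gipipe.ExpressionMatrix(df, max_missing_fraction=1.0)
    cs = gipipe.CentroidSet("sig", ["A", "B"], [f"g{i}" for i in range(10)],
                            rng.normal(size=(2, 10)))
    calls = gipipe.classify(expr, cs)
    assert calls.loc["empty", "label"] == "missing"
    assert np.isnan(calls.loc["empty", "sim_A"])
    assert calls.loc["ok", "label"] in ("A", "B")


def test_empty_gene_intersection_names_both_universes(rng):
    expr = _expr(rng.normal(size=(3, 2)), genes=["x1", "x2", "x3"])
    cs = gipipe.CentroidSet("sig", ["A", "B"], ["y1", "y2"],
                            rng.normal(size=(2, 2)))
    with pytest.raises(DataError, match=r"x1.*y1"):
        gipipe.classify(expr, cs)


def test_exact_tie_goes_to_first_declared_class(rng):
    profile = rng.normal(size=8)
    cs = gipipe.CentroidSet("sig", ["First", "Second"],
                            [f"g{i}" for i in range(8)],
                            np.vstack([profile, profile]))
    calls = gipipe.classify(_expr(profile[:, None], samples=["s0"]), cs)
    assert calls.loc["s0", "label"] == "First"
    assert bool(calls.loc["s0", "tie_flag"])


def test_spearman_invariant_to_monotone_transform_and_gene_order(rng):
    values = rng.normal(size=(30, 10))
    expr = _expr(values)
    cs = gipipe.CentroidSet("sig", ["A", "B"], [f"g{i}" for i in range(30)],
                            rng.normal(size=(2, 30)))
    base = gipipe.classify(expr, cs)["label"]

    transformed = gipipe.classify(_expr(np.exp(values / 3) + values ** 3), cs)["label"]
    pd.testing.assert_series_equal(base, transformed)

    perm = rng.permutation(30)
    permuted_expr = gipipe.ExpressionMatrix(expr.df.iloc[perm])
    pd.testing.assert_series_equal(base, gipipe.classify(permuted_expr, cs)["label"])


def test_train_then_classify_recovers_training_labels(rng):
    # well-separated classes: distinct mean patterns, modest noise
    patterns = {"A": rng.normal(size=15), "B": rng.normal(size=15)}
    labels = pd.Series(rng.choice(["A", "B"], size=40),
                       index=[f"s{j}" for j in range(40)])
    values = np.column_stack([patterns[labels[s]] * 3 + rng.normal(0, 0.3, 15)
                              for s in labels.index])
    expr = _expr(values)
    cs = gipipe.train_centroids(expr, labels, class_order=["A", "B"])
    calls = gipipe.classify(expr, cs)
    assert (calls["label"] == labels).all()


# ---------------------------------------------------------------------------
# Signature binding
# ---------------------------------------------------------------------------


def test_signature_vocabulary_mapping_and_mismatch(rng):
    cs = gipipe.CentroidSet("tp53", ["c1", "c2"], [f"g{i}" for i in range(5)],
                            rng.normal(size=(2, 5)))
    with pytest.raises(DataError, match="vocabulary"):
        gipipe.SignatureConfig(cs, ["only-one"])
    expr = _expr(rng.normal(size=(5, 3)))
    calls = gipipe.call_signature(expr, gipipe.SignatureConfig(cs, ["Mut-like", "WT-like"]))
    assert set(calls["label"]) <= {"Mut-like", "WT-like"}
    assert {"sim_Mut-like", "sim_WT-like"} <= set(calls.columns)


def test_absent_hrd_genes_leave_agi_indeterminate_for_wt():
    """With no HRD genes in the matrix the HRD call is missing everywhere and
    AGI is indeterminate exactly where TP53 is WT-like."""
    cfg = gipipe.default_config(n_samples=80, seed=13)
    cohort = gipipe.generate_cohort(cfg)
    cents = gipipe.true_centroids(cfg)
    keep = [g for g in cohort.expression.gene_ids if not g.startswith("HRDSIG")]
    expr = gipipe.ExpressionMatrix(cohort.expression.df.loc[keep])
    tp53 = gipipe.call_signature(expr, gipipe.SignatureConfig(cents["tp53"], ["Mut-like", "WT-like"]))
    with pytest.raises(DataError):
        gipipe.classify(expr, cents["hrd"])  # empty intersection is an error
    hrd_missing = pd.Series("missing", index=tp53.index)
    agi = gipipe.call_agi(tp53["label"], hrd_missing)
    wt = tp53["label"] == "WT-like"
    assert (agi.loc[wt, "agi"] == "indeterminate").all()
    assert (agi.loc[~wt, "agi"] == "AGI").all()
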