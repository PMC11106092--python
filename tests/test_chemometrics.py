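"""PLS-DA fitting, VIP scores and feature selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from msemarker.chemometrics import (
    class_presence_filter,
    fit_plsda,
    select_top_k,
    vip_scores,
)


def make_table(X, prefix="FT"):
    n, p = X.shape
    return pd.DataFrame(
        X,
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        columns=[f"{prefix}{j:03d}" for j in range(p)],
    )


def binary_labels(n0, n1):
    labels = {f"s{i}": "non-heated" for i in range(n0)}
    labels.update({f"s{i}": "heated" for i in range(n0, n0 + n1)})
    return labels


def test_perfectly_separating_feature_separates_scores():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (12, 20))
    X[:6, 0] = -5.0
    X[6:, 0] = 5.0
    table = make_table(X)
    labels = binary_labels(6, 6)
    model = fit_plsda(table, labels)
    t1 = model.scores[:, 0]
    assert (np.sign(t1[:6]) != np.sign(t1[6:])).all() or (
        len(set(np.sign(t1[:6]))) == 1 and len(set(np.sign(t1[6:]))) == 1
    )
    vip = vip_scores(model)
    assert vip.ranking().index[0] == "FT000"


def test_score_vectors_are_orthogonal():
    rng = np.random.default_rng(2)
    table = make_table(rng.normal(size=(10, 30)))
    labels = binary_labels(5, 5)
    model = fit_plsda(table, labels)
    t = model.scores
    assert abs(t[:, 0] @ t[:, 1]) < 1e-8 * np.linalg.norm(t[:, 0]) * np.linalg.norm(t[:, 1])
    assert np.linalg.norm(model.weights, axis=0) == pytest.approx([1.0, 1.0])


def test_matches_reference_pls_implementation():
    """Scores and weights reproduce scikit-learn's PLS (up to sign)."""
    rng = np.random.default_rng(3)
    for trial in range(3):
        n, p = 14, 40
        X = rng.normal(size=(n, p))
        y = np.array([0.0] * 7 + [1.0] * 7)
        table = make_table(X)
        labels = binary_labels(7, 7)
        model = fit_plsda(table, labels, n_components=2)
        ref = PLSRegression(n_components=2, scale=True).fit(X, y)
        for a in range(2):
            sign = np.sign(model.weights[:, a] @ ref.x_weights_[:, a])
            np.testing.assert_allclose(
                model.weights[:, a], sign * ref.x_weights_[:, a], atol=1e-6
            )
            np.testing.assert_allclose(
                model.scores[:, a], sign * ref.x_scores_[:, a], atol=1e-6
            )


def test_nan_treated_as_zero_intensity():
    X = np.array([[1.0, np.nan], [2.0, 1.0], [3.0, 2.0], [4.0, 1.0]])
    table = make_table(X)
    model = fit_plsda(table, binary_labels(2, 2))
    X2 = X.copy()
    X2[0, 1] = 0.0
    model2 = fit_plsda(make_table(X2), binary_labels(2, 2))
    np.testing.assert_allclose(model.scores, model2.scores)


def test_zero_variance_columns_dropped_not_zero_vip():
    X = np.random.default_rng(4).normal(size=(8, 5))
    X[:, 2] = 7.0
    with pytest.warns(UserWarning):
        model = fit_plsda(make_table(X), binary_labels(4, 4))
    vip = vip_scores(model)
    assert "FT002" in model.dropped
    assert "FT002" not in vip.scores.index
    assert len(vip.scores) == 4


def test_single_class_rejected():
    X = np.ones((4, 3))
    labels = {f"s{i}": "heated" for i in range(4)}
    with pytest.raises(ValueError):
        fit_plsda(make_table(X), labels)


def test_vip_identity_sum_of_squares_equals_p():
    rng = np.random.default_rng(5)
    for n, p in [(8, 10), (16, 200)]:
        X = rng.normal(size=(n, p))
        model = fit_plsda(make_table(X), binary_labels(n // 2, n // 2))
        vip = vip_scores(model)
        assert (vip.scores**2).sum() == pytest.approx(len(vip.scores), rel=1e-8)


def test_identical_columns_give_unit_vip():
    base = np.array([1.0, 2.0, 1.5, 3.0, 4.0, 3.5])
    X = np.tile(base[:, None], (1, 6))
    model = fit_plsda(make_table(X), binary_labels(3, 3), n_components=1)
    vip = vip_scores(model)
    np.testing.assert_allclose(vip.scores.to_numpy(), 1.0, atol=1e-8)


def test_vip_invariant_to_feature_order_and_global_rescaling():
    rng = np.random.default_rng(6)
    X = rng.lognormal(size=(10, 25))
    labels = binary_labels(5, 5)
    vip1 = vip_scores(fit_plsda(make_table(X), labels)).scores
    perm = rng.permutation(25)
    table_perm = make_table(X).iloc[:, perm]
    vip2 = vip_scores(fit_plsda(table_perm, labels)).scores
    pd.testing.assert_series_equal(vip1.sort_index(), vip2.sort_index())
    vip3 = vip_scores(fit_plsda(make_table(X * 1e4), labels)).scores
    np.testing.assert_allclose(vip1.to_numpy(), vip3.to_numpy(), rtol=1e-8)


def test_permuted_labels_select_no_consistent_features():
    """Permutation oracle: with pure noise and randomly permuted labels the
    VIP top features are arbitrary — no feature is selected consistently —
    whereas a planted 4-fold signal puts its markers on top every time.

    (A score-separation statistic cannot serve here: the first PLS1
    component aligns with y by construction, so at n << p even permuted
    labels 'separate'. Selection stability is the meaningful null.)
    """
    rng = np.random.default_rng(7)
    Xn = rng.lognormal(sigma=0.3, size=(16, 100))
    from collections import Counter

    counts = Counter()
    n_perm = 12
    for _ in range(n_perm):
        ids = list(rng.permutation(16))
        labels = {
            f"s{i}": ("heated" if rank < 8 else "non-heated")
            for rank, i in enumerate(ids)
        }
        vip = vip_scores(fit_plsda(make_table(Xn), labels))
        counts.update(vip.ranking().index[:5])
    # no noise feature should be a stable selection across permutations
    assert counts.most_common(1)[0][1] <= n_perm // 2

    Xsig = Xn.copy()
    Xsig[8:, :5] *= 4.0
    vip = vip_scores(fit_plsda(make_table(Xsig), binary_labels(8, 8)))
    assert set(vip.ranking().index[:5]) == {f"FT{j:03d}" for j in range(5)}


def test_select_top_k_shapes_and_tie_rule():
    meta = pd.DataFrame(
        {
            "feature_id": [f"FT{j}" for j in range(5)],
            "mz": np.linspace(400, 800, 5),
            "rt_s": np.linspace(100, 400, 5),
            "charge": [1, 2, 3, 2, 1],
        }
    )
    from msemarker.chemometrics import VIPResult

    vip = VIPResult(pd.Series([1.0, 1.0, 2.0, 0.5, 1.0],
                              index=[f"FT{j}" for j in range(5)]))
    top = select_top_k(vip, meta, k=3)
    assert list(top.columns) == ["feature_id", "mz", "rt_s", "charge", "vip"]
    assert list(top.feature_id) == ["FT2", "FT0", "FT1"]  # ties by id
    top1 = select_top_k(vip, meta, k=1)
    assert list(top1.feature_id) == ["FT2"]
    with pytest.warns(UserWarning):
        all_rows = select_top_k(vip, meta, k=10)
    assert len(all_rows) == 5
    with pytest.raises(ValueError):
        select_top_k(vip, meta, k=0)


def test_class_presence_filter():
    X = np.array(
        [
            [1.0, np.nan, 1.0],
            [2.0, np.nan, 1.0],
            [np.nan, 3.0, 1.0],
            [np.nan, 4.0, np.nan],
        ]
    )
    table = make_table(X)
    labels = binary_labels(2, 2)
    out = class_presence_filter(table, labels)
    assert set(out.feature_id) == {"FT000", "FT001"}
    assert dict(zip(out.feature_id, out.exclusive_to)) == {
        "FT000": "non-heated",
        "FT001": "heated",
    }


def test_class_presence_filter_finds_planted_exclusives():
    from msemarker.simulate import SimulationConfig, default_markers, simulate_study
    from msemarker.features import detect_features, merge_features, select_samples

    config = SimulationConfig(
        planted=default_markers(), seed=99, n_noise=30,
        n_heated=3, n_non_heated=3, n_exclusive_heated=2,
        n_exclusive_non_heated=1, rt_start=80.0, rt_end=300.0,
    )
    runs, sheet, truth = simulate_study(config)
    feats = []
    for sid, spectra in runs.items():
        feats.extend(
            detect_features([s for s in spectra if s.energy == "low"],
                            sample_id=sid)
        )
    table, meta = merge_features(feats)
    labels = dict(zip(sheet.sample_id, sheet.label))
    out = class_presence_filter(select_samples(table, labels), labels)
    counts = out.exclusive_to.value_counts().to_dict()
    assert counts.get("heated", 0) >= 2
    assert counts.get("non-heated", 0) >= 1


def test_plotting_helpers_render(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    from msemarker.plotting import feature_boxplots, score_scatter

    rng = np.random.default_rng(8)
    X = rng.lognormal(size=(10, 6))
    table = make_table(X)
    labels = binary_labels(5, 5)
    model = fit_plsda(table, labels)
    ax = score_scatter(model, labels)
    assert len(ax.collections) == 2  # one scatter per class
    axes = feature_boxplots(table, labels, ["FT000", "FT001"])
    assert len(axes) == 2
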