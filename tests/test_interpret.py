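"""Grad-CAM saliency, variant back-projection, group tests and shared loci."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from dlgwas.classifier import ConvNetClassifier
from dlgwas.encoding import build_pixel_map
from dlgwas.errors import ConfigurationError
from dlgwas.interpret import (
    grad_cam,
    group_difference_test,
    saliency_per_variant,
    shared_loci,
)
from dlgwas.nn import ArchitectureSpec, build_model


# ------------------------------------------------------------------ Grad-CAM
def test_constant_model_gives_all_zero_heatmap():
    model = build_model(ArchitectureSpec("plain_cnn", side=16, width=0.25), seed=0)
    for layer in model.param_layers():
        for k in layer.p:
            layer.p[k][:] = 0.0
    x = np.random.default_rng(1).random((4, 16, 16)).astype(np.float32)
    heat = grad_cam(model, x)
    assert heat.shape == (4, 16, 16)
    assert (heat == 0).all()


def test_heatmap_values_in_unit_interval():
    model = build_model(ArchitectureSpec("plain_cnn", side=16, width=0.25), seed=2)
    x = np.random.default_rng(3).random((6, 16, 16)).astype(np.float32)
    for method in ("channel", "elementwise"):
        heat = grad_cam(model, x, method=method, guided=False)
        assert heat.min() >= 0.0 and heat.max() <= 1.0
    heat = grad_cam(model, x)  # guided default
    assert heat.min() >= 0.0 and heat.max() <= 1.0


def test_gradcam_localises_contiguous_planted_signal():
    """Class driven by a contiguous pixel patch -> saliency concentrates there."""
    rng = np.random.default_rng(4)
    n, side = 200, 32
    X = rng.random((n, side, side)).astype(np.float32)
    y = np.array(["a", "b"] * (n // 2))
    mask = np.zeros((side, side), bool)
    mask[8:18, 4:24] = True  # 200 designated pixels
    sign = np.where(rng.random(mask.sum()) < 0.5, 1.0, -1.0).astype(np.float32)
    rows, cols = np.where(mask)
    X[np.ix_(np.flatnonzero(y == "b"), rows, cols)] += 0.8 * sign[None, :]
    clf = ConvNetClassifier(family="plain_cnn", width=0.25, epochs=15, random_state=4)
    clf.fit(X[:160], y[:160])
    assert (clf.predict(X[160:]) == y[160:]).mean() > 0.9
    heat = clf.grad_cam(X[160:])
    mh = heat.mean(axis=0)
    _, p = mannwhitneyu(mh[mask], mh[~mask], alternative="greater")
    assert p < 0.01


def test_resnet_gradcam_runs_and_normalises():
    model = build_model(ArchitectureSpec("resnet18", side=16, width=0.25), seed=5)
    x = np.random.default_rng(6).random((3, 16, 16)).astype(np.float32)
    heat = grad_cam(model, x, method="channel")
    assert heat.shape == (3, 16, 16)
    assert heat.min() >= 0.0 and heat.max() <= 1.0


# ------------------------------------------------- saliency back-projection
def test_uniform_heatmap_uniform_variant_scores():
    pm = build_pixel_map(8, side=4)
    heat = np.full((4, 4), 0.37)
    assert saliency_per_variant(heat, pm) == pytest.approx(np.full(8, 0.37))


def test_saliency_locality_single_variant():
    pm = build_pixel_map(8, side=4)
    heat = np.zeros((4, 4))
    r1, c1 = pm.slot_to_pixel(3, 1)
    r2, c2 = pm.slot_to_pixel(3, 2)
    heat[r1, c1] = 0.4
    heat[r2, c2] = 0.8
    scores = saliency_per_variant(heat, pm)
    assert scores[3] == pytest.approx(0.6)
    assert (np.delete(scores, 3) == 0).all()


def test_saliency_matches_bruteforce_loop():
    pm = build_pixel_map(30, side=9)
    rng = np.random.default_rng(7)
    heat = rng.random((9, 9))
    scores = saliency_per_variant(heat, pm)
    for v in range(pm.n_variants_used):
        pix = [pm.slot_to_pixel(v, s) for s in (1, 2)]
        assert scores[v] == pytest.approx(np.mean([heat[r, c] for r, c in pix]))


def test_saliency_side_mismatch_rejected():
    pm = build_pixel_map(8, side=4)
    with pytest.raises(ConfigurationError):
        saliency_per_variant(np.zeros((5, 5)), pm)


def test_saliency_ignores_unused_pixels():
    pm = build_pixel_map(3, side=4)  # 6 used of 16
    heat = np.zeros((4, 4))
    heat.flat[6:] = 99.0  # garbage on unused pixels
    assert (saliency_per_variant(heat, pm) == 0).all()


# -------------------------------------------------------- group differences
def test_null_calibration_of_raw_pvalues():
    rng = np.random.default_rng(8)
    scores = rng.standard_normal((100, 2000))
    labels = np.array(["x", "y"] * 50)
    table = group_difference_test(scores, labels)
    assert (table["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)
    assert int(table["significant_fdr"].sum()) == 0


def test_strongly_separated_variant_is_fdr_significant():
    rng = np.random.default_rng(9)
    scores = rng.standard_normal((100, 500))
    labels = np.array(["x"] * 50 + ["y"] * 50)
    scores[labels == "y", 7] += 5.0  # 5 within-group SDs
    table = group_difference_test(scores, labels)
    assert bool(table["significant_fdr"].iloc[7])
    assert table["q"].iloc[7] < 0.05


def test_bh_stepup_hand_example():
    """Benjamini-Hochberg step-up on (0.01, 0.02, 0.03, 0.5) with m = 4."""
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests([0.01, 0.02, 0.03, 0.5], method="fdr_bh")
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.5])


def test_zero_variance_equal_means_gives_p_one():
    scores = np.ones((20, 3))
    scores[:, 1] = np.concatenate([np.zeros(10), np.ones(10)])
    labels = np.array(["x"] * 10 + ["y"] * 10)
    table = group_difference_test(scores, labels)
    assert table["p"].iloc[0] == 1.0  # constant everywhere
    assert table["p"].iloc[2] == 1.0
    assert table["p"].iloc[1] == 0.0  # constant but different between groups


def test_q_values_dominate_p_values():
    rng = np.random.default_rng(10)
    scores = rng.standard_normal((60, 300))
    labels = np.array(["x", "y"] * 30)
    table = group_difference_test(scores, labels)
    assert (table["q"] >= table["p"] - 1e-12).all()


def test_wrong_group_count_rejected():
    with pytest.raises(ValueError):
        group_difference_test(np.zeros((6, 2)), np.array(["a", "b", "c"] * 2))


# ------------------------------------------------------------- shared loci
def _table(ids, ps):
    t = pd.DataFrame({"variant": ids, "p": ps})
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(t["p"], method="fdr_bh")
    t["q"] = q
    t["significant_raw"] = t["p"] < 0.05
    t["significant_fdr"] = t["q"] < 0.05
    return t


def test_three_identical_tables_share_their_significant_set():
    ids = [f"rs{i}" for i in range(6)]
    ps = [1e-5, 0.5, 1e-4, 0.9, 0.2, 1e-6]
    t = _table(ids, ps)
    rep = shared_loci({"a": t, "b": t, "c": t}, use="raw")
    assert set(rep[rep["shared"]]["variant"]) == {"rs0", "rs2", "rs5"}


def test_one_null_table_empties_the_intersection():
    ids = [f"rs{i}" for i in range(5)]
    sig = _table(ids, [1e-6] * 5)
    null = _table(ids, [0.9] * 5)
    rep = shared_loci({"a": sig, "b": sig, "c": null}, use="raw")
    assert rep["shared"].sum() == 0


def test_shared_loci_common_universe_intersection():
    a = _table(["rs1", "rs2", "rs3"], [1e-6, 1e-6, 0.5])
    b = _table(["rs2", "rs3", "rs4"], [1e-6, 1e-6, 0.5])
    c = _table(["rs2", "rs5"], [1e-6, 0.5])
    rep = shared_loci({"a": a, "b": b, "c": c}, use="raw")
    assert list(rep["variant"]) == ["rs2"]
    assert bool(rep["shared"].iloc[0])


def test_shared_planted_loci_recovered_from_simulated_scores():
    """Three tasks sharing 5 planted loci; task-private loci are excluded."""
    rng = np.random.default_rng(11)
    m, n = 400, 120
    ids = [f"rs{i}" for i in range(m)]
    common = list(range(5))
    private = {0: [10, 11], 1: [20, 21], 2: [30, 31]}
    tables = {}
    for task in range(3):
        scores = rng.standard_normal((n, m))
        labels = np.array(["g1", "g2"] * (n // 2))
        shift_cols = common + private[task]
        scores[np.ix_(labels == "g2", shift_cols)] += 2.0
        tables[f"t{task}"] = group_difference_test(scores, labels, variant_ids=ids)
    rep = shared_loci(tables, use="fdr")
    shared_ids = set(rep[rep["shared"]]["variant"])
    assert len(shared_ids & {f"rs{i}" for i in common}) >= 4
    for task, privs in private.items():
        assert not (shared_ids & {f"rs{i}" for i in privs})
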