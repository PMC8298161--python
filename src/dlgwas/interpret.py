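"""Grad-CAM saliency, back-projection to variants, and group-difference tests.

Grad-CAM: channel weights are the spatially averaged gradients of the target
class score with respect to the last convolutional layer's feature maps; the
heatmap is the rectified weighted sum of those maps, upsampled to input
resolution and min-max normalised per sample.  Per-variant saliency is the
mean of the variant's two allele-slot pixels.  Group differences use a
per-variant Welch two-sample t-test with Benjamini-Hochberg FDR control;
the normalised per-sample per-variant saliency plays the role of the
model-derived feature compared between diagnostic groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .encoding import PixelMap
from .errors import ConfigurationError


def grad_cam(
    model,
    images: np.ndarray,
    class_idx=None,
    batch_size: int = 32,
    method: str = None,
    guided: bool = True,
) -> np.ndarray:
    """Per-sample heatmaps (n, side, side) in [0, 1].

    ``method='channel'`` is the classic formulation — channel weights are the
    spatially averaged gradients, the map is the rectified weighted sum of
    feature maps.  It assumes importance is spatially uniform per channel,
    which holds for globally-average-pooled (residual) heads.  For a
    fully-connected head the importance of a feature is tied to its absolute
    grid position, which spatial averaging erases, so ``method='elementwise'``
    (the rectified sum over channels of gradient x activation) is used there.
    Both formulations have the target layer's spatial resolution; since one
    map cell covers several variants once upsampled, ``guided=True`` (default)
    sharpens the map to pixel resolution by modulating it with the magnitude
    of the class-score gradient at the input, the guided-Grad-CAM recipe.
    ``method=None`` picks by the model's head.  ``class_idx=None`` attributes
    each sample's predicted class.  A constant map normalises to all zeros.
    """
    if method is None:
        method = getattr(model, "cam_method", "elementwise")
    if method not in ("channel", "elementwise"):
        raise ValueError("method must be 'channel' or 'elementwise'")
    if images.ndim == 2:
        images = images[None, ...]
    side = images.shape[-1]
    maps = []
    for start in range(0, len(images), batch_size):
        x = images[start : start + batch_size]
        acts, grads, dinput, _ = model.gradcam_raw(x, class_idx=class_idx)
        if method == "channel":
            weights = grads.mean(axis=(2, 3))  # (n, channels)
            cam = np.maximum((weights[:, :, None, None] * acts).sum(axis=1), 0.0)
        else:
            cam = np.maximum((grads * acts).sum(axis=1), 0.0)
        cam = _upsample(cam, side)
        if guided:
            cam = cam * np.abs(dinput)
        maps.append(cam)
    heat = np.concatenate(maps, axis=0)
    lo = heat.min(axis=(1, 2), keepdims=True)
    hi = heat.max(axis=(1, 2), keepdims=True)
    span = hi - lo
    flat = span[:, 0, 0] <= 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        heat = (heat - lo) / np.where(span == 0, 1.0, span)
    heat[flat] = 0.0
    return heat


def _upsample(cam: np.ndarray, side: int) -> np.ndarray:
    """Nearest-neighbour upsampling to side x side (pixel-block layout)."""
    h = cam.shape[1]
    if h == side:
        return cam
    if side % h == 0:
        f = side // h
        return np.repeat(np.repeat(cam, f, axis=1), f, axis=2)
    # non-integer factor: index-map nearest neighbour
    idx = np.minimum((np.arange(side) * h) // side, h - 1)
    return cam[:, idx][:, :, idx]


def saliency_per_variant(heatmaps: np.ndarray, pm: PixelMap) -> np.ndarray:
    """Mean of each variant's two allele-slot pixels; cropped variants absent.

    Accepts one heatmap (side, side) or a batch (n, side, side); returns
    (n_variants_used,) or (n, n_variants_used).
    """
    single = heatmaps.ndim == 2
    if single:
        heatmaps = heatmaps[None, ...]
    if heatmaps.shape[-1] != pm.side or heatmaps.shape[-2] != pm.side:
        raise ConfigurationError(
            f"heatmap side {heatmaps.shape[-2:]} does not match pixel map side {pm.side}"
        )
    v = pm.n_variants_used
    flat = heatmaps.reshape(len(heatmaps), -1)[:, : 2 * v]
    scores = flat.reshape(len(heatmaps), v, 2).mean(axis=2)
    return scores[0] if single else scores


def group_difference_test(
    scores: np.ndarray, labels, variant_ids=None, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch t-test per variant between the two groups, BH-adjusted.

    Returns a table with per-variant group means, t, p, q and significance
    flags at raw p < alpha and BH q < alpha.  A variant with zero variance
    and equal means in both groups gets p = 1.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    a = scores[labels == groups[0]]
    b = scores[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    degenerate = ~np.isfinite(p)
    equal = np.isclose(mean_a, mean_b)
    p = np.where(degenerate & equal, 1.0, p)
    p = np.where(degenerate & ~equal, 0.0, p)
    t = np.where(np.isfinite(t), t, 0.0)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    table = pd.DataFrame(
        {
            "variant": variant_ids if variant_ids is not None else np.arange(scores.shape[1]),
            f"mean_{groups[0]}": mean_a,
            f"mean_{groups[1]}": mean_b,
            "t": t,
            "p": p,
            "q": q,
            "significant_raw": p < alpha,
            "significant_fdr": q < alpha,
        }
    )
    return table


def shared_loci(
    tables: dict, threshold: float = 0.05, use: str = "fdr"
) -> pd.DataFrame:
    """Variants significant in all tasks, over the common variant universe.

    ``tables`` maps task name -> group_difference_test output.  ``use='fdr'``
    flags on BH q-values, ``'raw'`` on unadjusted p (the production report's
    convention).  Returns one row per common variant with per-task p-values
    and the shared flag.
    """
    if use not in ("fdr", "raw"):
        raise ValueError("use must be 'fdr' or 'raw'")
    col = "q" if use == "fdr" else "p"
    names = list(tables)
    if not names:
        raise ValueError("no tables given")
    common = None
    for name in names:
        ids = set(tables[name]["variant"])
        common = ids if common is None else (common & ids)
    common = sorted(common)
    out = pd.DataFrame({"variant": common})
    shared = np.ones(len(common), dtype=bool)
    for name in names:
        t = tables[name].set_index("variant")
        out[f"p_{name}"] = t.loc[common, "p"].to_numpy()
        sig = (t.loc[common, col] < threshold).to_numpy()
        out[f"significant_{name}"] = sig
        shared &= sig
    out["shared"] = shared
    return out
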