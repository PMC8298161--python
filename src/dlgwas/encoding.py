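"""SNP-to-image encoding.

Each genotype call contributes two pixels (one per allele, canonical order),
laid out row-major in (chromosome, position) variant order on a square grid.
Nucleotides are coded A=1, T=2, C=3, G=4 and missing=0, then divided by 4 so
pixel values lie in {0, 0.25, 0.5, 0.75, 1.0}.  The mapping pixel <->
(variant, allele slot) is an explicit bijection, so images decode losslessly
back to coded genotypes, and saliency maps project back onto variants.

With a fixed side of S pixels at most floor(S^2 / 2) variants fit; trailing
variants in layout order are cropped and recorded.  The production-scale
configuration of 776 x 776 pixels accommodates 301,088 variants; the default
AUTO side sizes the grid to the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .data import GROUPS, MISSING, NUC2CODE, GenotypeDataset

AUTO = "auto"

_CODE_BY_SYMBOL = dict(NUC2CODE)


def encode_allele(symbol) -> int:
    """A->1, T->2, C->3, G->4, missing->0."""
    if symbol in (MISSING, "0", None):
        return 0
    try:
        return _CODE_BY_SYMBOL[symbol]
    except (KeyError, TypeError):
        raise ValueError(f"allele must be one of A,T,C,G or missing, got {symbol!r}") from None


@dataclass
class PixelMap:
    """Bijection between pixels of a side x side grid and (variant, allele slot).

    Variant ``j < n_variants_used`` occupies linear pixels ``2j`` (slot 1) and
    ``2j + 1`` (slot 2), row-major; all remaining pixels are unused.
    """

    side: int
    n_variants_total: int

    @property
    def n_variants_used(self) -> int:
        return min(self.n_variants_total, (self.side * self.side) // 2)

    @property
    def cropped_variants(self) -> np.ndarray:
        """Indices of trailing variants that do not fit on the grid."""
        return np.arange(self.n_variants_used, self.n_variants_total)

    @property
    def n_used_pixels(self) -> int:
        return 2 * self.n_variants_used

    def slot_to_pixel(self, variant: int, slot: int) -> tuple[int, int]:
        if not (0 <= variant < self.n_variants_used) or slot not in (1, 2):
            raise ValueError(f"no pixel for variant {variant} slot {slot}")
        lin = 2 * variant + (slot - 1)
        return divmod(lin, self.side)

    def pixel_to_slot(self, row: int, col: int):
        """(variant, slot) of a used pixel, or None for an unused pixel."""
        lin = row * self.side + col
        if lin >= self.n_used_pixels:
            return None
        return lin // 2, lin % 2 + 1

    def used_mask(self) -> np.ndarray:
        mask = np.zeros(self.side * self.side, dtype=bool)
        mask[: self.n_used_pixels] = True
        return mask.reshape(self.side, self.side)

    def to_json(self) -> str:
        return json.dumps(
            {
                "side": self.side,
                "n_variants_total": self.n_variants_total,
                "n_variants_used": self.n_variants_used,
                "layout": "row-major, two adjacent pixels per variant",
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PixelMap":
        d = json.loads(text)
        return cls(side=d["side"], n_variants_total=d["n_variants_total"])


def build_pixel_map(n_variants: int, side=AUTO) -> PixelMap:
    """Lay out ``n_variants`` on a square grid; AUTO side = ceil(sqrt(2 n))."""
    if side == AUTO:
        side = max(1, math.ceil(math.sqrt(2 * n_variants)))
    if side < 1:
        raise ValueError("side must be >= 1")
    return PixelMap(side=int(side), n_variants_total=int(n_variants))


@dataclass
class SNPImage:
    values: np.ndarray  # (side, side) float32 in [0,1]
    label: np.ndarray  # one-hot over label_classes
    sample_id: str = ""

    @property
    def side(self) -> int:
        return self.values.shape[0]


def encode_dataset(
    ds: GenotypeDataset, pm: PixelMap = None, label_classes=None
) -> tuple[np.ndarray, np.ndarray, PixelMap]:
    """Encode every sample; returns (images (n, side, side), one-hot labels, map)."""
    if pm is None:
        pm = build_pixel_map(ds.n_variants)
    if label_classes is None:
        label_classes = [g for g in GROUPS if g in set(ds.samples["group"])]
    v = pm.n_variants_used
    flat = np.zeros((ds.n_samples, pm.side * pm.side), dtype=np.float32)
    flat[:, : 2 * v] = ds.calls[:, :v, :].reshape(ds.n_samples, 2 * v).astype(np.float32) / 4.0
    images = flat.reshape(ds.n_samples, pm.side, pm.side)
    class_index = {g: c for c, g in enumerate(label_classes)}
    labels = np.zeros((ds.n_samples, len(label_classes)), dtype=np.float32)
    for i, g in enumerate(ds.samples["group"]):
        if g in class_index:
            labels[i, class_index[g]] = 1.0
    return images, labels, pm


def encode_sample(ds: GenotypeDataset, i: int, pm: PixelMap, label_classes=None) -> SNPImage:
    """Encode one sample (see :func:`encode_dataset`)."""
    if not 0 <= i < ds.n_samples:
        raise ValueError(f"sample index {i} out of range")
    images, labels, pm = encode_dataset(ds, pm, label_classes)
    return SNPImage(values=images[i], label=labels[i], sample_id=ds.samples["sample_id"].iloc[i])


def decode_image(image: np.ndarray, pm: PixelMap) -> np.ndarray:
    """Recover the (n_variants_used, 2) coded genotypes from an image."""
    if image.shape != (pm.side, pm.side):
        raise ValueError(f"image shape {image.shape} does not match side {pm.side}")
    flat = image.reshape(-1)[: pm.n_used_pixels]
    return np.rint(flat * 4.0).astype(np.uint8).reshape(pm.n_variants_used, 2)


class SNPImageEncoder:
    """Estimator-style wrapper: ``fit`` builds the pixel map, ``transform`` encodes.

    Parameters
    ----------
    side : int or "auto"
        Image side in pixels; "auto" sizes the grid to the fitted dataset.
    """

    def __init__(self, side=AUTO):
        self.side = side

    def get_params(self, deep=True):
        return {"side": self.side}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, ds: GenotypeDataset, y=None):
        self.pixel_map_ = build_pixel_map(ds.n_variants, self.side)
        self.n_features_in_ = ds.n_variants
        self.classes_ = [g for g in GROUPS if g in set(ds.samples["group"])]
        return self

    def transform(self, ds: GenotypeDataset) -> np.ndarray:
        if not hasattr(self, "pixel_map_"):
            raise RuntimeError("SNPImageEncoder is not fitted")
        images, _, _ = encode_dataset(ds, self.pixel_map_, self.classes_)
        return images

    def fit_transform(self, ds: GenotypeDataset, y=None) -> np.ndarray:
        return self.fit(ds).transform(ds)

    def labels_for(self, ds: GenotypeDataset) -> np.ndarray:
        _, labels, _ = encode_dataset(ds, self.pixel_map_, self.classes_)
        return labels
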