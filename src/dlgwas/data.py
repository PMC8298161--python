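"""Core genotype container.

Genotype calls are held as a dense ``(n_samples, n_variants, 2)`` uint8 array
of nucleotide codes (A=1, T=2, C=3, G=4, missing=0), the same coding the
image encoder uses.  Within a call the two alleles are stored in canonical
alphabetical order so that unordered genotypes compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

NUCLEOTIDES = ("A", "T", "C", "G")
#: nucleotide -> numeric code; 0 is reserved for a missing call
NUC2CODE = {"A": 1, "T": 2, "C": 3, "G": 4}
CODE2NUC = {v: k for k, v in NUC2CODE.items()}
CODE2NUC[0] = "0"
MISSING = 0

GROUPS = ("HC", "MCI", "AD")
SEXES = ("male", "female", "unknown")

# alphabetical rank of each code (A<C<G<T); used to canonicalise call order
_ALPHA_RANK = np.zeros(5, dtype=np.uint8)
for _c, _n in CODE2NUC.items():
    _ALPHA_RANK[_c] = {"0": 0, "A": 1, "C": 2, "G": 3, "T": 4}[_n]


def code_of(nucleotide: str) -> int:
    """Numeric code of a nucleotide symbol ('0' means missing)."""
    if nucleotide == "0":
        return MISSING
    try:
        return NUC2CODE[nucleotide]
    except KeyError:
        raise FormatError(f"allele symbol {nucleotide!r} not in {{A,C,G,T,0}}") from None


def canonicalize_calls(calls: np.ndarray) -> np.ndarray:
    """Order each call's two allele codes alphabetically; half-missing -> missing."""
    calls = np.asarray(calls, dtype=np.uint8)
    a, b = calls[..., 0], calls[..., 1]
    swap = _ALPHA_RANK[a] > _ALPHA_RANK[b]
    out = calls.copy()
    out[swap, 0], out[swap, 1] = b[swap], a[swap]
    # PLINK convention: a call with any missing allele is fully missing
    missing = (out[..., 0] == MISSING) | (out[..., 1] == MISSING)
    out[missing] = MISSING
    return out


def chromosome_sort_key(chrom: str) -> tuple[int, str]:
    """Sortable key: autosomes numerically, then X, then anything else."""
    try:
        return (int(chrom), "")
    except ValueError:
        order = {"X": 23, "Y": 24, "XY": 25, "MT": 26}
        return (order.get(str(chrom).upper(), 99), str(chrom))


@dataclass
class GenotypeDataset:
    """Samples x variants genotype calls with sample and variant metadata.

    Attributes
    ----------
    samples : DataFrame with columns ``sample_id``, ``group``, ``sex``.
    variants : DataFrame with columns ``rsid``, ``chromosome``, ``position``,
        ``allele_a``, ``allele_b`` and optional ``gene_label``; always sorted
        by (chromosome, position).
    calls : uint8 array of shape (n_samples, n_variants, 2), nucleotide codes.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.shape != (len(self.samples), len(self.variants), 2):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.samples["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id")
        if self.variants["rsid"].duplicated().any():
            raise FormatError("duplicate rsid")

    # -- dimensions ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_variants)

    # -- derived matrices ---------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_variants): True where the call is missing."""
        return self.calls[..., 0] == MISSING

    def allele_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant codes of allele_a and allele_b."""
        a = np.array([NUC2CODE[x] for x in self.variants["allele_a"]], dtype=np.uint8)
        b = np.array([NUC2CODE[x] for x in self.variants["allele_b"]], dtype=np.uint8)
        return a, b

    def dosage(self, count_allele: str = "b") -> np.ndarray:
        """Allele-count matrix (n_samples, n_variants) in {0,1,2}; -1 = missing.

        ``count_allele='b'`` counts copies of ``allele_b`` (the simulator's
        minor allele); ``'minor'`` counts the empirically rarer allele.
        """
        ca, cb = self.allele_codes()
        if count_allele == "b":
            target = cb
        elif count_allele == "a":
            target = ca
        elif count_allele == "minor":
            d = self.dosage("b").astype(np.float64)
            miss = d < 0
            with np.errstate(invalid="ignore"):
                freq = np.where(miss, np.nan, d)
            f = np.nanmean(freq, axis=0) / 2.0
            d = np.where(f[None, :] > 0.5, 2 - d, d)
            d[miss] = -1
            return d.astype(np.int8)
        else:
            raise ValueError(f"unknown count_allele {count_allele!r}")
        dose = (self.calls[..., 0] == target[None, :]).astype(np.int8) + (
            self.calls[..., 1] == target[None, :]
        ).astype(np.int8)
        dose[self.missing_mask()] = -1
        return dose

    # -- selection ----------------------------------------------------------
    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeDataset":
        si = (
            np.arange(self.n_samples)
            if sample_idx is None
            else np.asarray(sample_idx, dtype=np.intp)
        )
        vi = (
            np.arange(self.n_variants)
            if variant_idx is None
            else np.asarray(variant_idx, dtype=np.intp)
        )
        return GenotypeDataset(
            samples=self.samples.iloc[si],
            variants=self.variants.iloc[vi],
            calls=self.calls[np.ix_(si, vi)],
        )

    def select_groups(self, groups) -> "GenotypeDataset":
        keep = self.samples["group"].isin(list(groups)).to_numpy()
        return self.subset(sample_idx=np.flatnonzero(keep))

    def sort_variants(self) -> tuple["GenotypeDataset", np.ndarray]:
        """Sort variants by (chromosome, position); returns (dataset, permutation)."""
        keys = [
            (chromosome_sort_key(c), int(p))
            for c, p in zip(self.variants["chromosome"], self.variants["position"])
        ]
        perm = np.array(sorted(range(self.n_variants), key=lambda j: keys[j]))
        return self.subset(variant_idx=perm), perm

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True)
            )
            and np.array_equal(self.calls, other.calls)
        )
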