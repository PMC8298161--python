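"""Genotype quality control.

Six criteria, applied in a fixed order, each on the dataset surviving the
previous step: variant call rate, sample call rate, sex check, minor allele
frequency, Hardy-Weinberg equilibrium, and pairwise relatedness (PI_HAT).
Defaults mirror standard GWAS practice: call rates >= 0.90, MAF >= 0.05,
HWE p > 1e-6, PI_HAT < 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .data import GenotypeDataset
from .errors import UndefinedValueError

log = logging.getLogger(__name__)

#: minimum jointly non-missing variants for a PI_HAT estimate
MIN_PI_HAT_VARIANTS = 50
#: minimum non-missing X calls for the sex check
MIN_X_CALLS = 20
SEX_HET_CUTOFF = 0.2


@dataclass
class QCThresholds:
    variant_call_rate_min: float = 0.90
    sample_call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    pi_hat_max: float = 0.5
    sex_check_enabled: bool = True
    hwe_method: str = "chi2"  # or "exact"

    def __post_init__(self) -> None:
        for name in ("variant_call_rate_min", "sample_call_rate_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class QCReport:
    """Per-criterion exclusions (entity id, measured value) plus summary counts."""

    excluded_variants_call_rate: list = field(default_factory=list)
    excluded_samples_call_rate: list = field(default_factory=list)
    excluded_samples_sex_check: list = field(default_factory=list)
    excluded_variants_maf: list = field(default_factory=list)
    excluded_variants_hwe: list = field(default_factory=list)
    excluded_samples_relatedness: list = field(default_factory=list)
    relatedness_pairs: list = field(default_factory=list)  # (id1, id2, pi_hat)
    overall_genotyping_rate: float = float("nan")
    n_variants_in: int = 0
    n_samples_in: int = 0
    n_variants_out: int = 0
    n_samples_out: int = 0

    def summary_counts(self) -> dict:
        return {
            "variants_call_rate": len(self.excluded_variants_call_rate),
            "samples_call_rate": len(self.excluded_samples_call_rate),
            "samples_sex_check": len(self.excluded_samples_sex_check),
            "variants_maf": len(self.excluded_variants_maf),
            "variants_hwe": len(self.excluded_variants_hwe),
            "samples_relatedness": len(self.excluded_samples_relatedness),
        }

    def to_dict(self) -> dict:
        return {
            "exclusions": {
                "variants_call_rate": self.excluded_variants_call_rate,
                "samples_call_rate": self.excluded_samples_call_rate,
                "samples_sex_check": self.excluded_samples_sex_check,
                "variants_maf": self.excluded_variants_maf,
                "variants_hwe": self.excluded_variants_hwe,
                "samples_relatedness": self.excluded_samples_relatedness,
            },
            "relatedness_pairs": self.relatedness_pairs,
            "summary_counts": self.summary_counts(),
            "overall_genotyping_rate": self.overall_genotyping_rate,
            "dims": {
                "in": [self.n_samples_in, self.n_variants_in],
                "out": [self.n_samples_out, self.n_variants_out],
            },
        }


# ---------------------------------------------------------------------------
# per-entity statistics
# ---------------------------------------------------------------------------

def variant_call_rates(ds: GenotypeDataset) -> np.ndarray:
    if ds.n_samples < 1:
        raise UndefinedValueError("call rate needs at least one sample")
    return 1.0 - ds.missing_mask().mean(axis=0)


def variant_call_rate(ds: GenotypeDataset, j: int) -> float:
    return float(variant_call_rates(ds)[j])


def sample_call_rates(ds: GenotypeDataset) -> np.ndarray:
    if ds.n_variants < 1:
        raise UndefinedValueError("call rate needs at least one variant")
    return 1.0 - ds.missing_mask().mean(axis=1)


def minor_allele_frequencies(ds: GenotypeDataset) -> np.ndarray:
    """Per-variant MAF over the 2*(non-missing) observed allele draws."""
    dose = ds.dosage("b").astype(np.float64)
    obs = dose >= 0
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = ds.variants["rsid"].iloc[int(np.argmin(n_obs))]
        raise UndefinedValueError(f"all calls missing at variant {bad}")
    freq_b = np.where(obs, dose, 0.0).sum(axis=0) / (2.0 * n_obs)
    return np.minimum(freq_b, 1.0 - freq_b)


def minor_allele_frequency(ds: GenotypeDataset, j: int) -> float:
    return float(minor_allele_frequencies(ds.subset(variant_idx=[j]))[0])


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_test(n_AA: int, n_AB: int, n_BB: int, method: str = "chi2") -> float:
    """HWE p-value from genotype counts.

    ``chi2``: 1-df goodness-of-fit of observed counts against the p^2, 2pq,
    q^2 expectation. ``exact``: sum of the probabilities of all heterozygote
    counts no more probable than the observed one, under the conditional
    distribution given the allele totals (the standard SNP exact test).
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("need at least one genotype")
    if method == "chi2":
        p = (2 * n_AA + n_AB) / (2 * n)
        q = 1.0 - p
        if p == 0.0 or q == 0.0:
            return 1.0  # monomorphic: fits trivially
        exp = np.array([p * p * n, 2 * p * q * n, q * q * n])
        obs = np.array([n_AA, n_AB, n_BB], dtype=np.float64)
        stat = float(((obs - exp) ** 2 / exp).sum())
        return float(stats.chi2.sf(stat, df=1))
    if method == "exact":
        n_minor = min(2 * n_AA + n_AB, 2 * n_BB + n_AB)
        probs, hets = _exact_het_distribution(n, n_minor)
        p_obs = probs[hets == n_AB][0]
        # tolerate tie rounding at machine precision
        return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
    raise ValueError(f"unknown HWE method {method!r}")


def _exact_het_distribution(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """P(het count | n genotypes, n_minor minor alleles) over all valid counts."""
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) // 2 + hets <= n]
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    n_major = 2 * n - n_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    return probs / probs.sum(), hets


def hwe_pvalues(ds: GenotypeDataset, method: str = "chi2") -> np.ndarray:
    """Vectorised per-variant HWE p-values (pooled samples)."""
    dose = ds.dosage("b")
    obs = dose >= 0
    n_AA = ((dose == 0) & obs).sum(axis=0)
    n_AB = (dose == 1).sum(axis=0)
    n_BB = (dose == 2).sum(axis=0)
    if method == "chi2":
        n = n_AA + n_AB + n_BB
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (2 * n_AA + n_AB) / (2 * np.maximum(n, 1))
            q = 1.0 - p
            exp_AA, exp_AB, exp_BB = p * p * n, 2 * p * q * n, q * q * n
            stat = (
                (n_AA - exp_AA) ** 2 / exp_AA
                + (n_AB - exp_AB) ** 2 / exp_AB
                + (n_BB - exp_BB) ** 2 / exp_BB
            )
        stat = np.where((p == 0) | (q == 0) | (n == 0), 0.0, stat)
        return stats.chi2.sf(stat, df=1)
    return np.array(
        [hwe_test(int(a), int(h), int(b), method="exact") for a, h, b in zip(n_AA, n_AB, n_BB)]
    )


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def _ibs_counts(dose: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise IBS0/IBS1/IBS2 and jointly-typed counts via indicator matmuls."""
    obs = (dose >= 0).astype(np.float32)
    ind = [((dose == g) & (dose >= 0)).astype(np.float32) for g in (0, 1, 2)]
    n_valid = obs @ obs.T
    ibs2 = sum(a @ a.T for a in ind)
    ibs0 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    ibs1 = n_valid - ibs0 - ibs2
    return ibs0, ibs1, ibs2, n_valid


def _expected_ibs_weights(freq_minor: np.ndarray) -> dict:
    """Per-variant P(IBS=s | IBD=z) under the observed allele frequencies."""
    p = freq_minor
    q = 1.0 - p
    return {
        (0, 0): 2 * p**2 * q**2,
        (1, 0): 4 * p**3 * q + 4 * p * q**3,
        (2, 0): p**4 + q**4 + 4 * p**2 * q**2,
        (1, 1): 2 * p**2 * q + 2 * p * q**2,
        (2, 1): p**3 + q**3 + p**2 * q + p * q**2,
    }


def pi_hat_matrix(ds: GenotypeDataset) -> np.ndarray:
    """All-pairs method-of-moments PI_HAT; NaN where < MIN_PI_HAT_VARIANTS shared.

    Expected IBS probabilities given IBD state are summed per pair over the
    jointly non-missing autosomal variants (masked matrix products), then the
    IBD-state mixture (Z0, Z1, Z2) is solved by moments and PI_HAT = Z2 + Z1/2,
    clamped to [0, 1].
    """
    auto = ~ds.variants["chromosome"].astype(str).str.upper().isin(["X", "Y", "XY", "MT"])
    sub = ds.subset(variant_idx=np.flatnonzero(auto.to_numpy()))
    dose = sub.dosage("b")
    obs_f = (dose >= 0).astype(np.float32)
    obs = dose >= 0
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(obs, dose, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
    freq = np.minimum(freq, 1 - freq)
    # monomorphic variants carry no IBD information; weight them zero
    poly = freq > 0
    w = _expected_ibs_weights(freq.astype(np.float64))

    ibs0, ibs1, ibs2, n_valid = _ibs_counts(np.where(poly[None, :], dose, -1))
    obs_poly = obs_f * poly[None, :].astype(np.float32)

    def pair_sum(wvec):
        wv = (wvec * poly).astype(np.float32)
        return (obs_poly * wv[None, :]) @ obs_poly.T

    e00 = pair_sum(w[(0, 0)])
    e10 = pair_sum(w[(1, 0)])
    e20 = pair_sum(w[(2, 0)])
    e11 = pair_sum(w[(1, 1)])
    e21 = pair_sum(w[(2, 1)])

    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = ibs0 / e00
        z1 = (ibs1 - z0 * e10) / e11
        # P(IBS2|IBD2) = 1, so the divisor for z2 is the pair's variant count
        z2 = (ibs2 - z0 * e20 - z1 * e21) / np.maximum(n_valid, 1)
    z0 = np.clip(z0, 0.0, 1.0)
    z1 = np.clip(z1, 0.0, 1.0)
    z2 = np.clip(z2, 0.0, 1.0)
    pi = np.clip(z2 + 0.5 * z1, 0.0, 1.0)
    pi[n_valid < MIN_PI_HAT_VARIANTS] = np.nan
    np.fill_diagonal(pi, np.nan)
    return pi


def pi_hat(ds: GenotypeDataset, i: int, k: int) -> float:
    """PI_HAT for one sample pair (see :func:`pi_hat_matrix`)."""
    val = pi_hat_matrix(ds)[i, k]
    if np.isnan(val):
        raise UndefinedValueError(
            f"fewer than {MIN_PI_HAT_VARIANTS} jointly non-missing variants for pair ({i},{k})"
        )
    return float(val)


# ---------------------------------------------------------------------------
# sex check
# ---------------------------------------------------------------------------

def sex_check(ds: GenotypeDataset) -> list:
    """(sample_id, X heterozygosity, flagged) for samples with enough X calls.

    Reported males with X heterozygosity > 0.2 and reported females below it
    are flagged.  With no X variants the check is skipped (empty list).
    """
    on_x = ds.variants["chromosome"].astype(str).str.upper() == "X"
    if not on_x.any():
        log.info("sex check skipped: dataset has no X-chromosome variants")
        return []
    sub = ds.subset(variant_idx=np.flatnonzero(on_x.to_numpy()))
    dose = sub.dosage("b")
    obs = dose >= 0
    n_obs = obs.sum(axis=1)
    het = ((dose == 1) & obs).sum(axis=1) / np.maximum(n_obs, 1)
    out = []
    for i, sid in enumerate(ds.samples["sample_id"]):
        if n_obs[i] < MIN_X_CALLS:
            continue
        sex = ds.samples["sex"].iloc[i]
        flagged = (sex == "male" and het[i] > SEX_HET_CUTOFF) or (
            sex == "female" and het[i] < SEX_HET_CUTOFF
        )
        out.append((sid, float(het[i]), bool(flagged)))
    return out


# ---------------------------------------------------------------------------
# the full filter
# ---------------------------------------------------------------------------

def run_qc(ds: GenotypeDataset, thresholds: QCThresholds = None) -> tuple[GenotypeDataset, QCReport]:
    """Apply all six criteria in order; returns the filtered dataset and report."""
    th = thresholds or QCThresholds()
    report = QCReport(n_variants_in=ds.n_variants, n_samples_in=ds.n_samples)

    # 1. variant call rate
    cr = variant_call_rates(ds)
    drop = cr < th.variant_call_rate_min
    report.excluded_variants_call_rate = [
        (ds.variants["rsid"].iloc[j], float(cr[j])) for j in np.flatnonzero(drop)
    ]
    ds = ds.subset(variant_idx=np.flatnonzero(~drop))

    # 2. sample call rate
    if ds.n_variants:
        cr = sample_call_rates(ds)
        drop = cr < th.sample_call_rate_min
        report.excluded_samples_call_rate = [
            (ds.samples["sample_id"].iloc[i], float(cr[i])) for i in np.flatnonzero(drop)
        ]
        ds = ds.subset(sample_idx=np.flatnonzero(~drop))

    # 3. sex check
    if th.sex_check_enabled and ds.n_samples:
        flagged = {sid: het for sid, het, bad in sex_check(ds) if bad}
        report.excluded_samples_sex_check = sorted(flagged.items())
        keep = ~ds.samples["sample_id"].isin(flagged).to_numpy()
        ds = ds.subset(sample_idx=np.flatnonzero(keep))

    if ds.n_samples == 0 or ds.n_variants == 0:
        return _finalize(ds, report)

    # 4. minor allele frequency
    maf = minor_allele_frequencies(ds)
    drop = maf < th.maf_min
    report.excluded_variants_maf = [
        (ds.variants["rsid"].iloc[j], float(maf[j])) for j in np.flatnonzero(drop)
    ]
    ds = ds.subset(variant_idx=np.flatnonzero(~drop))

    # 5. Hardy-Weinberg equilibrium (exclude p <= hwe_p_min)
    if ds.n_variants:
        pv = hwe_pvalues(ds, method=th.hwe_method)
        drop = pv <= th.hwe_p_min
        report.excluded_variants_hwe = [
            (ds.variants["rsid"].iloc[j], float(pv[j])) for j in np.flatnonzero(drop)
        ]
        ds = ds.subset(variant_idx=np.flatnonzero(~drop))

    # 6. relatedness: for each PI_HAT >= max pair drop the lower-call-rate
    #    member (tie -> the later sample id)
    if ds.n_samples >= 2 and ds.n_variants >= MIN_PI_HAT_VARIANTS and th.pi_hat_max <= 1.0:
        pi = pi_hat_matrix(ds)
        cr = sample_call_rates(ds)
        ids = ds.samples["sample_id"].to_numpy()
        alive = np.ones(ds.n_samples, dtype=bool)
        with np.errstate(invalid="ignore"):
            pairs = np.argwhere(np.triu(pi >= th.pi_hat_max, k=1))
        for i, k in pairs:
            report.relatedness_pairs.append((ids[i], ids[k], float(pi[i, k])))
        for i, k in pairs:
            if not (alive[i] and alive[k]):
                continue
            if cr[i] < cr[k]:
                victim = i
            elif cr[k] < cr[i]:
                victim = k
            else:
                victim = i if ids[i] > ids[k] else k
            alive[victim] = False
            report.excluded_samples_relatedness.append((ids[victim], float(pi[i, k])))
        ds = ds.subset(sample_idx=np.flatnonzero(alive))

    return _finalize(ds, report)


def _finalize(ds: GenotypeDataset, report: QCReport) -> tuple[GenotypeDataset, QCReport]:
    report.n_samples_out, report.n_variants_out = ds.n_samples, ds.n_variants
    if ds.n_samples and ds.n_variants:
        report.overall_genotyping_rate = float(1.0 - ds.missing_mask().mean())
    return ds, report
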