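"""Case-control genotype simulator with planted causal loci and QC failures.

The generative model is the standard one for biallelic case-control data:

* each autosomal variant gets a minor-allele frequency drawn uniformly from
  ``maf_range`` and genotypes in Hardy-Weinberg proportions;
* disease status follows a logistic model on causal minor-allele dosage,
  ``log-odds = logit(baseline_prevalence) + sum_j log(OR_j) * dosage_j``,
  with rejection sampling until the case and control quotas are filled;
* variants are mutually independent (no linkage disequilibrium).

Quality-control failures are injected on top: designated variants/samples
receive elevated missingness (call rate below 0.9), designated variants get
a heterozygote deficit that violates Hardy-Weinberg equilibrium, and
designated samples are exact copies of earlier samples.  The returned truth
object records every planted feature so downstream QC and association
results can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import NUC2CODE, GenotypeDataset, canonicalize_calls
from .errors import SimulationError

_NUC_CODES = np.array([NUC2CODE[n] for n in "ACGT"], dtype=np.uint8)


@dataclass
class CausalVariant:
    """A planted disease locus: per-minor-allele odds ratio at a variant index."""

    index: int
    odds_ratio: float
    maf: Optional[float] = None  # None -> drawn from maf_range like the rest


@dataclass
class SimulationConfig:
    n_cases: int = 500
    n_controls: int = 500
    n_variants: int = 5000
    maf_range: tuple = (0.05, 0.5)
    causal: Sequence[CausalVariant] = field(default_factory=list)
    baseline_prevalence: float = 0.1
    missing_rate: float = 0.01
    n_low_callrate_variants: int = 0
    n_low_callrate_samples: int = 0
    n_hwe_violating_variants: int = 0
    n_duplicate_samples: int = 0
    #: elevated missingness for designated low-call-rate entities
    low_callrate_missing_rate: float = 0.2
    #: inbreeding-style heterozygote deficit for HWE violators (0..1)
    hwe_het_deficit: float = 0.6
    #: local linkage disequilibrium around causal loci: each causal variant's
    #: next (ld_block_size - 1) variants in layout order become noisy copies
    #: of its genotype (per-allele flip probability ld_flip_rate).  0 disables
    #: LD, leaving all variants independent.
    ld_block_size: int = 0
    ld_flip_rate: float = 0.1
    n_x_variants: int = 0
    n_sex_mismatch_samples: int = 0
    case_group: str = "AD"
    control_group: str = "HC"
    seed: int = 0
    max_rejection_attempts: int = 2_000_000

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0 or self.n_variants < 0:
            raise SimulationError("counts must be non-negative")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise SimulationError("maf_range must lie within (0, 0.5]")
        for cv in self.causal:
            if cv.odds_ratio <= 0:
                raise SimulationError("odds ratios must be positive")
            if cv.index >= self.n_variants:
                raise SimulationError("causal index beyond n_variants")
        if not 0 < self.baseline_prevalence < 1:
            raise SimulationError("baseline_prevalence must be in (0,1)")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset (rsids / sample ids)."""

    causal: list  # list of dicts: rsid, index, odds_ratio, maf
    ld_block_variants: dict  # causal rsid -> list of tagged neighbour rsids
    low_callrate_variants: list
    low_callrate_samples: list
    hwe_violating_variants: list
    duplicate_pairs: list  # (original_id, copy_id)
    sex_mismatch_samples: list

    def to_dict(self) -> dict:
        return {
            "causal": self.causal,
            "ld_block_variants": self.ld_block_variants,
            "low_callrate_variants": self.low_callrate_variants,
            "low_callrate_samples": self.low_callrate_samples,
            "hwe_violating_variants": self.hwe_violating_variants,
            "duplicate_pairs": self.duplicate_pairs,
            "sex_mismatch_samples": self.sex_mismatch_samples,
        }


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def simulate(cfg: SimulationConfig) -> tuple[GenotypeDataset, SimulationTruth]:
    """Draw a dataset from ``cfg``; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    if n < 2:
        raise SimulationError("need at least 2 samples")
    m_auto = cfg.n_variants
    m = m_auto + cfg.n_x_variants

    # --- variant metadata ------------------------------------------------
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    causal_idx = np.array([cv.index for cv in cfg.causal], dtype=int)
    for cv in cfg.causal:
        if cv.maf is not None:
            maf[cv.index] = cv.maf
    # unordered distinct allele pair per variant; stored alphabetically,
    # allele_b carries the minor allele's identity via a separate flag
    pair_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    pair_codes = _NUC_CODES[pair_idx]  # (m, 2): [major, minor] as drawn
    chrom = np.repeat("1", m).astype(object)
    if m_auto:
        # spread autosomal variants over chromosomes 1..22
        chrom[:m_auto] = [str(1 + (j % 22)) for j in range(m_auto)]
    chrom[m_auto:] = "X"
    variants = pd.DataFrame(
        {
            "rsid": [f"rs{j + 1:07d}" for j in range(m)],
            "chromosome": chrom,
            "position": np.arange(m, dtype=np.int64) // 22 * 1000 + 10_000,
        }
    )
    # alphabetical storage of the pair
    nuc = np.vectorize({1: "A", 2: "T", 3: "C", 4: "G"}.get)(pair_codes)
    variants["allele_a"] = np.sort(nuc, axis=1)[:, 0]
    variants["allele_b"] = np.sort(nuc, axis=1)[:, 1]
    minor_code = pair_codes[:, 1]

    # --- disease model: draw causal genotypes, accept by status ----------
    log_or = np.array([np.log(cv.odds_ratio) for cv in cfg.causal])
    base = _logit(cfg.baseline_prevalence)
    status = np.empty(n, dtype=bool)  # True = case
    causal_dosage = np.zeros((n, len(causal_idx)), dtype=np.int8)
    need_cases, need_controls = cfg.n_cases, cfg.n_controls
    filled = 0
    attempts = 0
    batch = max(1024, n)
    p_causal = maf[causal_idx] if len(causal_idx) else np.empty(0)
    while need_cases > 0 or need_controls > 0:
        attempts += batch
        if attempts > cfg.max_rejection_attempts:
            raise SimulationError(
                "rejection sampling stalled; odds ratios / prevalence unsatisfiable"
            )
        dos = rng.binomial(2, p_causal[None, :], size=(batch, len(causal_idx))).astype(
            np.int8
        )
        logits = base + dos @ log_or if len(causal_idx) else np.full(batch, base)
        is_case = rng.random(batch) < 1.0 / (1.0 + np.exp(-logits))
        for k in range(batch):
            if is_case[k] and need_cases > 0:
                status[filled] = True
            elif (not is_case[k]) and need_controls > 0:
                status[filled] = False
            else:
                continue
            causal_dosage[filled] = dos[k]
            filled += 1
            need_cases -= int(status[filled - 1])
            need_controls -= int(not status[filled - 1])
            if need_cases == 0 and need_controls == 0:
                break

    # interleave cases/controls deterministically by shuffling sample order
    order = rng.permutation(n)
    status = status[order]
    causal_dosage = causal_dosage[order]

    # --- non-causal genotype dosages (independent of status) -------------
    dosage = rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)
    if len(causal_idx):
        dosage[:, causal_idx] = causal_dosage

    # --- optional local LD: neighbours in (chromosome, position) order become
    # noisy copies of the causal genotype --------------------------------------
    ld_members: dict = {}
    if cfg.ld_block_size > 1 and len(causal_idx):
        order_sorted = sorted(
            range(m),
            key=lambda j: (
                (int(chrom[j]) if str(chrom[j]).isdigit() else 99),
                int(variants["position"].iloc[j]),
            ),
        )
        rank_of = {j: r for r, j in enumerate(order_sorted)}
        for cv in cfg.causal:
            j = cv.index
            members = []
            r = rank_of[j]
            for step in range(1, cfg.ld_block_size):
                if r + step >= m:
                    break
                k = order_sorted[r + step]
                if chrom[k] != chrom[j] or k in set(causal_idx):
                    break
                flips = rng.binomial(2, cfg.ld_flip_rate, size=n).astype(np.int8)
                dosage[:, k] = np.abs(dosage[:, j] - flips) % 3
                maf[k] = maf[j]
                members.append(int(k))
            ld_members[int(j)] = members
    ld_all = np.array(sorted(set(k for v in ld_members.values() for k in v)), dtype=int)

    truth_hwe: list = []
    noncausal = np.setdiff1d(np.setdiff1d(np.arange(m_auto), causal_idx), ld_all)
    if cfg.n_hwe_violating_variants:
        hwe_idx = rng.choice(noncausal, size=cfg.n_hwe_violating_variants, replace=False)
        f = cfg.hwe_het_deficit
        for j in hwe_idx:
            p = maf[j]
            probs = np.array(
                [(1 - p) ** 2 + f * p * (1 - p), (1 - f) * 2 * p * (1 - p), p**2 + f * p * (1 - p)]
            )
            dosage[:, j] = rng.choice(3, size=n, p=probs / probs.sum())
        truth_hwe = sorted(variants["rsid"].iloc[np.sort(hwe_idx)])
        noncausal = np.setdiff1d(noncausal, hwe_idx)
    else:
        hwe_idx = np.empty(0, dtype=int)

    # --- sex and X-chromosome hemizygosity --------------------------------
    sex = np.where(rng.random(n) < 0.5, "male", "female").astype(object)
    x_cols = np.arange(m_auto, m)
    if len(x_cols):
        males = np.flatnonzero(sex == "male")
        # hemizygous males: one allele, coded as a homozygous call
        dosage[np.ix_(males, x_cols)] = 2 * rng.binomial(
            1, maf[x_cols][None, :], size=(len(males), len(x_cols))
        ).astype(np.int8)
    sex_mismatch_ids: list = []
    if cfg.n_sex_mismatch_samples:
        if not len(x_cols):
            raise SimulationError("sex mismatches need n_x_variants > 0")
        males = np.flatnonzero(sex == "male")
        mism = rng.choice(males, size=cfg.n_sex_mismatch_samples, replace=False)
        # give reported-males diploid (frequently heterozygous) X calls
        dosage[np.ix_(mism, x_cols)] = rng.binomial(
            2, np.clip(maf[x_cols], 0.3, 0.5)[None, :], size=(len(mism), len(x_cols))
        ).astype(np.int8)
        sex_mismatch_ids = [f"S{i + 1:05d}" for i in sorted(mism)]

    # --- duplicates (exact copies, pre-missingness) ------------------------
    dup_pairs: list = []
    if cfg.n_duplicate_samples:
        if cfg.n_duplicate_samples * 2 > n:
            raise SimulationError("too many duplicate samples requested")
        copies = np.arange(n - cfg.n_duplicate_samples, n)
        originals = rng.choice(
            np.arange(n - cfg.n_duplicate_samples), size=cfg.n_duplicate_samples, replace=False
        )
        for orig, cp in zip(originals, copies):
            dosage[cp] = dosage[orig]
            status[cp] = status[orig]
            sex[cp] = sex[orig]
            dup_pairs.append((f"S{orig + 1:05d}", f"S{cp + 1:05d}"))

    # --- dosage -> nucleotide calls ---------------------------------------
    major_code = pair_codes[:, 0]
    calls = np.empty((n, m, 2), dtype=np.uint8)
    calls[..., 0] = np.where(dosage >= 1, minor_code[None, :], major_code[None, :])
    calls[..., 1] = np.where(dosage == 2, minor_code[None, :], major_code[None, :])

    # --- missingness --------------------------------------------------------
    miss = rng.random((n, m)) < cfg.missing_rate
    lcr_vars: list = []
    if cfg.n_low_callrate_variants:
        cand = noncausal
        if len(cand) < cfg.n_low_callrate_variants:
            raise SimulationError("not enough non-causal variants for low-call-rate set")
        lv = rng.choice(cand, size=cfg.n_low_callrate_variants, replace=False)
        miss[:, lv] |= rng.random((n, len(lv))) < cfg.low_callrate_missing_rate
        lcr_vars = sorted(variants["rsid"].iloc[np.sort(lv)])
    lcr_samps: list = []
    if cfg.n_low_callrate_samples:
        dup_members = set(int(s[1:]) - 1 for pair in dup_pairs for s in pair)
        cand = np.array([i for i in range(n) if i not in dup_members])
        ls = rng.choice(cand, size=cfg.n_low_callrate_samples, replace=False)
        miss[ls, :] |= rng.random((len(ls), m)) < cfg.low_callrate_missing_rate
        lcr_samps = [f"S{i + 1:05d}" for i in sorted(ls)]
    calls[miss] = 0
    calls = canonicalize_calls(calls)

    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:05d}" for i in range(n)],
            "group": np.where(status, cfg.case_group, cfg.control_group),
            "sex": sex,
        }
    )
    ds = GenotypeDataset(samples=samples, variants=variants, calls=calls)
    ds, perm = ds.sort_variants()

    truth = SimulationTruth(
        causal=[
            {
                "rsid": variants["rsid"].iloc[cv.index],
                "index_original": int(cv.index),
                "odds_ratio": float(cv.odds_ratio),
                "maf": float(maf[cv.index]),
            }
            for cv in cfg.causal
        ],
        ld_block_variants={
            variants["rsid"].iloc[j]: [variants["rsid"].iloc[k] for k in members]
            for j, members in ld_members.items()
        },
        low_callrate_variants=lcr_vars,
        low_callrate_samples=lcr_samps,
        hwe_violating_variants=truth_hwe,
        duplicate_pairs=dup_pairs,
        sex_mismatch_samples=sex_mismatch_ids,
    )
    return ds, truth
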