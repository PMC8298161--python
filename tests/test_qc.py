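"""Quality-control statistics against hand counts and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from dlgwas.data import GenotypeDataset
from dlgwas.errors import UndefinedValueError
from dlgwas.qc import (
    QCThresholds,
    hwe_test,
    minor_allele_frequencies,
    pi_hat,
    pi_hat_matrix,
    run_qc,
    sample_call_rates,
    sex_check,
    variant_call_rate,
    variant_call_rates,
)
from dlgwas.simulate import SimulationConfig, simulate

from conftest import make_random_ds


def dataset_from_dosage(dose, chromosome="1", sexes=None, groups=None):
    """Build a dataset with alleles A (code 1) / G (code 4) from a dosage matrix.

    dosage counts G; -1 means missing.
    """
    dose = np.asarray(dose)
    n, m = dose.shape
    calls = np.empty((n, m, 2), dtype=np.uint8)
    calls[..., 0] = np.where(dose >= 1, 4, 1)
    calls[..., 1] = np.where(dose == 2, 4, 1)
    calls[dose < 0] = 0
    # canonical alphabetical order: A before G -> (1, 4) ordering holds except
    # dosage 1 gives (G, A) -> fix by sorting codes via the alpha rank (A<G)
    het = dose == 1
    calls[..., 0][het] = 1
    calls[..., 1][het] = 4
    samples = pd.DataFrame(
        {
            "sample_id": [f"i{k}" for k in range(n)],
            "group": groups if groups is not None else ["AD"] * (n // 2) + ["HC"] * (n - n // 2),
            "sex": sexes if sexes is not None else ["unknown"] * n,
        }
    )
    variants = pd.DataFrame(
        {
            "rsid": [f"v{j}" for j in range(m)],
            "chromosome": [chromosome] * m,
            "position": np.arange(1, m + 1),
            "allele_a": ["A"] * m,
            "allele_b": ["G"] * m,
        }
    )
    return GenotypeDataset(samples=samples, variants=variants, calls=calls)


# ---------------------------------------------------------------- call rates
def test_call_rate_no_missing_is_one(tiny_ds):
    assert variant_call_rate(tiny_ds, 0) == 1.0


def test_call_rate_direct_count():
    dose = np.zeros((10, 1), dtype=int)
    dose[3, 0] = -1
    ds = dataset_from_dosage(dose)
    assert variant_call_rate(ds, 0) == pytest.approx(0.9)


def test_call_rates_match_bruteforce_loop():
    rng = np.random.default_rng(17)
    dose = rng.integers(0, 3, size=(100, 5))
    dose[rng.random((100, 5)) < 0.3] = -1
    ds = dataset_from_dosage(dose)
    vr = variant_call_rates(ds)
    sr = sample_call_rates(ds)
    for j in range(5):
        assert vr[j] == pytest.approx(sum(dose[i, j] >= 0 for i in range(100)) / 100)
    for i in range(100):
        assert sr[i] == pytest.approx(sum(dose[i, j] >= 0 for j in range(5)) / 5)


# ------------------------------------------------------------------- MAF
@pytest.mark.parametrize(
    "counts, expected",
    [
        ((100, 0, 0), 0.0),  # monomorphic
        ((25, 50, 25), 0.5),  # symmetric
        ((60, 30, 10), 0.25),  # (30 + 20) / 200
    ],
)
def test_maf_hand_counts(counts, expected):
    n_AA, n_AB, n_BB = counts
    dose = np.array([0] * n_AA + [1] * n_AB + [2] * n_BB)[:, None]
    ds = dataset_from_dosage(dose)
    assert minor_allele_frequencies(ds)[0] == pytest.approx(expected)


def test_maf_all_missing_is_error():
    ds = dataset_from_dosage(np.full((5, 1), -1))
    with pytest.raises(UndefinedValueError):
        minor_allele_frequencies(ds)


# ------------------------------------------------------------------- HWE
def test_hwe_exact_proportions_give_p_one():
    assert hwe_test(25, 50, 25) == pytest.approx(1.0)


def test_hwe_monomorphic_gives_p_one():
    assert hwe_test(0, 0, 77) == pytest.approx(1.0)
    assert hwe_test(0, 0, 77, method="exact") == pytest.approx(1.0)


def test_hwe_negative_counts_rejected():
    with pytest.raises(ValueError):
        hwe_test(-1, 2, 3)


def brute_force_exact_hwe(n_AA, n_AB, n_BB):
    """Exact test by full enumeration with integer arithmetic."""
    n = n_AA + n_AB + n_BB
    n_minor = min(2 * n_AA + n_AB, 2 * n_BB + n_AB)
    n_major = 2 * n - n_minor
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hm = (n_minor - h) // 2
        hM = n - h - hm
        if hM < 0:
            continue
        w = (
            math.factorial(n)
            // (math.factorial(hm) * math.factorial(h) * math.factorial(hM))
            * 2**h
        )
        weights[h] = w
    total = sum(weights.values())
    obs = weights[n_AB]
    return sum(w for w in weights.values() if w <= obs) / total


@pytest.mark.parametrize(
    "table", [(20, 20, 60), (5, 10, 5), (0, 10, 10), (7, 1, 2), (30, 10, 0)]
)
def test_hwe_exact_matches_enumeration(table):
    assert hwe_test(*table, method="exact") == pytest.approx(
        brute_force_exact_hwe(*table), rel=1e-9
    )


def test_hwe_chi2_textbook_value():
    # observed (20,20,60): p_minor = 0.3, expected (9.8, 42, 49) out of 100... -> large stat
    p = hwe_test(20, 20, 60, method="chi2")
    assert p < 1e-5


# --------------------------------------------------------------- sex check
def test_sex_check_skipped_without_x(tiny_ds):
    assert sex_check(tiny_ds) == []


def test_sex_check_flags_heterozygous_male_not_hemizygous_male():
    rng = np.random.default_rng(0)
    hemi = 2 * rng.integers(0, 2, size=(1, 40))  # all homozygous
    het = np.ones((1, 40), dtype=int)  # all heterozygous
    female = rng.integers(0, 3, size=(1, 40))
    dose = np.vstack([hemi, het, female])
    ds = dataset_from_dosage(dose, chromosome="X", sexes=["male", "male", "female"])
    result = {sid: flag for sid, het_rate, flag in sex_check(ds)}
    assert result["i0"] is False
    assert result["i1"] is True


# ----------------------------------------------------------------- PI_HAT
def test_pi_hat_self_copy_is_one():
    rng = np.random.default_rng(3)
    base = rng.binomial(2, 0.3, size=(1, 200))
    dose = np.vstack([base, base, rng.binomial(2, 0.3, size=(1, 200))])
    ds = dataset_from_dosage(dose)
    assert pi_hat(ds, 0, 1) == pytest.approx(1.0)


def test_pi_hat_unrelated_near_zero():
    vals = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        dose = rng.binomial(2, 0.3, size=(12, 1000))
        ds = dataset_from_dosage(dose)
        vals.append(pi_hat(ds, 0, 1))
    assert abs(np.median(vals)) < 0.1


def test_pi_hat_parent_offspring_near_half():
    vals = []
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        m = 1000
        p1a = rng.binomial(1, 0.3, size=(10, m))
        p1b = rng.binomial(1, 0.3, size=(10, m))
        child_from_p1 = np.where(rng.random((10, m)) < 0.5, p1a, p1b)
        child_other = rng.binomial(1, 0.3, size=(10, m))
        parent = p1a + p1b
        child = child_from_p1 + child_other
        dose = np.vstack([parent, child])
        ds = dataset_from_dosage(dose)
        vals.append(np.mean([pi_hat(ds, i, 10 + i) for i in range(3)]))
    assert np.median(vals) == pytest.approx(0.5, abs=0.1)


def test_pi_hat_too_few_shared_variants_raises():
    dose = np.full((2, 60), -1)
    dose[:, :20] = 1
    ds = dataset_from_dosage(dose)
    with pytest.raises(UndefinedValueError):
        pi_hat(ds, 0, 1)


# ----------------------------------------------------------------- run_qc
def test_run_qc_clean_dataset_no_exclusions():
    cfg = SimulationConfig(
        n_cases=100, n_controls=100, n_variants=300, maf_range=(0.15, 0.5),
        missing_rate=0.005, seed=31,
    )
    ds, _ = simulate(cfg)
    filtered, report = run_qc(ds)
    assert report.summary_counts() == {k: 0 for k in report.summary_counts()}
    assert filtered.shape == ds.shape


def test_run_qc_recovers_injected_failures_exactly():
    cfg = SimulationConfig(
        n_cases=150, n_controls=150, n_variants=800, maf_range=(0.15, 0.5),
        missing_rate=0.01, n_low_callrate_variants=5, n_low_callrate_samples=2,
        n_hwe_violating_variants=3, n_duplicate_samples=1, seed=41,
    )
    ds, truth = simulate(cfg)
    _, report = run_qc(ds)
    assert sorted(r for r, _ in report.excluded_variants_call_rate) == truth.low_callrate_variants
    assert sorted(s for s, _ in report.excluded_samples_call_rate) == truth.low_callrate_samples
    assert sorted(r for r, _ in report.excluded_variants_hwe) == truth.hwe_violating_variants
    removed = {s for s, _ in report.excluded_samples_relatedness}
    assert len(removed) == 1 and removed <= set(truth.duplicate_pairs[0])


def test_run_qc_nonbinding_thresholds_identity(random_ds):
    th = QCThresholds(
        variant_call_rate_min=0.0, sample_call_rate_min=0.0, maf_min=0.0,
        hwe_p_min=0.0, pi_hat_max=1.01, sex_check_enabled=False,
    )
    filtered, report = run_qc(random_ds, th)
    assert filtered.equals(random_ds)


def test_run_qc_survivors_satisfy_thresholds():
    cfg = SimulationConfig(
        n_cases=120, n_controls=120, n_variants=500, maf_range=(0.03, 0.5),
        missing_rate=0.03, n_low_callrate_variants=4, n_hwe_violating_variants=3,
        n_duplicate_samples=1, seed=55,
    )
    ds, _ = simulate(cfg)
    filtered, _ = run_qc(ds)
    assert (variant_call_rates(filtered) >= 0.90).all()
    assert (sample_call_rates(filtered) >= 0.90).all()
    assert (minor_allele_frequencies(filtered) >= 0.05).all()
    from dlgwas.qc import hwe_pvalues

    assert (hwe_pvalues(filtered) > 1e-6).all()
    pi = pi_hat_matrix(filtered)
    with np.errstate(invalid="ignore"):
        assert not (pi >= 0.5).any()


def test_run_qc_empty_result_is_explicit_not_crash(random_ds):
    th = QCThresholds(maf_min=1.0)  # impossible: exclude everything by MAF
    filtered, report = run_qc(random_ds, th)
    assert filtered.n_variants == 0
    assert report.n_variants_out == 0
    assert math.isnan(report.overall_genotyping_rate)


def test_sample_order_permutation_does_not_change_variant_exclusions():
    cfg = SimulationConfig(
        n_cases=80, n_controls=80, n_variants=300, maf_range=(0.04, 0.5),
        missing_rate=0.02, n_hwe_violating_variants=2, seed=77,
    )
    ds, _ = simulate(cfg)
    _, rep1 = run_qc(ds)
    perm = np.random.default_rng(1).permutation(ds.n_samples)
    _, rep2 = run_qc(ds.subset(sample_idx=perm))
    for field in ("excluded_variants_call_rate", "excluded_variants_maf", "excluded_variants_hwe"):
        assert sorted(getattr(rep1, field)) == sorted(getattr(rep2, field))
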