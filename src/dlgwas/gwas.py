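"""Case-control association scan and the linear-SVM classification baseline.

The per-variant test is the allelic 1-df chi-square on the 2x2 allele-count
table (cases vs controls x minor vs major allele), with the cross-product
odds ratio.  Genome-wide significance uses the Bonferroni threshold 0.05/N.
Scan calibration is summarised by the genomic inflation factor: the median
observed statistic over the median of the 1-df chi-square distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data import GenotypeDataset
from .errors import UndefinedValueError

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def significance_threshold(n_tests: int) -> float:
    """Bonferroni genome-wide threshold 0.05 / N."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return 0.05 / n_tests


def allelic_test(
    case_minor: int, case_major: int, ctrl_minor: int, ctrl_major: int
) -> tuple[float, float, float]:
    """(chi-square statistic, p, OR) for one 2x2 allele-count table.

    OR = (case_minor * ctrl_major) / (case_major * ctrl_minor); NaN when any
    cell is zero.  A zero table margin leaves the statistic undefined.
    """
    a, b, c, d = case_minor, case_major, ctrl_minor, ctrl_major
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise UndefinedValueError("zero margin in allele-count table")
    stat = (a * d - b * c) ** 2 * n / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(stat, df=1))
    odds = (a * d) / (b * c) if min(a, b, c, d) > 0 else float("nan")
    return float(stat), p, float(odds)


@dataclass
class AssociationTable:
    """Scan result: per-variant statistics plus scan-level summaries."""

    table: pd.DataFrame  # rsid, chromosome, position, allele columns, maf, stat, p, OR
    n_tests: int
    threshold: float
    inflation_factor: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.threshold]


def association_scan(ds: GenotypeDataset, case_group: str, control_group: str) -> AssociationTable:
    """Allelic chi-square scan of every variant, cases vs controls."""
    groups = ds.samples["group"].to_numpy()
    is_case = groups == case_group
    is_ctrl = groups == control_group
    if is_case.sum() == 0 or is_ctrl.sum() == 0:
        raise UndefinedValueError("both groups must be present for the scan")
    dose = ds.dosage("minor").astype(np.float64)
    obs = dose >= 0

    def allele_counts(mask):
        d = dose[mask]
        o = obs[mask]
        minor = np.where(o, d, 0).sum(axis=0)
        total = 2.0 * o.sum(axis=0)
        return minor, total - minor

    a, b = allele_counts(is_case)
    c, d = allele_counts(is_ctrl)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, (a * d - b * c) ** 2 * n / np.maximum(denom, 1), np.nan)
        odds = np.where((a > 0) & (b > 0) & (c > 0) & (d > 0), (a * d) / np.maximum(b * c, 1e-300), np.nan)
    p = stats.chi2.sf(stat, df=1)
    maf = (a + c) / np.maximum(n, 1)

    table = ds.variants[["rsid", "chromosome", "position", "allele_a", "allele_b"]].copy()
    table["maf"] = maf
    table["chi2"] = stat
    table["p"] = p
    table["odds_ratio"] = odds
    finite = stat[np.isfinite(stat)]
    lam = genomic_inflation(finite) if len(finite) else float("nan")
    n_tests = int(np.isfinite(stat).sum())
    return AssociationTable(
        table=table,
        n_tests=n_tests,
        threshold=significance_threshold(max(n_tests, 1)),
        inflation_factor=lam,
    )


def genomic_inflation(statistics) -> float:
    """lambda = median(chi2 statistics) / 0.4549 (the null 1-df median)."""
    arr = np.asarray(statistics, dtype=np.float64)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("need at least one finite statistic")
    return float(np.median(arr) / CHI2_1DF_MEDIAN)


def manhattan_qq_data(result: AssociationTable) -> dict:
    """Plot-ready series for Manhattan and QQ plots."""
    t = result.table
    if len(t) == 0:
        raise ValueError("empty association table")
    from .data import chromosome_sort_key

    chroms = sorted(t["chromosome"].unique(), key=chromosome_sort_key)
    offset, xs, offsets = 0, np.zeros(len(t)), {}
    for ch in chroms:
        mask = (t["chromosome"] == ch).to_numpy()
        pos = t["position"].to_numpy()[mask]
        xs[mask] = offset + pos
        offsets[ch] = offset
        offset += pos.max() + 1
    logp = -np.log10(np.clip(t["p"].to_numpy(), 1e-300, 1.0))
    pv = np.sort(t["p"].to_numpy()[np.isfinite(t["p"])])
    n = len(pv)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(pv, 1e-300, 1.0))
    return {
        "manhattan": pd.DataFrame(
            {"x": xs, "neglog10p": logp, "chromosome": t["chromosome"]}
        ),
        "chromosome_offsets": offsets,
        "qq": pd.DataFrame({"expected": expected, "observed": observed}),
    }


def scan_features(
    ds: GenotypeDataset, result: AssociationTable, extra_dosage_rsids=()
) -> tuple[np.ndarray, list]:
    """Standardised minor-allele dosage of scan-significant variants.

    The production analogue uses intensity-derived values of the significant
    loci plus APOE-e4 carrier status; for genotype-only data the standardised
    dosage is the predictor, optionally augmented with named extra variants.
    """
    rsids = list(result.significant()["rsid"])
    for r in extra_dosage_rsids:
        if r not in rsids and r in set(ds.variants["rsid"]):
            rsids.append(r)
    if not rsids:
        return np.zeros((ds.n_samples, 0)), []
    idx = [int(np.flatnonzero(ds.variants["rsid"] == r)[0]) for r in rsids]
    dose = ds.dosage("minor")[:, idx].astype(np.float64)
    obs = dose >= 0
    col_mean = np.where(obs, dose, np.nan)
    col_mean = np.nanmean(col_mean, axis=0)
    dose = np.where(obs, dose, col_mean[None, :])  # mean-impute missing calls
    return StandardScaler().fit_transform(dose), rsids


def svm_baseline(
    features: np.ndarray,
    labels: np.ndarray,
    repeats: int = 500,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> dict:
    """Linear-kernel SVM over repeated random stratified splits.

    Returns mean +/- SD of accuracy / sensitivity / specificity over repeats
    and a pooled ROC (decision scores accumulated across repeats).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need two classes")
    rng = np.random.default_rng(seed)
    accs, sens, spes = [], [], []
    pooled_scores, pooled_truth = [], []
    for _ in range(repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        xtr, xte, ytr, yte = train_test_split(
            features, labels, test_size=test_fraction, stratify=labels, random_state=rs
        )
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(xtr, ytr)
        pred = clf.predict(xte)
        pos = clf.classes_[1]
        tp = int(((pred == pos) & (yte == pos)).sum())
        tn = int(((pred != pos) & (yte != pos)).sum())
        fp = int(((pred == pos) & (yte != pos)).sum())
        fn = int(((pred != pos) & (yte == pos)).sum())
        accs.append((tp + tn) / len(yte))
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        spes.append(tn / (tn + fp) if tn + fp else np.nan)
        pooled_scores.extend(clf.decision_function(xte))
        pooled_truth.extend(yte == pos)
    from .evaluation import roc_auc

    roc, auc = roc_auc(np.asarray(pooled_scores), np.asarray(pooled_truth, dtype=int))
    return {
        "accuracy_mean": float(np.mean(accs)),
        "accuracy_sd": float(np.std(accs, ddof=1)) if repeats > 1 else 0.0,
        "sensitivity_mean": float(np.nanmean(sens)),
        "sensitivity_sd": float(np.nanstd(sens, ddof=1)) if repeats > 1 else 0.0,
        "specificity_mean": float(np.nanmean(spes)),
        "specificity_sd": float(np.nanstd(spes, ddof=1)) if repeats > 1 else 0.0,
        "auc": float(auc),
        "roc": roc,
        "repeats": repeats,
    }
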