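"""PLINK text (.ped/.map) and diagnosis-table I/O.

Only the whitespace-separated text formats are supported; the missing-allele
symbol is ``0``.  Coordinates are 1-based as in .map files and chromosome
labels are kept as strings so that ``X`` is representable.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .data import CODE2NUC, MISSING, GenotypeDataset, canonicalize_calls
from .errors import FormatError

_SEX_FROM_PED = {"1": "male", "2": "female"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
# binary .ped phenotype: 1=control, 2=case; the diagnosis TSV overrides this
_GROUP_FROM_PED = {"1": "control", "2": "case"}


def read_diagnosis_table(path) -> pd.DataFrame:
    """Read a TSV with header ``sample_id  group  sex`` (sex optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"{path}: diagnosis table needs 'sample_id' and 'group' columns")
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    return df[["sample_id", "group", "sex"]]


def write_diagnosis_table(samples: pd.DataFrame, path) -> None:
    samples[["sample_id", "group", "sex"]].to_csv(path, sep="\t", index=False)


def read_plink_text(
    ped_path,
    map_path,
    diagnosis_path=None,
    control_group: str = "HC",
    case_group: str = "AD",
) -> GenotypeDataset:
    """Read a .ped/.map pair into a :class:`GenotypeDataset`.

    The .ped phenotype column (1=control, 2=case) assigns ``control_group`` /
    ``case_group`` labels; a diagnosis TSV, when given, wins on conflict.
    Variants are re-sorted by (chromosome, position).
    """
    variants = _read_map(map_path)
    n_var = len(variants)

    sample_rows, call_rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_var:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_var} columns "
                    f"(6 + 2x{n_var} variants), found {len(fields)}"
                )
            sex = _SEX_FROM_PED.get(fields[4], "unknown")
            pheno = _GROUP_FROM_PED.get(fields[5], "unknown")
            group = {"control": control_group, "case": case_group}.get(pheno, "unknown")
            sample_rows.append({"sample_id": fields[1], "group": group, "sex": sex})
            call_rows.append(_parse_alleles(fields[6:], ped_path, lineno))

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "group", "sex"])
    calls = (
        np.asarray(call_rows, dtype=np.uint8).reshape(len(samples), n_var, 2)
        if samples.shape[0]
        else np.zeros((0, n_var, 2), dtype=np.uint8)
    )
    calls = canonicalize_calls(calls)

    if diagnosis_path is not None:
        diag = read_diagnosis_table(diagnosis_path).set_index("sample_id")
        hit = samples["sample_id"].isin(diag.index)
        samples.loc[hit, "group"] = diag.loc[samples.loc[hit, "sample_id"], "group"].to_numpy()
        samples.loc[hit, "sex"] = diag.loc[samples.loc[hit, "sample_id"], "sex"].to_numpy()

    allele_a, allele_b = _observed_alleles(calls, n_var)
    variants = variants.assign(allele_a=allele_a, allele_b=allele_b)

    ds = GenotypeDataset(samples=samples, variants=variants, calls=calls)
    ds, _ = ds.sort_variants()
    return ds


# sorted symbol table for vectorised allele parsing
_SYMBOLS = np.array(["0", "A", "C", "G", "T"])
_SYMBOL_CODES = np.array([0, 1, 3, 4, 2], dtype=np.uint8)


def _parse_alleles(fields: list, ped_path, lineno: int) -> np.ndarray:
    arr = np.asarray(fields)
    pos = np.searchsorted(_SYMBOLS, arr)
    pos_clipped = np.clip(pos, 0, len(_SYMBOLS) - 1)
    bad = _SYMBOLS[pos_clipped] != arr
    if bad.any():
        sym = arr[bad][0]
        raise FormatError(f"{ped_path}:{lineno}: allele symbol {sym!r} not in {{A,C,G,T,0}}")
    return _SYMBOL_CODES[pos_clipped]


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 4 columns (chr rsid cM pos), "
                    f"found {len(fields)}"
                )
            chrom, rsid, _cm, pos = fields
            pos = int(pos)
            if pos < 1:
                raise FormatError(f"{map_path}:{lineno}: position must be >= 1")
            rows.append({"rsid": rsid, "chromosome": chrom, "position": pos})
    variants = pd.DataFrame(rows, columns=["rsid", "chromosome", "position"])
    variants["position"] = variants["position"].astype(np.int64)
    # allele columns are filled from the observed calls on demand
    return variants


def _observed_alleles(calls: np.ndarray, n_var: int) -> tuple[list, list]:
    """Infer each variant's two alleles from the calls (for .map round-trips)."""
    aa, bb = [], []
    for j in range(n_var):
        codes = np.unique(calls[:, j, :])
        codes = [int(c) for c in codes if c != MISSING]
        nucs = sorted(CODE2NUC[c] for c in codes)
        if len(nucs) == 0:
            nucs = ["A", "T"]  # unobservable; placeholder pair
        elif len(nucs) == 1:
            nucs = nucs + [next(x for x in "ACGT" if x != nucs[0])]
        aa.append(nucs[0])
        bb.append(nucs[1])
    return aa, bb


def write_plink_text(ds: GenotypeDataset, ped_path, map_path, control_group: str = "HC") -> None:
    """Write ``ds`` as a .ped/.map pair; missing calls become ``0 0``.

    The .ped phenotype is 1 for ``control_group`` members and 2 otherwise, so
    a two-group dataset round-trips its labels through ``read_plink_text``
    with the matching (control_group, case_group) pair; three-group label
    fidelity needs the diagnosis TSV.  Variant allele metadata is inferred on
    re-read from the observed calls (a .map file carries no alleles), so a
    variant monomorphic in the written samples cannot round-trip its unseen
    allele.
    """
    for path in (ped_path, map_path):
        parent = os.path.dirname(os.path.abspath(path))
        if not os.path.isdir(parent):
            raise IOError(f"directory does not exist: {parent}")

    with open(map_path, "w") as fh:
        for _, v in ds.variants.iterrows():
            fh.write(f"{v.chromosome}\t{v.rsid}\t0\t{v.position}\n")

    lut = np.array([CODE2NUC[c] for c in range(5)])
    with open(ped_path, "w") as fh:
        for i, s in ds.samples.reset_index(drop=True).iterrows():
            pheno = "1" if s.group == control_group else "2"
            alleles = lut[ds.calls[i].reshape(-1)]
            fh.write(
                f"{s.sample_id} {s.sample_id} 0 0 {_SEX_TO_PED.get(s.sex, '0')} {pheno} "
                + " ".join(alleles)
                + "\n"
            )
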