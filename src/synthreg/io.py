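"""Data containers and on-disk formats for multi-study SNP panels.

A *study* is a case-control cohort genotyped on one platform: an additive
genotype matrix (0/1/2 minor-allele counts, missing entries allowed) plus a
per-individual case/control label.  Several studies are pooled against the
*superset* of SNP identifiers observed in any study; a SNP column may be
entirely absent from a study (platform non-overlap) or missing for single
individuals (e.g. failed imputation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StudyDataset",
    "PooledData",
    "ValidationError",
    "ParseError",
    "read_study_table",
    "write_study_table",
    "read_manifest",
    "build_pooled",
    "pair_count",
]

MISSING_TOKENS = ("", "NA", "NaN", "nan", "na")

_STATUS_MAP = {
    "case": 1, "control": -1,
    "1": 1, "-1": -1,
    "1.0": 1, "-1.0": -1,
}

_PLINK_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
_ALLELE_SUFFIX = re.compile(r"_[ACGT]$")


class ValidationError(ValueError):
    """A dataset violates a structural invariant (values, classes, ids)."""


class ParseError(ValueError):
    """A file could not be interpreted as a study table."""


def encode_status(status) -> np.ndarray:
    """Map case/control labels to the +1/-1 coding used throughout.

    Accepts {case, control} strings, {1, -1}, or {1, 0} (1 = case).
    """
    arr = np.asarray(status)
    if arr.dtype.kind in "OUS":
        out = np.empty(arr.shape[0], dtype=np.int8)
        for i, v in enumerate(arr):
            key = str(v).strip().lower()
            if key not in _STATUS_MAP:
                raise ValidationError(f"unrecognized status label {v!r}")
            out[i] = _STATUS_MAP[key]
        return out
    vals = set(np.unique(arr).tolist())
    if vals <= {1, -1}:
        return arr.astype(np.int8)
    if vals <= {0, 1}:
        return np.where(arr == 1, 1, -1).astype(np.int8)
    raise ValidationError(f"status values {sorted(vals)} not interpretable as case/control")


@dataclass
class StudyDataset:
    """One study's genotype matrix, missingness included, plus labels.

    genotypes is float with NaN for missing entries; every non-missing entry
    must be 0, 1 or 2 (additive minor-allele coding).  status is +1 for
    cases, -1 for controls.
    """

    study_id: str
    snp_ids: list[str]
    genotypes: np.ndarray
    status: np.ndarray

    def __post_init__(self):
        self.snp_ids = list(self.snp_ids)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be 2-dimensional")
        self.status = encode_status(self.status)
        n, p = self.genotypes.shape
        if p != len(self.snp_ids):
            raise ValidationError(
                f"study {self.study_id}: {p} genotype columns but {len(self.snp_ids)} snp_ids")
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValidationError(f"study {self.study_id}: duplicate snp_ids")
        if self.status.shape[0] != n:
            raise ValidationError(f"study {self.study_id}: status length mismatch")
        if n < 2:
            raise ValidationError(f"study {self.study_id}: needs at least 2 individuals")
        if not (np.any(self.status == 1) and np.any(self.status == -1)):
            raise ValidationError(
                f"study {self.study_id}: needs at least one case and one control")
        obs = self.genotypes[np.isfinite(self.genotypes)]
        bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))]
        if bad.size:
            i, j = np.argwhere(
                np.isfinite(self.genotypes)
                & ~np.isin(self.genotypes, (0.0, 1.0, 2.0)))[0]
            raise ValidationError(
                f"study {self.study_id}: genotype {self.genotypes[i, j]!r} at "
                f"row {i}, column {self.snp_ids[j]!r} is not 0/1/2/missing")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.status == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.status == -1))

    def subset_rows(self, idx) -> "StudyDataset":
        """New study restricted to the given individuals (validates classes)."""
        idx = np.asarray(idx)
        return StudyDataset(self.study_id, self.snp_ids,
                            self.genotypes[idx], self.status[idx])

    def subset_snps(self, keep: list[str]) -> "StudyDataset":
        """New study restricted to the given SNP columns, in this study's order."""
        keep_set = set(keep)
        cols = [i for i, s in enumerate(self.snp_ids) if s in keep_set]
        return StudyDataset(self.study_id, [self.snp_ids[i] for i in cols],
                            self.genotypes[:, cols], self.status)


@dataclass
class PooledData:
    """Studies aligned to the superset of SNP ids.

    superset follows first-appearance order across the studies in input
    order, which downstream argmax tie-breaking relies on.  availability
    maps SNP -> set of study ids whose platform carries the column (K_j);
    n_j counts non-missing entries, generalizing the whole-study count to
    entry-level missingness.
    """

    studies: list[StudyDataset]
    superset: list[str] = field(init=False)
    availability: dict[str, set[str]] = field(init=False)
    n_j: dict[str, int] = field(init=False)

    def __post_init__(self):
        if not self.studies:
            raise ValidationError("need at least one study")
        ids = [s.study_id for s in self.studies]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate study_id among {ids}")
        superset: list[str] = []
        seen: set[str] = set()
        availability: dict[str, set[str]] = {}
        for study in self.studies:
            for snp in study.snp_ids:
                if snp not in seen:
                    seen.add(snp)
                    superset.append(snp)
                    availability[snp] = set()
                availability[snp].add(study.study_id)
        self.superset = superset
        self.availability = availability
        self._col = {s: i for i, s in enumerate(superset)}
        self._arrays: tuple | None = None
        X, _, _ = self.to_arrays()
        counts = np.isfinite(X).sum(axis=0)
        self.n_j = {s: int(counts[i]) for i, s in enumerate(superset)}
        self._pair_cache: dict[tuple[int, int], int] = {}

    @property
    def p(self) -> int:
        return len(self.superset)

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.studies)

    @property
    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    def column_index(self, snp: str) -> int:
        try:
            return self._col[snp]
        except KeyError:
            raise KeyError(f"unknown SNP id {snp!r}") from None

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row-stacked (X, y, study_idx) aligned to the superset.

        Columns absent from a study's platform are NaN for its rows, so
        platform non-overlap and entry-level missingness share one
        representation downstream.
        """
        if self._arrays is None:
            n = self.n_total
            X = np.full((n, self.p), np.nan)
            y = np.empty(n, dtype=np.int8)
            study_idx = np.empty(n, dtype=np.intp)
            r = 0
            for li, study in enumerate(self.studies):
                cols = [self._col[s] for s in study.snp_ids]
                X[r:r + study.n, cols] = study.genotypes
                y[r:r + study.n] = study.status
                study_idx[r:r + study.n] = li
                r += study.n
            self._arrays = (X, y, study_idx)
        return self._arrays

    def pair_count(self, j: str, k: str) -> int:
        """n_jk: individuals with both SNPs non-missing (within K_j ∩ K_k)."""
        cj, ck = self.column_index(j), self.column_index(k)
        key = (cj, ck) if cj <= ck else (ck, cj)
        if key not in self._pair_cache:
            X, _, _ = self.to_arrays()
            self._pair_cache[key] = int(
                np.sum(np.isfinite(X[:, cj]) & np.isfinite(X[:, ck])))
        return self._pair_cache[key]


def build_pooled(studies: list[StudyDataset]) -> PooledData:
    """Pool studies against the superset of their SNP columns."""
    return PooledData(list(studies))


def pair_count(pooled: PooledData, j: str, k: str) -> int:
    """Number of individuals with both j and k observed (symmetric, cached)."""
    return pooled.pair_count(j, k)


def _validate_genotype_frame(df: pd.DataFrame, study_id: str) -> np.ndarray:
    geno = np.full(df.shape, np.nan)
    for cpos, col in enumerate(df.columns):
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        tokens = vals.astype(str).str.strip()
        is_missing = vals.isna() | tokens.isin(MISSING_TOKENS)
        bad = ~is_missing & (numeric.isna() | ~numeric.isin((0.0, 1.0, 2.0)))
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"study {study_id}: genotype {vals.iloc[row]!r} at row {row}, "
                f"column {col!r} is not 0/1/2/missing")
        geno[:, cpos] = numeric.to_numpy(dtype=float)
    return geno


def read_study_table(path, study_id: str, dialect: str = "csv") -> StudyDataset:
    """Read one study from a delimited text table.

    dialect "csv": header row of SNP ids plus a ``status`` column holding
    {case, control} or {1, -1}; missing genotypes are empty or "NA".
    dialect "plink_raw": PLINK additive recoding — six metadata columns
    (FID IID PAT MAT SEX PHENOTYPE, phenotype 1=control/2=case) followed by
    genotype columns; a trailing _<allele> counting-allele suffix on SNP
    names is stripped.
    """
    if dialect == "csv":
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         keep_default_na=False)
        status_col = next((c for c in df.columns if c.lower() == "status"), None)
        if status_col is None:
            raise ParseError(f"{path}: no 'status' column")
        status = encode_status(df[status_col].to_numpy())
        geno_df = df.drop(columns=[status_col])
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        missing_meta = [c for c in _PLINK_META_COLS if c not in df.columns]
        if missing_meta:
            raise ParseError(f"{path}: missing PLINK columns {missing_meta}")
        pheno = pd.to_numeric(df["PHENOTYPE"], errors="coerce")
        if not pheno.isin((1.0, 2.0)).all():
            raise ParseError(f"{path}: PHENOTYPE must be 1 (control) or 2 (case)")
        status = np.where(pheno == 2.0, 1, -1).astype(np.int8)
        geno_df = df.drop(columns=list(_PLINK_META_COLS))
        geno_df.columns = [_ALLELE_SUFFIX.sub("", c) for c in geno_df.columns]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    genotypes = _validate_genotype_frame(geno_df, study_id)
    return StudyDataset(study_id, list(geno_df.columns), genotypes, status)


def write_study_table(study: StudyDataset, path) -> None:
    """Write the CSV dialect read by :func:`read_study_table`."""
    df = pd.DataFrame(study.genotypes, columns=study.snp_ids)
    for c in df.columns:  # keep 0/1/2 as integers, missing as empty
        df[c] = df[c].map(lambda v: "" if not np.isfinite(v) else str(int(v)))
    df["status"] = np.where(study.status == 1, "case", "control")
    df.to_csv(path, index=False)


def read_manifest(path) -> PooledData:
    """Load studies from a manifest: ``studies: [{id, path, dialect}]``.

    Relative study paths resolve against the manifest's directory.
    """
    from pathlib import Path

    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "studies" not in cfg:
        raise ParseError(f"{path}: manifest needs a 'studies' list")
    studies = []
    for entry in cfg["studies"]:
        p = Path(entry["path"])
        if not p.is_absolute():
            p = path.parent / p
        studies.append(read_study_table(p, entry["id"],
                                        entry.get("dialect", "csv")))
    return build_pooled(studies)
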