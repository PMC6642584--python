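"""Standardization and the pooled sufficient statistics behind boosting.

The working model is linear quasi-likelihood: the case/control label is
coded +1/-1 and centered per study, genotype columns are centered and
scaled per study so the observed-entry sum of squares equals the
observed-entry count.  Two families of statistics then drive everything:

* the pooled score Δ_j = (1/n_j) Σ x_ij · y_i over every observed entry of
  SNP j, the sample-size-weighted average of per-study case/control mean
  differences; and
* scaled pairwise cross-products C_jk between SNP columns, computed over
  pairwise-complete entries and rescaled by n_j/n_jk so they estimate the
  full-cohort sum at the scale the boosting update expects.  This
  pairwise-complete route is what lets every study contribute to every
  statistic it can inform, under both platform non-overlap and entry-level
  missingness, and it reduces exactly to the plain cross-product sum when
  the data are complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PooledData, StudyDataset, encode_status

__all__ = [
    "StandardizedStudy",
    "StandardizedPooled",
    "standardize_study",
    "delta_study",
    "delta_pooled",
    "cov_term",
]


def _standardize_block(x: np.ndarray, min_obs: int = 2):
    """Center/scale columns over observed entries; flag degenerate columns.

    Returns (standardized x with NaN preserved, means, scales, degenerate).
    A column is degenerate in this block when it has fewer than ``min_obs``
    observed entries or zero variance; its entries are set to NaN so it no
    longer counts as available here.
    """
    x = np.asarray(x, dtype=float).copy()
    finite = np.isfinite(x)
    n_obs = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n_obs > 0, np.nansum(x, axis=0) / np.maximum(n_obs, 1), np.nan)
        centered = x - means
        ss = np.nansum(centered**2, axis=0)
        scales = np.sqrt(ss / np.maximum(n_obs, 1))
    degenerate = (n_obs < min_obs) | (scales <= 0) | ~np.isfinite(scales)
    safe = np.where(degenerate, 1.0, scales)
    out = centered / safe
    out[:, degenerate] = np.nan
    return out, means, scales, degenerate


@dataclass
class StandardizedStudy:
    """Per-study standardized view: for each non-degenerate column the
    observed entries have mean 0 and sum of squares equal to their count;
    y is +1/-1 centered within the study."""

    study_id: str
    snp_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    degenerate: np.ndarray

    def delta(self, j: str) -> float:
        try:
            c = self.snp_ids.index(j)
        except ValueError:
            raise KeyError(f"SNP {j!r} not in study {self.study_id}") from None
        if self.degenerate[c]:
            raise ValueError(f"SNP {j!r} is degenerate/unavailable in study {self.study_id}")
        col = self.x[:, c]
        obs = np.isfinite(col)
        return float(np.sum(col[obs] * self.y[obs]) / obs.sum())


def standardize_study(study: StudyDataset) -> StandardizedStudy:
    """Standardize one study's genotypes and outcome.

    Genotype columns: observed-entry mean subtracted, then scaled so the
    observed-entry sum of squares equals the observed-entry count.
    Zero-variance columns are flagged degenerate and treated as unavailable.
    Outcome: +1 case / -1 control, centered.
    """
    x, means, scales, degenerate = _standardize_block(study.genotypes)
    y = encode_status(study.status).astype(float)
    y -= y.mean()
    return StandardizedStudy(study.study_id, list(study.snp_ids),
                             x, y, means, scales, degenerate)


class StandardizedPooled:
    """Pooled standardized data plus cached pairwise statistics.

    Holds a row-stacked matrix aligned to the superset (NaN where a SNP is
    unavailable), standardized within each study.  Provides Δ_j for every
    SNP and lazily computed pairwise-complete cross-product columns, cached
    because boosting only ever needs columns of the active set.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, study_idx: np.ndarray,
                 snp_ids: list[str] | None = None,
                 study_ids: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        study_idx = np.zeros(n, dtype=np.intp) if study_idx is None else np.asarray(study_idx)
        self.snp_ids = list(snp_ids) if snp_ids is not None else [f"x{c}" for c in range(p)]
        self.study_ids = study_ids
        self._col = {s: i for i, s in enumerate(self.snp_ids)}
        y = encode_status(y).astype(float)

        Xs = np.empty_like(X)
        ys = np.empty_like(y)
        self.degenerate_by_study = {}
        for li in np.unique(study_idx):
            rows = study_idx == li
            xs, _, _, degen = _standardize_block(X[rows])
            Xs[rows] = xs
            yl = y[rows] - y[rows].mean()
            ys[rows] = yl
            self.degenerate_by_study[int(li)] = degen
        self.X = Xs
        self.y = ys
        self.study_idx = study_idx
        self.mask = np.isfinite(Xs)
        self._maskf = self.mask.astype(float)
        self.Xz = np.where(self.mask, Xs, 0.0)
        self.n_j = self.mask.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (self.Xz.T @ ys) / self.n_j
        self.delta_ = np.where(self.n_j > 0, d, 0.0)
        self._pair_cols: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_pooled(cls, pooled: PooledData) -> "StandardizedPooled":
        X, y, study_idx = pooled.to_arrays()
        return cls(X, y, study_idx, snp_ids=pooled.superset,
                   study_ids=pooled.study_ids)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column_index(self, snp: str) -> int:
        try:
            return self._col[snp]
        except KeyError:
            raise KeyError(f"unknown SNP id {snp!r}") from None

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    # ---- statistics ---------------------------------------------------
    def delta(self, j) -> float:
        """Pooled score Δ_j over all observed entries of SNP j."""
        c = self.column_index(j) if isinstance(j, str) else int(j)
        if self.n_j[c] == 0:
            raise ValueError(f"SNP {self.snp_ids[c]!r} has no observed entries")
        return float(self.delta_[c])

    def _pair_column(self, c: int) -> tuple[np.ndarray, np.ndarray]:
        """(S_·c, n_·c): raw cross-product sums over pairwise-complete rows
        with SNP c, and the pairwise counts, for every superset column."""
        if c not in self._pair_cols:
            xc = self.Xz[:, c]
            mc = self._maskf[:, c]
            S = self.Xz.T @ xc
            counts = self._maskf.T @ mc
            self._pair_cols[c] = (S, counts)
        return self._pair_cols[c]

    def pair_mean_column(self, c: int) -> np.ndarray:
        """Vector over j of (1/n_jk) Σ_pairwise x_ij x_ic — the per-pair
        mean cross-product, zero where no individual observes both."""
        S, counts = self._pair_column(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = S / counts
        return np.where(counts > 0, m, 0.0)

    def cov_term(self, j, k) -> float:
        """C_jk = (n_j/n_jk) Σ_pairwise x_ij x_ik (0 if no shared rows).

        Estimates the full double sum Σ_{l∈K_j} Σ_i x_lij x_lik at the scale
        the boosting update divides by n_j; exact when data are complete,
        and C_jj = n_j by standardization.
        """
        cj = self.column_index(j) if isinstance(j, str) else int(j)
        ck = self.column_index(k) if isinstance(k, str) else int(k)
        S, counts = self._pair_column(ck)
        if counts[cj] == 0:
            return 0.0
        return float(self.n_j[cj] / counts[cj] * S[cj])


def delta_study(std: StandardizedStudy, j: str) -> float:
    """Per-study score Δ_lj = (1/n_lj) Σ_observed x_lij y_li."""
    return std.delta(j)


def delta_pooled(sp: StandardizedPooled, j) -> float:
    """Pooled score Δ_j — the n_lj-weighted average of the per-study Δ_lj."""
    return sp.delta(j)


def cov_term(sp: StandardizedPooled, j, k) -> float:
    """Scaled pairwise cross-product C_jk (see StandardizedPooled.cov_term)."""
    return sp.cov_term(j, k)
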