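"""Subsampling-based stability selection for the boosting selector.

B subsamples of size n/2 are drawn without replacement (stratified per
study by default), boosting is refit on each, and the inclusion frequency
IF_j is the share of subsamples in which SNP j carries a nonzero
coefficient after the final step M.  With q the average number of selected
SNPs per subsample and p the superset size, the expected number of false
positives among SNPs with IF ≥ π_thr is bounded by

    E(V) ≤ q² / (p · (2·π_thr − 1)),     π_thr ∈ (0.5, 1),

so whenever the bound is ≤ α the familywise error rate P(V ≥ 1) is
controlled at level α.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .boosting import BoostingConfig, _run_boosting
from .core import StandardizedPooled
from .io import PooledData, StudyDataset, build_pooled

__all__ = [
    "StabilityConfig",
    "StabilityResult",
    "SelectionReport",
    "StabilitySelection",
    "draw_subsample",
    "inclusion_frequencies",
    "efp_bound",
    "significant_snps",
]

DEFAULT_THRESHOLDS = (0.6, 0.65, 0.7, 0.75, 0.8, 0.9)


def efp_bound(pi_thr: float, q: float, p: int) -> float:
    """Upper bound q²/(p·(2π−1)) on the expected number of false positives."""
    if not 0.5 < pi_thr < 1.0:
        raise ValueError(f"pi_thr must be in (0.5, 1), got {pi_thr}")
    if q < 0:
        raise ValueError("q must be >= 0")
    if p < 1:
        raise ValueError("p must be >= 1")
    return (1.0 / (2.0 * pi_thr - 1.0)) * q * q / p


@dataclass
class StabilityConfig:
    """B subsamples of the given per-study fraction, one boosting config,
    a master seed, and the grid of IF thresholds to report bounds for."""

    n_subsamples: int = 100
    fraction: float = 0.5
    boosting: BoostingConfig = field(default_factory=BoostingConfig)
    seed: int = 0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    stratified: bool = True
    n_retries: int = 5

    def __post_init__(self):
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        for t in self.thresholds:
            if not 0.5 < t < 1.0:
                raise ValueError(f"threshold {t} outside (0.5, 1)")


@dataclass
class StabilityResult:
    snp_ids: list[str]
    inclusion_frequencies: np.ndarray
    q: float
    p: int
    bounds: dict[float, float]
    config: StabilityConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_ids,
                             "IF": self.inclusion_frequencies})

    def frequency(self, snp: str) -> float:
        return float(self.inclusion_frequencies[self.snp_ids.index(snp)])


@dataclass
class SelectionReport:
    snps: list[str]
    pi_thr: float
    bound: float
    alpha: float
    fwer_controlled: bool


class _SingleClassSubsample(RuntimeError):
    pass


def _draw_study_rows(rows: np.ndarray, y: np.ndarray, fraction: float,
                     rng: np.random.Generator, n_retries: int) -> np.ndarray:
    m = int(np.floor(fraction * rows.size))
    for _ in range(n_retries + 1):
        pick = rng.choice(rows, size=m, replace=False)
        if np.any(y[pick] == 1) and np.any(y[pick] == -1):
            return pick
    raise _SingleClassSubsample(
        f"subsample of size {m} kept a single outcome class after "
        f"{n_retries} retries")


def _subsample_rows(y: np.ndarray, study_idx: np.ndarray, fraction: float,
                    rng: np.random.Generator, stratified: bool,
                    n_retries: int) -> np.ndarray:
    if stratified:
        parts = []
        for li in np.unique(study_idx):
            rows = np.nonzero(study_idx == li)[0]
            parts.append(_draw_study_rows(rows, y, fraction, rng, n_retries))
        return np.sort(np.concatenate(parts))
    all_rows = np.arange(y.shape[0])
    for _ in range(n_retries + 1):
        pick = rng.choice(all_rows, size=int(np.floor(fraction * y.shape[0])),
                          replace=False)
        ok = all(
            np.any(y[pick[study_idx[pick] == li]] == 1)
            and np.any(y[pick[study_idx[pick] == li]] == -1)
            for li in np.unique(study_idx[pick]))
        if ok:
            return np.sort(pick)
    raise _SingleClassSubsample(
        "pooled subsample kept a single-class study after retries")


def draw_subsample(pooled: PooledData, fraction: float = 0.5,
                   rng: np.random.Generator | int | None = None,
                   stratified: bool = True, n_retries: int = 5) -> PooledData:
    """Draw floor(fraction·n_l) individuals per study without replacement.

    The returned PooledData is rebuilt from scratch, so availability sets
    and counts refer to the subsample; downstream standardization treats it
    as a dataset in its own right.
    """
    rng = np.random.default_rng(rng)
    studies = []
    if stratified:
        for study in pooled.studies:
            rows = np.arange(study.n)
            pick = _draw_study_rows(rows, study.status.astype(int), fraction,
                                    rng, n_retries)
            studies.append(study.subset_rows(np.sort(pick)))
    else:
        _, y, sidx = pooled.to_arrays()
        pick = _subsample_rows(y.astype(int), sidx, fraction, rng, False,
                               n_retries)
        offsets = np.concatenate([[0], np.cumsum([s.n for s in pooled.studies])])
        for li, study in enumerate(pooled.studies):
            local = pick[sidx[pick] == li] - offsets[li]
            if local.size:
                studies.append(study.subset_rows(local))
    return build_pooled(studies)


class StabilitySelection(BaseEstimator):
    """Stability selection around :class:`SynthesisBoosting`.

    Parameters mirror the boosting estimator plus the resampling design:
    ``n_subsamples`` (B), ``sample_fraction`` (per-study subsample share,
    default 1/2), ``thresholds`` (the π_thr grid to report E(V) bounds
    for) and ``random_state`` (master seed; per-subsample substreams are
    spawned deterministically so reruns are bitwise identical).

    Attributes
    ----------
    inclusion_frequencies_ : ndarray of shape (p,)
        IF_j, multiples of 1/B.
    q_ : float
        Average active-set size at the final boosting step.
    p_ : int
        Superset size.
    bounds_ : dict
        π_thr -> E(V) bound on the threshold grid.
    """

    def __init__(self, n_steps: int = 200, shrinkage: float = 0.05,
                 selection_cap: int | None = None, n_subsamples: int = 100,
                 sample_fraction: float = 0.5,
                 thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                 stratified: bool = True, n_retries: int = 5,
                 random_state: int = 0):
        self.n_steps = n_steps
        self.shrinkage = shrinkage
        self.selection_cap = selection_cap
        self.n_subsamples = n_subsamples
        self.sample_fraction = sample_fraction
        self.thresholds = thresholds
        self.stratified = stratified
        self.n_retries = n_retries
        self.random_state = random_state

    def fit(self, X, y, studies=None, snp_ids=None):
        from sklearn.utils.validation import check_array

        from .io import encode_status

        X = check_array(X, dtype=float, ensure_all_finite="allow-nan")
        y = encode_status(np.asarray(y)).astype(int)
        if studies is None:
            study_idx = np.zeros(X.shape[0], dtype=np.intp)
        else:
            _, study_idx = np.unique(np.asarray(studies), return_inverse=True)
        cfg = BoostingConfig(self.n_steps, self.shrinkage, self.selection_cap)
        B = int(self.n_subsamples)
        p = X.shape[1]
        counts = np.zeros(p)
        sizes = np.zeros(B)
        children = np.random.SeedSequence(self.random_state).spawn(B)
        for b in range(B):
            rng = np.random.default_rng(children[b])
            rows = _subsample_rows(y, study_idx, self.sample_fraction, rng,
                                   self.stratified, self.n_retries)
            sp = StandardizedPooled(X[rows], y[rows], study_idx[rows],
                                    snp_ids=snp_ids)
            fit = _run_boosting(sp, cfg)
            sel = fit.coef != 0.0
            counts += sel
            sizes[b] = sel.sum()
        self.n_features_in_ = p
        self.snp_ids_ = list(snp_ids) if snp_ids is not None else [f"x{c}" for c in range(p)]
        self.inclusion_frequencies_ = counts / B
        self.selection_counts_ = counts.astype(int)
        self.q_ = float(sizes.mean())
        self.p_ = p
        self.bounds_ = {t: efp_bound(t, self.q_, p) for t in self.thresholds}
        return self

    def get_support(self, threshold: float, indices: bool = False):
        mask = self.inclusion_frequencies_ >= threshold
        return np.nonzero(mask)[0] if indices else mask

    def result(self, config: StabilityConfig | None = None) -> StabilityResult:
        if config is None:
            config = StabilityConfig(
                n_subsamples=self.n_subsamples, fraction=self.sample_fraction,
                boosting=BoostingConfig(self.n_steps, self.shrinkage,
                                        self.selection_cap),
                seed=self.random_state, thresholds=tuple(self.thresholds),
                stratified=self.stratified, n_retries=self.n_retries)
        return StabilityResult(self.snp_ids_, self.inclusion_frequencies_,
                               self.q_, self.p_, dict(self.bounds_), config)


def inclusion_frequencies(pooled: PooledData,
                          config: StabilityConfig | None = None,
                          **kwargs) -> StabilityResult:
    """Run stability selection on pooled studies and report IFs, q and the
    per-threshold E(V) bounds."""
    if config is None:
        config = StabilityConfig(**kwargs)
    X, y, study_idx = pooled.to_arrays()
    est = StabilitySelection(
        n_steps=config.boosting.n_steps, shrinkage=config.boosting.shrinkage,
        selection_cap=config.boosting.selection_cap,
        n_subsamples=config.n_subsamples, sample_fraction=config.fraction,
        thresholds=tuple(config.thresholds), stratified=config.stratified,
        n_retries=config.n_retries, random_state=config.seed)
    est.fit(X, y, studies=study_idx, snp_ids=pooled.superset)
    return est.result(config)


def significant_snps(result: StabilityResult, pi_thr: float,
                     alpha: float = 0.05) -> SelectionReport:
    """SNPs with IF ≥ π_thr, with the E(V) bound and whether it certifies
    FWER control at level alpha (bound ≤ alpha)."""
    bound = efp_bound(pi_thr, result.q, result.p)
    snps = [s for s, f in zip(result.snp_ids, result.inclusion_frequencies)
            if f >= pi_thr]
    return SelectionReport(snps, pi_thr, bound, alpha, bound <= alpha)
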