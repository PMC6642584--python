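"""Covariance-based componentwise boosting over the SNP superset.

Starting from β = 0, each step refits every candidate SNP against what the
current model leaves unexplained,

    γ_j = Δ_j − (1/n_j) Σ_{k: β_k ≠ 0} β_k · C_jk ,

selects j* = argmax γ_j² (the score-statistic criterion), and takes the
shrunken update β_{j*} += ν·γ_{j*}.  Because γ_j depends on the data only
through the pooled scores Δ_j and the pairwise statistics C_jk, every study
contributes to every statistic it can inform — no complete-case restriction
is needed — and on complete data the procedure coincides coordinate-for-
coordinate with classical residual-based componentwise boosting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import StandardizedPooled
from .io import PooledData

__all__ = [
    "BoostingConfig",
    "BoostingFit",
    "SynthesisBoosting",
    "candidate_gammas",
    "boost_step",
    "boost_fit",
]


@dataclass
class BoostingConfig:
    """M boosting steps with shrinkage ν; optionally stop once the active
    set would exceed ``selection_cap`` distinct SNPs."""

    n_steps: int = 200
    shrinkage: float = 0.05
    selection_cap: int | None = None

    def __post_init__(self):
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if not 0 < self.shrinkage <= 1:
            raise ValueError("shrinkage must be in (0, 1]")
        if self.selection_cap is not None and self.selection_cap < 1:
            raise ValueError("selection_cap must be >= 1")


@dataclass
class StepRecord:
    step: int
    snp: str
    gamma: float
    beta: float


@dataclass
class BoostingFit:
    """Sparse coefficient vector over the superset plus the selection path."""

    snp_ids: list[str]
    coef: np.ndarray
    history: list[StepRecord]
    converged: bool
    config: BoostingConfig

    @property
    def beta(self) -> dict[str, float]:
        return {s: float(b) for s, b in zip(self.snp_ids, self.coef) if b != 0.0}

    @property
    def active_set(self) -> list[str]:
        return [s for s, b in zip(self.snp_ids, self.coef) if b != 0.0]

    def to_frame(self) -> pd.DataFrame:
        first = {}
        for rec in self.history:
            first.setdefault(rec.snp, rec.step)
        rows = [(s, float(b), first.get(s)) for s, b in zip(self.snp_ids, self.coef)
                if b != 0.0]
        return pd.DataFrame(rows, columns=["snp_id", "beta", "first_selected_step"])


def _run_boosting(sp: StandardizedPooled, config: BoostingConfig) -> BoostingFit:
    p = sp.p
    beta = np.zeros(p)
    gamma = sp.delta_.copy()
    history: list[StepRecord] = []
    cols: dict[int, np.ndarray] = {}
    active = 0
    converged = False
    for m in range(config.n_steps):
        j = int(np.argmax(gamma * gamma))  # first index wins ties
        g = gamma[j]
        if g == 0.0:
            converged = True
            break
        entering = beta[j] == 0.0
        if entering and config.selection_cap is not None and active >= config.selection_cap:
            break
        upd = config.shrinkage * g
        beta[j] += upd
        if entering:
            active += 1
        if j not in cols:
            cols[j] = sp.pair_mean_column(j)
        # γ_j' = Δ_j − Σ_k β_k (S_jk / n_jk); only the j* term changed
        gamma = gamma - upd * cols[j]
        history.append(StepRecord(m, sp.snp_ids[j], float(g), float(beta[j])))
    return BoostingFit(list(sp.snp_ids), beta, history, converged, config)


def _as_standardized(data) -> StandardizedPooled:
    if isinstance(data, StandardizedPooled):
        return data
    if isinstance(data, PooledData):
        return StandardizedPooled.from_pooled(data)
    raise TypeError(f"expected PooledData or StandardizedPooled, got {type(data)!r}")


def candidate_gammas(data, beta=None) -> pd.Series:
    """γ_j for every superset SNP given current coefficients.

    With β = 0 this is just the pooled score Δ_j; otherwise each active
    coefficient is decorrelated out through the pairwise statistics.
    """
    sp = _as_standardized(data)
    gamma = sp.delta_.copy()
    if beta is not None:
        if isinstance(beta, dict):
            items = [(sp.column_index(s), b) for s, b in beta.items()]
        else:
            arr = np.asarray(beta, dtype=float)
            items = [(int(c), arr[c]) for c in np.nonzero(arr)[0]]
        for c, b in items:
            if b != 0.0:
                gamma = gamma - b * sp.pair_mean_column(c)
    return pd.Series(gamma, index=sp.snp_ids)


def boost_step(data, beta, config: BoostingConfig):
    """One selection-and-update step; returns (j* or None, updated beta).

    j* is None (the converged sentinel) when every γ_j is exactly zero.
    """
    sp = _as_standardized(data)
    gamma = candidate_gammas(sp, beta).to_numpy()
    j = int(np.argmax(gamma * gamma))
    if gamma[j] == 0.0:
        return None, beta
    new = dict(beta) if isinstance(beta, dict) else {
        sp.snp_ids[c]: float(v) for c, v in enumerate(np.asarray(beta)) if v != 0.0}
    snp = sp.snp_ids[j]
    new[snp] = new.get(snp, 0.0) + config.shrinkage * float(gamma[j])
    return snp, new


def boost_fit(data, config: BoostingConfig | None = None, **kwargs) -> BoostingFit:
    """Run the full boosting path on pooled (or pre-standardized) data."""
    if config is None:
        config = BoostingConfig(**kwargs)
    return _run_boosting(_as_standardized(data), config)


class SynthesisBoosting(BaseEstimator):
    """Componentwise boosting for pooled multi-study case-control panels.

    Accepts a row-stacked genotype matrix (NaN marks entries a study did
    not observe, including whole platform-absent column blocks), binary
    case/control labels, and per-row study membership.  Standardization is
    per study; selection statistics pool across studies through pairwise-
    complete covariances, so partially overlapping platforms need no
    complete-case restriction.

    Parameters
    ----------
    n_steps : int, default 200
        Number of boosting steps M.
    shrinkage : float, default 0.05
        Shrinkage ν in (0, 1] applied to every selected update.
    selection_cap : int or None
        Optional alternative stop: halt before the active set would exceed
        this many SNPs.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Coefficients on the per-study standardized scale (sparse).
    history_ : list of StepRecord
        Per-step (step, snp, γ, updated β) records.
    active_set_ : list of str
        SNPs with nonzero coefficient.
    converged_ : bool
        True when boosting stopped because every γ_j was exactly zero.
    """

    def __init__(self, n_steps: int = 200, shrinkage: float = 0.05,
                 selection_cap: int | None = None):
        self.n_steps = n_steps
        self.shrinkage = shrinkage
        self.selection_cap = selection_cap

    def _config(self) -> BoostingConfig:
        return BoostingConfig(self.n_steps, self.shrinkage, self.selection_cap)

    def fit(self, X, y, studies=None, snp_ids=None):
        from sklearn.utils.validation import check_array

        X = check_array(X, dtype=float, ensure_all_finite="allow-nan")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if studies is None:
            study_idx = np.zeros(X.shape[0], dtype=np.intp)
        else:
            _, study_idx = np.unique(np.asarray(studies), return_inverse=True)
        sp = StandardizedPooled(X, y, study_idx, snp_ids=snp_ids)
        fit = _run_boosting(sp, self._config())
        self.n_features_in_ = X.shape[1]
        self.snp_ids_ = fit.snp_ids
        self.coef_ = fit.coef
        self.history_ = fit.history
        self.active_set_ = fit.active_set
        self.converged_ = fit.converged
        # pooled location/scale per column, for scoring new individuals
        obs = np.isfinite(sp.X)
        raw = np.asarray(X, dtype=float)
        n_obs = np.isfinite(raw).sum(axis=0)
        self.feature_means_ = np.where(n_obs > 0, np.nansum(raw, axis=0) / np.maximum(n_obs, 1), 0.0)
        with np.errstate(invalid="ignore"):
            var = np.nansum((raw - self.feature_means_) ** 2, axis=0) / np.maximum(n_obs, 1)
        scale = np.sqrt(var)
        self.feature_scales_ = np.where(scale > 0, scale, 1.0)
        del obs
        return self

    def get_support(self, indices: bool = False):
        mask = self.coef_ != 0.0
        return np.nonzero(mask)[0] if indices else mask

    def decision_function(self, X) -> np.ndarray:
        """Genetic risk score x'β on the pooled standardized scale; missing
        entries contribute zero (mean imputation after standardization)."""
        from sklearn.utils.validation import check_array, check_is_fitted

        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float, ensure_all_finite="allow-nan")
        Z = (X - self.feature_means_) / self.feature_scales_
        return np.where(np.isfinite(Z), Z, 0.0) @ self.coef_
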