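"""Reference analyses the covariance-based selector is compared against.

* ``residual_boost_oracle`` — classical componentwise boosting written the
  literal way (recompute residuals each step), defined only for complete
  data.  On complete-overlap panels the covariance-based path must match
  it coordinate-for-coordinate; this equivalence is the package's primary
  correctness check.
* ``restrict_complete_case`` — the "partial" analysis: drop the studies
  (or intersect to the SNPs) that cause partial overlap.
* ``univariate_pvalues`` / ``bonferroni`` — single-SNP association tests
  for reference reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .boosting import BoostingConfig, BoostingFit, StepRecord
from .core import StandardizedPooled
from .io import PooledData, build_pooled

__all__ = [
    "residual_boost_oracle",
    "restrict_complete_case",
    "univariate_pvalues",
    "bonferroni",
]


def residual_boost_oracle(data, config: BoostingConfig) -> BoostingFit:
    """Residual-based componentwise boosting on complete pooled data.

    Each step recomputes residuals r = y − Xβ over all pooled individuals,
    scores every candidate by γ_j = (1/n) Σ x_ij r_i, and applies the
    shrunken update to the argmax of γ². Raises on any missing entry.
    """
    sp = data if isinstance(data, StandardizedPooled) else StandardizedPooled.from_pooled(data)
    if not sp.is_complete:
        raise ValueError("residual oracle requires complete data "
                         "(no missing entries, full SNP overlap)")
    X, y = sp.X, sp.y
    n, p = X.shape
    beta = np.zeros(p)
    history: list[StepRecord] = []
    converged = False
    for m in range(config.n_steps):
        r = y - X @ beta
        gamma = (X.T @ r) / n
        j = int(np.argmax(gamma * gamma))
        if gamma[j] == 0.0:
            converged = True
            break
        if (config.selection_cap is not None and beta[j] == 0.0
                and np.count_nonzero(beta) >= config.selection_cap):
            break
        beta[j] += config.shrinkage * gamma[j]
        history.append(StepRecord(m, sp.snp_ids[j], float(gamma[j]), float(beta[j])))
    return BoostingFit(list(sp.snp_ids), beta, history, converged, config)


def restrict_complete_case(pooled: PooledData,
                           policy: str = "drop_studies") -> PooledData:
    """The complete-case ("partial") restriction of a pooled panel.

    policy "drop_studies": keep only studies whose platform covers the
    full superset (the usual reaction to partial overlap — discard the
    studies causing it).  policy "intersect": keep all studies but only
    the SNPs every study carries.
    """
    superset = set(pooled.superset)
    if policy == "drop_studies":
        keep = [s for s in pooled.studies if set(s.snp_ids) == superset]
        if not keep:
            raise ValueError("no study covers the full superset")
        return build_pooled(keep)
    if policy == "intersect":
        common = set(pooled.studies[0].snp_ids)
        for s in pooled.studies[1:]:
            common &= set(s.snp_ids)
        if not common:
            raise ValueError("no SNP is shared by all studies")
        return build_pooled([s.subset_snps(common) for s in pooled.studies])
    raise ValueError(f"unknown policy {policy!r}")


def univariate_pvalues(pooled: PooledData,
                       method: str = "score_linear") -> pd.DataFrame:
    """Single-SNP association p-values over the pooled studies.

    "score_linear": score test in the linear working model — for each SNP
    z = √n_j · Δ_j / s_y with s_y the root mean square of the centered
    outcome over the rows where the SNP is observed; two-sided normal p.
    "logistic_wald": per-SNP pooled logistic regression (statsmodels),
    Wald p on the genotype slope.
    Degenerate SNPs (no usable observations) get p = 1 with a flag.
    """
    sp = StandardizedPooled.from_pooled(pooled)
    p = sp.p
    pvals = np.ones(p)
    degenerate = np.zeros(p, dtype=bool)
    if method == "score_linear":
        for c in range(p):
            obs = sp.mask[:, c]
            n_obs = int(obs.sum())
            if n_obs == 0:
                degenerate[c] = True
                continue
            s_y = np.sqrt(np.mean(sp.y[obs] ** 2))
            if s_y == 0:
                degenerate[c] = True
                continue
            z = np.sqrt(n_obs) * sp.delta_[c] / s_y
            pvals[c] = 2.0 * stats.norm.sf(abs(z))
    elif method == "logistic_wald":
        import statsmodels.api as sm

        X, yraw, _ = pooled.to_arrays()
        y01 = (yraw == 1).astype(float)
        for c in range(p):
            g = X[:, c]
            obs = np.isfinite(g)
            if obs.sum() < 3 or np.nanstd(g[obs]) == 0:
                degenerate[c] = True
                continue
            try:
                design = np.column_stack([np.ones(obs.sum()), g[obs]])
                res = sm.Logit(y01[obs], design).fit(disp=0, maxiter=100)
                pvals[c] = float(res.pvalues[1])
            except Exception:
                degenerate[c] = True
    else:
        raise ValueError(f"unknown method {method!r}")
    pvals = np.clip(pvals, 0.0, 1.0)
    pvals[degenerate] = 1.0
    return pd.DataFrame({"snp_id": sp.snp_ids, "p_value": pvals,
                         "degenerate": degenerate}).set_index("snp_id")


def bonferroni(pvalues, alpha: float = 0.05) -> list:
    """Identifiers whose p-value survives the Bonferroni cut α / #tests."""
    if isinstance(pvalues, pd.DataFrame):
        pvalues = pvalues["p_value"]
    series = pd.Series(pvalues)
    if series.empty:
        return []
    cut = alpha / len(series)
    return list(series.index[series <= cut])
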