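"""Synthetic multi-study case-control SNP panels.

The generator emulates the structure of pooled consortium genotype data:
several case-control studies of unequal size, LD-blocked genotypes in
approximate Hardy-Weinberg proportions, a sparse additive log-odds disease
model, per-study platform masks that delete whole SNP columns, and
uniform (MCAR) entry-level missingness.

Genotypes come from a two-haplotype latent-Gaussian model: within an LD
block the latent vector is equicorrelated with correlation ρ, each of two
independent draws is thresholded at the (1 − MAF) quantile to give a
haplotype indicator, and the genotype is their sum.  Marginally each SNP
is then approximately Binomial(2, MAF) (Hardy-Weinberg), with positive LD
inside blocks and independence across blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .io import PooledData, StudyDataset, build_pooled

__all__ = [
    "SimScenario",
    "uniform_blocks",
    "gen_genotypes",
    "gen_outcome",
    "gen_study",
    "make_pooled",
    "split_study",
    "recovery_scenario",
    "null_scenario",
    "CANONICAL_MASK_FRACTION",
]

# GP2-vs-GP1 platform coverage ratio used as the canonical mask: 13349/15961
CANONICAL_MASK_FRACTION = 13349 / 15961


def uniform_blocks(p: int, size: int, rho: float) -> list[tuple[int, float]]:
    """Tile p columns into LD blocks of the given size (last may be short)."""
    blocks = [(size, rho)] * (p // size)
    if p % size:
        blocks.append((p % size, rho))
    return blocks


def snp_name(c: int) -> str:
    return f"snp{c:05d}"


@dataclass
class SimScenario:
    """Generative parameters for a multi-study panel.

    platform_masks holds one entry per study: None (full superset), a keep
    fraction in (0, 1], or an explicit list of SNP ids.  causal maps SNP id
    to per-allele log-odds effect.  intercept None means auto-centering so
    the population case share is near 1/2.
    """

    study_sizes: list[int] = field(default_factory=lambda: [1600, 400])
    p: int = 500
    maf: np.ndarray | tuple[float, float] = (0.1, 0.4)
    ld_blocks: list[tuple[int, float]] | None = None
    causal: dict[str, float] = field(default_factory=dict)
    intercept: float | None = None
    platform_masks: list | None = None
    miss_rate: float = 0.0
    case_fraction: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.ld_blocks is None:
            self.ld_blocks = uniform_blocks(self.p, 10, 0.3)
        if sum(b for b, _ in self.ld_blocks) != self.p:
            raise ValueError("LD block sizes must sum to p")
        if not 0 <= self.miss_rate < 1:
            raise ValueError("miss_rate must be in [0, 1)")
        if self.platform_masks is not None and len(self.platform_masks) != len(self.study_sizes):
            raise ValueError("one platform mask per study required")
        self.snp_ids = [snp_name(c) for c in range(self.p)]
        unknown = set(self.causal) - set(self.snp_ids)
        if unknown:
            raise ValueError(f"causal SNPs {sorted(unknown)} outside the superset")

    def maf_vector(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.maf, tuple):
            return rng.uniform(self.maf[0], self.maf[1], size=self.p)
        maf = np.asarray(self.maf, dtype=float)
        if maf.shape != (self.p,):
            raise ValueError("explicit maf must have length p")
        if np.any((maf <= 0) | (maf > 0.5)):
            raise ValueError("maf values must lie in (0, 0.5]")
        return maf

    def effect_vector(self) -> np.ndarray:
        eff = np.zeros(self.p)
        for snp, b in self.causal.items():
            eff[self.snp_ids.index(snp)] = b
        return eff


def _latent_block(n: int, size: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    shared = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, size))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise


def gen_genotypes(scenario: SimScenario, n: int,
                  rng: np.random.Generator | int | None = None,
                  maf: np.ndarray | None = None) -> np.ndarray:
    """Draw an n × p additive genotype matrix under the scenario's LD model."""
    rng = np.random.default_rng(rng)
    if maf is None:
        maf = scenario.maf_vector(rng)
    thresh = norm.ppf(1.0 - maf)
    G = np.zeros((n, scenario.p), dtype=float)
    for _hap in range(2):
        start = 0
        for size, rho in scenario.ld_blocks:
            z = _latent_block(n, size, rho, rng)
            G[:, start:start + size] += z > thresh[start:start + size]
            start += size
    return G


def gen_outcome(genotypes: np.ndarray, scenario: SimScenario,
                rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Sample case (+1) / control (-1) labels from the additive log-odds model
    P(case) = expit(intercept + Σ_causal β_j g_j)."""
    rng = np.random.default_rng(rng)
    eff = scenario.effect_vector()
    intercept = scenario.intercept
    if intercept is None:
        # center the linear predictor at the population genotype mean
        intercept = -float(np.mean(genotypes @ eff))
    eta = intercept + genotypes @ eff
    return np.where(rng.random(genotypes.shape[0]) < expit(eta), 1, -1).astype(np.int8)


def gen_study(scenario: SimScenario, n: int,
              rng: np.random.Generator | int | None = None,
              maf: np.ndarray | None = None,
              max_oversample: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Generate (genotypes, statuses) for one study of size n.

    With case_fraction set, individuals are generated in excess and
    subsampled to the target case:control ratio; raises if the generation
    budget (max_oversample × n per class) cannot reach it.
    """
    rng = np.random.default_rng(rng)
    if maf is None:
        maf = scenario.maf_vector(rng)
    G = gen_genotypes(scenario, n, rng, maf=maf)
    y = gen_outcome(G, scenario, rng)
    if scenario.case_fraction is None:
        return G, y
    n_case = int(round(scenario.case_fraction * n))
    n_ctrl = n - n_case
    rounds = 0
    while (np.sum(y == 1) < n_case or np.sum(y == -1) < n_ctrl):
        if rounds >= max_oversample:
            raise RuntimeError(
                f"could not reach case_fraction={scenario.case_fraction} "
                f"within the generation budget")
        G2 = gen_genotypes(scenario, n, rng, maf=maf)
        y2 = gen_outcome(G2, scenario, rng)
        G = np.vstack([G, G2])
        y = np.concatenate([y, y2])
        rounds += 1
    cases = np.nonzero(y == 1)[0][:n_case]
    ctrls = np.nonzero(y == -1)[0][:n_ctrl]
    keep = np.sort(np.concatenate([cases, ctrls]))
    return G[keep], y[keep]


def _mask_columns(scenario: SimScenario, mask, rng: np.random.Generator) -> list[str]:
    if mask is None:
        return list(scenario.snp_ids)
    if isinstance(mask, (int, float)):
        if not 0 < mask <= 1:
            raise ValueError("mask fraction must be in (0, 1]")
        keep_n = int(round(mask * scenario.p))
        if keep_n == 0:
            raise ValueError("platform mask removes every SNP from a study")
        cols = np.sort(rng.choice(scenario.p, size=keep_n, replace=False))
        return [scenario.snp_ids[c] for c in cols]
    cols = list(mask)
    if not cols:
        raise ValueError("platform mask removes every SNP from a study")
    return cols


def make_pooled(scenario: SimScenario) -> tuple[PooledData, dict]:
    """Generate the full multi-study panel plus a ground-truth record.

    Studies share one MAF/LD configuration (drawn from the scenario seed);
    per-study substreams control individuals, masks and missingness so the
    output is reproducible given the seed.
    """
    children = np.random.SeedSequence(scenario.seed).spawn(len(scenario.study_sizes) + 1)
    maf = scenario.maf_vector(np.random.default_rng(children[0]))
    studies = []
    masks_used = {}
    for li, n_l in enumerate(scenario.study_sizes):
        rng = np.random.default_rng(children[li + 1])
        G, y = gen_study(scenario, n_l, rng, maf=maf)
        mask_spec = None if scenario.platform_masks is None else scenario.platform_masks[li]
        keep = _mask_columns(scenario, mask_spec, rng)
        keep_idx = [scenario.snp_ids.index(s) for s in keep]
        Gm = G[:, keep_idx]
        if scenario.miss_rate > 0:
            holes = rng.random(Gm.shape) < scenario.miss_rate
            Gm = np.where(holes, np.nan, Gm)
        sid = f"study{chr(ord('A') + li)}"
        studies.append(StudyDataset(sid, keep, Gm, y))
        masks_used[sid] = keep
    truth = {
        "causal": dict(scenario.causal),
        "maf": maf,
        "masks": masks_used,
        "seed": scenario.seed,
    }
    return build_pooled(studies), truth


def split_study(genotypes: np.ndarray, status: np.ndarray, snp_ids: list[str],
                rng: np.random.Generator | int | None = None,
                weights: tuple[float, float] = (8.0, 1.0),
                mask_fraction: float = CANONICAL_MASK_FRACTION,
                ) -> list[StudyDataset]:
    """Split one complete dataset into a large full-platform study and a
    small study masked to ``mask_fraction`` of the superset.

    Mirrors the design of artificially separating a complete cohort 8:1 and
    deleting columns of the small part to emulate a second platform.
    """
    rng = np.random.default_rng(rng)
    n = genotypes.shape[0]
    perm = rng.permutation(n)
    n_small = int(round(n * weights[1] / sum(weights)))
    small, large = perm[:n_small], perm[n_small:]
    p = len(snp_ids)
    keep_n = int(round(mask_fraction * p))
    keep_cols = np.sort(rng.choice(p, size=keep_n, replace=False))
    study_a = StudyDataset("studyA", snp_ids, genotypes[large], status[large])
    study_b = StudyDataset("studyB", [snp_ids[c] for c in keep_cols],
                           genotypes[np.ix_(small, keep_cols)], status[small])
    return [study_a, study_b]


def _spread_causal(p: int, n_causal: int, effect: float) -> dict[str, float]:
    cols = np.linspace(0, p - 1, n_causal + 2)[1:-1].round().astype(int)
    return {snp_name(int(c)): effect for c in cols}


def recovery_scenario(seed: int = 0, study_sizes=(1600, 400), p: int = 500,
                      n_causal: int = 5, odds_ratio: float = 1.6,
                      mask_fraction: float = CANONICAL_MASK_FRACTION,
                      miss_rate: float = 0.02) -> SimScenario:
    """The canonical two-study recovery design: a large full-platform study
    and a small study masked to the canonical coverage ratio, with a sparse
    additive signal at the given per-allele odds ratio."""
    return SimScenario(
        study_sizes=list(study_sizes), p=p,
        causal=_spread_causal(p, n_causal, float(np.log(odds_ratio))),
        platform_masks=[None, mask_fraction],
        miss_rate=miss_rate, seed=seed)


def null_scenario(seed: int = 0, n: int = 400, p: int = 200,
                  miss_rate: float = 0.0) -> SimScenario:
    """A single-study no-signal design for calibration checks."""
    return SimScenario(study_sizes=[n], p=p, causal={}, miss_rate=miss_rate,
                       seed=seed)
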