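import numpy as np
import pytest

from synthreg import StudyDataset, build_pooled


def random_study(rng, study_id="A", n=30, snp_ids=None, p=5, miss_rate=0.0):
    """A valid random study: additive genotypes, both classes present."""
    if snp_ids is None:
        snp_ids = [f"s{j}" for j in range(p)]
    g = rng.integers(0, 3, (n, len(snp_ids))).astype(float)
    if miss_rate > 0:
        g[rng.random(g.shape) < miss_rate] = np.nan
    y = rng.choice([1, -1], n)
    while len(set(y.tolist())) < 2:
        y = rng.choice([1, -1], n)
    return StudyDataset(study_id, snp_ids, g, y)


def random_pooled(rng, sizes=(30, 20), p=5, miss_rate=0.0, overlap="full"):
    """Pooled random studies; overlap='partial' masks trailing SNPs of the
    second and later studies."""
    snp_ids = [f"s{j}" for j in range(p)]
    studies = []
    for li, n in enumerate(sizes):
        ids = snp_ids
        if overlap == "partial" and li > 0:
            ids = snp_ids[: max(2, p - 2 * li)]
        studies.append(random_study(rng, study_id=f"st{li}", n=n,
                                    snp_ids=ids, miss_rate=miss_rate))
    return build_pooled(studies)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
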