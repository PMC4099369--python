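import numpy as np
import pytest

from sdsreg import GenotypeMatrix, Grm, PhenotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture
def small_diploid():
    """4 individuals x 3 markers, all polymorphic, hand-checkable."""
    codes = np.array(
        [
            [0, 1, 2],
            [2, 1, 0],
            [2, 0, 1],
            [1, 2, 1],
        ]
    )
    return GenotypeMatrix(
        codes=codes,
        ploidy="diploid",
        sample_ids=["a", "b", "c", "d"],
        marker_ids=["m1", "m2", "m3"],
    )


def random_grm(n, rng, scale=0.3):
    """A valid (symmetric PSD-ish, unit-diagonal) random GRM for tests."""
    w = rng.standard_normal((n, 4 * n))
    theta = w @ w.T / (4 * n)
    d = np.sqrt(np.diag(theta))
    theta = theta / np.outer(d, d)
    theta = scale * theta + (1 - scale) * np.eye(n)
    theta = (theta + theta.T) / 2
    return Grm(theta=theta, sample_ids=[f"i{k}" for k in range(n)])


@pytest.fixture
def aligned_panel_grm(rng):
    """n=30 random phenotype panel aligned with a random GRM."""
    n = 30
    grm = random_grm(n, rng)
    panel = PhenotypePanel(y=rng.standard_normal(n), sample_ids=list(grm.sample_ids))
    return panel, grm
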