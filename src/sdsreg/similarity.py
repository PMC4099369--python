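"""Per-pair phenotypic similarity and squared-difference indexes.

For a trait vector ``y`` with grand mean ``ybar``, every unordered pair
(i, j), i > j, contributes

* the similarity (centered cross-product) ``s_ij = (y_i - ybar)(y_j - ybar)``,
  whose expectation under a purely additive model is ``theta_ij * sigma2_a``;
* the half squared difference ``d_ij = (y_i - y_j)^2 / 2``, whose expectation
  is ``sigma2_p - theta_ij * sigma2_a`` (intercept the phenotypic variance,
  slope minus the additive variance);
* the standardized similarity ``s_ij / sigma2_p_hat`` whose regression slope
  on relatedness is the heritability directly.

Pairs are ordered by stacking the columns of the strict lower triangle
("Vech" order): (2,1), (3,1), ..., (n,1), (3,2), ...
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relatedness import Grm


@dataclass
class PhenotypePanel:
    """A single trait measured on ``n`` individuals, keyed by sample ID."""

    y: np.ndarray
    sample_ids: list[str]
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if len(self.sample_ids) != self.y.size:
            raise ValueError("sample_ids length does not match y")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotypes contain non-finite values")

    @property
    def n(self) -> int:
        return self.y.size

    def reindex(self, sample_ids: list[str]) -> "PhenotypePanel":
        """Reorder (and subset) to ``sample_ids``; every ID must be present."""
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"phenotype panel is missing sample IDs {missing[:5]}")
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return PhenotypePanel(
            y=self.y[idx], sample_ids=list(sample_ids), trait_name=self.trait_name
        )


def align_phenotypes(panel: PhenotypePanel, grm: Grm) -> PhenotypePanel:
    """Explicit join: reorder the panel into the GRM's sample order."""
    return panel.reindex(list(grm.sample_ids))


@dataclass
class PairSimilarityTable:
    """All n(n-1)/2 lower-triangle pairs with their indexes.

    ``s_std`` is ``None`` when the trait is constant (the plug-in phenotypic
    variance is zero and the standardized index is undefined).
    """

    i_idx: np.ndarray  # larger index of each pair (0-based)
    j_idx: np.ndarray  # smaller index of each pair
    theta_hat: np.ndarray
    s: np.ndarray
    d: np.ndarray
    s_std: np.ndarray | None
    sigma2_p: float  # divisor-(n-1) sample variance of y
    n: int

    @property
    def n_pairs(self) -> int:
        return self.theta_hat.size

    @property
    def pair_index(self) -> list[tuple[int, int]]:
        return list(zip(self.i_idx.tolist(), self.j_idx.tolist()))


def vech_pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) arrays, i > j, in column-stacked lower-triangle order."""
    j_idx, i_idx = np.triu_indices(n, k=1)  # upper triangle row-major == Vech of lower
    return i_idx, j_idx


def pair_table(
    panel: PhenotypePanel, grm: Grm, half_difference: bool = True
) -> PairSimilarityTable:
    """Build the per-pair similarity table for an aligned panel/GRM pair.

    ``half_difference=False`` stores the raw squared difference
    ``(y_i - y_j)^2`` instead of its half; under that convention the
    difference-model regression intercept estimates twice the phenotypic
    variance and the slope minus twice the additive variance.
    """
    if list(panel.sample_ids) != list(grm.sample_ids):
        raise ValueError(
            "phenotype and GRM sample IDs differ; join explicitly with align_phenotypes()"
        )
    n = panel.n
    if n < 3:
        raise ValueError("need n >= 3 individuals")
    i_idx, j_idx = vech_pair_indices(n)
    y = panel.y
    yc = y - y.mean()
    s = yc[i_idx] * yc[j_idx]
    diff = y[i_idx] - y[j_idx]
    d = diff * diff
    if half_difference:
        d = d / 2.0
    sigma2_p = float(y.var(ddof=1))
    s_std = s / sigma2_p if sigma2_p > 0.0 else None
    theta_hat = grm.theta[i_idx, j_idx]
    return PairSimilarityTable(
        i_idx=i_idx,
        j_idx=j_idx,
        theta_hat=theta_hat,
        s=s,
        d=d,
        s_std=s_std,
        sigma2_p=sigma2_p,
        n=n,
    )
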