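"""Least-squares estimation of additive variance and heritability from pairs.

Two regression models over the n(n-1)/2 lower-triangle pairs:

* covariance model -- regress the similarity ``s_ij`` (or its standardized
  form) on relatedness ``theta_ij``; the slope estimates ``sigma2_a`` (or
  ``h2``), the intercept should be near zero;
* difference model -- regress the half squared difference ``d_ij`` on
  ``theta_ij``; the intercept estimates ``sigma2_p`` and the slope minus
  ``sigma2_a``.

Either model can be fitted on the raw pairs (Ritland's classical procedure)
or, the default for large samples, on the means of equal-width relatedness
bins: pairs with neighbouring ``theta_ij`` contribute near-identically to
the regression line, so averaging within bins drives the residual term to
zero while fixing the regression size at the bin count regardless of n.

Bootstrap resampling draws individuals with replacement, drops duplicates
(so that a resampled GRM stays non-singular for likelihood-based
estimators) and re-estimates on the induced sub-panel/sub-GRM.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .relatedness import Grm
from .similarity import PairSimilarityTable, PhenotypePanel, pair_table

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 1000

_INDEX_NAMES = ("s", "s_std", "d")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple OLS with free intercept: returns (intercept, slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar = x.mean()
    ybar = y.mean()
    dx = x - xbar
    sxx = float(dx @ dx)
    if sxx <= 0.0:
        raise ValueError("zero variance in the regressor; slope undefined")
    slope = float(dx @ (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    return intercept, slope


@dataclass
class BinTable:
    """Equal-width relatedness bins with per-bin means of a pair index."""

    edges: np.ndarray
    counts: np.ndarray
    theta_mean: np.ndarray  # NaN where a bin is empty
    index_mean: np.ndarray  # NaN where a bin is empty
    occupied: np.ndarray
    index: str
    range_mode: str

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())


def bin_pairs(
    table: PairSimilarityTable,
    index: str = "s",
    n_bins: int = DEFAULT_N_BINS,
    range_mode: str = "data",
) -> BinTable:
    """Distribute pairs into equal-width relatedness bins and average.

    ``range_mode="data"`` spans [min theta, max theta]; ``"unit"`` spans
    [0, 1] with out-of-range values clipped into the end bins.  Interior
    edge ties go to the upper bin; the global maximum goes into the last
    bin (half-open intervals, the final one closed on the right).
    """
    if index not in _INDEX_NAMES:
        raise ValueError(f"index must be one of {_INDEX_NAMES}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = getattr(table, index)
    if values is None:
        raise ValueError("standardized index unavailable: phenotypic variance is zero")
    theta = table.theta_hat
    if range_mode == "data":
        lo, hi = float(theta.min()), float(theta.max())
        if lo == hi and n_bins > 1:
            raise ValueError("all relatedness values identical; cannot form >1 data-range bin")
        if lo == hi:
            hi = lo + 1.0  # single bin: any positive width holds everything
        assign_from = theta
    elif range_mode == "unit":
        lo, hi = 0.0, 1.0
        assign_from = np.clip(theta, lo, hi)
    else:
        raise ValueError("range_mode must be 'data' or 'unit'")
    edges = np.linspace(lo, hi, n_bins + 1)
    # digitize(right=False): edges[k-1] <= x < edges[k], so interior edge
    # ties land in the upper bin; clip sends x == hi into the last bin.
    which = np.digitize(assign_from, edges) - 1
    np.clip(which, 0, n_bins - 1, out=which)
    counts = np.bincount(which, minlength=n_bins)
    occupied = counts > 0
    with np.errstate(invalid="ignore"):
        theta_mean = np.bincount(which, weights=theta, minlength=n_bins) / counts
        index_mean = np.bincount(which, weights=values, minlength=n_bins) / counts
    n_empty = int((~occupied).sum())
    if n_empty:
        logger.debug("%d of %d bins are empty and will be excluded", n_empty, n_bins)
    return BinTable(
        edges=edges,
        counts=counts,
        theta_mean=theta_mean,
        index_mean=index_mean,
        occupied=occupied,
        index=index,
        range_mode=range_mode,
    )


def binned_regression(bins: BinTable) -> tuple[float, float]:
    """Unweighted OLS of bin-mean index on bin-mean relatedness.

    Returns (intercept, slope) over the occupied bins only.
    """
    occ = bins.occupied
    if int(occ.sum()) < 2:
        raise ValueError("need at least 2 occupied bins for a regression")
    return _ols(bins.theta_mean[occ], bins.index_mean[occ])


@dataclass
class SdsEstimate:
    """Variance components and heritability from a pair regression."""

    sigma2_a: float
    sigma2_p: float
    h2: float
    intercept: float
    slope: float
    n_bins_used: int
    method: str
    h2_valid: bool = True


def _fit_index(
    table: PairSimilarityTable,
    index: str,
    n_bins: int,
    binned: bool,
    range_mode: str,
) -> tuple[float, float, int]:
    """(intercept, slope, points used) for one index, binned or raw."""
    if binned:
        bins = bin_pairs(table, index=index, n_bins=n_bins, range_mode=range_mode)
        intercept, slope = binned_regression(bins)
        return intercept, slope, bins.n_occupied
    values = getattr(table, index)
    if values is None:
        raise ValueError("standardized index unavailable: phenotypic variance is zero")
    intercept, slope = _ols(table.theta_hat, values)
    return intercept, slope, table.n_pairs


def estimate_sds2(
    panel: PhenotypePanel,
    grm: Grm,
    n_bins: int = DEFAULT_N_BINS,
    binned: bool = True,
    range_mode: str = "data",
) -> SdsEstimate:
    """Covariance-model estimate: slope of similarity on relatedness.

    The additive variance is the slope of the ``s`` regression; the
    heritability is the slope of the ``s_std`` regression, which equals
    ``sigma2_a / sigma2_p`` under the plug-in variance -- both routes are
    computed and cross-checked.
    """
    table = pair_table(panel, grm)
    if table.s_std is None:
        raise ValueError("phenotypic variance is zero; heritability undefined")
    intercept, slope, used = _fit_index(table, "s", n_bins, binned, range_mode)
    _, slope_std, _ = _fit_index(table, "s_std", n_bins, binned, range_mode)
    h2 = slope_std
    # identical bins, index scaled by 1/sigma2_p => slopes must agree exactly
    assert abs(h2 - slope / table.sigma2_p) <= 1e-10 * max(1.0, abs(h2)), (
        "standardized-index and variance-ratio heritability routes diverged"
    )
    return SdsEstimate(
        sigma2_a=slope,
        sigma2_p=table.sigma2_p,
        h2=h2,
        intercept=intercept,
        slope=slope,
        n_bins_used=used,
        method="sds2_binned" if binned else "sds2_unbinned",
    )


def estimate_sds1(
    panel: PhenotypePanel,
    grm: Grm,
    n_bins: int = DEFAULT_N_BINS,
    binned: bool = True,
    range_mode: str = "data",
) -> SdsEstimate:
    """Difference-model estimate: regress half squared differences.

    ``sigma2_a = -slope`` and ``sigma2_p = intercept``; a non-positive
    intercept leaves ``h2`` flagged invalid (NaN).
    """
    table = pair_table(panel, grm)
    intercept, slope, used = _fit_index(table, "d", n_bins, binned, range_mode)
    sigma2_a = -slope
    sigma2_p = intercept
    if sigma2_p > 0.0:
        h2 = sigma2_a / sigma2_p
        valid = True
    else:
        h2 = float("nan")
        valid = False
    return SdsEstimate(
        sigma2_a=sigma2_a,
        sigma2_p=sigma2_p,
        h2=h2,
        intercept=intercept,
        slope=slope,
        n_bins_used=used,
        method="sds1_binned" if binned else "sds1_unbinned",
        h2_valid=valid,
    )


def estimate_ritland_unbinned(panel: PhenotypePanel, grm: Grm) -> SdsEstimate:
    """Classical un-binned covariance regression over all raw pairs.

    The legacy reference the binned estimator is validated against; memory
    scales with n(n-1)/2, so intended for moderate n.
    """
    return estimate_sds2(panel, grm, binned=False)


@dataclass
class BootstrapResult:
    """Resampled estimates of one statistic with SD and percentile CI."""

    B: int
    estimates: np.ndarray
    sd: float
    ci95: tuple[float, float]
    resample_sizes: list[int]
    n_failed: int = 0


_ESTIMATOR_TAGS = ("sds2", "sds1", "ritland", "reml")


def _dispatch_estimator(estimator, n_bins: int, range_mode: str):
    if callable(estimator):
        return estimator
    if estimator == "sds2":
        return lambda p, g: estimate_sds2(p, g, n_bins=n_bins, range_mode=range_mode).h2
    if estimator == "sds1":
        return lambda p, g: estimate_sds1(p, g, n_bins=n_bins, range_mode=range_mode).h2
    if estimator == "ritland":
        return lambda p, g: estimate_ritland_unbinned(p, g).h2
    if estimator == "reml":
        from .reml import spectral_reml

        return lambda p, g: spectral_reml(p, g).h2
    raise ValueError(f"estimator must be callable or one of {_ESTIMATOR_TAGS}")


def bootstrap_ci(
    panel: PhenotypePanel,
    grm: Grm,
    B: int = 1000,
    estimator="sds2",
    seed: int | None = None,
    n_bins: int = DEFAULT_N_BINS,
    range_mode: str = "data",
) -> BootstrapResult:
    """Bootstrap SD and 95% percentile CI with duplicate exclusion.

    Each resample draws n individuals with replacement and keeps the unique
    ones, so the resampled GRM is never singular.  The trait is re-centered
    within each resample.  Regression-based estimates are not truncated at
    zero (negative CI bounds are legal); the likelihood baseline is
    boundary-constrained by construction.  Failing resamples are skipped
    with a warning; more than 50% failures is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if list(panel.sample_ids) != list(grm.sample_ids):
        raise ValueError("phenotype and GRM sample IDs differ; align first")
    fn = _dispatch_estimator(estimator, n_bins, range_mode)
    rng = np.random.default_rng(seed)
    n = panel.n
    estimates: list[float] = []
    sizes: list[int] = []
    n_failed = 0
    for _ in range(B):
        idx = np.unique(rng.integers(0, n, size=n))
        sizes.append(int(idx.size))
        sub_panel = PhenotypePanel(
            y=panel.y[idx],
            sample_ids=[panel.sample_ids[k] for k in idx],
            trait_name=panel.trait_name,
        )
        sub_grm = grm.subset(idx)
        try:
            estimates.append(float(fn(sub_panel, sub_grm)))
        except Exception as exc:  # noqa: BLE001 - resample-level robustness
            n_failed += 1
            logger.warning("bootstrap resample failed and was skipped: %s", exc)
    if n_failed > B / 2:
        raise RuntimeError(f"{n_failed}/{B} bootstrap resamples failed")
    est = np.asarray(estimates, dtype=float)
    sd = float(est.std(ddof=1)) if est.size > 1 else 0.0
    lo, hi = np.percentile(est, [2.5, 97.5])
    return BootstrapResult(
        B=B,
        estimates=est,
        sd=sd,
        ci95=(float(lo), float(hi)),
        resample_sizes=sizes,
        n_failed=n_failed,
    )
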