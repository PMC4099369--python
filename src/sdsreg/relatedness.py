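"""Genomic relationship matrices (GRMs) from marker data and under the AR1 model.

A GRM collects the pairwise coefficients of genetic relationship
``theta_ij`` between the individuals of a sample.  Two routes are provided:

* the marker route -- integer genotype codes are standardized column-wise to
  zero mean and unit variance (VanRaden/GCTA coding) and the GRM is the
  cross-product ``W W' / m`` over the ``m`` retained markers;
* the theoretical route -- a first-order autoregressive (AR1) population in
  which relatedness decays geometrically with the index distance between
  individuals, ``theta_ij = theta_a ** |i - j|``.

The agreement between the two is summarised by the Pearson correlation of
their strict lower triangles (:func:`grm_correlation`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

logger = logging.getLogger(__name__)

DIPLOID = "diploid"
HAPLOID = "haploid"

#: legal genotype codes and allele count per ploidy
_LEGAL_CODES = {DIPLOID: frozenset((0, 1, 2)), HAPLOID: frozenset((0, 1))}
_ALLELES_PER_LOCUS = {DIPLOID: 2, HAPLOID: 1}


def _default_ids(n: int, stem: str) -> list[str]:
    return [f"{stem}{i + 1}" for i in range(n)]


@dataclass
class GenotypeMatrix:
    """Integer marker codes for ``n`` individuals at ``m`` loci.

    Diploid codes count copies of the reference allele (0, 1, 2); haploid
    codes are the 0/1 reference-homozygote indicator.  Missing values are
    not representable: readers reject them before construction.
    """

    codes: np.ndarray
    ploidy: str
    sample_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("genotype codes must be integers (missing values are rejected)")
        if self.ploidy not in _LEGAL_CODES:
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        n, m = self.codes.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 individuals and m >= 1 markers, got {n} x {m}")
        legal = _LEGAL_CODES[self.ploidy]
        observed = set(np.unique(self.codes).tolist())
        if not observed <= legal:
            raise ValueError(
                f"illegal {self.ploidy} genotype codes {sorted(observed - legal)}"
            )
        if len(self.sample_ids) != n or len(self.marker_ids) != m:
            raise ValueError("sample_ids/marker_ids lengths do not match codes shape")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Restrict to the marker columns in ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            codes=self.codes[:, idx],
            ploidy=self.ploidy,
            sample_ids=list(self.sample_ids),
            marker_ids=[self.marker_ids[k] for k in idx],
        )


@dataclass
class StandardizedGenotypes:
    """Column-standardized genotypes ``W`` with the allele frequencies used."""

    w: np.ndarray
    freqs: np.ndarray
    ploidy: str
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def m(self) -> int:
        return self.w.shape[1]


@dataclass
class Grm:
    """Symmetric ``n x n`` genetic relationship matrix with sample IDs."""

    theta: np.ndarray
    sample_ids: list[str]
    source: str = "marker"  # {marker, ar1_theoretical, file}

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        n = self.theta.shape[0]
        if self.theta.ndim != 2 or self.theta.shape[1] != n:
            raise ValueError("theta must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match theta")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta contains non-finite entries")
        if not np.array_equal(self.theta, self.theta.T):
            raise ValueError("theta must be exactly symmetric")

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    def subset(self, idx: np.ndarray) -> "Grm":
        """Sub-GRM for the individuals in ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        sub = self.theta[np.ix_(idx, idx)]
        sub = np.ascontiguousarray(sub)
        return Grm(theta=sub, sample_ids=[self.sample_ids[k] for k in idx], source=self.source)


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Reference-allele frequency estimate ``p_l`` for every marker.

    For diploids this is the mean code over ``2n`` allele copies; for
    haploids it is the frequency of the reference homozygote.  Monomorphic
    markers (``p_l`` of 0 or 1) are allowed here and rejected downstream.
    """
    k = _ALLELES_PER_LOCUS[genotypes.ploidy]
    return genotypes.codes.sum(axis=0) / (k * genotypes.n)


def standardize(genotypes: GenotypeMatrix) -> StandardizedGenotypes:
    """Standardize codes to zero-mean, unit-variance columns.

    Diploid: ``w_il = (z_il - 2 p_l) / sqrt(2 p_l (1 - p_l))``;
    haploid: ``w_il = (z_il - p_l) / sqrt(p_l (1 - p_l))``.
    Monomorphic markers are dropped with a logged warning (their scale is
    undefined); an error is raised if nothing remains.
    """
    p = allele_frequencies(genotypes)
    polymorphic = (p > 0.0) & (p < 1.0)
    n_dropped = int((~polymorphic).sum())
    if n_dropped == genotypes.m:
        raise ValueError("all markers are monomorphic; nothing to standardize")
    if n_dropped:
        logger.warning(
            "dropping %d monomorphic marker(s) before standardization", n_dropped
        )
    p = p[polymorphic]
    z = genotypes.codes[:, polymorphic].astype(float)
    k = _ALLELES_PER_LOCUS[genotypes.ploidy]
    w = (z - k * p) / np.sqrt(k * p * (1.0 - p))
    return StandardizedGenotypes(
        w=w, freqs=p, ploidy=genotypes.ploidy, sample_ids=list(genotypes.sample_ids)
    )


def compute_grm(std: StandardizedGenotypes) -> Grm:
    """Marker GRM ``theta = W W' / m`` (symmetrized against round-off)."""
    if std.m < 1:
        raise ValueError("no markers left to build a GRM from")
    theta = std.w @ std.w.T / std.m
    theta = (theta + theta.T) / 2.0
    ids = std.sample_ids or _default_ids(std.n, "ind")
    return Grm(theta=theta, sample_ids=ids, source="marker")


def grm_from_genotypes(genotypes: GenotypeMatrix) -> Grm:
    """Convenience: standardize then build the marker GRM."""
    return compute_grm(standardize(genotypes))


def ar1_grm(n: int, theta_a: float, sample_ids: list[str] | None = None) -> Grm:
    """Theoretical AR1 GRM: ``theta[i, j] = theta_a ** |i - j|``.

    Positive definite for ``|theta_a| < 1``; the diagonal is exactly 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not abs(theta_a) < 1.0:
        raise ValueError(f"|theta_a| must be < 1, got {theta_a}")
    first = theta_a ** np.arange(n, dtype=float)
    theta = toeplitz(first)
    ids = sample_ids if sample_ids is not None else _default_ids(n, "ind")
    return Grm(theta=theta, sample_ids=ids, source="ar1_theoretical")


def grm_correlation(grm_hat: Grm, grm_true: Grm) -> float:
    """Pearson correlation over the strict lower triangles of two GRMs.

    The diagonal is excluded: for the theoretical AR1 matrix it is the
    constant 1 and would contribute zero-variance points.  Runs in a
    single row-wise pass so no n(n-1)/2 index arrays are materialized.
    """
    if grm_hat.n != grm_true.n:
        raise ValueError("GRMs have different sizes")
    n = grm_hat.n
    if n < 3:
        raise ValueError("need n >= 3 for a meaningful lower-triangle correlation")
    a, b = grm_hat.theta, grm_true.theta
    sx = sy = sxx = syy = sxy = 0.0
    for i in range(1, n):
        x = a[i, :i]
        y = b[i, :i]
        sx += float(x.sum())
        sy += float(y.sum())
        sxx += float(x @ x)
        syy += float(y @ y)
        sxy += float(x @ y)
    cnt = n * (n - 1) // 2
    vx = sxx - sx * sx / cnt
    vy = syy - sy * sy / cnt
    if vx <= 0.0 or vy <= 0.0:
        raise ValueError("zero variance in lower-triangle elements; correlation undefined")
    return float((sxy - sx * sy / cnt) / np.sqrt(vx * vy))
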