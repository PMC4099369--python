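"""AR1 population, genotype, and phenotype simulator.

The study population has a full spectrum of relatedness: individuals are
ordered so that the genetic correlation between neighbours is a constant
``theta_a`` (default 0.95) and decays geometrically with index distance.
Latent marker values are sampled by the stationary AR1 recursion

    z_1 ~ N(0, I),   z_i = theta_a z_{i-1} + sqrt(1 - theta_a^2) eps_i,

the unique linear recursion with standard-normal marginals and
nearest-neighbour correlation ``theta_a``.  Each latent value is then
trichotomized at the standard-normal quartiles (+-0.67449) into diploid
genotype codes 0/1/2 with expected frequencies 1:2:1.

A randomly placed fraction of markers (default 10%) is causal.  Genetic
effects are ``a = sqrt(h2) W_c u_c / sqrt(m_c)`` with standard-normal
causal effects ``u_c`` on the standardized causal genotypes.  Three
scalings of the effect vector are offered (``effect_scaling``):

* ``"norm"`` (default) -- ``u_c`` is rescaled to unit mean square, fixing
  the effect-vector scale so the realized genetic variance fluctuates only
  through genotype sampling.  At small n it sits slightly below ``h2``
  (the sample variance of positively correlated effects is shrunk), and
  its spread is independent of the marker count;
* ``"expectation"`` -- ``u_c`` is left i.i.d., so ``sigma2_a = h2`` holds
  in expectation only and the chi-square fluctuation of ``|u_c|^2`` adds
  variance that shrinks with the causal count;
* ``"exact"`` -- ``a`` is rescaled so the realized genetic variance equals
  ``h2`` in every replicate.

Residuals are i.i.d. ``N(0, 1 - h2)``; the phenotypic variance is 1 by
design.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import DEFAULT_N_BINS, estimate_sds1, estimate_sds2
from .relatedness import GenotypeMatrix, ar1_grm, grm_correlation, grm_from_genotypes
from .similarity import PhenotypePanel

logger = logging.getLogger(__name__)

#: standard-normal 75th percentile used to trichotomize latent values
GENOTYPE_THRESHOLD = 0.67449


@dataclass
class SimConfig:
    """Parameters of one simulated population/trait."""

    n: int
    m: int
    h2: float
    theta_a: float = 0.95
    causal_fraction: float = 0.10
    mu: float = 0.0
    sigma2_p: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 < self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must be in (0, 1]")
        if not abs(self.theta_a) < 1.0:
            raise ValueError("|theta_a| must be < 1")
        if self.n < 2 or self.m < 1:
            raise ValueError("need n >= 2 and m >= 1")


@dataclass
class SimOutput:
    """One simulated replicate: genotypes, trait, and the generating truth."""

    genotypes: GenotypeMatrix
    y: PhenotypePanel
    causal_idx: np.ndarray
    u: np.ndarray
    a: np.ndarray
    e: np.ndarray
    realized_h2: float
    config: SimConfig


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_ar1_latent(
    n: int, m: int, theta_a: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """n x m latent matrix via the stationary AR1 recursion over individuals.

    Every row is marginally standard normal; rows i and j have correlation
    ``theta_a ** |i - j|`` in expectation.
    """
    if not abs(theta_a) < 1.0:
        raise ValueError("|theta_a| must be < 1")
    rng = _as_rng(seed)
    eps = rng.standard_normal((n, m))
    z = np.empty((n, m))
    z[0] = eps[0]
    innov = np.sqrt(1.0 - theta_a * theta_a)
    for i in range(1, n):
        z[i] = theta_a * z[i - 1] + innov * eps[i]
    return z


def latent_to_genotypes(latent: np.ndarray) -> GenotypeMatrix:
    """Trichotomize latent normals at +-0.67449 into diploid codes 0/1/2.

    Values on a threshold (measure zero) are assigned upward.
    """
    latent = np.asarray(latent, dtype=float)
    if not np.all(np.isfinite(latent)):
        raise ValueError("latent values must be finite")
    codes = (latent >= -GENOTYPE_THRESHOLD).astype(np.int64) + (
        latent >= GENOTYPE_THRESHOLD
    )
    n, m = codes.shape
    return GenotypeMatrix(
        codes=codes,
        ploidy="diploid",
        sample_ids=[f"ind{i + 1}" for i in range(n)],
        marker_ids=[f"snp{l + 1}" for l in range(m)],
    )


def assign_qtl(
    m: int, causal_fraction: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Sorted distinct causal-marker indices, drawn uniformly without replacement."""
    if not 0.0 < causal_fraction <= 1.0:
        raise ValueError("causal_fraction must be in (0, 1]")
    k = round(causal_fraction * m)
    if k == 0:
        raise ValueError(f"causal_fraction {causal_fraction} rounds to 0 markers of {m}")
    rng = _as_rng(seed)
    return np.sort(rng.choice(m, size=k, replace=False))


def realized_h2(a: np.ndarray, e: np.ndarray) -> float:
    """Variance ratio var(a) / (var(a) + var(e)), divisor n-1 throughout."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if a.size != e.size or a.size < 2:
        raise ValueError("a and e must have equal length >= 2")
    va = float(a.var(ddof=1))
    ve = float(e.var(ddof=1))
    if va + ve == 0.0:
        raise ValueError("both variance components are zero")
    return va / (va + ve)


_EFFECT_SCALINGS = ("norm", "expectation", "exact")


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    causal_idx: np.ndarray,
    cfg: SimConfig,
    seed: int | np.random.Generator | None = None,
    effect_scaling: str = "norm",
) -> SimOutput:
    """Draw causal effects and residuals, returning the full truth set.

    ``effect_scaling`` picks how the causal effect vector is scaled (see
    the module docstring): ``"norm"`` fixes its mean square at 1,
    ``"expectation"`` leaves it i.i.d., ``"exact"`` forces the realized
    genetic variance to ``h2``.
    """
    from .relatedness import standardize  # local import to avoid cycle at import time

    if effect_scaling not in _EFFECT_SCALINGS:
        raise ValueError(f"effect_scaling must be one of {_EFFECT_SCALINGS}")
    rng = _as_rng(seed)
    causal_idx = np.asarray(causal_idx, dtype=int)
    n = genotypes.n
    u = rng.standard_normal(causal_idx.size)
    if cfg.h2 > 0.0:
        w_causal = standardize(genotypes.subset_markers(causal_idx))
        u_used = u[: w_causal.m]
        if effect_scaling == "norm":
            u_used = u_used * np.sqrt(w_causal.m / float(u_used @ u_used))
        a_raw = (w_causal.w @ u_used) / np.sqrt(w_causal.m)
        if effect_scaling == "exact":
            var_raw = float(a_raw.var(ddof=1))
            if var_raw == 0.0:
                raise ValueError("raw genetic effects have zero variance")
            a = a_raw * np.sqrt(cfg.h2 * cfg.sigma2_p / var_raw)
        else:
            a = a_raw * np.sqrt(cfg.h2 * cfg.sigma2_p)
    else:
        a = np.zeros(n)
    if cfg.h2 < 1.0:
        e = rng.standard_normal(n) * np.sqrt((1.0 - cfg.h2) * cfg.sigma2_p)
    else:
        e = np.zeros(n)
    y = cfg.mu + a + e
    panel = PhenotypePanel(y=y, sample_ids=list(genotypes.sample_ids), trait_name="sim")
    if cfg.h2 == 0.0:
        rh2 = 0.0
    elif cfg.h2 == 1.0:
        rh2 = 1.0
    else:
        rh2 = realized_h2(a, e)
    return SimOutput(
        genotypes=genotypes,
        y=panel,
        causal_idx=causal_idx,
        u=u,
        a=a,
        e=e,
        realized_h2=rh2,
        config=cfg,
    )


def simulate(cfg: SimConfig, effect_scaling: str = "norm") -> SimOutput:
    """End-to-end replicate: latent AR1 -> genotypes -> QTL -> phenotypes.

    All randomness flows from ``cfg.seed`` through a single generator, so
    identical configs give bit-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    latent = sample_ar1_latent(cfg.n, cfg.m, cfg.theta_a, rng)
    genotypes = latent_to_genotypes(latent)
    causal_idx = assign_qtl(cfg.m, cfg.causal_fraction, rng)
    return simulate_phenotypes(genotypes, causal_idx, cfg, rng, effect_scaling)


@dataclass
class MethodSummary:
    """Replicate-level summary of one estimator in a simulation cell."""

    mean: float
    sd: float
    range90: tuple[float, float]
    t_stat: float
    p_value: float
    flag_sig: bool
    estimates: np.ndarray = field(repr=False, default=None)


@dataclass
class CellSummary:
    """One simulation cell: per-method summaries plus the realized truth."""

    per_method: dict[str, MethodSummary]
    realized: MethodSummary
    config: SimConfig
    reps: int
    seed: int | None


def _summarize(values: np.ndarray, target: float) -> MethodSummary:
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    lo, hi = np.percentile(values, [5.0, 95.0])
    if sd > 0:
        t_stat, p_value = stats.ttest_1samp(values, popmean=target)
        t_stat, p_value = float(t_stat), float(p_value)
    else:
        t_stat, p_value = 0.0, 1.0
    return MethodSummary(
        mean=mean,
        sd=sd,
        range90=(float(lo), float(hi)),
        t_stat=t_stat,
        p_value=p_value,
        flag_sig=p_value < 0.05,
        estimates=values,
    )


def run_sim_cell(
    cfg: SimConfig,
    reps: int = 100,
    methods: tuple[str, ...] = ("sds2", "reml"),
    n_bins: int = DEFAULT_N_BINS,
    seed: int | None = None,
    effect_scaling: str = "norm",
) -> CellSummary:
    """Replicate a simulation cell and summarize each estimator.

    For every replicate: simulate, build the all-marker GRM, estimate by
    each requested method.  Reports mean, SD, the 90% range (5th-95th
    percentiles, linear interpolation) and a two-sided one-sample t-test
    of the replicate mean against the true ``h2`` at alpha = 0.05.
    """
    if reps < 2:
        raise ValueError("need reps >= 2")
    unknown = set(methods) - {"sds2", "sds1", "ritland", "reml"}
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    per_method: dict[str, list[float]] = {meth: [] for meth in methods}
    realized: list[float] = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        latent = sample_ar1_latent(cfg.n, cfg.m, cfg.theta_a, rng)
        genotypes = latent_to_genotypes(latent)
        causal_idx = assign_qtl(cfg.m, cfg.causal_fraction, rng)
        out = simulate_phenotypes(genotypes, causal_idx, cfg, rng, effect_scaling)
        realized.append(out.realized_h2)
        if methods:
            grm = grm_from_genotypes(genotypes)
        for meth in methods:
            try:
                if meth == "sds2":
                    est = estimate_sds2(out.y, grm, n_bins=n_bins).h2
                elif meth == "sds1":
                    est = estimate_sds1(out.y, grm, n_bins=n_bins).h2
                elif meth == "ritland":
                    from .estimators import estimate_ritland_unbinned

                    est = estimate_ritland_unbinned(out.y, grm).h2
                else:
                    from .reml import spectral_reml

                    est = spectral_reml(out.y, grm).h2
            except Exception as exc:
                raise RuntimeError(f"estimator {meth!r} failed on replicate {r}") from exc
            per_method[meth].append(float(est))
    return CellSummary(
        per_method={
            meth: _summarize(np.asarray(vals), cfg.h2) for meth, vals in per_method.items()
        },
        realized=_summarize(np.asarray(realized), cfg.h2),
        config=cfg,
        reps=reps,
        seed=seed,
    )


def grm_accuracy(
    n: int, m: int, theta_a: float = 0.95, seed: int | np.random.Generator | None = None
) -> float:
    """Correlation between the marker GRM of one simulated population and
    the theoretical AR1 matrix (strict lower triangles)."""
    rng = _as_rng(seed)
    latent = sample_ar1_latent(n, m, theta_a, rng)
    genotypes = latent_to_genotypes(latent)
    grm_hat = grm_from_genotypes(genotypes)
    grm_true = ar1_grm(n, theta_a, sample_ids=list(genotypes.sample_ids))
    return grm_correlation(grm_hat, grm_true)


def grm_accuracy_grid(
    n_grid: tuple[int, ...],
    m_grid: tuple[int, ...],
    theta_a: float = 0.95,
    seed: int | None = None,
) -> list[tuple[int, int, float]]:
    """(n, m, r) rows over a grid of sample sizes and marker densities."""
    ss = np.random.SeedSequence(seed)
    rows = []
    children = iter(ss.spawn(len(n_grid) * len(m_grid)))
    for n in n_grid:
        for m in m_grid:
            rng = np.random.default_rng(next(children))
            rows.append((n, m, grm_accuracy(n, m, theta_a, rng)))
    return rows
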