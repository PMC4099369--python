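"""Fit the single-GRM mixed model by spectral REML and bootstrap the SDS fit.

The REML baseline maximizes the restricted likelihood of
y = mu + a + e, a ~ N(0, GRM * sigma2_a), over the heritability ratio in
[0, 1]; the bootstrap resamples individuals with replacement (duplicates
dropped so the resampled GRM stays invertible).
"""
from sdsreg import (
    SimConfig,
    bootstrap_ci,
    estimate_sds2,
    grm_from_genotypes,
    simulate,
    spectral_reml,
)

out = simulate(SimConfig(n=500, m=2000, h2=0.5, seed=1))
grm = grm_from_genotypes(out.genotypes)

sds = estimate_sds2(out.y, grm)
reml = spectral_reml(out.y, grm)
boot = bootstrap_ci(out.y, grm, B=200, estimator="sds2", seed=1)

print(f"realized heritability: {out.realized_h2:.3f}")
print(f"SDS  h2 = {sds.h2:.3f}   bootstrap SD = {boot.sd:.3f}   "
      f"95% CI = ({boot.ci95[0]:.3f}, {boot.ci95[1]:.3f})")
print(f"REML h2 = {reml.h2:.3f}   sigma2_a = {reml.sigma2_a:.3f}   "
      f"sigma2_e = {reml.sigma2_e:.3f}")
print(f"REML restricted loglik = {reml.loglik:.2f}, "
      f"boundary = {reml.at_boundary}, converged = {reml.converged}")

# REML constrains h2 to [0, 1]; the SDS regression does not, so its
# bootstrap interval may legitimately cross zero for weak signals.
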