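"""How marker density and sample size drive GRM estimation accuracy.

Correlates the marker-estimated relationship matrix with the theoretical
AR1 matrix over a small (n, m) grid.  Accuracy improves with marker count
and degrades with sample size at fixed density, because larger samples
contain ever more distant pairs whose tiny relatedness drowns in the
1/sqrt(m) noise of each GRM element.
"""
from sdsreg import grm_accuracy_grid

rows = grm_accuracy_grid(
    n_grid=(200, 500, 1000), m_grid=(200, 2000, 20000), theta_a=0.95, seed=1
)
print(f"{'n':>6}{'m':>8}{'r':>8}")
for n, m, r in rows:
    print(f"{n:>6}{m:>8}{r:>8.3f}")
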