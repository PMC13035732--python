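"""Standard NMF vs min-max fair NMF on a complexity-imbalanced benchmark.

Builds the two-group synthetic dataset (a rank-6 group and a rank-3 group on
orthogonal features), estimates each group's standalone baseline error, and
compares the per-group relative losses of standard NMF with both fair
solvers at rank 6.  A group's loss is its error in the shared model minus
its standalone baseline, normalized by the group's magnitude; the fair
solvers minimize the worst group's loss instead of the total error.
"""

import numpy as np

from fairnmf import (
    FitConfig,
    estimate_all_baselines,
    fit_fairer_am,
    fit_fairer_mu,
    fit_standard,
    gen_dataset1,
)

G = gen_dataset1(seed=0).normalized()
cfg = FitConfig(rank=6, max_iter=500, error_floor_pct=0.1, seed=0)

E = estimate_all_baselines(G, cfg, T=5, seed=0)
print(f"baseline errors E_l (standalone rank-6 NMF): {np.round(E.E, 4)}")

for name, fit in [
    ("standard NMF (MU)", lambda: fit_standard(G, cfg, E.E)),
    ("fairer NMF (AM)  ", lambda: fit_fairer_am(G, E, cfg)),
    ("fairer NMF (MU)  ", lambda: fit_fairer_mu(G, E, cfg)),
]:
    m = fit().metrics
    print(
        f"{name}: per-group losses {np.round(m.relative_losses, 3)}  "
        f"max-loss f = {m.f:.3f}"
    )

print(
    "\nStandard NMF sacrifices the high-rank group (large first loss); the\n"
    "min-max solvers pull the worst group's loss down, the alternating\n"
    "scheme equalizing the two groups almost exactly."
)
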