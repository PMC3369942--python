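"""Filament length control by severing ('binding antenna' mechanism).

Filaments grow at their plus end at speed v while a severing agent binds
anywhere along the filament at rate r per unit length and cuts it; the
minus-end fragment depolymerizes. Longer filaments recruit more severing
agents, so the stationary length distribution is unimodal with a length
scale sqrt(v/r).
"""

import numpy as np

from sarcosim.analysis import severing_steady_pdf
from sarcosim.kinetics import sample_severing_lengths

v, r = 1.0, np.pi / 2  # r chosen so the stationary mean length is 1.0
rng = np.random.default_rng(0)
lengths = sample_severing_lengths(v, r, 10_000, rng)
grid = np.linspace(0, 5, 500)
pdf = severing_steady_pdf(v, r, grid)

print(f"sample mean length        : {lengths.mean():.3f}  (expected ~1.0)")
print(f"relative s.d. (sigma_ell) : {lengths.std() / lengths.mean():.3f}"
      "  (the mechanism's intrinsic polydispersity, ~0.52)")
print(f"density peak at l         : {grid[np.argmax(pdf)]:.2f}")
print(
    "\nThe stochastic sampler and the numerically solved stationary density"
    " describe the same unimodal distribution; its scale sqrt(v/r) ties the"
    " sarcomere spacing to the polymerization/severing balance."
)
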