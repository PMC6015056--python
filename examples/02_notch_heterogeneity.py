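"""Two-cell spacing enabled by intracellular Notch heterogeneity.

With left/right Notch pools (finite diffusion W) the lattice supports a
period-3 pattern — tip cells separated by TWO stalk cells — that the
classical single-pool model cannot hold.  The stalk cells are polarized:
high activated Notch on the side facing the tip, low on the other.
"""

import numpy as np

from tipstalk import ModelParams, notch_asymmetry, solve_pattern

for W in (0.0, 3.0, 50.0):
    params = ModelParams(b0=0.9, K=0.025, kd=0.2, kf0=0.3, h=0.0, W=W, n_cells=12)
    r = solve_pattern(params, spacing=2)
    asym = notch_asymmetry(r.state)
    print(f"W={W:>4}: spacing {r.spacing_observed} ({r.stable}); "
          f"D period = {np.round(r.state.D[:3], 4)}; "
          f"max |N_left - N_right| = {asym.max():.3f}")

# The stable two-cell pattern exists at every finite diffusion rate
# tried; per-cell Notch asymmetry is largest at W = 0 (decoupled sides)
# and shrinks as diffusion mixes the two pools.
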