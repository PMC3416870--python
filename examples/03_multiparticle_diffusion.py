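"""Multiparticle lattice diffusion: hop interval and mean-squared displacement.

All particles hop to a random neighbor every tau = lambda^2/(2 d D); the
resulting mean-squared displacement grows as 2 d D t, which is what defines
a diffusivity D on the lattice.
"""

import numpy as np

from mesord import GridState, diffuse_step, diffusion_timestep
from mesord._kernels import seed_rng

lam, D, d = 1.0, 0.25, 2
tau = diffusion_timestep(lam, D, d)
print(f"hop interval tau = lambda^2/(2 d D) = {tau}")

n = 201
counts = np.zeros((1, n, n), dtype=np.int64)
counts[0, n // 2, n // 2] = 20000          # 2e4 walkers at the center
state = GridState(0.0, counts)
seed_rng(123)
steps = 400
for _ in range(steps):
    diffuse_step(state, 0)

x = np.arange(n) - n // 2
X, Y = np.meshgrid(x, x)
msd = (state.counts[0] * (X ** 2 + Y ** 2)).sum() / state.counts[0].sum()
t = steps * tau
print(f"after {steps} hops (t = {t}): MSD = {msd:.1f}, "
      f"2 d D t = {2 * d * D * t:.1f}")
print(f"total walkers conserved: {state.counts.sum()} of 20000")
print("-> MSD tracks 2dDt and reflecting walls lose no particles.")
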