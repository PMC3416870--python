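"""Fractional stoichiometry via helper reactions in the Oregonator.

The catalyst reset Z -> f Y with f = 3/2 cannot fire in integer particle
numbers; two fast helper reactions realize it exactly on average.  This
script integrates the 5-species helper kinetics and the direct fractional
3-variable kinetics and shows they agree over an oscillation.
"""

import numpy as np
from scipy.integrate import solve_ivp

from mesord.models.oregonator import (default_params, fractional_mean_field,
                                      oregonator_network, rest_state)
from mesord.pde import make_rhs_split

p = default_params()
net = oregonator_network(p)
split5 = make_rhs_split(net)
mf = fractional_mean_field(p)


def rhs5(t, y):
    q, loss = split5(y)
    return q - loss


def rhs3(t, y):
    x, yy, z = y
    return [p.c1 * yy - p.c2 * x * yy + p.c3 * x - 2 * p.c4 * x * x,
            -p.c1 * yy - p.c2 * x * yy + p.f * p.c5 * z,
            p.c3 * x - p.c5 * z]


x0, y0, z0 = rest_state(p)
start3 = [0.5 * p.x_scale, y0, z0]            # super-threshold kick
start5 = start3 + [0.0, 0.0]
T = 80.0
ts = np.linspace(0, T, 400)
s5 = solve_ivp(rhs5, [0, T], start5, method="LSODA", t_eval=ts,
               rtol=1e-9, atol=1e-12)
s3 = solve_ivp(rhs3, [0, T], start3, method="LSODA", t_eval=ts,
               rtol=1e-9, atol=1e-12)

scale = np.abs(s3.y).max(axis=1)
err = np.max(np.abs(s5.y[:3] - s3.y) / scale[:, None])
print(f"max relative deviation helper vs fractional over t<={T}: {err:.2e}")
print(f"helper pool peak (S1 + S2): {(s5.y[3] + s5.y[4]).max():.2e} "
      f"vs Z peak {s5.y[2].max():.2f}")
print("-> with helper rates 1000x dominant the helper pool is negligible "
      "and the fractional chemistry is reproduced to a fraction of a "
      "percent.")
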