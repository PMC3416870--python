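"""Phase-plane analysis: nullclines, fixed points, linear stability.

Each model is reduced to two slow variables (diffusion off):

* Gray-Scott — (u, v), the full point kinetics;
* Oregonator — (X, Z), with the fast inhibitor Y eliminated at its
  quasi-steady state y = f c₅ z/(c₁ + c₂ x);
* calcium — (c, h), Ca²⁺ concentration and open-channel fraction at fixed
  IP₃.

Nullclines are traced as zero-level contours of each rhs component on a
grid; fixed points are sign-change candidates refined by a Newton root
finder to residual < 1e-10 and classified by the eigenvalues of the
numerical Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy import optimize

__all__ = ["FixedPoint", "PhasePlane", "nullclines"]


@dataclass
class FixedPoint:
    point: Tuple[float, float]
    eigenvalues: np.ndarray
    stable: bool

    @property
    def x(self) -> float:
        return self.point[0]

    @property
    def y(self) -> float:
        return self.point[1]


@dataclass
class PhasePlane:
    rhs: Callable
    x_grid: np.ndarray
    y_grid: np.ndarray
    #: zero-level curves of each rhs component, as lists of (N, 2) arrays
    nullclines: Tuple[list, list]
    fixed_points: List[FixedPoint]


def _reduced_rhs(model_kind: str, params) -> Tuple[Callable, tuple, tuple]:
    if model_kind == "gray_scott":
        p = params

        def rhs(w):
            u, v = w
            auto = p.k1 * u * v * v
            return np.array([p.k3 - p.k4 * u - auto, auto - p.k2 * v])

        u_hi = 1.5 * p.u_background
        return rhs, (0.0, u_hi), (0.0, 1.5 * p.k3 / p.k2 * 2)
    if model_kind == "oregonator":
        p = params

        def rhs(w):
            x, z = w
            y = p.f * p.c5 * z / (p.c1 + p.c2 * x)
            return np.array([
                p.c1 * y - p.c2 * x * y + p.c3 * x - 2 * p.c4 * x * x,
                p.c3 * x - p.c5 * z,
            ])

        return rhs, (1e-6 * p.x_scale, 1.2 * p.x_scale), \
            (1e-6 * p.z_scale, 1.5 * p.z_scale)
    if model_kind == "calcium":
        p = params
        mu = p.mu

        def rhs(w):
            c, h = w
            act = p.b + (1 - p.b) * c / (p.k_act + c)
            hinf = p.k_inhib ** 2 / (p.k_inhib ** 2 + c * c)
            return np.array([
                p.beta + p.k_flux * mu * act * h - p.gamma * c
                / (p.k_gamma + c),
                (hinf - h) / p.tau_h,
            ])

        return rhs, (0.0, 4.0), (0.0, 1.0)
    raise ValueError(f"unknown model kind {model_kind!r}")


def _trace_contours(F: np.ndarray, xg: np.ndarray, yg: np.ndarray) -> list:
    """Zero-level segments of F on the grid via linear interpolation on
    grid edges (enough for plotting and for locating intersections)."""
    pts = []
    sx = np.sign(F)
    # horizontal edges
    cross = sx[:, :-1] * sx[:, 1:] < 0
    iy, ix = np.nonzero(cross)
    f0, f1 = F[iy, ix], F[iy, ix + 1]
    t = f0 / (f0 - f1)
    pts.append(np.column_stack([xg[ix] + t * (xg[ix + 1] - xg[ix]), yg[iy]]))
    # vertical edges
    cross = sx[:-1, :] * sx[1:, :] < 0
    iy, ix = np.nonzero(cross)
    f0, f1 = F[iy, ix], F[iy + 1, ix]
    t = f0 / (f0 - f1)
    pts.append(np.column_stack([xg[ix], yg[iy] + t * (yg[iy + 1] - yg[iy])]))
    return [np.concatenate(pts)] if pts else []


def nullclines(model_kind: str, params, n_grid: int = 400,
               x_window: Optional[tuple] = None,
               y_window: Optional[tuple] = None) -> PhasePlane:
    """Nullclines and classified fixed points of a model's reduced kinetics."""
    rhs, xw, yw = _reduced_rhs(model_kind, params)
    if x_window is not None:
        xw = x_window
    if y_window is not None:
        yw = y_window
    xg = np.linspace(xw[0], xw[1], n_grid)
    yg = np.linspace(yw[0], yw[1], n_grid)
    F0 = np.empty((n_grid, n_grid))
    F1 = np.empty((n_grid, n_grid))
    for j, y in enumerate(yg):
        W = np.vstack([xg, np.full(n_grid, y)])
        vals = rhs(W)
        F0[j], F1[j] = vals[0], vals[1]
    curves = (_trace_contours(F0, xg, yg), _trace_contours(F1, xg, yg))

    # fixed-point candidates: cells where both components change sign nearby
    cand = []
    s0, s1 = np.sign(F0), np.sign(F1)

    def mixed(s, j, i):
        blk = s[j:j + 2, i:i + 2]
        return blk.min() < 0 <= blk.max() or 0 in blk

    for j in range(n_grid - 1):
        rows0 = s0[j:j + 2]
        rows1 = s1[j:j + 2]
        has0 = (rows0[:, :-1] * rows0[:, 1:] <= 0) \
            | (rows0[0, :-1] * rows0[1, :-1] <= 0)
        has1 = (rows1[:, :-1] * rows1[:, 1:] <= 0) \
            | (rows1[0, :-1] * rows1[1, :-1] <= 0)
        both = np.nonzero(has0.any(axis=0) & has1.any(axis=0))[0]
        for i in both:
            cand.append((0.5 * (xg[i] + xg[i + 1]),
                         0.5 * (yg[j] + yg[j + 1])))

    fps: List[FixedPoint] = []
    for c in cand:
        sol = optimize.root(rhs, c, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        pt = sol.x
        if not (xw[0] - 1e-9 <= pt[0] <= xw[1] + 1e-9
                and yw[0] - 1e-9 <= pt[1] <= yw[1] + 1e-9):
            continue
        if np.max(np.abs(rhs(pt))) > 1e-10:
            continue
        if any(np.hypot(pt[0] - f.x, pt[1] - f.y)
               < 1e-6 * (1 + abs(pt[0]) + abs(pt[1])) for f in fps):
            continue
        J = np.empty((2, 2))
        f0 = rhs(pt)
        for k in range(2):
            d = 1e-7 * (1 + abs(pt[k]))
            q = pt.copy()
            q[k] += d
            J[:, k] = (rhs(q) - f0) / d
        ev = np.linalg.eigvals(J)
        fps.append(FixedPoint(point=(float(pt[0]), float(pt[1])),
                              eigenvalues=ev,
                              stable=bool(np.all(ev.real < 0))))
    fps.sort(key=lambda f: f.x)
    if not fps:
        warnings.warn("no fixed points found in the search window",
                      stacklevel=2)
    return PhasePlane(rhs=rhs, x_grid=xg, y_grid=yg, nullclines=curves,
                      fixed_points=fps)
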