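"""Recurrent firing-rate model of a rate-code integrator.

A single self-exciting population with a logistic gain::

    tau_m dF/dt = -F + g(F),   g(F) = F_max / (1 + exp(-beta (r F + E - theta)))

where ``r`` scales the recurrent feedback and ``E`` is the external input.
The module finds the fixed points ``g(F*) = F*``, classifies their
stability (stable iff ``g'(F*) < 1``), scans one parameter for a
bifurcation diagram, and integrates trajectories.  Because the gain is a
sigmoid crossed with the identity line, there are at most three fixed
points and at most two of them stable — the bistability that makes a
rate-code integrator lose any graded (intermediate) activity level when
inputs change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .params import InvalidArgumentError


@dataclass(frozen=True)
class RateModelParams:
    F_max: float = 20.0
    beta: float = 1.0
    theta: float = 0.5
    r: float = 1.0
    E: float = 0.0
    tau_m: float = 20.0  # ms; sets the time scale only, not the fixed points

    def __post_init__(self) -> None:
        if self.F_max <= 0 or self.beta <= 0 or self.tau_m <= 0:
            raise InvalidArgumentError("F_max, beta and tau_m must be positive")


@dataclass(frozen=True)
class FixedPoint:
    F_star: float
    stable: bool

    @property
    def stability(self) -> str:
        return "stable" if self.stable else "unstable"


def gain(F, p: RateModelParams):
    """Logistic transfer function g(F)."""
    return p.F_max / (1.0 + np.exp(-p.beta * (p.r * F + p.E - p.theta)))


def gain_slope(F, p: RateModelParams):
    """dg/dF = beta r g (1 - g/F_max)."""
    g = gain(F, p)
    return p.beta * p.r * g * (1.0 - g / p.F_max)


def rate_rhs(F, p: RateModelParams):
    """dF/dt of the rate equation, per ms."""
    return (-F + gain(F, p)) / p.tau_m


def find_fixed_points(
    p: RateModelParams,
    F_range: tuple[float, float] | None = None,
    tol: float = 1e-8,
    n_grid: int = 4001,
) -> list[FixedPoint]:
    """All roots of ``g(F) - F`` on ``F_range``, classified by ``g'(F*)``.

    Roots are bracketed by sign changes on a fine grid and refined by
    bisection to ``|dF| < tol``.  The default range pads ``[0, F_max]`` by
    5% on each side so boundary roots are always bracketed.
    """
    if tol <= 0:
        raise InvalidArgumentError("tol must be positive")
    if F_range is None:
        F_range = (-0.05 * p.F_max, 1.05 * p.F_max)
    lo, hi = F_range
    grid = np.linspace(lo, hi, n_grid)
    h = gain(grid, p) - grid
    roots: list[float] = []
    zero_hits = np.nonzero(h == 0.0)[0]
    roots.extend(grid[zero_hits].tolist())
    sign_change = np.nonzero(np.sign(h[:-1]) * np.sign(h[1:]) < 0)[0]
    for i in sign_change:
        roots.append(brentq(lambda F: gain(F, p) - F, grid[i], grid[i + 1], xtol=tol))
    roots = sorted(roots)
    return [FixedPoint(F_star=f, stable=bool(gain_slope(f, p) < 1.0)) for f in roots]


def bifurcation_scan(
    p: RateModelParams,
    scan_parameter: str,
    values,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Fixed-point branches along one parameter (``"r"`` or ``"E"``).

    Returns a tidy table (parameter value, F_star, stability) plus a
    ``saddle_node`` flag on the first value after each change in root
    count, marking where branches are created or destroyed.
    """
    if scan_parameter not in ("r", "E"):
        raise InvalidArgumentError(f"scan parameter must be 'r' or 'E', got {scan_parameter!r}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidArgumentError("scan values must be nonempty")
    if np.any(np.diff(values) < 0):
        raise InvalidArgumentError("scan values must be sorted")
    rows = []
    prev_count = None
    for v in values:
        pv = replace(p, **{scan_parameter: float(v)})
        fps = find_fixed_points(pv, tol=tol)
        event = prev_count is not None and len(fps) != prev_count
        prev_count = len(fps)
        for fp in fps:
            rows.append(
                {
                    scan_parameter: float(v),
                    "F_star": fp.F_star,
                    "stability": fp.stability,
                    "saddle_node": bool(event),
                }
            )
    return pd.DataFrame(rows)


def max_stable_count(branches: pd.DataFrame, scan_parameter: str) -> int:
    """Largest number of simultaneously stable fixed points along a scan."""
    stable = branches[branches["stability"] == "stable"]
    if stable.empty:
        return 0
    return int(stable.groupby(scan_parameter).size().max())


def simulate_rate(
    p: RateModelParams,
    F0: float,
    duration: float,
    dt: float = 0.5,
    E_schedule: list[tuple[float, float]] | None = None,
):
    """Integrate the rate equation with classic fixed-step RK4.

    ``E_schedule`` optionally lists ``(time_ms, E)`` switch points (sorted);
    the external input is piecewise constant between them, which is how a
    temporal gap in the sensory evidence is modeled.
    Returns ``(t, F)`` arrays.
    """
    if dt >= p.tau_m / 10:
        raise InvalidArgumentError("dt must be < tau_m/10 for accurate integration")
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    F = np.empty(n + 1)
    F[0] = F0
    sched = sorted(E_schedule) if E_schedule else []
    si = 0
    pv = p
    for k in range(n):
        while si < len(sched) and sched[si][0] <= t[k]:
            pv = replace(p, E=sched[si][1])
            si += 1
        f = F[k]
        k1 = rate_rhs(f, pv)
        k2 = rate_rhs(f + 0.5 * dt * k1, pv)
        k3 = rate_rhs(f + 0.5 * dt * k2, pv)
        k4 = rate_rhs(f + dt * k3, pv)
        F[k + 1] = f + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return t, F


def export_branches(branches: pd.DataFrame, path) -> None:
    """Write a branch table as headered TSV for plotting."""
    branches.to_csv(path, sep="\t", index=False)
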