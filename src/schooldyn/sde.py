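"""Phenomenological transcritical model of the group polarization.

Near the milling-to-schooling transition the polarization P is modelled
by the scalar Ito equation

    dP = r P (1 - P) dt + sigma dW,

the normal form of a transcritical bifurcation driven by additive noise.
The drift derives from the single-well effective potential

    U(P) = -r (P^2/2 - P^3/3),

whose extrema sit at P = 0 and P = 1 for every r: the two equilibria
exchange stability at r = 0 (P = 0, "milling", is stable for r < 0;
P = 1, "schooling", for r > 0). The control parameter r is a proxy for
the distance z_l - z_l* of the alignment-zone width from the transition.
sigma is the *collective* noise intensity, not the individual-level one.

Escape from the marginally stable milling state for small r > 0 follows
the Kramers law

    kappa = <T_milling>^-1 = A sqrt(|U''(0) U''(1)|) exp(-2 dU / sigma^2)
          = A r exp(-r / (3 sigma^2)),

with barrier dU = U(1) - U(0) = r/6 and curvatures U'' = -+ r at P = 0, 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from numpy.typing import NDArray

__all__ = [
    "SDEParams",
    "SDEPath",
    "effective_potential",
    "drift",
    "sde_simulate",
    "deterministic_limit",
    "kramers_rate",
    "sde_bifurcation_cloud",
    "sde_hysteresis",
    "first_passage_time",
]

BoundaryMode = Literal["reflect", "clip"]


@dataclass(frozen=True)
class SDEParams:
    """Parameters of one polarization-SDE integration."""

    r: float = 0.0
    sigma: float = 0.01
    dt: float = 1e-3
    total_time: float = 10.0
    P0: float = 0.5
    boundary_mode: BoundaryMode = "reflect"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.P0 <= 1.0:
            raise ValueError("P0 must lie in [0, 1]")
        if self.total_time <= 0:
            raise ValueError("total_time must be > 0")
        if self.boundary_mode not in ("reflect", "clip"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")

    def with_updates(self, **kwargs) -> "SDEParams":
        return replace(self, **kwargs)


@dataclass
class SDEPath:
    """One sample path of the polarization SDE."""

    t: NDArray[np.float64]
    P: NDArray[np.float64]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "P": self.P})


def effective_potential(P, r):
    """Effective potential, curvature and barrier of the transcritical drift.

    Returns ``(U, U'', dU)`` where U(P) = -r (P^2/2 - P^3/3),
    U''(P) = -r (1 - 2 P), and dU = U(1) - U(0) = r/6 is the barrier
    between the two equilibria.
    """
    P = np.asarray(P, dtype=float)
    U = -r * (P**2 / 2.0 - P**3 / 3.0)
    Upp = -r * (1.0 - 2.0 * P)
    dU = r / 6.0
    return U, Upp, dU


def drift(P, r):
    """Drift -U'(P) = r P (1 - P)."""
    P = np.asarray(P, dtype=float)
    return r * P * (1.0 - P)


def _apply_boundary(P: NDArray[np.float64], mode: BoundaryMode) -> NDArray[np.float64]:
    if mode == "clip":
        return np.clip(P, 0.0, 1.0)
    # reflect at 0 and 1; iterate for (rare) overshoots past both walls
    P = np.asarray(P, dtype=float)
    for _ in range(100):
        out = np.abs(P)
        out = 1.0 - np.abs(1.0 - out)
        if np.all((out >= 0.0) & (out <= 1.0)):
            return out
        P = out
    raise FloatingPointError("reflection failed to converge; dt too large?")


def _euler_maruyama(
    x0: NDArray[np.float64],
    r: float,
    n_steps: int,
    dt: float,
    sigma: float,
    rng: np.random.Generator,
    boundary_mode: BoundaryMode,
    record: bool = False,
) -> NDArray[np.float64]:
    """Advance an ensemble of SDE states n_steps; vectorized over paths.

    Returns the final states, or the full (n_steps+1, n_paths) array when
    ``record`` is set.
    """
    x = np.array(x0, dtype=float, copy=True)
    out = np.empty((n_steps + 1, x.size)) if record else None
    if record:
        out[0] = x
    sq = sigma * np.sqrt(dt)
    for k in range(n_steps):
        x += r * x * (1.0 - x) * dt
        if sigma > 0:
            x += sq * rng.standard_normal(x.size)
        x = _apply_boundary(x, boundary_mode)
        if record:
            out[k + 1] = x
    return out if record else x


def sde_simulate(params: SDEParams, rng: np.random.Generator | None = None,
                 P0: float | None = None) -> SDEPath:
    """Integrate the polarization SDE by Euler-Maruyama.

    P_{k+1} = P_k + r P_k (1 - P_k) dt + sigma sqrt(dt) xi_k, with
    boundaries at 0 and 1 handled per ``params.boundary_mode`` (default
    reflection, which keeps P a valid polarization exactly).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(round(params.total_time / params.dt))
    t = params.dt * np.arange(n + 1)
    start = params.P0 if P0 is None else P0
    paths = _euler_maruyama(
        np.asarray([start]), params.r, n, params.dt, params.sigma, rng,
        params.boundary_mode, record=True,
    )
    return SDEPath(t=t, P=paths[:, 0])


def deterministic_limit(r: float, P0: float, total_time: float = 50.0,
                        dt: float = 1e-3) -> float:
    """Long-time limit of the noise-free dynamics dP/dt = r P (1 - P).

    From an interior start 0 < P0 < 1 the flow converges to 1 for r > 0
    and to 0 for r < 0; for r = 0 the drift vanishes and P stays at P0.
    Computed by explicit Euler integration to ``total_time``.
    """
    if not 0.0 <= P0 <= 1.0:
        raise ValueError("P0 must lie in [0, 1]")
    path = sde_simulate(SDEParams(r=r, sigma=0.0, dt=dt, total_time=total_time, P0=P0))
    return float(path.P[-1])


def kramers_rate(r, sigma: float, A: float):
    """Kramers escape rate kappa = A r exp(-r / (3 sigma^2)).

    Valid for r > 0 (a marginally stable well at P = 0 with barrier r/6),
    sigma > 0 and prefactor A > 0. Maximal at r = 3 sigma^2.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("kramers_rate requires r > 0")
    if sigma <= 0 or A <= 0:
        raise ValueError("kramers_rate requires sigma > 0 and A > 0")
    return A * r * np.exp(-r / (3.0 * sigma**2))


def first_passage_time(params: SDEParams, start: float = 0.05, target: float = 0.95,
                       rng: np.random.Generator | None = None,
                       n_paths: int = 1) -> NDArray[np.float64]:
    """First-passage times from ``start`` to ``target`` for an ensemble.

    Integrates ``n_paths`` independent paths simultaneously; each entry
    is the first time its path reaches ``target``, or NaN if it does not
    arrive within params.total_time (censored)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(round(params.total_time / params.dt))
    sq = params.sigma * np.sqrt(params.dt)
    x = np.full(n_paths, float(start))
    fpt = np.full(n_paths, np.nan)
    alive = np.ones(n_paths, dtype=bool)
    for k in range(n):
        x[alive] += (
            params.r * x[alive] * (1.0 - x[alive]) * params.dt
            + sq * rng.standard_normal(int(alive.sum()))
        )
        x[alive] = _apply_boundary(x[alive], params.boundary_mode)
        arrived = alive & (x >= target)
        fpt[arrived] = (k + 1) * params.dt
        alive &= ~arrived
        if not alive.any():
            break
    return fpt


def sde_bifurcation_cloud(
    r_grid,
    n_paths: int = 50,
    template: SDEParams = SDEParams(),
    base_seed: int = 0,
    P0_mode: Literal["uniform", "fixed"] = "uniform",
) -> pd.DataFrame:
    """Terminal polarization of ``n_paths`` finite-time runs per r value.

    For each r on the grid, integrate ``n_paths`` independent paths to
    template.total_time (default 10 time units). Near r = 0 the flat
    potential lets initial conditions leak to either equilibrium, the
    noisy-transcritical signature. Initial conditions are uniform on
    [0, 1] unless ``P0_mode="fixed"`` (then template.P0).

    Returns a long-format frame (r, path, P0, P_final).
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    n_steps = int(round(template.total_time / template.dt))
    frames = []
    for i, r in enumerate(np.asarray(r_grid, dtype=float)):
        rng = np.random.default_rng(base_seed + i)
        if P0_mode == "uniform":
            p0 = rng.uniform(size=n_paths)
        else:
            p0 = np.full(n_paths, template.P0)
        final = _euler_maruyama(p0, float(r), n_steps, template.dt, template.sigma,
                                rng, template.boundary_mode)
        frames.append(pd.DataFrame(
            {"r": float(r), "path": np.arange(n_paths), "P0": p0, "P_final": final}
        ))
    return pd.concat(frames, ignore_index=True)


def sde_hysteresis(
    r_grid,
    hold_time: float = 10.0,
    n_paths: int = 50,
    sigma: float = 0.01,
    dt: float = 1e-3,
    base_seed: int = 0,
    boundary_mode: BoundaryMode = "reflect",
    P0: float = 0.0,
) -> pd.DataFrame:
    """Quasi-static hysteresis ramp of the bifurcation parameter r.

    r is stepped up the sorted grid and back down, holding each value for
    ``hold_time`` while the state is carried from hold to hold (starting
    from P0 at the lowest r). The mean P over the final 10% of each hold
    is recorded. ``n_paths`` independent chains are averaged.

    Returns a frame (direction, r, P_mean, P_std) ordered as traversed.
    """
    grid = np.sort(np.asarray(r_grid, dtype=float))
    n_hold = int(round(hold_time / dt))
    tail = max(1, n_hold // 10)
    rng = np.random.default_rng(base_seed)
    x = np.full(n_paths, float(P0))
    rows = []
    for direction, rs in (("forward", grid), ("backward", grid[::-1])):
        for r in rs:
            paths = _euler_maruyama(x, float(r), n_hold, dt, sigma, rng,
                                    boundary_mode, record=True)
            hold_means = paths[-tail:].mean(axis=0)  # per-chain trailing mean
            rows.append({
                "direction": direction, "r": float(r),
                "P_mean": float(hold_means.mean()), "P_std": float(hold_means.std()),
            })
            x = paths[-1]
    return pd.DataFrame(rows)


def hysteresis_loop_area(df: pd.DataFrame) -> float:
    """Trapezoidal area enclosed between forward and backward branches."""
    fwd = df[df.direction == "forward"].sort_values("r")
    bwd = df[df.direction == "backward"].sort_values("r")
    if not np.allclose(fwd.r.to_numpy(), bwd.r.to_numpy()):
        raise ValueError("forward and backward branches must share the r grid")
    gap = bwd.P_mean.to_numpy() - fwd.P_mean.to_numpy()
    return float(np.trapezoid(gap, fwd.r.to_numpy()))
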