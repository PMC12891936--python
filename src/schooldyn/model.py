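"""3D zonal self-propelled-particle model of fish schooling.

Each of N identical individuals swims at constant speed U and, at every
time step, reorients according to prioritized "three-A" rules evaluated
over concentric spherical shells around the focal fish:

* avoidance  — neighbours at distance d <= z_r: turn away (top priority);
* alignment  — z_r < d <= z_r + z_l: match the mean neighbour heading;
* attraction — z_r + z_l < d <= z_r + z_l + z_a: turn toward neighbours.

Alignment and attraction are restricted to a forward vision cone of full
angle ``alpha``; the posterior blind cone of angle 360 - alpha hides
neighbours. Repulsion is not censored by vision by default (collision
avoidance uses near-field cues), but ``blind_cone_repulsion`` extends the
censoring to it. After the deterministic desired heading is formed,
isotropic rotational noise is added (a Gaussian per Cartesian component
followed by renormalization), and the realized turn is capped at a
maximum turning angle.

All lengths are in body lengths (BL) and times in the model time unit
(nominally seconds, with U in BL per time unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "SimParams",
    "SchoolState",
    "NeighborSets",
    "Trajectory",
    "init_random_school",
    "classify_neighbors",
    "desired_heading",
    "apply_rotational_noise",
    "constrain_turn",
    "step_school",
    "simulate",
]

_EPS = 1e-12

TurnLimitMode = Literal["per_step", "rate"]


@dataclass(frozen=True)
class SimParams:
    """Model and integration parameters.

    Defaults follow the standard parameterization of the model for a
    school of 100 fish: unit avoidance radius, 270-degree field of
    vision, 40-degree maximum turn, swim speed 3 BL per time unit and
    individual noise sigma = 0.01.

    ``z_l`` and ``z_a`` are shell *widths*: the alignment shell spans
    (z_r, z_r + z_l] and the attraction shell (z_r + z_l, z_r + z_l + z_a].

    ``turn_limit_mode`` selects how the printed maximum turning angle is
    applied: ``"per_step"`` caps each discrete heading update at
    ``theta_max`` regardless of dt, while ``"rate"`` (default) treats it
    as an angular speed and caps a step at ``theta_max * dt``, the
    convention of the original zonal model.

    ``term_weighting`` selects how the alignment and attraction responses
    are combined when the avoidance zone is empty. ``"count"`` (default)
    adds the raw sums of unit vectors, so each response is implicitly
    weighted by how many neighbours drive it — the original formulation,
    under which a crowded attraction shell can outvote a sparse alignment
    shell and sustain milling. ``"normalized"`` first normalizes each
    response to a unit direction so both get equal weight regardless of
    neighbour counts; alignment is then effectively stronger and the
    milling-to-schooling transition shifts to much smaller z_l.

    ``align_self`` includes the focal fish's own current heading in the
    alignment sum (directional persistence, default True).
    """

    n: int = 100
    z_r: float = 1.0
    z_l: float = 4.0
    z_a: float = 10.0
    alpha: float = 270.0
    theta_max: float = 40.0
    speed: float = 3.0
    sigma: float = 0.01
    dt: float = 0.25
    turn_limit_mode: TurnLimitMode = "rate"
    total_time: float = 500.0
    seed: int = 0
    blind_cone_repulsion: bool = False
    term_weighting: Literal["count", "normalized"] = "count"
    align_self: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.z_r <= 0:
            raise ValueError(f"z_r must be > 0, got {self.z_r}")
        if self.z_l < 0 or self.z_a < 0:
            raise ValueError("zone widths z_l, z_a must be >= 0")
        if not 0 < self.alpha <= 360:
            raise ValueError(f"alpha must be in (0, 360], got {self.alpha}")
        if not 0 < self.theta_max <= 180:
            raise ValueError(f"theta_max must be in (0, 180], got {self.theta_max}")
        if self.speed <= 0:
            raise ValueError(f"speed must be > 0, got {self.speed}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.total_time <= 0:
            raise ValueError(f"total_time must be > 0, got {self.total_time}")
        if self.turn_limit_mode not in ("per_step", "rate"):
            raise ValueError(f"unknown turn_limit_mode {self.turn_limit_mode!r}")
        if self.term_weighting not in ("count", "normalized"):
            raise ValueError(f"unknown term_weighting {self.term_weighting!r}")

    # -- derived geometry ------------------------------------------------
    @property
    def align_outer(self) -> float:
        """Outer radius of the alignment shell (BL)."""
        return self.z_r + self.z_l

    @property
    def attract_outer(self) -> float:
        """Outer radius of the attraction shell = interaction range (BL)."""
        return self.z_r + self.z_l + self.z_a

    @property
    def cos_half_alpha(self) -> float:
        return float(np.cos(np.radians(self.alpha) / 2.0))

    @property
    def theta_cap(self) -> float:
        """Maximum turn per integration step, radians."""
        cap = np.radians(self.theta_max)
        if self.turn_limit_mode == "rate":
            cap *= self.dt
        return float(cap)

    def with_updates(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass
class SchoolState:
    """Positions and unit headings of the school at one instant."""

    t: float
    positions: NDArray[np.float64]  # (N, 3), body lengths
    headings: NDArray[np.float64]  # (N, 3), unit vectors

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float)
        if self.positions.shape != self.headings.shape or self.positions.ndim != 2:
            raise ValueError("positions and headings must both be (N, 3)")
        if self.positions.shape[1] != 3:
            raise ValueError("states are three-dimensional")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def validate(self, tol: float = 1e-9) -> None:
        norms = np.linalg.norm(self.headings, axis=1)
        if not np.allclose(norms, 1.0, atol=tol):
            raise ValueError("headings must be unit vectors")

    def copy(self) -> "SchoolState":
        return SchoolState(self.t, self.positions.copy(), self.headings.copy())


@dataclass(frozen=True)
class NeighborSets:
    """Zone membership of all neighbours of one focal individual."""

    rep_ids: NDArray[np.intp]
    align_ids: NDArray[np.intp]
    attract_ids: NDArray[np.intp]


def _unit_rows(v: NDArray[np.float64]) -> tuple[NDArray[np.float64], NDArray[np.bool_]]:
    """Row-normalize, zeroing rows with vanishing norm; return (unit, ok)."""
    nrm = np.linalg.norm(v, axis=-1)
    ok = nrm > _EPS
    out = np.zeros_like(v)
    out[ok] = v[ok] / nrm[ok, None]
    return out, ok


def init_random_school(params: SimParams, rng_seed: int | np.random.Generator | None = None) -> SchoolState:
    """Random initial school: positions uniform in the unit cube [0,1]^3,
    headings uniform on the unit sphere, t = 0."""
    rng = np.random.default_rng(params.seed if rng_seed is None else rng_seed) \
        if not isinstance(rng_seed, np.random.Generator) else rng_seed
    pos = rng.uniform(0.0, 1.0, size=(params.n, 3))
    hdg = rng.standard_normal(size=(params.n, 3))
    nrm = np.linalg.norm(hdg, axis=1)
    # a Gaussian triple at exactly the origin has probability zero; redraw defensively
    while np.any(nrm < _EPS):  # pragma: no cover
        bad = nrm < _EPS
        hdg[bad] = rng.standard_normal(size=(int(bad.sum()), 3))
        nrm = np.linalg.norm(hdg, axis=1)
    return SchoolState(0.0, pos, hdg / nrm[:, None])


def _zone_masks(
    state: SchoolState, params: SimParams
) -> tuple[NDArray[np.bool_], NDArray[np.bool_], NDArray[np.bool_], NDArray[np.float64]]:
    """Dense pairwise zone membership.

    Returns boolean (N, N) masks (rep, align, attract) with [i, j] = "j is in
    that zone of focal i", plus the (N, N, 3) unit displacement tensor
    rhat[i, j] pointing from i to j.
    """
    pos, hdg = state.positions, state.headings
    disp = pos[None, :, :] - pos[:, None, :]
    dist = np.linalg.norm(disp, axis=2)
    np.fill_diagonal(dist, np.inf)
    rhat = disp / dist[:, :, None]
    cos_to_j = np.einsum("ijk,ik->ij", rhat, hdg)
    visible = cos_to_j >= params.cos_half_alpha
    rep = dist <= params.z_r
    if params.blind_cone_repulsion:
        rep &= visible
    align = (dist > params.z_r) & (dist <= params.align_outer) & visible
    attract = (dist > params.align_outer) & (dist <= params.attract_outer) & visible
    return rep, align, attract, rhat


def classify_neighbors(state: SchoolState, focal: int, params: SimParams) -> NeighborSets:
    """Zone membership for one focal fish.

    Repulsion is a closed ball d <= z_r around the focal fish; alignment
    and attraction are the subsequent closed-right shells, additionally
    censored by the vision cone of half-angle alpha/2 about the focal
    heading. Empty sets are legal.
    """
    if not 0 <= focal < state.n:
        raise IndexError(f"focal index {focal} out of range for N={state.n}")
    rep, align, attract, _ = _zone_masks(state, params)
    return NeighborSets(
        rep_ids=np.flatnonzero(rep[focal]),
        align_ids=np.flatnonzero(align[focal]),
        attract_ids=np.flatnonzero(attract[focal]),
    )


def _desired_headings_all(state: SchoolState, params: SimParams) -> NDArray[np.float64]:
    """Noise-free desired headings of all N fish from the time-t state."""
    rep, align, attract, rhat = _zone_masks(state, params)
    hdg = state.headings

    rep_sum = np.einsum("ij,ijk->ik", rep, rhat)
    align_sum = align.astype(float) @ hdg
    if params.align_self:
        align_sum = align_sum + hdg
    attract_sum = np.einsum("ij,ijk->ik", attract, rhat)

    rep_u, rep_ok = _unit_rows(rep_sum)
    if params.term_weighting == "count":
        social = align_sum + attract_sum
    else:
        align_u, _ = _unit_rows(align_sum)
        attract_u, _ = _unit_rows(attract_sum)
        social = align_u + attract_u  # absent/degenerate terms are zero rows
    social_u, social_ok = _unit_rows(social)

    any_rep = rep.any(axis=1)
    desired = np.where(social_ok[:, None], social_u, hdg)
    use_rep = any_rep & rep_ok
    desired[use_rep] = -rep_u[use_rep]
    # repulsion with perfectly cancelling neighbours: keep current heading
    desired[any_rep & ~rep_ok] = hdg[any_rep & ~rep_ok]
    return desired


def desired_heading(state: SchoolState, focal: int, params: SimParams) -> NDArray[np.float64]:
    """Deterministic (pre-noise) desired heading of one focal fish.

    Prioritized response: if any neighbour sits in the avoidance zone the
    fish turns opposite the mean direction toward those neighbours;
    otherwise it averages the normalized alignment and attraction
    responses, dropping whichever is absent. With no perceived neighbours
    (or a perfectly cancelling response) the current heading is retained.
    """
    if not 0 <= focal < state.n:
        raise IndexError(f"focal index {focal} out of range for N={state.n}")
    return _desired_headings_all(state, params)[focal].copy()


def apply_rotational_noise(
    heading: NDArray[np.float64], sigma: float, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Perturb a unit heading by isotropic rotational noise.

    An independent N(0, sigma) draw is added to each Cartesian component
    and the vector renormalized — a spherically wrapped Gaussian about the
    input direction. For small sigma the standard deviation of the angle
    between input and output is approximately sigma * sqrt(2/3).
    """
    heading = np.asarray(heading, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return heading.copy()
    out = heading + rng.normal(0.0, sigma, size=heading.shape)
    nrm = np.linalg.norm(out, axis=-1)
    while np.any(nrm < _EPS):  # pragma: no cover - prob. ~0 degenerate draw
        bad = nrm < _EPS
        redraw = heading[bad] + rng.normal(0.0, sigma, size=(int(np.sum(bad)), 3))
        out[bad] = redraw
        nrm = np.linalg.norm(out, axis=-1)
    return out / nrm[..., None]


def _least_aligned_perp(current: NDArray[np.float64]) -> NDArray[np.float64]:
    """Deterministic unit vector perpendicular to each row of ``current``:
    the coordinate axis least aligned with it, projected orthogonal."""
    current = np.atleast_2d(current)
    k = np.argmin(np.abs(current), axis=1)
    e = np.zeros_like(current)
    e[np.arange(len(current)), k] = 1.0
    perp = e - np.einsum("ij,ij->i", e, current)[:, None] * current
    unit, _ = _unit_rows(perp)
    return unit


def _constrain_turn_all(
    current: NDArray[np.float64], desired: NDArray[np.float64], theta_cap: float
) -> NDArray[np.float64]:
    cosang = np.clip(np.einsum("ij,ij->i", current, desired), -1.0, 1.0)
    angle = np.arccos(cosang)
    out = desired.copy()
    over = angle > theta_cap + 1e-12
    if not np.any(over):
        return out
    perp = desired[over] - cosang[over, None] * current[over]
    perp_u, ok = _unit_rows(perp)
    if not np.all(ok):
        # antiparallel target: turn plane is ambiguous, use a fixed perpendicular
        perp_u[~ok] = _least_aligned_perp(current[over][~ok])
    out[over] = np.cos(theta_cap) * current[over] + np.sin(theta_cap) * perp_u
    return out


def constrain_turn(
    current: NDArray[np.float64], desired: NDArray[np.float64], params: SimParams
) -> NDArray[np.float64]:
    """Cap the turn from ``current`` toward ``desired`` at params.theta_cap.

    If the angle between the two unit vectors exceeds the cap, the result
    is ``current`` rotated by exactly the cap toward ``desired`` within
    their common plane. An antiparallel target leaves the turn plane
    undefined; a fixed perpendicular (least-aligned coordinate axis,
    projected) is used so runs are reproducible.
    """
    current = np.asarray(current, dtype=float)
    desired = np.asarray(desired, dtype=float)
    single = current.ndim == 1
    res = _constrain_turn_all(
        np.atleast_2d(current), np.atleast_2d(desired), params.theta_cap
    )
    return res[0] if single else res


def step_school(state: SchoolState, params: SimParams, rng: np.random.Generator) -> SchoolState:
    """Advance the whole school by one time step dt.

    Synchronous update: every desired heading is computed from the state
    at time t; rotational noise is added; the turn from p_i(t) to the
    noisy target is capped; finally positions advance along the *new*
    headings at constant speed U.
    """
    desired = _desired_headings_all(state, params)
    noisy = apply_rotational_noise(desired, params.sigma, rng)
    new_h = _constrain_turn_all(state.headings, noisy, params.theta_cap)
    # renormalize to keep unit norm exact against drift over long runs
    new_h /= np.linalg.norm(new_h, axis=1)[:, None]
    new_pos = state.positions + params.speed * params.dt * new_h
    return SchoolState(state.t + params.dt, new_pos, new_h)


@dataclass
class Trajectory:
    """Result of one simulation run: order-parameter series, the final
    state, and (optionally) thinned full states."""

    series: "OrderSeries"  # noqa: F821 - defined in schooldyn.observables
    final_state: SchoolState
    states: list[SchoolState] | None = None
    params: SimParams | None = None


def simulate(
    params: SimParams,
    initial_state: SchoolState | None = None,
    rng: np.random.Generator | None = None,
    record_states_every: int | None = None,
) -> Trajectory:
    """Run the model for total_time, recording order parameters each step.

    Parameters
    ----------
    params
        Model parameters; ``params.seed`` seeds the run unless ``rng`` is
        given (as in chained quasi-static ramps).
    initial_state
        Start state; defaults to a random school in the unit cube.
    record_states_every
        If set, keep every k-th full state (plus the initial one).
    """
    from .observables import OrderSeries, milling_order, nnd_stats, polarization

    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = init_random_school(params, rng) if initial_state is None else initial_state.copy()

    n_steps = int(round(params.total_time / params.dt))
    t = np.empty(n_steps + 1)
    P = np.empty(n_steps + 1)
    M = np.empty(n_steps + 1)
    nnd_mean = np.empty(n_steps + 1)
    nnd_std = np.empty(n_steps + 1)
    states: list[SchoolState] | None = [] if record_states_every else None

    for k in range(n_steps + 1):
        t[k] = state.t
        P[k] = polarization(state)
        M[k] = milling_order(state)
        if params.n >= 2:
            nnd_mean[k], nnd_std[k] = nnd_stats(state)
        else:
            nnd_mean[k] = nnd_std[k] = np.nan
        if states is not None and k % record_states_every == 0:
            states.append(state.copy())
        if k < n_steps:
            state = step_school(state, params, rng)

    series = OrderSeries(t=t, P=P, M=M, nnd_mean=nnd_mean, nnd_std=nnd_std)
    return Trajectory(series=series, final_state=state, states=states, params=params)
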