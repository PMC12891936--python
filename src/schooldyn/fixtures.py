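"""Deterministic synthetic configurations with known ground truth.

These generators make every downstream stage testable without running
the simulator: a ring mill has milling order exactly 1, an aligned
lattice school has polarization exactly 1, and a two-state order series
has an exactly known milling residence fraction.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray

from .model import SchoolState
from .observables import OrderSeries

__all__ = ["make_ring_mill", "make_aligned_school", "make_two_state_series"]


def _orthonormal_frame(normal: NDArray[np.float64]) -> tuple[NDArray, NDArray, NDArray]:
    n = np.asarray(normal, dtype=float)
    nrm = np.linalg.norm(n)
    if nrm == 0:
        raise ValueError("plane normal must be nonzero")
    n = n / nrm
    # any axis not parallel to n seeds the in-plane basis
    seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2, n


def make_ring_mill(
    n: int,
    radius: float,
    normal: NDArray[np.float64] | tuple[float, float, float] = (0.0, 0.0, 1.0),
    center: NDArray[np.float64] | tuple[float, float, float] = (0.0, 0.0, 0.0),
    sense: int = +1,
) -> SchoolState:
    """N fish equally spaced on a circle, headings tangential with a
    common rotation sense: milling order exactly 1, polarization ~0
    (exactly 0 for n >= 2 by symmetry of the tangent sum)."""
    if n < 3:
        raise ValueError("a ring mill needs at least 3 fish")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if sense not in (+1, -1):
        raise ValueError("sense must be +1 or -1")
    e1, e2, _ = _orthonormal_frame(np.asarray(normal, dtype=float))
    phi = 2 * np.pi * np.arange(n) / n
    c = np.asarray(center, dtype=float)
    pos = c + radius * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    hdg = sense * (-np.sin(phi)[:, None] * e1 + np.cos(phi)[:, None] * e2)
    return SchoolState(0.0, pos, hdg)


def make_aligned_school(
    n: int,
    spacing: float = 2.0,
    heading: NDArray[np.float64] | tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> SchoolState:
    """Cubic-lattice school with identical headings: polarization exactly
    1; pairwise distances >= spacing."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    h = np.asarray(heading, dtype=float)
    nrm = np.linalg.norm(h)
    if nrm == 0:
        raise ValueError("heading must be nonzero")
    h = h / nrm
    side = int(np.ceil(n ** (1.0 / 3.0)))
    idx = np.arange(side**3)[:n]
    pos = spacing * np.stack(
        [idx % side, (idx // side) % side, idx // side**2], axis=1
    ).astype(float)
    return SchoolState(0.0, pos, np.tile(h, (n, 1)))


def make_two_state_series(
    total_time: float,
    switch_time: float,
    dt: float = 0.1,
    milling_MP: tuple[float, float] = (0.9, 0.05),
    schooling_MP: tuple[float, float] = (0.05, 0.95),
) -> OrderSeries:
    """Synthetic order series: milling-valued before ``switch_time``,
    schooling-valued after, so the milling residence fraction is exactly
    switch_time / total_time (up to one sample of discretization)."""
    if not 0 <= switch_time <= total_time:
        raise ValueError("switch_time must lie in [0, total_time]")
    n = int(round(total_time / dt))
    t = dt * np.arange(n)
    milling = t < switch_time
    M = np.where(milling, milling_MP[0], schooling_MP[0])
    P = np.where(milling, milling_MP[1], schooling_MP[1])
    nnd = np.full(n, 1.0)
    return OrderSeries(t=t, P=P, M=M, nnd_mean=nnd, nnd_std=np.zeros(n))
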