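"""Ensemble experiments over the fish-school simulator.

Monte-Carlo protocols that characterize the collective phases and the
milling-to-schooling transition:

* :func:`run_ensemble` — repeated runs from random initial conditions at
  one parameter point, with steady-state summaries and phase labels;
* :func:`phase_diagram` — ensembles over a (z_l, z_a) grid;
* :func:`bifurcation_sweep` — ensembles along z_l with the 50%-schooling
  crossing z_l*;
* :func:`histogram_orders` — steady-state P/M histograms across runs
  (bimodal near the transition);
* :func:`escape_rate_curve` / :func:`fit_kramers` — milling residence
  times beyond z_l* and the Kramers-law fit kappa = A r exp(-r/(3 s^2));
* :func:`hysteresis_ramp` — quasi-static up/down ramps of z_l carrying
  the school state between holds.

All protocols derive per-run seeds as base_seed + run index, so any
result can be regenerated exactly from its manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import SchoolState, SimParams, simulate
from .observables import (
    OrderSeries,
    PhaseThresholds,
    classify_phase,
    residence_fraction,
    steady_state_average,
)

__all__ = [
    "EnsembleResult",
    "BifurcationResult",
    "KramersFit",
    "run_ensemble",
    "phase_diagram",
    "bifurcation_sweep",
    "find_crossing",
    "histogram_orders",
    "escape_rate_curve",
    "milling_escape_curve",
    "fit_kramers",
    "hysteresis_ramp",
]


@dataclass
class EnsembleResult:
    """Steady-state summaries of n_runs independent runs at one point."""

    params: SimParams
    runs: pd.DataFrame  # seed, P, M, NND_mean, NND_std, phase, tau, T_milling
    base_seed: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def percentage(self, phase: str) -> float:
        return 100.0 * float((self.runs["phase"] == phase).mean())

    @property
    def schooling_percentage(self) -> float:
        return self.percentage("schooling")

    @property
    def milling_percentage(self) -> float:
        return self.percentage("milling")

    @property
    def mean_tau(self) -> float:
        return float(self.runs["tau"].mean())

    def summary_row(self) -> dict:
        p = self.params
        return {
            "z_l": p.z_l, "z_a": p.z_a, "sigma": p.sigma,
            "n_runs": self.n_runs,
            "P": float(self.runs["P"].mean()), "M": float(self.runs["M"].mean()),
            "NND_mean": float(self.runs["NND_mean"].mean()),
            "NND_std": float(self.runs["NND_std"].mean()),
            "schooling_pct": self.schooling_percentage,
            "milling_pct": self.milling_percentage,
            "mean_tau": self.mean_tau,
            "label": self.runs["phase"].mode().iat[0],
        }


def run_ensemble(
    params: SimParams,
    n_runs: int,
    base_seed: int = 0,
    window: float = 50.0,
    thresholds: PhaseThresholds = PhaseThresholds(),
) -> EnsembleResult:
    """n_runs independent simulations from random unit-cube initial
    conditions; run k uses seed base_seed + k."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rows = []
    for k in range(n_runs):
        seed = base_seed + k
        traj = simulate(params.with_updates(seed=seed))
        summ = steady_state_average(traj.series, window)
        label = classify_phase(summ, params, thresholds)
        tau, t_mill = residence_fraction(traj.series, thresholds)
        rows.append({
            "seed": seed, "P": summ.P, "M": summ.M,
            "NND_mean": summ.nnd_mean, "NND_std": summ.nnd_std,
            "phase": label.phase, "tau": tau, "T_milling": t_mill,
        })
    return EnsembleResult(params=params, runs=pd.DataFrame(rows), base_seed=base_seed)


def phase_diagram(
    z_l_values: Sequence[float],
    z_a_values: Sequence[float],
    params: SimParams,
    n_runs: int = 10,
    base_seed: int = 0,
    window: float = 50.0,
    thresholds: PhaseThresholds = PhaseThresholds(),
) -> pd.DataFrame:
    """Ensemble summaries over the (z_l, z_a) grid, long format.

    Seeds are blocked per grid point (base_seed + 1000 * point index) so
    points are independent and individually reproducible.
    """
    if len(z_l_values) == 0 or len(z_a_values) == 0:
        raise ValueError("grid must be nonempty")
    rows = []
    for idx, z_a in enumerate(z_a_values):
        for jdx, z_l in enumerate(z_l_values):
            point_seed = base_seed + 1000 * (idx * len(z_l_values) + jdx)
            ens = run_ensemble(
                params.with_updates(z_l=float(z_l), z_a=float(z_a)),
                n_runs, point_seed, window, thresholds,
            )
            rows.append(ens.summary_row())
    return pd.DataFrame(rows)


@dataclass
class BifurcationResult:
    """z_l sweep with the 50%-schooling crossing."""

    table: pd.DataFrame  # one summary row per z_l
    ensembles: list[EnsembleResult] = field(repr=False)
    z_l_star: float | None = None  # first grid value with pct >= 50
    z_l_star_interp: float | None = None  # linear interpolation of the crossing

    @property
    def found(self) -> bool:
        return self.z_l_star is not None


def bifurcation_sweep(
    z_l_values: Sequence[float],
    params: SimParams,
    n_runs: int = 10,
    base_seed: int = 0,
    window: float = 50.0,
    thresholds: PhaseThresholds = PhaseThresholds(),
) -> BifurcationResult:
    """Ensembles along sorted z_l values; locates where the percentage of
    runs converging to schooling first reaches 50%.

    The crossing is reported both as the first grid value at or past 50%
    and linearly interpolated between the bracketing grid points.
    """
    z_l_values = list(map(float, z_l_values))
    if sorted(z_l_values) != z_l_values:
        raise ValueError("z_l values must be sorted ascending")
    ensembles = []
    for j, z_l in enumerate(z_l_values):
        ensembles.append(run_ensemble(
            params.with_updates(z_l=z_l), n_runs, base_seed + 1000 * j,
            window, thresholds,
        ))
    table = pd.DataFrame([e.summary_row() for e in ensembles])
    z_l_star, z_l_star_interp = find_crossing(
        z_l_values, table["schooling_pct"].to_numpy()
    )
    return BifurcationResult(table=table, ensembles=ensembles,
                             z_l_star=z_l_star, z_l_star_interp=z_l_star_interp)


def find_crossing(
    x: Sequence[float], pct: Sequence[float], level: float = 50.0
) -> tuple[float | None, float | None]:
    """First grid value where ``pct`` reaches ``level``, plus the linear
    interpolation between the bracketing grid points.

    Returns (None, None) when the level is never reached.
    """
    x = list(map(float, x))
    pct = np.asarray(pct, dtype=float)
    for j in range(len(x)):
        if pct[j] >= level:
            if j == 0:
                return x[0], x[0]
            x0, x1, y0, y1 = x[j - 1], x[j], pct[j - 1], pct[j]
            return x[j], x0 + (level - y0) * (x1 - x0) / (y1 - y0)
    return None, None


def _bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient; > ~0.555 suggests bimodality."""
    n = len(x)
    if n < 4:
        return float("nan")
    g = stats.skew(x, bias=False)
    k = stats.kurtosis(x, bias=False)  # excess
    return float((g**2 + 1.0) / (k + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def histogram_orders(
    ensemble: EnsembleResult, bins: int | Sequence[float] = 10
) -> dict:
    """Normalized histograms of steady-state P and M across runs, with
    Sarle's bimodality coefficient for each."""
    if ensemble.n_runs < 2:
        raise ValueError("histograms need at least 2 runs")
    P = ensemble.runs["P"].to_numpy()
    M = ensemble.runs["M"].to_numpy()
    hist_P, edges_P = np.histogram(P, bins=bins, range=(0.0, 1.0), density=True)
    hist_M, edges_M = np.histogram(M, bins=bins, range=(0.0, 1.0), density=True)
    return {
        "hist_P": hist_P, "edges_P": edges_P, "bimodality_P": _bimodality_coefficient(P),
        "hist_M": hist_M, "edges_M": edges_M, "bimodality_M": _bimodality_coefficient(M),
    }


def escape_rate_curve(
    z_l_values: Sequence[float],
    params: SimParams,
    n_runs: int = 10,
    base_seed: int = 0,
    thresholds: PhaseThresholds = PhaseThresholds(),
    min_milling_time: float = 5.0,
    ensembles: Sequence[EnsembleResult] | None = None,
) -> pd.DataFrame:
    """Milling residence time and escape rate per z_l beyond the transition.

    For each run the cumulative milling time T_milling is measured; runs
    that never entered milling (T_milling < min_milling_time) are
    excluded and counted. Runs still milling at the end are censored —
    their T_milling equals the full duration, a lower bound — included
    in the mean and counted separately. kappa = 1 / <T_milling>.

    Pass precomputed ``ensembles`` (e.g. from a bifurcation sweep at the
    same seeds) to avoid re-simulating.
    """
    rows = []
    for j, z_l in enumerate(map(float, z_l_values)):
        if ensembles is not None:
            ens = ensembles[j]
            if abs(ens.params.z_l - z_l) > 1e-9:
                raise ValueError("ensembles do not match z_l_values")
        else:
            ens = run_ensemble(params.with_updates(z_l=z_l), n_runs,
                               base_seed + 1000 * j, thresholds=thresholds)
        runs = ens.runs
        entered = runs["T_milling"] >= min_milling_time
        censored = entered & (runs["phase"] == "milling")
        t_mill = runs.loc[entered, "T_milling"]
        mean_t = float(t_mill.mean()) if entered.any() else float("nan")
        rows.append({
            "z_l": z_l,
            "n_runs": len(runs),
            "n_transient": int((entered & ~censored).sum()),
            "n_censored": int(censored.sum()),
            "n_never_milled": int((~entered).sum()),
            "mean_T_milling": mean_t,
            "kappa": 1.0 / mean_t if mean_t and np.isfinite(mean_t) and mean_t > 0 else float("nan"),
        })
    return pd.DataFrame(rows)


def milling_escape_curve(
    z_l_values: Sequence[float],
    params: SimParams,
    n_runs: int = 8,
    base_seed: int = 0,
    z_l_mill: float = 2.0,
    t_equilibrate: float = 150.0,
    thresholds: PhaseThresholds = PhaseThresholds(),
) -> pd.DataFrame:
    """Escape rate measured from runs released out of a developed mill.

    From random initial conditions above the transition most runs
    polarize directly and never mill, which starves the residence-time
    statistics. This protocol instead equilibrates each run into a mill
    at ``z_l_mill`` (safely below the transition) for ``t_equilibrate``
    time units, then switches the alignment width to the target z_l and
    measures the milling residence time T_milling of the remainder of
    the run — escape from the milling well in the Kramers sense. Runs
    still milling at the end are censored (T_milling = remaining T, a
    lower bound) and counted. kappa = 1 / <T_milling>.
    """
    mill_states = []
    for k in range(n_runs):
        p_mill = params.with_updates(z_l=float(z_l_mill), total_time=t_equilibrate,
                                     seed=base_seed + k)
        mill_states.append(simulate(p_mill).final_state)
    rows = []
    for j, z_l in enumerate(map(float, z_l_values)):
        t_mills, censored = [], 0
        for k, st in enumerate(mill_states):
            p = params.with_updates(z_l=z_l, seed=base_seed + 100_000 + 1000 * j + k)
            traj = simulate(p, initial_state=st)
            _, t_mill = residence_fraction(traj.series, thresholds)
            t_mills.append(t_mill)
            if traj.series.M[-1] >= thresholds.order_high:
                censored += 1
        mean_t = float(np.mean(t_mills))
        rows.append({
            "z_l": z_l, "n_runs": n_runs, "n_censored": censored,
            "mean_T_milling": mean_t,
            "kappa": 1.0 / mean_t if mean_t > 0 else float("nan"),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KramersFit:
    """Fitted Kramers escape law kappa(r) = A r exp(-r / (3 sigma_eff^2))."""

    A: float
    sigma_eff: float
    z_l_star: float
    residual_norm: float  # RMS residual of log kappa
    r_squared: float

    def predict(self, r):
        from .sde import kramers_rate

        return kramers_rate(r, self.sigma_eff, self.A)


def fit_kramers(curve: pd.DataFrame, z_l_star: float) -> KramersFit:
    """Least-squares fit of (A, sigma_eff) to an escape-rate curve.

    The fit is performed on log kappa versus r = z_l - z_l_star, where
    the model is linear in (log A, 1/(3 sigma_eff^2)):

        log kappa = log A + log r - r / (3 sigma_eff^2).

    Only rows with finite kappa and r > 0 participate; at least 3 are
    required.
    """
    df = curve.copy()
    df["r"] = df["z_l"] - z_l_star
    df = df[(df["r"] > 0) & np.isfinite(df["kappa"]) & (df["kappa"] > 0)]
    if len(df) < 3:
        raise ValueError(f"need >= 3 usable points to fit, got {len(df)}")
    r = df["r"].to_numpy()
    y = np.log(df["kappa"].to_numpy())

    def model(r, log_A, inv3s2):
        return log_A + np.log(r) - inv3s2 * r

    # the model is linear in the two parameters: seed with the exact
    # linear-regression solution, then let curve_fit polish/report
    slope, intercept = np.polyfit(r, y - np.log(r), 1)
    p0 = (intercept, max(-slope, 1e-12))
    import warnings

    with warnings.catch_warnings():
        # in the sigma_eff -> inf (linear) limit one direction of the
        # Jacobian degenerates; the fit itself is still well defined
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, _ = optimize.curve_fit(model, r, y, p0=p0, maxfev=10000)
    log_A, inv3s2 = popt
    if inv3s2 <= 0:
        # linear-in-r regime (vanishing exponential correction)
        inv3s2 = 1e-12
    resid = y - model(r, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return KramersFit(
        A=float(np.exp(log_A)),
        sigma_eff=float(np.sqrt(1.0 / (3.0 * inv3s2))),
        z_l_star=float(z_l_star),
        residual_norm=float(np.sqrt(ss_res / len(r))),
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
    )


def hysteresis_ramp(
    z_l_grid: Sequence[float],
    params: SimParams,
    hold_time: float = 400.0,
    n_runs: int = 20,
    base_seed: int = 0,
    window: float = 50.0,
) -> pd.DataFrame:
    """Quasi-static ramp of z_l up the sorted grid and back down.

    Each chain starts from a random school at the lowest z_l, holds every
    grid value for ``hold_time`` (the state carries over between holds),
    then descends from the final forward state. The trailing ``window``
    of every hold is averaged. Chains are independent repetitions; the
    returned frame (direction, z_l, P_mean, M_mean, P_std, n_runs) is
    averaged over them, ordered as traversed.
    """
    grid = sorted(map(float, z_l_grid))
    if window > hold_time:
        raise ValueError("hold_time must cover the averaging window")
    acc: dict[tuple[str, float], list[tuple[float, float]]] = {}
    for chain in range(n_runs):
        rng = np.random.default_rng(base_seed + chain)
        state: SchoolState | None = None  # random init at the first hold
        for direction, zs in (("forward", grid), ("backward", grid[::-1])):
            for z_l in zs:
                p = params.with_updates(z_l=z_l, total_time=hold_time)
                traj = simulate(p, initial_state=state, rng=rng)
                summ = steady_state_average(traj.series, window)
                acc.setdefault((direction, z_l), []).append((summ.P, summ.M))
                state = traj.final_state
    rows = []
    for direction, zs in (("forward", grid), ("backward", grid[::-1])):
        for z_l in zs:
            vals = np.array(acc[(direction, z_l)])
            rows.append({
                "direction": direction, "z_l": z_l,
                "P_mean": float(vals[:, 0].mean()), "M_mean": float(vals[:, 1].mean()),
                "P_std": float(vals[:, 0].std()), "n_runs": len(vals),
            })
    return pd.DataFrame(rows)
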