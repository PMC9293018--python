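"""Parameter estimation from sparse count time series.

The estimator minimizes a squared-deviation objective between observed and
model-predicted counts with a hybrid of the downhill (Nelder-Mead) simplex
and simulated annealing: during simplex comparisons every stored vertex
value is made to look *worse* by a positive Boltzmann-distributed amount
proportional to the temperature, and every trial value is made to look
*better* by a similar amount, so the search accepts uphill moves at high
temperature and degenerates to the plain downhill simplex as T -> 0.  The
temperature is cooled geometrically, the simplex is re-seeded around the
incumbent best point at every temperature, and the whole schedule can be
restarted several times.

Counts in this system span four orders of magnitude (~1e4 to ~1e8 per ml),
so the default objective compares log10-transformed counts; otherwise the
late diatom values would dominate the fit.  Free parameters are searched in
log10 space whenever their bounds are strictly positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    DEFAULT_OPTIONS,
    PARAMETER_FIELDS,
    ModelOptions,
    ModelParameters,
    SystemState,
)
from .simulate import IntegrationError, integrate

__all__ = [
    "ObservationSet",
    "FitConfig",
    "FitResult",
    "SPECIES",
    "predict_at_times",
    "squared_deviation",
    "goodness_of_fit",
    "fit_parameters",
    "DEFAULT_BOUNDS",
]

SPECIES = ("B", "D")

#: Initial-state pools that may be estimated alongside rate parameters.
INIT_FIELDS = ("DOM_E0", "DOM_B0")

OBS_COLUMNS = ("time_days", "species", "replicate", "value")

_RATE_BOUNDS = (1e-6, 1e3)
_POOL_BOUNDS = (1e3, 1e10)

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "nu_mu_D": _RATE_BOUNDS,
    "nu_delta_D": _RATE_BOUNDS,
    "nu_mu_B": _RATE_BOUNDS,
    "nu_delta_B": _RATE_BOUNDS,
    "lam": _RATE_BOUNDS,
    "delta_DOME": _RATE_BOUNDS,
    "delta_DOMB": _RATE_BOUNDS,
    "CC_D": _POOL_BOUNDS,
    "CC_B": _POOL_BOUNDS,
    "K_DOME": _POOL_BOUNDS,
    "K_DOMB": _POOL_BOUNDS,
    "DOM_E0": _POOL_BOUNDS,
    "DOM_B0": _POOL_BOUNDS,
}

#: All parameters estimated when a config does not restrict the free set.
DEFAULT_FREE_PARAMETERS = (
    "nu_mu_D",
    "nu_delta_D",
    "nu_mu_B",
    "nu_delta_B",
    "lam",
    "CC_D",
    "K_DOME",
    "K_DOMB",
    "delta_DOME",
    "delta_DOMB",
    "DOM_E0",
    "DOM_B0",
)


class FitConfigurationError(ValueError):
    """The fit configuration is internally inconsistent."""


@dataclass(frozen=True)
class ObservationSet:
    """Replicated count observations in tidy long format.

    ``data`` has columns ``time_days`` (float), ``species`` ("B" or "D"),
    ``replicate`` (int) and ``value`` (counts per ml, >= 0).  An optional
    boolean ``censored`` column flags values reported at a detection floor.
    """

    data: pd.DataFrame
    units: dict = field(default_factory=lambda: {"B": "CFU ml^-1", "D": "cells ml^-1"})

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"observation table missing column(s): {missing}")
        bad_species = sorted(set(self.data["species"]) - set(SPECIES))
        if bad_species:
            raise ValueError(
                f"unknown species label(s) {bad_species}; allowed labels are {list(SPECIES)}"
            )
        values = self.data["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("observation values must be finite and >= 0")
        for sp in sorted(set(self.data["species"])):
            n_times = self.data.loc[self.data["species"] == sp, "time_days"].nunique()
            if n_times < 3:
                raise ValueError(
                    f"species {sp!r} has only {n_times} distinct time point(s); need >= 3"
                )

    def __len__(self) -> int:
        return len(self.data)

    def species_present(self) -> tuple[str, ...]:
        return tuple(sp for sp in SPECIES if sp in set(self.data["species"]))

    def times(self) -> np.ndarray:
        """Sorted union of observation times across species."""
        return np.sort(self.data["time_days"].unique())

    def replicate_means(self, species: str) -> pd.Series:
        """Per-time mean across replicates, indexed by time."""
        sub = self.data[self.data["species"] == species]
        return sub.groupby("time_days")["value"].mean()


@dataclass(frozen=True)
class FitConfig:
    """Free-parameter set, objective options and annealing schedule.

    The schedule defaults — initial temperature equal to the starting
    objective value, geometric cooling by 0.9, 50 simplex steps per
    temperature and 3 restarts — suit the 5-point / 3-replicate co-culture
    design; ``n_temps`` bounds the cooling chain.  A zero-temperature
    simplex polish runs after annealing unless ``polish`` is disabled.
    """

    free_parameters: tuple[str, ...] = DEFAULT_FREE_PARAMETERS
    bounds: dict = field(default_factory=dict)
    objective_scale: str = "log10"
    include_ratio_series: bool = False
    ratio_is_diatom_over_bacterium: bool = True
    fit_to_replicates: bool = True
    weight_by_series_variance: bool = False
    T0: float | None = None
    cooling: float = 0.9
    steps_per_temp: int = 50
    n_temps: int = 60
    restarts: int = 3
    polish: bool = True
    polish_maxiter: int = 800
    polish_fatol: float = 1e-10
    polish_xatol: float = 1e-8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "free_parameters", tuple(self.free_parameters))
        known = set(PARAMETER_FIELDS) | set(INIT_FIELDS)
        unknown = [p for p in self.free_parameters if p not in known]
        if unknown:
            raise FitConfigurationError(f"unknown free parameter(s): {unknown}")
        if len(set(self.free_parameters)) != len(self.free_parameters):
            raise FitConfigurationError("duplicate free parameter names")
        if self.objective_scale not in ("log10", "linear"):
            raise FitConfigurationError("objective_scale must be 'log10' or 'linear'")
        if not (0.0 < self.cooling < 1.0):
            raise FitConfigurationError("cooling factor must be in (0, 1)")
        if self.T0 is not None and self.T0 < 0.0:
            raise FitConfigurationError("T0 must be > 0 (or None for auto)")
        for name, (lo, hi) in self.bounds.items():
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
                raise FitConfigurationError(f"invalid bounds for {name}: ({lo}, {hi})")

    def bound_for(self, name: str) -> tuple[float, float]:
        return tuple(self.bounds.get(name, DEFAULT_BOUNDS[name]))


@dataclass(frozen=True)
class FitResult:
    """Best parameters found, objective value and fit diagnostics."""

    params_hat: ModelParameters
    init_hat: SystemState
    objective_value: float
    gof: dict
    n_evaluations: int
    converged: bool
    at_bounds: tuple[str, ...]
    seed: int
    trace: tuple

    def free_values(self, names) -> dict[str, float]:
        out = {}
        for name in names:
            if name in INIT_FIELDS:
                out[name] = getattr(self.init_hat, name[:-1])
            else:
                out[name] = getattr(self.params_hat, name)
        return out


# --------------------------------------------------------------------------
# prediction and objective


def predict_at_times(
    params: ModelParameters,
    init: SystemState,
    times,
    options: ModelOptions = DEFAULT_OPTIONS,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, np.ndarray]:
    """Model-predicted B and D at exactly the requested times.

    Times need not include 0; the integration always starts at the initial
    state at t = 0.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    order = np.argsort(times)
    sorted_times = times[order]
    grid = np.unique(np.concatenate(([0.0], sorted_times)))
    traj = integrate(params, init, grid, options, rtol=rtol, atol=atol)
    idx = np.searchsorted(grid, sorted_times)
    out_b = np.empty_like(times)
    out_d = np.empty_like(times)
    out_b[order] = traj.B[idx]
    out_d[order] = traj.D[idx]
    return {"B": out_b, "D": out_d}


def series_ratio(D: np.ndarray, B: np.ndarray, diatom_over_bacterium: bool = True) -> np.ndarray:
    """Element-wise cell-count ratio with a guard for zero denominators."""
    num, den = (np.asarray(D, float), np.asarray(B, float))
    if not diatom_over_bacterium:
        num, den = den, num
    out = np.full(num.shape, np.nan)
    ok = den > 0
    if not np.all(ok):
        warnings.warn("ratio undefined where the denominator count is 0; reported as NaN")
    out[ok] = num[ok] / den[ok]
    return out


def _transform(values: np.ndarray, scale: str) -> np.ndarray:
    # epsilon of 1 count/ml keeps the log objective finite at zero counts
    if scale == "log10":
        return np.log10(np.asarray(values, float) + 1.0)
    return np.asarray(values, float)


def squared_deviation(
    obs: ObservationSet,
    params: ModelParameters,
    init: SystemState,
    config: FitConfig,
    options: ModelOptions = DEFAULT_OPTIONS,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Sum of squared deviations between observed and predicted counts.

    With the default ``log10`` scale each count x enters as log10(x + 1).
    Each replicate contributes its own term unless ``fit_to_replicates`` is
    off, in which case per-time replicate means are fitted.  The optional
    ratio series is computed from per-time replicate means.
    """
    if len(obs) == 0:
        raise ValueError("observation set is empty")
    times = obs.times()
    pred = predict_at_times(params, init, times, options, rtol=rtol, atol=atol)
    pred_at = {sp: dict(zip(times, pred[sp])) for sp in SPECIES}

    total = 0.0
    for sp in obs.species_present():
        sub = obs.data[obs.data["species"] == sp]
        if not config.fit_to_replicates:
            sub = sub.groupby("time_days", as_index=False)["value"].mean()
        o = _transform(sub["value"].to_numpy(), config.objective_scale)
        p = _transform(
            np.array([pred_at[sp][t] for t in sub["time_days"]]), config.objective_scale
        )
        if np.all(sub["value"].to_numpy() == 0):
            warnings.warn(f"all observations of series {sp!r} are zero")
        sse = float(np.sum((o - p) ** 2))
        if config.weight_by_series_variance:
            var = float(np.var(o))
            if var > 0:
                sse /= var
            else:
                warnings.warn(f"series {sp!r} has zero variance; left unweighted")
        total += sse

    if config.include_ratio_series:
        want = config.ratio_is_diatom_over_bacterium
        obs_ratio = series_ratio(
            obs.replicate_means("D").reindex(times).to_numpy(),
            obs.replicate_means("B").reindex(times).to_numpy(),
            want,
        )
        pred_ratio = series_ratio(pred["D"], pred["B"], want)
        ok = np.isfinite(obs_ratio) & np.isfinite(pred_ratio)
        o = _transform(obs_ratio[ok], config.objective_scale)
        p = _transform(pred_ratio[ok], config.objective_scale)
        sse = float(np.sum((o - p) ** 2))
        if config.weight_by_series_variance:
            var = float(np.var(o))
            if var > 0:
                sse /= var
        total += sse
    return total


def goodness_of_fit(observed, predicted, method: str = "pearson"):
    """Coefficient of determination between observed and predicted series.

    ``method="pearson"`` (default) returns the squared Pearson correlation
    together with the two-sided p-value of the t-statistic
    r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 degrees of freedom.
    ``method="ss"`` returns 1 - SS_res / SS_tot instead (may be negative,
    reported as-is); the p-value is still the Pearson one.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be 1-D arrays of equal length")
    if observed.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        raise ValueError("R^2 undefined: a series has zero variance")
    r, p = stats.pearsonr(observed, predicted)
    if method == "pearson":
        return float(r**2), float(p)
    if method == "ss":
        ss_res = float(np.sum((observed - predicted) ** 2))
        ss_tot = float(np.sum((observed - observed.mean()) ** 2))
        return 1.0 - ss_res / ss_tot, float(p)
    raise ValueError("method must be 'pearson' or 'ss'")


def _build_fast_objective(obs, config, options, rtol, atol):
    """Precompiled squared-deviation objective for the optimizer loop.

    Mirrors :func:`squared_deviation` exactly but hoists all table
    manipulation out of the per-evaluation path; only the ODE solve and a
    few array operations remain per call.
    """
    times = obs.times()
    grid = np.unique(np.concatenate(([0.0], times)))
    pos = np.searchsorted(grid, times)
    col = {"B": 0, "D": 1}

    series = []  # (state column, grid positions, transformed obs, weight)
    for sp in obs.species_present():
        sub = obs.data[obs.data["species"] == sp]
        if not config.fit_to_replicates:
            sub = sub.groupby("time_days", as_index=False)["value"].mean()
        o = _transform(sub["value"].to_numpy(), config.objective_scale)
        t_idx = pos[np.searchsorted(times, sub["time_days"].to_numpy())]
        weight = 1.0
        if config.weight_by_series_variance:
            var = float(np.var(o))
            weight = 1.0 / var if var > 0 else 1.0
        series.append((col[sp], t_idx, o, weight))

    ratio = None
    if config.include_ratio_series:
        want = config.ratio_is_diatom_over_bacterium
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs_ratio = series_ratio(
                obs.replicate_means("D").reindex(times).to_numpy(),
                obs.replicate_means("B").reindex(times).to_numpy(),
                want,
            )
        ratio = (want, obs_ratio, pos)

    from .model import ode_rhs  # local alias keeps the closure tight
    from scipy.integrate import solve_ivp

    def objective(params, init_state):
        y0 = np.asarray(init_state.as_array(), dtype=float)
        # LSODA: the search can visit stiff corners of the bounds box
        # (large rates, small half-saturations) that stall explicit RK
        sol = solve_ivp(
            ode_rhs,
            (grid[0], grid[-1]),
            y0,
            method="LSODA",
            t_eval=grid,
            rtol=rtol,
            atol=atol,
            args=(params, options),
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            return math.inf
        states = np.clip(sol.y, 0.0, None)
        total = 0.0
        for state_col, t_idx, o, weight in series:
            p = _transform(states[state_col][t_idx], config.objective_scale)
            total += weight * float(np.sum((o - p) ** 2))
        if ratio is not None:
            want, obs_ratio, r_pos = ratio
            num, den = (1, 0) if want else (0, 1)
            pred_den = states[den][r_pos]
            pred_ratio = np.where(pred_den > 0, states[num][r_pos] / np.where(pred_den > 0, pred_den, 1.0), np.nan)
            ok = np.isfinite(obs_ratio) & np.isfinite(pred_ratio)
            o = _transform(obs_ratio[ok], config.objective_scale)
            p = _transform(pred_ratio[ok], config.objective_scale)
            sse = float(np.sum((o - p) ** 2))
            if config.weight_by_series_variance:
                var = float(np.var(o))
                if var > 0:
                    sse /= var
            total += sse
        return total

    return objective


# --------------------------------------------------------------------------
# annealed Nelder-Mead simplex

_ALPHA, _GAMMA, _RHO, _SIGMA = 1.0, 2.0, 0.5, 0.5


def _simplex_steps(func, simplex, fvals, n_steps, T, rng, lo, hi):
    """Run Nelder-Mead iterations with thermal noise on the comparisons.

    Vertex values are perturbed upward and trial values downward by
    exponential deviates scaled by T, following the classic annealed
    simplex; at T = 0 this is the standard downhill simplex.  ``simplex``
    and ``fvals`` are modified in place; returns them after ``n_steps``.
    """
    n = simplex.shape[1]

    def flu_up(y):  # stored vertices look worse
        return y - T * math.log(rng.random()) if T > 0 else y

    def flu_down(y):  # trial points look better
        return y + T * math.log(rng.random()) if T > 0 else y

    def clip(x):
        return np.minimum(np.maximum(x, lo), hi)

    for _ in range(n_steps):
        yflu = np.array([flu_up(y) for y in fvals])
        order = np.argsort(yflu)
        simplex[:] = simplex[order]
        fvals[:] = fvals[order]
        yflu = yflu[order]

        centroid = simplex[:-1].mean(axis=0)
        xr = clip(centroid + _ALPHA * (centroid - simplex[-1]))
        fr = func(xr)
        frf = flu_down(fr)
        if frf < yflu[0]:
            xe = clip(centroid + _GAMMA * (xr - centroid))
            fe = func(xe)
            fef = flu_down(fe)
            if fef < frf:
                simplex[-1], fvals[-1] = xe, fe
            else:
                simplex[-1], fvals[-1] = xr, fr
        elif frf < yflu[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            if frf < yflu[-1]:  # outside contraction
                xc = clip(centroid + _RHO * (xr - centroid))
            else:  # inside contraction
                xc = clip(centroid - _RHO * (centroid - simplex[-1]))
            fc = func(xc)
            if flu_down(fc) < min(frf, yflu[-1]):
                simplex[-1], fvals[-1] = xc, fc
            else:  # shrink toward the best vertex
                for i in range(1, n + 1):
                    simplex[i] = clip(simplex[0] + _SIGMA * (simplex[i] - simplex[0]))
                    fvals[i] = func(simplex[i])
    return simplex, fvals


def _init_simplex(func, x0, lo, hi, frac):
    """Axis-aligned simplex around x0 with steps = frac * (hi - lo)."""
    n = x0.size
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        step = frac * (hi[i] - lo[i])
        if step == 0.0:
            step = max(abs(x0[i]) * frac, frac)
        if x0[i] + step <= hi[i]:
            simplex[i + 1, i] = x0[i] + step
        else:
            simplex[i + 1, i] = x0[i] - step
    fvals = np.array([func(v) for v in simplex])
    return simplex, fvals


def anneal_simplex(
    func,
    x0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
    T0: float | None = None,
    cooling: float = 0.9,
    steps_per_temp: int = 50,
    n_temps: int = 60,
    restarts: int = 3,
    polish: bool = True,
    polish_maxiter: int = 800,
    fatol: float = 1e-10,
    xatol: float = 1e-8,
):
    """Minimize ``func`` over the box [lo, hi] starting from x0.

    Returns ``(x_best, f_best, n_evaluations, converged, trace)`` where
    ``trace`` records the incumbent objective at the end of every
    temperature block.
    """
    x0 = np.asarray(x0, dtype=float)
    n_eval = 0
    best = {"x": x0.copy(), "f": math.inf}

    def wrapped(x):
        nonlocal n_eval
        n_eval += 1
        f = func(x)
        if f < best["f"]:
            best["f"] = float(f)
            best["x"] = np.array(x, copy=True)
        return f

    f0 = wrapped(x0)
    if not math.isfinite(f0):
        raise FitConfigurationError("objective is non-finite at the start point")
    t0 = float(T0) if T0 is not None else max(f0, 1e-12)

    trace = []
    for _ in range(max(restarts, 1)):
        T = t0
        # the chain point may drift uphill while T is high; only the
        # restart anchor uses the incumbent best
        x_chain = best["x"].copy()
        for _k in range(n_temps):
            if T <= 0:
                break
            frac = 0.25 * max(T / t0, 1e-2) ** 0.5
            simplex, fvals = _init_simplex(wrapped, x_chain, lo, hi, frac)
            _simplex_steps(wrapped, simplex, fvals, steps_per_temp, T, rng, lo, hi)
            x_chain = simplex[int(np.argmin(fvals))].copy()
            trace.append((T, best["f"]))
            T *= cooling

    converged = True
    if polish:
        simplex, fvals = _init_simplex(wrapped, best["x"], lo, hi, 0.02)
        converged = False
        for _ in range(polish_maxiter):
            _simplex_steps(wrapped, simplex, fvals, 1, 0.0, rng, lo, hi)
            f_spread = float(np.max(fvals) - np.min(fvals))
            x_spread = float(np.max(np.abs(simplex - simplex[0])))
            if f_spread <= fatol + 1e-8 * abs(float(np.min(fvals))) and x_spread <= xatol:
                converged = True
                break
        trace.append((0.0, best["f"]))
    return best["x"], best["f"], n_eval, converged, tuple(trace)


# --------------------------------------------------------------------------
# the full fit


def _make_vector_maps(free, config, base_params, init):
    """Set up the transformed search space (log10 where bounds allow)."""
    lo_t, hi_t, x0_t, use_log = [], [], [], []
    for name in free:
        lo, hi = config.bound_for(name)
        if lo > hi:
            raise FitConfigurationError(f"empty bounds for {name}")
        if name in INIT_FIELDS:
            start = getattr(init, name[:-1])
        else:
            start = getattr(base_params, name)
        start = min(max(start, lo), hi)
        log_ok = lo > 0
        use_log.append(log_ok)
        if log_ok:
            lo_t.append(math.log10(lo))
            hi_t.append(math.log10(hi))
            x0_t.append(math.log10(start) if start > 0 else math.log10(lo))
        else:
            lo_t.append(lo)
            hi_t.append(hi)
            x0_t.append(start)
    return (
        np.array(lo_t),
        np.array(hi_t),
        np.array(x0_t),
        tuple(use_log),
    )


def _vector_to_model(x, free, use_log, base_params, init):
    changes_p, changes_i = {}, {}
    for value, name, logged in zip(x, free, use_log):
        value = 10.0**value if logged else float(value)
        if name in INIT_FIELDS:
            changes_i[name[:-1]] = value
        else:
            changes_p[name] = value
    params = base_params.replace(**changes_p) if changes_p else base_params
    start = init.replace(**changes_i) if changes_i else init
    return params, start


def fit_parameters(
    obs: ObservationSet,
    config: FitConfig,
    init: SystemState,
    base_params: ModelParameters,
    options: ModelOptions = DEFAULT_OPTIONS,
    rtol: float = 1e-6,
    atol: float = 1e-2,
) -> FitResult:
    """Estimate the free parameters of the model from count observations.

    ``base_params`` and ``init`` supply both the frozen parameter values
    and the starting point for the free ones (clipped into bounds).  The
    result is deterministic given ``config.rng_seed``.  Looser integration
    tolerances than the simulator defaults are used inside the objective;
    the returned objective value is re-evaluated once at the optimum.
    """
    free = config.free_parameters
    n_points = len(obs)
    if n_points < len(free):
        raise FitConfigurationError(
            f"{n_points} data points cannot constrain {len(free)} free parameters"
        )
    lo, hi, x0, use_log = _make_vector_maps(free, config, base_params, init)
    rng = np.random.default_rng(config.rng_seed)

    fast_objective = _build_fast_objective(obs, config, options, rtol, atol)

    def objective(x):
        params, start = _vector_to_model(x, free, use_log, base_params, init)
        return fast_objective(params, start)

    try:
        x_best, _, n_eval, converged, trace = anneal_simplex(
            objective,
            x0,
            lo,
            hi,
            rng,
            T0=config.T0,
            cooling=config.cooling,
            steps_per_temp=config.steps_per_temp,
            n_temps=config.n_temps,
            restarts=config.restarts,
            polish=config.polish,
            polish_maxiter=config.polish_maxiter,
            fatol=config.polish_fatol,
            xatol=config.polish_xatol,
        )
    except FitConfigurationError:
        raise FitConfigurationError(
            f"objective is non-finite at the start point (free parameters: {list(free)})"
        ) from None

    params_hat, init_hat = _vector_to_model(x_best, free, use_log, base_params, init)
    final_obj = squared_deviation(obs, params_hat, init_hat, config, options)

    at_bounds = tuple(
        name
        for name, xv, l, h in zip(free, x_best, lo, hi)
        if xv - l <= 1e-9 * max(1.0, abs(l)) or h - xv <= 1e-9 * max(1.0, abs(h))
    )

    gof = _fit_gof(obs, params_hat, init_hat, config, options)
    return FitResult(
        params_hat=params_hat,
        init_hat=init_hat,
        objective_value=float(final_obj),
        gof=gof,
        n_evaluations=n_eval,
        converged=converged and not math.isinf(final_obj),
        at_bounds=at_bounds,
        seed=config.rng_seed,
        trace=trace,
    )


def _fit_gof(obs, params, init, config, options):
    """Per-series R^2 / p-value of replicate means against predictions."""
    gof: dict[str, tuple[float, float]] = {}
    times = obs.times()
    try:
        pred = predict_at_times(params, init, times, options)
    except IntegrationError:
        return {sp: (float("nan"), float("nan")) for sp in (*SPECIES, "ratio")}
    means = {}
    for sp in obs.species_present():
        m = obs.replicate_means(sp).reindex(times)
        ok = m.notna().to_numpy()
        means[sp] = (m.to_numpy()[ok], pred[sp][ok])
        try:
            gof[sp] = goodness_of_fit(*means[sp])
        except ValueError:
            gof[sp] = (float("nan"), float("nan"))
    if set(SPECIES) <= set(means):
        want = config.ratio_is_diatom_over_bacterium
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs_ratio = series_ratio(
                obs.replicate_means("D").reindex(times).to_numpy(),
                obs.replicate_means("B").reindex(times).to_numpy(),
                want,
            )
            pred_ratio = series_ratio(pred["D"], pred["B"], want)
        ok = np.isfinite(obs_ratio) & np.isfinite(pred_ratio)
        try:
            gof["ratio"] = goodness_of_fit(obs_ratio[ok], pred_ratio[ok])
        except ValueError:
            gof["ratio"] = (float("nan"), float("nan"))
    return gof
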