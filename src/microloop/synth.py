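"""Synthetic observation tables with the co-culture experiment's design.

The generator reproduces the statistical structure of the real sampling
scheme — five time points at 7-day intervals over 28 days, triplicate
cultures, counts spanning roughly 1e4 to 1e8 per ml — from a known ground
truth, so the whole fitting pipeline can be exercised and validated in a
closed loop.  Observation noise is multiplicative by default (plate counts
and haemocytometer counts have approximately constant coefficient of
variation); a Poisson counting model is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitting import FitConfig, ObservationSet, fit_parameters
from .model import DEFAULT_OPTIONS, ModelOptions, ModelParameters, SystemState
from .simulate import Trajectory, integrate

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "RecoveryReport",
    "reference_truth",
    "generate_observations",
    "parameter_recovery_experiment",
]


@dataclass(frozen=True)
class SyntheticDesign:
    """Sampling schedule, replication and observation-noise model.

    noise_cv is the coefficient of variation of the multiplicative
    lognormal noise (default 0.10, a mid-range value for replicate plate
    and haemocytometer counts).  Counts below ``detection_floor`` are
    censored to the floor and flagged.
    """

    sample_times: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0, 28.0)
    n_replicates: int = 3
    noise_model: str = "lognormal_cv"
    noise_cv: float = 0.10
    detection_floor: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sample_times) == 0 or any(t < 0 for t in self.sample_times):
            raise ValueError("sample_times must be nonempty and >= 0")
        if list(self.sample_times) != sorted(set(self.sample_times)):
            raise ValueError("sample_times must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_model not in ("lognormal_cv", "poisson_counting"):
            raise ValueError("noise_model must be 'lognormal_cv' or 'poisson_counting'")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def to_dict(self) -> dict:
        return {
            "sample_times": list(self.sample_times),
            "n_replicates": self.n_replicates,
            "noise_model": self.noise_model,
            "noise_cv": self.noise_cv,
            "detection_floor": self.detection_floor,
            "rng_seed": self.rng_seed,
        }


@dataclass(frozen=True)
class GroundTruth:
    """Known parameters, initial state and options behind a synthetic set."""

    params: ModelParameters
    init: SystemState
    options: ModelOptions = DEFAULT_OPTIONS


def reference_truth() -> GroundTruth:
    """A synthetic reference parameterization for closed-loop tests.

    The values are chosen so the simulated co-culture shows the
    experiment's qualitative shape — inocula of 1e5 bacteria and 2e5
    diatoms per ml, a bacterial lag of about two weeks followed by strong
    growth, and a near-linear diatom rise toward ~1e7 cells per ml over 28
    days.  They are NOT fitted values from any study; they exist so tests
    and examples are self-contained.
    """
    params = ModelParameters(
        nu_mu_D=0.35,
        nu_delta_D=0.05,
        nu_mu_B=2.0,
        nu_delta_B=0.05,
        lam=0.08,
        CC_D=1.6e7,
        K_DOME=5e6,
        K_DOMB=1e8,
        delta_DOME=0.01,
        delta_DOMB=0.01,
        CC_B=1e9,
    )
    init = SystemState(B=1e5, D=2e5, DOM_E=0.0, DOM_B=0.0)
    return GroundTruth(params=params, init=init)


def generate_observations(
    truth: GroundTruth, design: SyntheticDesign
) -> tuple[ObservationSet, Trajectory]:
    """Draw a noisy observation table from a ground-truth trajectory.

    Under ``lognormal_cv`` each observation is mean * exp(sigma Z - sigma^2/2)
    with sigma = sqrt(ln(1 + cv^2)), which is unbiased in expectation; under
    ``poisson_counting`` each observation is a Poisson draw with the model
    value as its mean.  Values below the detection floor are reported at the
    floor with ``censored = True``.  Returns the table together with the
    noiseless trajectory for auditing.

    Noise draws are keyed by (seed, species, replicate, time), so two
    designs sharing a seed produce identical observations at the sampling
    times they have in common: densifying or truncating the schedule never
    reshuffles the noise elsewhere.
    """
    times = np.asarray(design.sample_times, dtype=float)
    grid = times if times[0] == 0.0 else np.concatenate(([0.0], times))
    traj = integrate(truth.params, truth.init, grid, truth.options)
    keep = np.searchsorted(grid, times)
    means = {"B": traj.B[keep], "D": traj.D[keep]}

    rows = []
    for sp_index, sp in enumerate(("B", "D")):
        for t, mean in zip(times, means[sp]):
            for rep in range(1, design.n_replicates + 1):
                cell_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        (design.rng_seed, sp_index, rep, int(round(t * 1e6)))
                    )
                )
                if design.noise_model == "lognormal_cv":
                    if design.noise_cv > 0:
                        sigma = math.sqrt(math.log(1.0 + design.noise_cv**2))
                        value = mean * math.exp(
                            sigma * cell_rng.standard_normal() - 0.5 * sigma**2
                        )
                    else:
                        value = mean
                else:
                    value = float(cell_rng.poisson(mean))
                censored = value < design.detection_floor
                rows.append(
                    {
                        "time_days": t,
                        "species": sp,
                        "replicate": rep,
                        "value": max(value, design.detection_floor),
                        "censored": censored,
                    }
                )
    obs = ObservationSet(pd.DataFrame(rows))
    return obs, traj


@dataclass(frozen=True)
class RecoveryReport:
    """Aggregate of a repeated generate-then-fit experiment."""

    estimates: pd.DataFrame  # dataset, parameter, truth, estimate, rel_error
    gof: pd.DataFrame  # dataset, series, r2, p_value
    failures: tuple[int, ...]
    seed: int

    def median_abs_rel_error(self) -> pd.Series:
        """Median |estimate - truth| / truth per free parameter."""
        return self.estimates.groupby("parameter")["rel_error"].apply(
            lambda e: float(np.median(np.abs(e)))
        )

    def bias(self) -> pd.Series:
        """Median signed relative error per free parameter."""
        return self.estimates.groupby("parameter")["rel_error"].median()


def _truth_value(truth: GroundTruth, name: str) -> float:
    if name in ("DOM_E0", "DOM_B0"):
        return getattr(truth.init, name[:-1])
    return getattr(truth.params, name)


def _neutral_start(truth: GroundTruth, fit_config: FitConfig):
    """Start each free parameter at the midpoint of its bounds.

    Frozen parameters keep their true values; free ones start at the
    geometric midpoint (arithmetic if the lower bound is 0) so recovery
    measures a genuine search, not a perturbation around the answer.
    """
    params, init = truth.params, truth.init
    for name in fit_config.free_parameters:
        lo, hi = fit_config.bound_for(name)
        start = math.sqrt(lo * hi) if lo > 0 else 0.5 * (lo + hi)
        if name in ("DOM_E0", "DOM_B0"):
            init = init.replace(**{name[:-1]: start})
        else:
            params = params.replace(**{name: start})
    return params, init


def parameter_recovery_experiment(
    truth: GroundTruth,
    design: SyntheticDesign,
    fit_config: FitConfig,
    n_datasets: int,
    seed: int = 0,
) -> RecoveryReport:
    """Generate ``n_datasets`` synthetic tables and refit each one.

    Dataset seeds and fit seeds are spawned deterministically from
    ``seed``; individual fit failures are recorded in the report rather
    than raised.  The frozen parameters of each fit are taken from the
    ground truth; the free ones start from the midpoint of their bounds
    (see :func:`_neutral_start`), never from the truth.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(n_datasets)
    start_params, start_init = _neutral_start(truth, fit_config)

    est_rows, gof_rows, failures = [], [], []
    for i, child in enumerate(children):
        data_seed, fit_seed = (int(s) % (2**31) for s in child.generate_state(2))
        obs, _ = generate_observations(truth, replace(design, rng_seed=data_seed))
        cfg = replace(fit_config, rng_seed=fit_seed)
        try:
            result = fit_parameters(obs, cfg, start_init, start_params, truth.options)
        except Exception:
            failures.append(i)
            continue
        for name, estimate in result.free_values(cfg.free_parameters).items():
            tv = _truth_value(truth, name)
            rel = (estimate - tv) / tv if tv != 0 else float("nan")
            est_rows.append(
                {
                    "dataset": i,
                    "parameter": name,
                    "truth": tv,
                    "estimate": estimate,
                    "rel_error": rel,
                }
            )
        for series, (r2, p) in result.gof.items():
            gof_rows.append({"dataset": i, "series": series, "r2": r2, "p_value": p})

    return RecoveryReport(
        estimates=pd.DataFrame(est_rows),
        gof=pd.DataFrame(gof_rows),
        failures=tuple(failures),
        seed=seed,
    )
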