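"""Rate laws and ODE right-hand side for a diatom-bacterium co-culture.

The model tracks four concentrations in a well-mixed batch co-culture of a
phototrophic diatom and a heterotrophic marine bacterium:

* ``B`` — bacterial cells (CFU ml^-1),
* ``D`` — diatom cells (cells ml^-1),
* ``DOM_E`` — dissolved organic matter actively exuded by living diatoms
  (photosynthates), and
* ``DOM_B`` — dissolved organic matter derived from dead diatom biomass.

DOM pools are denominated in bacterial-cell equivalents per ml: one DOM unit
converts to one bacterial cell (an explicit yield multiplier is available on
:class:`ModelOptions`).

Diatom growth follows a generalized logistic (Verhulst) law with carrying
capacity ``CC_D``; diatom cells additionally lose carbon to exudation at a
constant per-cell rate ``lam`` and die at a rate that is damped when the
population is actively growing.  Bacterial growth is substrate-limited via
Monod kinetics on each DOM pool and feeds back on itself through a
``1/(1 + mu_B)`` damping factor, which makes the bacterial growth-rate law
self-referential; see :func:`growth_rate_bacterium` for how the fixed point
is resolved.

The right-hand side (state order ``B, D, DOM_E, DOM_B``):

.. math::

    dB/dt     &= (\\mu_B - \\delta_B)\\,B \\\\
    dD/dt     &= (\\mu_D - \\delta_D - \\lambda)\\,D \\\\
    dDOM_E/dt &= \\lambda D - c_E B - \\delta_{DOM_E}\\,DOM_E \\\\
    dDOM_B/dt &= \\delta_D D - c_B B - \\delta_{DOM_B}\\,DOM_B

where the consumption fluxes ``c_E, c_B`` depend on
``ModelOptions.consumption_mode`` (see below).  All rates are per day; the
experimental design this model was built for samples every 7 days over 28
days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "ModelParameters",
    "SystemState",
    "RateSet",
    "ModelOptions",
    "InvalidParameterError",
    "DomainError",
    "growth_rate_diatom",
    "death_rate_diatom",
    "growth_rate_bacterium",
    "death_rate_bacterium",
    "compute_rates",
    "ode_rhs",
    "STATE_FIELDS",
    "PARAMETER_FIELDS",
]

STATE_FIELDS = ("B", "D", "DOM_E", "DOM_B")

PARAMETER_FIELDS = (
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
    "CC_B",
)


class InvalidParameterError(ValueError):
    """A model parameter violates its admissible range."""


class DomainError(ValueError):
    """A rate law was evaluated outside its mathematical domain."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and capacities of the co-culture model.

    Parameters
    ----------
    nu_mu_D
        Maximal diatom growth rate (day^-1).
    nu_delta_D
        Maximal diatom death rate (day^-1).
    nu_mu_B
        Maximal bacterial growth rate (day^-1).
    nu_delta_B
        Maximal bacterial death rate (day^-1).
    lam
        Exudation rate: first-order rate at which living diatom cells
        release photosynthates into the DOM_E pool (day^-1).
    CC_D
        Diatom carrying capacity (cells ml^-1).
    K_DOME, K_DOMB
        Monod half-saturation constants of the exudate and dead-biomass
        pools (DOM units, i.e. bacterial-cell equivalents ml^-1).
    delta_DOME, delta_DOMB
        First-order loss rates of DOM that leaves the system unused
        (day^-1).
    CC_B
        Bacterial carrying capacity (cells ml^-1).  Accepted for
        completeness but not referenced by any rate law; it does not
        affect the dynamics.
    """

    nu_mu_D: float
    nu_delta_D: float
    nu_mu_B: float
    nu_delta_B: float
    lam: float
    CC_D: float
    K_DOME: float
    K_DOMB: float
    delta_DOME: float
    delta_DOMB: float
    CC_B: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAMETER_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0.0:
                raise InvalidParameterError(
                    f"parameter {name} must be finite and >= 0, got {value!r}"
                )
        if self.CC_D <= 0.0:
            raise InvalidParameterError("CC_D must be strictly positive")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAMETER_FIELDS}


@dataclass(frozen=True)
class SystemState:
    """Concentrations of the four state variables at one time point."""

    B: float
    D: float
    DOM_E: float
    DOM_B: float

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0.0:
                raise InvalidParameterError(
                    f"state component {name} must be finite and >= 0, got {value!r}"
                )

    def as_array(self) -> tuple[float, float, float, float]:
        return (self.B, self.D, self.DOM_E, self.DOM_B)

    def replace(self, **changes: float) -> "SystemState":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in STATE_FIELDS}


@dataclass(frozen=True)
class RateSet:
    """Realized (state-dependent) rates at one instant, all day^-1."""

    mu_D: float
    delta_D: float
    mu_B: float
    mu_B_E: float
    mu_B_B: float
    delta_B: float


@dataclass(frozen=True)
class ModelOptions:
    """Switches resolving ambiguities of the published equation set.

    consumption_mode
        ``"split"`` (default) apportions total bacterial DOM consumption
        between the two pools in proportion to each pool's Monod fraction,
        so gross uptake equals gross growth and an empty pool is never
        drained.  ``"literal"`` subtracts the full ``mu_B * B`` flux from
        *each* pool, reading the printed DOM equations at face value; it
        double-counts uptake and can drive an empty pool negative, and is
        retained only for fidelity checks.
    exudation_costs_biomass
        Whether exudation depletes the diatom cell count (the ``-lam * D``
        term in dD/dt).  Default on.
    mu_B_resolution
        ``"quadratic_fixed_point"`` (default) solves the self-referential
        bacterial growth law exactly; ``"explicit_no_self_term"`` drops the
        1/(1 + mu_B) damping for sensitivity comparison.
    yield_cells_per_dom
        Bacterial cells produced per DOM unit consumed (default 1, i.e.
        DOM is measured in bacterial-cell equivalents).
    """

    consumption_mode: str = "split"
    exudation_costs_biomass: bool = True
    mu_B_resolution: str = "quadratic_fixed_point"
    yield_cells_per_dom: float = 1.0

    def __post_init__(self) -> None:
        if self.consumption_mode not in ("split", "literal"):
            raise InvalidParameterError(
                f"consumption_mode must be 'split' or 'literal', got {self.consumption_mode!r}"
            )
        if self.mu_B_resolution not in ("quadratic_fixed_point", "explicit_no_self_term"):
            raise InvalidParameterError(
                "mu_B_resolution must be 'quadratic_fixed_point' or "
                f"'explicit_no_self_term', got {self.mu_B_resolution!r}"
            )
        if not math.isfinite(self.yield_cells_per_dom) or self.yield_cells_per_dom <= 0:
            raise InvalidParameterError("yield_cells_per_dom must be finite and > 0")

    def to_dict(self) -> dict:
        return {
            "consumption_mode": self.consumption_mode,
            "exudation_costs_biomass": self.exudation_costs_biomass,
            "mu_B_resolution": self.mu_B_resolution,
            "yield_cells_per_dom": self.yield_cells_per_dom,
        }


DEFAULT_OPTIONS = ModelOptions()


def growth_rate_diatom(D: float, params: ModelParameters) -> float:
    """Logistic diatom growth rate ``nu_mu_D * (1 - D / CC_D)``.

    Negative when ``D > CC_D`` (overcapacity decline).
    """
    if params.CC_D <= 0.0:
        raise InvalidParameterError("CC_D must be strictly positive")
    return params.nu_mu_D * (1.0 - D / params.CC_D)


def death_rate_diatom(mu_D: float, params: ModelParameters) -> float:
    """Growth-damped diatom death rate ``nu_delta_D / (1 + mu_D)``.

    Actively growing populations die more slowly; the law is strictly
    decreasing in ``mu_D`` and requires ``mu_D > -1``.
    """
    if mu_D <= -1.0:
        raise DomainError(f"death_rate_diatom requires mu_D > -1, got {mu_D}")
    return params.nu_delta_D / (1.0 + mu_D)


def _monod(pool: float, K: float) -> float:
    # 0/0 at an empty pool with K == 0 is taken as 0 (no substrate, no uptake).
    if pool <= 0.0:
        return 0.0
    return pool / (pool + K)


def growth_rate_bacterium(
    DOM_E: float,
    DOM_B: float,
    params: ModelParameters,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> tuple[float, float, float]:
    """Bacterial growth rate on the two DOM pools.

    The growth law is self-referential: the total rate ``mu_B`` satisfies

        mu_B = nu_mu_B/(1 + mu_B) * [DOM_E/(DOM_E+K_DOME) + DOM_B/(DOM_B+K_DOMB)]

    With ``S`` the bracketed sum of Monod fractions this is the quadratic
    ``mu_B * (1 + mu_B) = nu_mu_B * S``, whose unique nonnegative root

        mu_B = (-1 + sqrt(1 + 4 * nu_mu_B * S)) / 2

    is returned under the default ``quadratic_fixed_point`` resolution.
    Under ``explicit_no_self_term`` the damping factor is dropped and
    ``mu_B = nu_mu_B * S``.

    Returns
    -------
    (mu_B, mu_B_E, mu_B_B)
        Total rate and its per-pool components, split in proportion to the
        Monod fractions (both zero when no substrate is available).
    """
    if DOM_E < 0.0 or DOM_B < 0.0:
        raise DomainError("DOM pools must be >= 0")
    s_e = _monod(DOM_E, params.K_DOME)
    s_b = _monod(DOM_B, params.K_DOMB)
    s = s_e + s_b
    if s == 0.0:
        return 0.0, 0.0, 0.0
    if options.mu_B_resolution == "quadratic_fixed_point":
        mu_b = 0.5 * (-1.0 + math.sqrt(1.0 + 4.0 * params.nu_mu_B * s))
    else:
        mu_b = params.nu_mu_B * s
    return mu_b, mu_b * (s_e / s), mu_b * (s_b / s)


def death_rate_bacterium(mu_B: float, params: ModelParameters) -> float:
    """Growth-damped bacterial death rate ``nu_delta_B / (1 + mu_B)``."""
    if mu_B < 0.0:
        raise DomainError(f"death_rate_bacterium requires mu_B >= 0, got {mu_B}")
    return params.nu_delta_B / (1.0 + mu_B)


def compute_rates(
    state: SystemState | tuple[float, float, float, float],
    params: ModelParameters,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> RateSet:
    """Evaluate all realized rates at one state."""
    if isinstance(state, SystemState):
        _, d, dom_e, dom_b = state.as_array()
    else:
        _, d, dom_e, dom_b = state
    mu_d = growth_rate_diatom(d, params)
    delta_d = death_rate_diatom(mu_d, params)
    mu_b, mu_b_e, mu_b_b = growth_rate_bacterium(dom_e, dom_b, params, options)
    delta_b = death_rate_bacterium(mu_b, params)
    return RateSet(
        mu_D=mu_d, delta_D=delta_d, mu_B=mu_b, mu_B_E=mu_b_e, mu_B_B=mu_b_b, delta_B=delta_b
    )


def ode_rhs(t, state, params: ModelParameters, options: ModelOptions = DEFAULT_OPTIONS):
    """Time derivative of ``(B, D, DOM_E, DOM_B)``.

    ``state`` may be a :class:`SystemState` or any length-4 sequence in the
    order ``B, D, DOM_E, DOM_B``.  Components are clamped to zero before
    rate evaluation so that adaptive steppers that overshoot slightly below
    zero see a well-defined vector field; the clamp does not alter the
    mathematical solution for nonnegative initial data.
    """
    if isinstance(state, SystemState):
        b, d, dom_e, dom_b = state.as_array()
    else:
        b, d, dom_e, dom_b = (float(x) for x in state)
    if not (math.isfinite(b) and math.isfinite(d) and math.isfinite(dom_e) and math.isfinite(dom_b)):
        raise DomainError(f"non-finite state at t={t}: {(b, d, dom_e, dom_b)}")
    b = max(b, 0.0)
    d = max(d, 0.0)
    dom_e = max(dom_e, 0.0)
    dom_b = max(dom_b, 0.0)

    rates = compute_rates((b, d, dom_e, dom_b), params, options)
    lam = params.lam if options.exudation_costs_biomass else 0.0
    db = (rates.mu_B - rates.delta_B) * b
    dd = (rates.mu_D - rates.delta_D - lam) * d

    inv_yield = 1.0 / options.yield_cells_per_dom
    if options.consumption_mode == "split":
        cons_e = rates.mu_B_E * b * inv_yield
        cons_b = rates.mu_B_B * b * inv_yield
    else:  # literal reading of the printed DOM equations
        cons_e = rates.mu_B * b * inv_yield
        cons_b = rates.mu_B * b * inv_yield
    ddom_e = params.lam * d - cons_e - params.delta_DOME * dom_e
    ddom_b = rates.delta_D * d - cons_b - params.delta_DOMB * dom_b
    return (db, dd, ddom_e, ddom_b)
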