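"""Cooling-collar model: power budget, efficiency, and skin-floor guard.

The collar consists of two thermoelectric elements strapped over the
carotid arteries.  A 60 W source drives the elements at an average
conversion efficiency of 60 %, so the collar can pump at most 36 W of
heat out of its cold faces.  A feedback controller keeps the skin
interface from dropping below a safety floor (5 °C).

Two element representations are supported:

``quasi_steady`` (default)
    Elements are massless: at every instant the element temperature
    solves the local heat balance  g_n·(T_n − T_1) + g_e·(T_e − T_1) = P,
    where ``g_n`` is the element–neck contact conductance, ``g_e`` the
    parasitic element–environment conductance and ``P`` the pumped
    power after the floor guard.  The element temperature doubles as
    the skin-interface ("skin temperature") proxy.

``dynamic``
    Elements carry a small heat capacity and are integrated as extra
    state variables; the same guard law modulates the pumped power.

The floor guard is proportional: pumped power scales linearly from full
power down to zero over the last ``guard_band_C`` degrees above
``skin_floor_C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "CollarSpec",
    "CollarState",
    "ElementSolution",
    "effective_extraction",
    "guard_scale",
    "collar_update",
    "solve_element_quasi_steady",
]

MODE_OFF = "off"
MODE_POWER_LIMITED = "power_limited"
MODE_FLOOR_LIMITED = "floor_limited"

ELEMENT_MODES = ("quasi_steady", "dynamic")


@dataclass(frozen=True)
class CollarSpec:
    """Static description of the cooling collar."""

    source_power_W: float = 60.0
    efficiency: float = 0.60
    n_elements: int = 2
    skin_floor_C: float = 5.0
    guard_band_C: float = 1.0
    element_mode: str = "quasi_steady"
    #: heat capacity of one element, only used in ``dynamic`` mode
    element_heat_capacity_J_C: float = 400.0

    def __post_init__(self) -> None:
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError(f"efficiency must be in (0, 1], got {self.efficiency}")
        if self.source_power_W < 0.0:
            raise ValueError("source_power_W must be non-negative")
        if self.n_elements < 1:
            raise ValueError("n_elements must be at least 1")
        if self.guard_band_C <= 0.0:
            raise ValueError("guard_band_C must be positive")
        if self.element_mode not in ELEMENT_MODES:
            raise ValueError(
                f"element_mode must be one of {ELEMENT_MODES}, got {self.element_mode!r}"
            )


@dataclass(frozen=True)
class CollarState:
    """Instantaneous controller state of the collar."""

    active: bool = False
    extraction_per_element: float = 0.0
    element_temperatures: tuple[float, ...] = ()
    controller_mode: str = MODE_OFF


@dataclass(frozen=True)
class ElementSolution:
    """Quasi-steady solution for a single element."""

    temperature_C: float
    extraction_W: float          # heat pumped out of the element cold face
    heat_from_contact_W: float   # heat drawn from the neck through g_n
    mode: str


def effective_extraction(spec: CollarSpec) -> float:
    """Maximum heat-pumping power of the collar: source power x efficiency."""
    return spec.source_power_W * spec.efficiency


def guard_scale(spec: CollarSpec, skin_T: float) -> float:
    """Proportional floor-guard factor in [0, 1] for a given skin temperature."""
    s = (skin_T - spec.skin_floor_C) / spec.guard_band_C
    return min(1.0, max(0.0, s))


def collar_update(state: CollarState, spec: CollarSpec, neck_skin_T: float) -> CollarState:
    """Advance the controller given the current skin-interface temperature.

    When active and well above the floor the collar runs power-limited at
    ``effective_extraction(spec) / n_elements`` per element; within the
    guard band the extraction is scaled down proportionally so the floor
    is never crossed; when inactive extraction is zero.
    """
    if not state.active:
        return replace(state, extraction_per_element=0.0, controller_mode=MODE_OFF)
    scale = guard_scale(spec, neck_skin_T)
    per_element = scale * effective_extraction(spec) / spec.n_elements
    mode = MODE_POWER_LIMITED if scale >= 1.0 else MODE_FLOOR_LIMITED
    return replace(state, extraction_per_element=per_element, controller_mode=mode)


def solve_element_quasi_steady(
    spec: CollarSpec,
    active: bool,
    g_contact: float,
    g_env: float,
    contact_T: float,
    env_T: float,
) -> ElementSolution:
    """Self-consistent massless-element temperature and pumped power.

    The element temperature obeys ``G·(T_passive − T) = P`` with
    ``G = g_contact + g_env`` and the guard law ``P = P_max·scale(T)``.
    Because the guard is piecewise linear in ``T`` the fixed point has a
    closed form in each regime; the regimes are tried in order
    (power-limited, floor-limited, fully throttled).

    Inter-element coupling ``g_12`` is omitted here: with the symmetric
    two-element collar both elements sit at the same temperature and the
    coupling carries no heat.  The ``dynamic`` element mode retains it.
    """
    G = g_contact + g_env
    if G <= 0.0:
        raise ValueError("element must have positive total conductance")
    passive_T = (g_contact * contact_T + g_env * env_T) / G
    if not active:
        return ElementSolution(passive_T, 0.0, g_contact * (contact_T - passive_T), MODE_OFF)

    p_max = effective_extraction(spec) / spec.n_elements
    floor = spec.skin_floor_C
    band = spec.guard_band_C

    # Regime 1: full power keeps the element above the guard band.
    T_full = passive_T - p_max / G
    if T_full >= floor + band:
        return ElementSolution(T_full, p_max, g_contact * (contact_T - T_full), MODE_POWER_LIMITED)
    # Regime 3: even unpowered the interface sits at/below the floor.
    if passive_T <= floor:
        return ElementSolution(passive_T, 0.0, g_contact * (contact_T - passive_T), MODE_FLOOR_LIMITED)
    # Regime 2: guard band.  P = p_max (T - floor)/band with T = passive - P/G.
    P = p_max * G * (passive_T - floor) / (G * band + p_max)
    T = passive_T - P / G
    return ElementSolution(T, P, g_contact * (contact_T - T), MODE_FLOOR_LIMITED)


def element_states(
    spec: CollarSpec,
    active: bool,
    g_contacts: Sequence[float],
    g_envs: Sequence[float],
    contact_T: float,
    env_T: float,
) -> list[ElementSolution]:
    """Quasi-steady solutions for every element of the collar."""
    if len(g_contacts) != spec.n_elements or len(g_envs) != spec.n_elements:
        raise ValueError("one contact and one environment conductance required per element")
    return [
        solve_element_quasi_steady(spec, active, gc, ge, contact_T, env_T)
        for gc, ge in zip(g_contacts, g_envs)
    ]
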