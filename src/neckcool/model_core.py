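"""Thermal network of the head/neck/body system and its ODE right-hand side.

The body is reduced to three perfused tissue compartments — body (b),
head (h) and neck (n) — linked by a single circulatory loop of four
blood nodes: body blood -> neck inflow -> head blood -> neck outflow ->
body blood.  Each node is lumped: its temperature varies in time but is
uniform in space.

Two balance equations generate the dynamics.  For a blood node ``i`` in
contact with tissue ``t``::

    rho_b V_i c_b dT_i/dt = g_it (T_t - T_i) + rho_b c_b phi (T_{i-1} - T_i)

i.e. wall exchange through the vessel conductance ``g_it = h_b S_v``
plus advection by the loop flow ``phi``.  For a tissue node ``t``::

    m_t c_t dT_t/dt = sum_j g_tj (T_j - T_t) + sum_i g_it (T_i - T_t) + Qm_t

summing conduction over every adjacent body (tissue, cooling element or
environment, ``g_tj = lambda_t S_t / L_t``), the reciprocal of the blood
wall-exchange term (so that the loop conserves energy exactly), and the
compartment's metabolic heat.

Units are SI throughout (W, J, kg, m^3, s) with temperatures in °C;
only temperature differences enter the equations, so °C is safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

from .device import (
    CollarSpec,
    ElementSolution,
    effective_extraction,
    guard_scale,
    solve_element_quasi_steady,
)

__all__ = [
    "ENVIRONMENT_ID",
    "CONDUCTION",
    "CONVECTION",
    "TissueNode",
    "BloodNode",
    "BloodProperties",
    "Conductance",
    "EnvironmentNode",
    "CoolingElementNode",
    "ThermalNetwork",
    "NetworkConfigurationError",
    "validate_network",
    "blood_node_derivative",
    "tissue_node_derivative",
    "assemble_rhs",
    "energy_balance",
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
]

ENVIRONMENT_ID = "environment"
CONDUCTION = "conduction"
CONVECTION = "convection"


class NetworkConfigurationError(ValueError):
    """Raised when a thermal network is structurally invalid."""


# ---------------------------------------------------------------------------
# Node and edge types
# ---------------------------------------------------------------------------

@dataclass
class TissueNode:
    """A lumped tissue compartment (body, head or neck)."""

    id: str
    mass_kg: float
    specific_heat_J_kgC: float
    metabolic_heat_W: float = 0.0

    @property
    def heat_capacity_J_C(self) -> float:
        return self.mass_kg * self.specific_heat_J_kgC


@dataclass
class BloodNode:
    """A lumped blood segment of the circulatory loop.

    ``upstream`` names the blood node feeding this one; ``contact_tissue``
    the tissue exchanging heat through the vessel wall conductance
    ``wall_conductance_W_C`` (= h_b S_v).  ``flow_m3_s`` is the loop flow,
    identical along the closed cycle.
    """

    id: str
    volume_m3: float
    upstream: str
    contact_tissue: str
    wall_conductance_W_C: float
    flow_m3_s: float


@dataclass
class BloodProperties:
    density_kg_m3: float = 1050.0
    specific_heat_J_kgC: float = 3617.0


@dataclass
class Conductance:
    """A symmetric heat-exchange edge: q(a->b) = g (T_a - T_b)."""

    from_id: str
    to_id: str
    g_W_C: float
    kind: str = CONDUCTION

    def touches(self, node_id: str) -> bool:
        return node_id in (self.from_id, self.to_id)

    def other(self, node_id: str) -> str:
        if node_id == self.from_id:
            return self.to_id
        if node_id == self.to_id:
            return self.from_id
        raise KeyError(node_id)


@dataclass
class EnvironmentNode:
    """Fixed-temperature boundary condition."""

    temperature_C: float = 24.0


@dataclass
class CoolingElementNode:
    """One thermoelectric element of the collar (see :mod:`neckcool.device`)."""

    id: str


@dataclass
class ThermalNetwork:
    tissues: list[TissueNode] = field(default_factory=list)
    blood: list[BloodNode] = field(default_factory=list)
    blood_props: BloodProperties = field(default_factory=BloodProperties)
    conductances: list[Conductance] = field(default_factory=list)
    environment: EnvironmentNode = field(default_factory=EnvironmentNode)
    elements: list[CoolingElementNode] = field(default_factory=list)

    # -- lookups -----------------------------------------------------------
    def tissue(self, node_id: str) -> TissueNode:
        for t in self.tissues:
            if t.id == node_id:
                return t
        raise KeyError(f"no tissue node {node_id!r}")

    def blood_node(self, node_id: str) -> BloodNode:
        for b in self.blood:
            if b.id == node_id:
                return b
        raise KeyError(f"no blood node {node_id!r}")

    def node_ids(self) -> list[str]:
        """All named internal nodes plus the environment."""
        return (
            [t.id for t in self.tissues]
            + [b.id for b in self.blood]
            + [e.id for e in self.elements]
            + [ENVIRONMENT_ID]
        )

    def state_ids(self, dynamic_elements: bool = False) -> list[str]:
        """State-vector ordering: tissues, then blood, then (optionally) elements."""
        ids = [t.id for t in self.tissues] + [b.id for b in self.blood]
        if dynamic_elements:
            ids += [e.id for e in self.elements]
        return ids

    def heat_capacities(self, dynamic_elements: bool = False,
                        element_capacity_J_C: float = 0.0) -> np.ndarray:
        rho_c = self.blood_props.density_kg_m3 * self.blood_props.specific_heat_J_kgC
        caps = [t.heat_capacity_J_C for t in self.tissues]
        caps += [rho_c * b.volume_m3 for b in self.blood]
        if dynamic_elements:
            caps += [element_capacity_J_C] * len(self.elements)
        return np.asarray(caps, dtype=float)

    def blood_heat_capacity_J_C(self, node: BloodNode) -> float:
        return (self.blood_props.density_kg_m3
                * self.blood_props.specific_heat_J_kgC
                * node.volume_m3)

    def element_couplings(self, element_id: str) -> tuple[float, float]:
        """(tissue-contact conductance, environment conductance) of one element.

        Sums conduction edges from the element to tissues and to the
        environment respectively; element–element edges are excluded.
        """
        tissue_ids = {t.id for t in self.tissues}
        g_contact = 0.0
        g_env = 0.0
        for c in self.conductances:
            if c.kind != CONDUCTION or not c.touches(element_id):
                continue
            other = c.other(element_id)
            if other in tissue_ids:
                g_contact += c.g_W_C
            elif other == ENVIRONMENT_ID:
                g_env += c.g_W_C
        return g_contact, g_env

    def element_contact_tissue(self, element_id: str) -> str:
        tissue_ids = {t.id for t in self.tissues}
        contacts = [
            c.other(element_id)
            for c in self.conductances
            if c.kind == CONDUCTION and c.touches(element_id)
            and c.other(element_id) in tissue_ids
        ]
        if len(set(contacts)) != 1:
            raise NetworkConfigurationError(
                f"element {element_id!r} must contact exactly one tissue, "
                f"found {sorted(set(contacts))}"
            )
        return contacts[0]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_network(net: ThermalNetwork) -> list[str]:
    """Return human-readable diagnostics; an empty list means the network is valid."""
    diags: list[str] = []
    tissue_ids = [t.id for t in net.tissues]
    blood_ids = [b.id for b in net.blood]
    element_ids = [e.id for e in net.elements]
    all_ids = tissue_ids + blood_ids + element_ids + [ENVIRONMENT_ID]

    for ids, label in ((tissue_ids, "tissue"), (blood_ids, "blood"), (element_ids, "element")):
        if len(set(ids)) != len(ids):
            diags.append(f"duplicate {label} node ids: {ids}")

    for t in net.tissues:
        if t.mass_kg <= 0:
            diags.append(f"tissue {t.id!r}: mass_kg must be positive, got {t.mass_kg}")
        if t.specific_heat_J_kgC <= 0:
            diags.append(f"tissue {t.id!r}: specific_heat_J_kgC must be positive")
        if t.metabolic_heat_W < 0:
            diags.append(f"tissue {t.id!r}: metabolic_heat_W must be non-negative")

    if net.blood_props.density_kg_m3 <= 0:
        diags.append("blood density_kg_m3 must be positive")
    if net.blood_props.specific_heat_J_kgC <= 0:
        diags.append("blood specific_heat_J_kgC must be positive")

    flows = set()
    for b in net.blood:
        if b.volume_m3 <= 0:
            diags.append(f"blood node {b.id!r}: volume_m3 must be positive, got {b.volume_m3}")
        if b.flow_m3_s <= 0:
            diags.append(f"blood node {b.id!r}: flow_m3_s must be positive")
        if b.wall_conductance_W_C < 0:
            diags.append(f"blood node {b.id!r}: wall_conductance_W_C must be non-negative")
        if b.contact_tissue not in tissue_ids:
            diags.append(f"blood node {b.id!r}: contact tissue {b.contact_tissue!r} not found")
        if b.upstream not in blood_ids:
            diags.append(f"blood node {b.id!r}: upstream node {b.upstream!r} not found")
        flows.add(b.flow_m3_s)
    if len(flows) > 1:
        diags.append(f"loop flow must be identical on every blood node, got {sorted(flows)}")

    # The upstream pointers must form one closed cycle covering all blood nodes.
    if net.blood and all(b.upstream in blood_ids for b in net.blood):
        upstream = {b.id: b.upstream for b in net.blood}
        if len(set(upstream.values())) != len(upstream):
            shared = [u for u in upstream.values() if list(upstream.values()).count(u) > 1]
            diags.append(f"blood nodes {sorted(set(shared))} feed more than one downstream node")
        else:
            seen = [blood_ids[0]]
            while upstream[seen[-1]] not in seen:
                seen.append(upstream[seen[-1]])
            if len(seen) != len(blood_ids):
                missing = sorted(set(blood_ids) - set(seen))
                diags.append(f"blood loop is not a single closed cycle; unreached: {missing}")

    for c in net.conductances:
        if c.g_W_C < 0:
            diags.append(f"conductance {c.from_id}->{c.to_id}: g_W_C must be non-negative")
        for endpoint in (c.from_id, c.to_id):
            if endpoint not in all_ids:
                diags.append(f"conductance {c.from_id}->{c.to_id}: unknown endpoint {endpoint!r}")
        if c.kind == CONDUCTION and (c.from_id in blood_ids or c.to_id in blood_ids):
            diags.append(f"conduction edge {c.from_id}->{c.to_id} may not touch a blood node")
        if c.kind == CONVECTION:
            pair = {c.from_id, c.to_id}
            matches = [b for b in net.blood if b.id in pair and b.contact_tissue in pair]
            if not matches:
                diags.append(
                    f"convection edge {c.from_id}->{c.to_id} does not match any "
                    "blood-node/contact-tissue pair"
                )
            elif abs(matches[0].wall_conductance_W_C - c.g_W_C) > 1e-12 * max(1.0, c.g_W_C):
                diags.append(
                    f"convection edge {c.from_id}->{c.to_id}: g={c.g_W_C} disagrees with "
                    f"wall_conductance_W_C={matches[0].wall_conductance_W_C}"
                )
        if c.kind not in (CONDUCTION, CONVECTION):
            diags.append(f"conductance {c.from_id}->{c.to_id}: unknown kind {c.kind!r}")

    return diags


def _require_valid(net: ThermalNetwork) -> None:
    diags = validate_network(net)
    if diags:
        raise NetworkConfigurationError("; ".join(diags))


# ---------------------------------------------------------------------------
# Per-node derivatives (reference scalar path)
# ---------------------------------------------------------------------------

def blood_node_derivative(
    node: BloodNode, net: ThermalNetwork, temps: Mapping[str, float]
) -> float:
    """dT_i/dt of one blood node, °C/s.

    ``temps`` maps node ids (including the contact tissue and upstream
    blood node) to temperatures.
    """
    if node.volume_m3 <= 0:
        raise NetworkConfigurationError(f"blood node {node.id!r}: non-positive volume")
    try:
        t_up = temps[node.upstream]
    except KeyError as exc:
        raise NetworkConfigurationError(
            f"blood node {node.id!r}: upstream temperature {node.upstream!r} unresolved"
        ) from exc
    t_tissue = temps[node.contact_tissue]
    t_i = temps[node.id]
    rho = net.blood_props.density_kg_m3
    c_b = net.blood_props.specific_heat_J_kgC
    q = node.wall_conductance_W_C * (t_tissue - t_i) + rho * c_b * node.flow_m3_s * (t_up - t_i)
    return q / (rho * node.volume_m3 * c_b)


def tissue_node_derivative(
    node: TissueNode,
    net: ThermalNetwork,
    temps: Mapping[str, float],
    extra_heat_W: float = 0.0,
) -> float:
    """dT_t/dt of one tissue node, °C/s.

    Sums conduction over every adjacent body (tissue, element,
    environment), the reciprocal wall-exchange term of every blood node
    in contact, the metabolic heat, and an optional extra heat input
    (negative for an external sink).  Element temperatures must be
    present in ``temps``; the environment temperature is taken from the
    network if absent.
    """
    t_t = temps[node.id]
    q = node.metabolic_heat_W + extra_heat_W
    for c in net.conductances:
        if c.kind != CONDUCTION or not c.touches(node.id):
            continue
        other = c.other(node.id)
        t_other = net.environment.temperature_C if other == ENVIRONMENT_ID else temps[other]
        q += c.g_W_C * (t_other - t_t)
    for b in net.blood:
        if b.contact_tissue == node.id:
            q += b.wall_conductance_W_C * (temps[b.id] - t_t)
    return q / node.heat_capacity_J_C


# ---------------------------------------------------------------------------
# Vectorized right-hand side
# ---------------------------------------------------------------------------

class _RhsContext:
    """Precomputed index arrays for fast evaluation of the network ODEs."""

    def __init__(self, net: ThermalNetwork, collar: CollarSpec | None, active: bool):
        self.net = net
        self.collar = collar
        self.active = bool(active)
        self.dynamic = collar is not None and collar.element_mode == "dynamic"

        self.tissue_ids = [t.id for t in net.tissues]
        self.blood_ids = [b.id for b in net.blood]
        self.element_ids = [e.id for e in net.elements]
        self.n_t = len(self.tissue_ids)
        self.n_b = len(self.blood_ids)
        self.n_e = len(self.element_ids)
        self.n_state = self.n_t + self.n_b + (self.n_e if self.dynamic else 0)

        self.C_t = np.array([t.heat_capacity_J_C for t in net.tissues])
        self.Qm = np.array([t.metabolic_heat_W for t in net.tissues])
        rho = net.blood_props.density_kg_m3
        c_b = net.blood_props.specific_heat_J_kgC
        self.C_b = np.array([rho * c_b * b.volume_m3 for b in net.blood])
        self.g_wall = np.array([b.wall_conductance_W_C for b in net.blood])
        self.mdot_c = np.array([rho * c_b * b.flow_m3_s for b in net.blood])
        tidx = {tid: k for k, tid in enumerate(self.tissue_ids)}
        bidx = {bid: k for k, bid in enumerate(self.blood_ids)}
        self.contact_idx = np.array([tidx[b.contact_tissue] for b in net.blood], dtype=int)
        self.upstream_idx = np.array([bidx[b.upstream] for b in net.blood], dtype=int)

        # Conduction graph over [tissues, elements, environment].
        solid_index = {tid: k for k, tid in enumerate(self.tissue_ids)}
        solid_index.update(
            {eid: self.n_t + k for k, eid in enumerate(self.element_ids)})
        solid_index[ENVIRONMENT_ID] = self.n_t + self.n_e
        ia, ib, gg = [], [], []
        for c in net.conductances:
            if c.kind != CONDUCTION:
                continue
            ia.append(solid_index[c.from_id])
            ib.append(solid_index[c.to_id])
            gg.append(c.g_W_C)
        self.edge_a = np.array(ia, dtype=int)
        self.edge_b = np.array(ib, dtype=int)
        self.edge_g = np.array(gg)

        if self.n_e and not self.dynamic:
            self.elem_couplings = [net.element_couplings(eid) for eid in self.element_ids]
            # quasi-steady elements need a well-posed local balance
            for eid, (gc, ge) in zip(self.element_ids, self.elem_couplings):
                if gc + ge <= 0:
                    raise NetworkConfigurationError(
                        f"element {eid!r} has no conductance; quasi-steady solve impossible"
                    )
            self.elem_contact_tidx = np.array(
                [tidx[net.element_contact_tissue(eid)] for eid in self.element_ids], dtype=int
            )

    # -- element boundary --------------------------------------------------
    def element_solutions(self, T_t: np.ndarray) -> list[ElementSolution]:
        """Quasi-steady element temperatures/powers given tissue temperatures."""
        T_env = self.net.environment.temperature_C
        out = []
        for k, (gc, ge) in enumerate(self.elem_couplings):
            contact_T = float(T_t[self.elem_contact_tidx[k]])
            out.append(
                solve_element_quasi_steady(self.collar or CollarSpec(),
                                           self.active, gc, ge, contact_T, T_env)
            )
        return out

    def element_pumped_power(self, T_e: np.ndarray) -> np.ndarray:
        """Guard-modulated pumped power per element in dynamic mode."""
        if not self.active or self.collar is None:
            return np.zeros(self.n_e)
        p_max = effective_extraction(self.collar) / self.collar.n_elements
        return np.array([p_max * guard_scale(self.collar, float(T)) for T in T_e])

    # -- rhs ---------------------------------------------------------------
    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        if y.shape[-1] != self.n_state:
            raise ValueError(
                f"state vector has length {y.shape[-1]}, expected {self.n_state}"
            )
        T_t = y[: self.n_t]
        T_b = y[self.n_t: self.n_t + self.n_b]
        if self.dynamic:
            T_e = y[self.n_t + self.n_b:]
        elif self.n_e:
            T_e = np.array([s.temperature_C for s in self.element_solutions(T_t)])
        else:
            T_e = np.empty(0)

        T_solid = np.concatenate([T_t, T_e, [self.net.environment.temperature_C]])
        q_solid = np.zeros(self.n_t + self.n_e + 1)
        dq = self.edge_g * (T_solid[self.edge_b] - T_solid[self.edge_a])
        np.add.at(q_solid, self.edge_a, dq)
        np.add.at(q_solid, self.edge_b, -dq)

        q_tissue = q_solid[: self.n_t] + self.Qm
        wall = self.g_wall * (T_b - T_t[self.contact_idx])
        np.add.at(q_tissue, self.contact_idx, wall)

        dT_t = q_tissue / self.C_t
        dT_b = (self.g_wall * (T_t[self.contact_idx] - T_b)
                + self.mdot_c * (T_b[self.upstream_idx] - T_b)) / self.C_b
        if self.dynamic:
            q_elem = q_solid[self.n_t: self.n_t + self.n_e] - self.element_pumped_power(T_e)
            dT_e = q_elem / self.collar.element_heat_capacity_J_C
            return np.concatenate([dT_t, dT_b, dT_e])
        return np.concatenate([dT_t, dT_b])


def assemble_rhs(
    net: ThermalNetwork,
    collar: CollarSpec | None = None,
    active: bool = False,
) -> _RhsContext:
    """Build the vectorized right-hand side ``f(t, y) -> dy/dt``.

    State ordering is fixed: tissue temperatures in catalog order (body,
    head, neck), then blood temperatures (loop order), then element
    temperatures when the collar runs in ``dynamic`` element mode.  In
    the default ``quasi_steady`` mode the element temperatures are
    solved algebraically inside each evaluation and are not state
    variables.  With ``collar=None`` the elements behave as an inactive
    quasi-steady collar (passive conduction path only).
    """
    _require_valid(net)
    return _RhsContext(net, collar, active)


# ---------------------------------------------------------------------------
# Energy bookkeeping
# ---------------------------------------------------------------------------

def energy_balance(
    net: ThermalNetwork,
    temps: Mapping[str, float],
    collar: CollarSpec | None = None,
    active: bool = False,
) -> dict[str, float]:
    """Explicit global energy audit at a given state.

    Returns the instantaneous storage rate ``sum_k C_k dT_k/dt``, the
    total metabolic input, the net heat flow to the environment through
    direct tissue–environment edges, and the heat the collar removes
    from the network.  By construction
    ``storage = metabolic - environment - collar`` holds exactly; the
    residual is reported for verification.

    In quasi-steady element mode the collar term is the heat crossing
    the element–tissue contacts (the parasitic environment->element leak
    stays inside the device).  In dynamic mode elements are internal
    nodes: the collar term is the pumped power and element–environment
    edges count as environment flow.
    """
    rhs = assemble_rhs(net, collar, active)
    y = np.array([temps[i] for i in net.state_ids(dynamic_elements=rhs.dynamic)])
    dy = rhs(0.0, y)
    caps = net.heat_capacities(
        dynamic_elements=rhs.dynamic,
        element_capacity_J_C=(collar.element_heat_capacity_J_C if rhs.dynamic else 0.0),
    )
    storage = float(np.sum(caps * dy))
    metabolic = float(sum(t.metabolic_heat_W for t in net.tissues))

    T_env = net.environment.temperature_C
    tissue_ids = {t.id for t in net.tissues}
    element_ids = {e.id for e in net.elements}
    env_flow = 0.0
    for c in net.conductances:
        if c.kind != CONDUCTION or not c.touches(ENVIRONMENT_ID):
            continue
        other = c.other(ENVIRONMENT_ID)
        if other in tissue_ids:
            env_flow += c.g_W_C * (temps[other] - T_env)
        elif other in element_ids and rhs.dynamic:
            env_flow += c.g_W_C * (temps[other] - T_env)

    if rhs.dynamic:
        T_e = np.array([temps[e.id] for e in net.elements])
        collar_heat = float(np.sum(rhs.element_pumped_power(T_e)))
    elif net.elements:
        T_t = np.array([temps[t.id] for t in net.tissues])
        sols = rhs.element_solutions(T_t)
        collar_heat = float(sum(s.heat_from_contact_W for s in sols))
    else:
        collar_heat = 0.0

    return {
        "storage_rate_W": storage,
        "metabolic_W": metabolic,
        "environment_flow_W": env_flow,
        "collar_heat_W": collar_heat,
        "residual_W": storage - (metabolic - env_flow - collar_heat),
    }


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def network_to_dict(net: ThermalNetwork) -> dict:
    return {
        "blood_properties": asdict(net.blood_props),
        "environment": asdict(net.environment),
        "tissues": [asdict(t) for t in net.tissues],
        "blood_nodes": [asdict(b) for b in net.blood],
        "elements": [asdict(e) for e in net.elements],
        "conductances": [asdict(c) for c in net.conductances],
    }


def network_from_dict(data: dict) -> ThermalNetwork:
    try:
        net = ThermalNetwork(
            tissues=[TissueNode(**t) for t in data.get("tissues", [])],
            blood=[BloodNode(**b) for b in data.get("blood_nodes", [])],
            blood_props=BloodProperties(**data.get("blood_properties", {})),
            conductances=[Conductance(**c) for c in data.get("conductances", [])],
            environment=EnvironmentNode(**data.get("environment", {})),
            elements=[CoolingElementNode(**e) for e in data.get("elements", [])],
        )
    except TypeError as exc:
        raise NetworkConfigurationError(f"malformed network mapping: {exc}") from exc
    return net


def save_network(net: ThermalNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=False)


def load_network(path) -> ThermalNetwork:
    with open(path) as fh:
        return network_from_dict(yaml.safe_load(fh))
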