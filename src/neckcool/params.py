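"""Species parameter catalogs (sheep, 70 kg human) and the config reader.

A :class:`ParameterSet` holds everything needed to instantiate the
three-compartment thermal network and its collar: tissue masses and
specific heats, blood properties and segment volumes, the loop flow,
every conductance, the metabolic budget and its partition, and the
collar spec.  Each value carries a provenance note — ``supplement``
(transcribed from the published parameter table), ``literature-default``
(standard physiological value) or ``calibrated`` (fitted against the
experimental summaries).

Two catalogs are bundled as YAML files (``data/sheep_default.yaml``,
``data/human_default.yaml``).  The basal metabolic budget defaults to
1200 kcal/day (~58.1 W), interpreted per day — the only physically
plausible reading for basal metabolism.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

from .device import CollarSpec
from .model_core import (
    CONDUCTION,
    CONVECTION,
    ENVIRONMENT_ID,
    BloodNode,
    BloodProperties,
    Conductance,
    CoolingElementNode,
    EnvironmentNode,
    NetworkConfigurationError,
    ThermalNetwork,
    TissueNode,
    validate_network,
)

__all__ = [
    "KCAL_PER_DAY_TO_W",
    "TISSUE_IDS",
    "BLOOD_IDS",
    "ELEMENT_IDS",
    "ParameterSet",
    "ParameterError",
    "load_parameters",
    "default_parameters",
    "save_parameters",
    "build_network",
    "build_collar",
]

#: 1 kcal/day expressed in watts.
KCAL_PER_DAY_TO_W = 4184.0 / 86400.0

TISSUE_IDS = ("body", "head", "neck")
#: Loop order: body blood feeds the neck inflow, which feeds the head, etc.
BLOOD_IDS = ("blood_neck_in", "blood_head", "blood_neck_out", "blood_body")
_UPSTREAM = {
    "blood_neck_in": "blood_body",
    "blood_head": "blood_neck_in",
    "blood_neck_out": "blood_head",
    "blood_body": "blood_neck_out",
}
_CONTACT = {
    "blood_neck_in": "neck",
    "blood_head": "head",
    "blood_neck_out": "neck",
    "blood_body": "body",
}
ELEMENT_IDS = ("element_1", "element_2")

PROVENANCE_KINDS = ("supplement", "literature-default", "calibrated")


class ParameterError(ValueError):
    """Raised for schema violations or unphysical parameter values."""


# ---------------------------------------------------------------------------
# ParameterSet
# ---------------------------------------------------------------------------

_SCHEMA: dict[str, Any] = {
    "species": str,
    "body_mass_kg": float,
    "environment_T_C": float,
    "metabolic_total_kcal_day": float,
    "metabolic_shares": {"body": float, "head": float, "neck": float},
    "tissues": {
        tid: {"mass_kg": float, "specific_heat_J_kgC": float} for tid in TISSUE_IDS
    },
    "blood": {"density_kg_m3": float, "specific_heat_J_kgC": float},
    "blood_nodes": {
        bid: {"volume_m3": float, "wall_conductance_W_C": float} for bid in BLOOD_IDS
    },
    "flow_m3_s": float,
    "conductances": {"g_be": float, "g_he": float, "g_bn": float, "g_nh": float},
    "collar": {
        "source_power_W": float,
        "efficiency": float,
        "n_elements": int,
        "skin_floor_C": float,
        "guard_band_C": float,
        "element_mode": str,
        "element_heat_capacity_J_C": float,
        "g_elem_neck_W_C": float,
        "g_elem_env_W_C": float,
        "g_elem_elem_W_C": float,
    },
    "provenance": dict,
}

#: physical quantities that must be strictly positive
_POSITIVE = {
    "body_mass_kg",
    "metabolic_total_kcal_day",
    "tissues.*.mass_kg",
    "tissues.*.specific_heat_J_kgC",
    "blood.density_kg_m3",
    "blood.specific_heat_J_kgC",
    "blood_nodes.*.volume_m3",
    "flow_m3_s",
}
#: quantities that must be non-negative
_NON_NEGATIVE = {
    "blood_nodes.*.wall_conductance_W_C",
    "conductances.*",
    "collar.g_elem_neck_W_C",
    "collar.g_elem_env_W_C",
    "collar.g_elem_elem_W_C",
    "collar.source_power_W",
}


@dataclass
class ParameterSet:
    """A named species configuration with all physical constants."""

    species: str
    body_mass_kg: float
    environment_T_C: float
    metabolic_total_kcal_day: float
    metabolic_shares: dict[str, float]
    tissues: dict[str, dict[str, float]]
    blood: dict[str, float]
    blood_nodes: dict[str, dict[str, float]]
    flow_m3_s: float
    conductances: dict[str, float]
    collar: dict[str, Any]
    provenance: dict[str, str] = field(default_factory=dict)

    # -- derived -----------------------------------------------------------
    @property
    def metabolic_total_W(self) -> float:
        return self.metabolic_total_kcal_day * KCAL_PER_DAY_TO_W

    def metabolic_heat_W(self, tissue_id: str) -> float:
        return self.metabolic_total_W * self.metabolic_shares[tissue_id]

    # -- dotted-path access (used by the calibrator) ------------------------
    def get(self, path: str) -> Any:
        obj: Any = self.to_dict()
        for part in path.split("."):
            obj = obj[part]
        return obj

    def with_value(self, path: str, value: Any, provenance: str = "calibrated") -> "ParameterSet":
        """Return a copy with ``path`` set to ``value`` and flagged accordingly."""
        data = self.to_dict()
        obj = data
        parts = path.split(".")
        for part in parts[:-1]:
            obj = obj[part]
        if parts[-1] not in obj:
            raise ParameterError(f"unknown parameter path {path!r}")
        obj[parts[-1]] = value
        data.setdefault("provenance", {})[path] = provenance
        return ParameterSet.from_dict(data)

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return copy.deepcopy(
            {
                "species": self.species,
                "body_mass_kg": self.body_mass_kg,
                "environment_T_C": self.environment_T_C,
                "metabolic_total_kcal_day": self.metabolic_total_kcal_day,
                "metabolic_shares": self.metabolic_shares,
                "tissues": self.tissues,
                "blood": self.blood,
                "blood_nodes": self.blood_nodes,
                "flow_m3_s": self.flow_m3_s,
                "conductances": self.conductances,
                "collar": self.collar,
                "provenance": self.provenance,
            }
        )

    @classmethod
    def from_dict(cls, data: dict, fill_defaults: bool = False) -> "ParameterSet":
        if fill_defaults:
            species = data.get("species")
            if species is None:
                raise ParameterError("missing required key: species")
            base = default_parameters(str(species)).to_dict()
            data = _merge_with_defaults(data, base)
        _check_schema(data, _SCHEMA, prefix="")
        _check_physical(data)
        ps = cls(**{k: data[k] for k in _SCHEMA})
        ps._validate_consistency()
        return ps

    def _validate_consistency(self) -> None:
        shares = self.metabolic_shares
        if abs(sum(shares.values()) - 1.0) > 1e-6:
            raise ParameterError(
                f"metabolic_shares must sum to 1, got {sum(shares.values()):.6f}"
            )
        for sid, s in shares.items():
            if not (0.0 <= s <= 1.0):
                raise ParameterError(f"metabolic_shares.{sid} out of [0, 1]: {s}")
        blood_mass = self.blood["density_kg_m3"] * sum(
            bn["volume_m3"] for bn in self.blood_nodes.values()
        )
        tissue_mass = sum(t["mass_kg"] for t in self.tissues.values())
        total = blood_mass + tissue_mass
        if abs(total - self.body_mass_kg) > 0.02 * self.body_mass_kg:
            raise ParameterError(
                f"tissue+blood mass {total:.2f} kg inconsistent with "
                f"body_mass_kg {self.body_mass_kg:.2f}"
            )


# ---------------------------------------------------------------------------
# Schema helpers
# ---------------------------------------------------------------------------

def _check_schema(data: Any, schema: Any, prefix: str) -> None:
    if isinstance(schema, dict):
        if schema is dict or not isinstance(data, dict):
            if not isinstance(data, dict):
                raise ParameterError(f"{prefix or '<root>'} must be a mapping")
        unknown = set(data) - set(schema)
        if unknown:
            raise ParameterError(
                f"unknown key{'s' if len(unknown) > 1 else ''}: "
                + ", ".join(sorted(f"{prefix}{k}" for k in unknown))
            )
        missing = set(schema) - set(data)
        if missing:
            raise ParameterError(
                "missing key" + ("s: " if len(missing) > 1 else ": ")
                + ", ".join(sorted(f"{prefix}{k}" for k in missing))
            )
        for key, sub in schema.items():
            _check_schema(data[key], sub, f"{prefix}{key}.")
    elif schema is dict:
        if not isinstance(data, dict):
            raise ParameterError(f"{prefix[:-1]} must be a mapping")
    elif schema is float:
        if isinstance(data, bool) or not isinstance(data, (int, float)):
            raise ParameterError(f"{prefix[:-1]} must be a number, got {data!r}")
    elif schema is int:
        if isinstance(data, bool) or not isinstance(data, int):
            raise ParameterError(f"{prefix[:-1]} must be an integer, got {data!r}")
    elif schema is str:
        if not isinstance(data, str):
            raise ParameterError(f"{prefix[:-1]} must be a string, got {data!r}")


def _match_pattern(path: str, pattern: str) -> bool:
    p_parts = path.split(".")
    q_parts = pattern.split(".")
    if len(p_parts) != len(q_parts):
        return False
    return all(q == "*" or p == q for p, q in zip(p_parts, q_parts))


def _iter_numeric(data: Any, prefix: str = ""):
    if isinstance(data, dict):
        for k, v in data.items():
            yield from _iter_numeric(v, f"{prefix}{k}.")
    elif isinstance(data, (int, float)) and not isinstance(data, bool):
        yield prefix[:-1], float(data)


def _check_physical(data: dict) -> None:
    for path, value in _iter_numeric({k: v for k, v in data.items() if k != "provenance"}):
        if any(_match_pattern(path, pat) for pat in _POSITIVE) and value <= 0:
            raise ParameterError(f"{path} must be positive, got {value}")
        if any(_match_pattern(path, pat) for pat in _NON_NEGATIVE) and value < 0:
            raise ParameterError(f"{path} must be non-negative, got {value}")


def _merge_with_defaults(data: dict, base: dict) -> dict:
    """Overlay a (possibly partial) user mapping onto the species defaults.

    Keys absent from the user file are taken from the bundled catalog and
    flagged ``literature-default`` unless the catalog marks them otherwise;
    keys the user supplies keep the user's provenance entry if given, else
    are flagged ``calibrated`` (an explicit override).
    """
    merged = copy.deepcopy(base)
    user_prov = dict(data.get("provenance", {}))

    def overlay(dst: dict, src: dict, prefix: str) -> None:
        for key, val in src.items():
            if key == "provenance":
                continue
            path = f"{prefix}{key}"
            if isinstance(val, dict) and isinstance(dst.get(key), dict):
                overlay(dst[key], val, f"{path}.")
            else:
                dst[key] = val
                if path != "species":
                    merged["provenance"][path] = user_prov.get(path, "calibrated")

    overlay(merged, data, "")
    merged["provenance"].update(user_prov)
    return merged


# ---------------------------------------------------------------------------
# Catalog I/O
# ---------------------------------------------------------------------------

def default_parameters(species: str) -> ParameterSet:
    """The bundled catalog for ``sheep`` or ``human``."""
    if species not in ("sheep", "human"):
        raise ParameterError(f"no bundled catalog for species {species!r}")
    ref = resources.files("neckcool").joinpath(f"data/{species}_default.yaml")
    data = yaml.safe_load(ref.read_text())
    return ParameterSet.from_dict(data)


def load_parameters(path) -> ParameterSet:
    """Read a parameter file, filling unspecified keys from the species defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParameterError("parameter file must contain a mapping")
    return ParameterSet.from_dict(data, fill_defaults=True)


def save_parameters(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_network(params: ParameterSet) -> ThermalNetwork:
    """Instantiate the canonical three-compartment/four-blood-node topology."""
    tissues = [
        TissueNode(
            id=tid,
            mass_kg=params.tissues[tid]["mass_kg"],
            specific_heat_J_kgC=params.tissues[tid]["specific_heat_J_kgC"],
            metabolic_heat_W=params.metabolic_heat_W(tid),
        )
        for tid in TISSUE_IDS
    ]
    blood = [
        BloodNode(
            id=bid,
            volume_m3=params.blood_nodes[bid]["volume_m3"],
            upstream=_UPSTREAM[bid],
            contact_tissue=_CONTACT[bid],
            wall_conductance_W_C=params.blood_nodes[bid]["wall_conductance_W_C"],
            flow_m3_s=params.flow_m3_s,
        )
        for bid in BLOOD_IDS
    ]
    g = params.conductances
    edges = [
        Conductance("body", ENVIRONMENT_ID, g["g_be"], CONDUCTION),
        Conductance("head", ENVIRONMENT_ID, g["g_he"], CONDUCTION),
        Conductance("body", "neck", g["g_bn"], CONDUCTION),
        Conductance("neck", "head", g["g_nh"], CONDUCTION),
    ]
    c = params.collar
    for eid in ELEMENT_IDS[: int(c["n_elements"])]:
        edges.append(Conductance(eid, "neck", c["g_elem_neck_W_C"], CONDUCTION))
        edges.append(Conductance(eid, ENVIRONMENT_ID, c["g_elem_env_W_C"], CONDUCTION))
    if int(c["n_elements"]) == 2:
        edges.append(
            Conductance("element_1", "element_2", c["g_elem_elem_W_C"], CONDUCTION)
        )
    # convection edges mirror the blood wall conductances
    for bn in blood:
        edges.append(
            Conductance(bn.id, bn.contact_tissue, bn.wall_conductance_W_C, CONVECTION)
        )
    net = ThermalNetwork(
        tissues=tissues,
        blood=blood,
        blood_props=BloodProperties(
            density_kg_m3=params.blood["density_kg_m3"],
            specific_heat_J_kgC=params.blood["specific_heat_J_kgC"],
        ),
        conductances=edges,
        environment=EnvironmentNode(temperature_C=params.environment_T_C),
        elements=[CoolingElementNode(id=eid) for eid in ELEMENT_IDS[: int(c["n_elements"])]],
    )
    diags = validate_network(net)
    if diags:
        raise NetworkConfigurationError("; ".join(diags))
    return net


def build_collar(params: ParameterSet) -> CollarSpec:
    c = params.collar
    return CollarSpec(
        source_power_W=float(c["source_power_W"]),
        efficiency=float(c["efficiency"]),
        n_elements=int(c["n_elements"]),
        skin_floor_C=float(c["skin_floor_C"]),
        guard_band_C=float(c["guard_band_C"]),
        element_mode=str(c["element_mode"]),
        element_heat_capacity_J_C=float(c["element_heat_capacity_J_C"]),
    )
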