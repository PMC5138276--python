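import numpy as np
import pytest

from neckcool import (
    BloodNode,
    BloodProperties,
    Conductance,
    CoolingElementNode,
    EnvironmentNode,
    ThermalNetwork,
    TissueNode,
    build_collar,
    build_network,
    default_parameters,
)
from neckcool.model_core import CONDUCTION, CONVECTION, ENVIRONMENT_ID


@pytest.fixture(scope="session")
def sheep_params():
    return default_parameters("sheep")


@pytest.fixture(scope="session")
def human_params():
    return default_parameters("human")


@pytest.fixture(scope="session")
def sheep_net(sheep_params):
    return build_network(sheep_params)


@pytest.fixture(scope="session")
def sheep_collar(sheep_params):
    return build_collar(sheep_params)


def make_random_network(
    rng: np.random.Generator,
    with_elements: bool = False,
    zero_sources: bool = False,
) -> ThermalNetwork:
    """A random valid network: 2-3 tissues, a closed blood loop, random edges."""
    n_t = int(rng.integers(2, 4))
    tissues = [
        TissueNode(
            id=f"t{k}",
            mass_kg=float(rng.uniform(0.5, 50.0)),
            specific_heat_J_kgC=float(rng.uniform(2000.0, 4500.0)),
            metabolic_heat_W=0.0 if zero_sources else float(rng.uniform(0.0, 40.0)),
        )
        for k in range(n_t)
    ]
    n_b = int(rng.integers(2, 5))
    blood_ids = [f"v{k}" for k in range(n_b)]
    flow = float(rng.uniform(1e-6, 3e-5))
    blood = [
        BloodNode(
            id=blood_ids[k],
            volume_m3=float(rng.uniform(1e-5, 4e-3)),
            upstream=blood_ids[(k - 1) % n_b],
            contact_tissue=tissues[int(rng.integers(0, n_t))].id,
            wall_conductance_W_C=float(rng.uniform(0.0, 60.0)),
            flow_m3_s=flow,
        )
        for k in range(n_b)
    ]
    edges = [
        Conductance(b.id, b.contact_tissue, b.wall_conductance_W_C, CONVECTION)
        for b in blood
    ]
    for k in range(n_t):
        for j in range(k + 1, n_t):
            if rng.uniform() < 0.7:
                edges.append(
                    Conductance(tissues[k].id, tissues[j].id,
                                float(rng.uniform(0.0, 5.0)), CONDUCTION)
                )
        if rng.uniform() < 0.8:
            edges.append(
                Conductance(tissues[k].id, ENVIRONMENT_ID,
                            float(rng.uniform(0.1, 5.0)), CONDUCTION)
            )
    elements = []
    if with_elements:
        contact = tissues[int(rng.integers(0, n_t))].id
        for eid in ("e1", "e2"):
            elements.append(CoolingElementNode(id=eid))
            edges.append(Conductance(eid, contact, float(rng.uniform(0.2, 3.0)), CONDUCTION))
            edges.append(Conductance(eid, ENVIRONMENT_ID, float(rng.uniform(0.05, 3.0)), CONDUCTION))
        edges.append(Conductance("e1", "e2", float(rng.uniform(0.0, 1.0)), CONDUCTION))
    return ThermalNetwork(
        tissues=tissues,
        blood=blood,
        blood_props=BloodProperties(
            density_kg_m3=float(rng.uniform(1000.0, 1100.0)),
            specific_heat_J_kgC=float(rng.uniform(3400.0, 4000.0)),
        ),
        conductances=edges,
        environment=EnvironmentNode(temperature_C=float(rng.uniform(5.0, 30.0))),
        elements=elements,
    )
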