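"""Thermal-network construction, per-node balances and energy bookkeeping."""

import numpy as np
import pytest

from neckcool import (
    BloodNode,
    BloodProperties,
    Conductance,
    EnvironmentNode,
    ThermalNetwork,
    TissueNode,
    assemble_rhs,
    blood_node_derivative,
    energy_balance,
    find_steady_state,
    tissue_node_derivative,
    validate_network,
)
from neckcool.device import CollarSpec
from neckcool.model_core import (
    CONDUCTION,
    CONVECTION,
    ENVIRONMENT_ID,
    NetworkConfigurationError,
    network_from_dict,
    network_to_dict,
)

from conftest import make_random_network


def single_loop_net(g_wall=0.0, flow=1e-5, volume=1e-4, rho=1000.0, c_b=4000.0):
    """Minimal two-blood-node loop through one tissue, for hand checks."""
    tissue = TissueNode(id="t", mass_kg=1.0, specific_heat_J_kgC=3500.0)
    blood = [
        BloodNode("v0", volume, "v1", "t", g_wall, flow),
        BloodNode("v1", volume, "v0", "t", g_wall, flow),
    ]
    edges = [Conductance(b.id, "t", g_wall, CONVECTION) for b in blood]
    return ThermalNetwork(
        tissues=[tissue],
        blood=blood,
        blood_props=BloodProperties(rho, c_b),
        conductances=edges,
        environment=EnvironmentNode(20.0),
    )


class TestBloodNodeDerivative:
    def test_isothermal_equilibrium_is_stationary(self):
        net = single_loop_net(g_wall=3.0)
        temps = {"t": 37.0, "v0": 37.0, "v1": 37.0}
        assert blood_node_derivative(net.blood[0], net, temps) == pytest.approx(0.0)

    def test_pure_advection_hand_value(self):
        # g_it = 0, rho=1000, c=4000, phi=1e-5, V=1e-4, upstream 1 °C hotter
        net = single_loop_net(g_wall=0.0)
        temps = {"t": 36.0, "v0": 36.0, "v1": 37.0}
        dT = blood_node_derivative(net.blood[0], net, temps)
        assert dT == pytest.approx(0.1, rel=1e-12)

    def test_pure_wall_exchange_relaxes_toward_tissue(self):
        net = single_loop_net(g_wall=2.0, flow=1e-9)
        hot_tissue = {"t": 39.0, "v0": 36.0, "v1": 36.0}
        cold_tissue = {"t": 33.0, "v0": 36.0, "v1": 36.0}
        assert blood_node_derivative(net.blood[0], net, hot_tissue) > 0
        assert blood_node_derivative(net.blood[0], net, cold_tissue) < 0

    def test_missing_upstream_is_configuration_error(self):
        net = single_loop_net()
        net.blood[0].upstream = "nowhere"
        with pytest.raises(NetworkConfigurationError):
            blood_node_derivative(net.blood[0], net, {"t": 37.0, "v0": 37.0})


class TestTissueNodeDerivative:
    def test_isolated_node_without_sources_is_stationary(self):
        t = TissueNode("t", 2.0, 3500.0, metabolic_heat_W=0.0)
        net = ThermalNetwork(tissues=[t], environment=EnvironmentNode(20.0))
        assert tissue_node_derivative(t, net, {"t": 31.0}) == pytest.approx(0.0)

    def test_single_env_edge_steady_state_offset(self):
        # steady state T* = T_e + Qm/g
        g, qm = 1.5, 6.0
        t = TissueNode("t", 2.0, 3500.0, metabolic_heat_W=qm)
        net = ThermalNetwork(
            tissues=[t],
            conductances=[Conductance("t", ENVIRONMENT_ID, g, CONDUCTION)],
            environment=EnvironmentNode(20.0),
        )
        t_star = 20.0 + qm / g
        assert tissue_node_derivative(t, net, {"t": t_star}) == pytest.approx(0.0, abs=1e-14)
        ss = find_steady_state(net)
        assert ss["t"] == pytest.approx(t_star, abs=1e-6)

    def test_two_edge_steady_state_is_weighted_mean(self):
        g1, g2, t1, t2 = 2.0, 5.0, 30.0, 40.0
        t = TissueNode("t", 2.0, 3500.0)
        others = [TissueNode("a", 1.0, 3500.0), TissueNode("b", 1.0, 3500.0)]
        net = ThermalNetwork(
            tissues=[t] + others,
            conductances=[
                Conductance("t", "a", g1, CONDUCTION),
                Conductance("t", "b", g2, CONDUCTION),
            ],
            environment=EnvironmentNode(20.0),
        )
        t_star = (g1 * t1 + g2 * t2) / (g1 + g2)
        dT = tissue_node_derivative(t, net, {"t": t_star, "a": t1, "b": t2})
        assert dT == pytest.approx(0.0, abs=1e-13)


class TestValidateNetwork:
    def test_canonical_sheep_network_is_valid(self, sheep_net):
        assert validate_network(sheep_net) == []

    def test_broken_blood_cycle_is_reported_with_node_name(self, sheep_params):
        from neckcool import build_network

        net = build_network(sheep_params)
        net.blood_node("blood_head").upstream = "blood_head"
        diags = validate_network(net)
        assert any("blood_head" in d for d in diags)

    def test_negative_mass_is_reported_with_field_name(self, sheep_params):
        from neckcool import build_network

        net = build_network(sheep_params)
        net.tissue("body").mass_kg = -1.0
        diags = validate_network(net)
        assert len(diags) == 1 and "mass_kg" in diags[0] and "body" in diags[0]

    def test_unequal_loop_flow_is_reported(self, sheep_params):
        from neckcool import build_network

        net = build_network(sheep_params)
        net.blood_node("blood_head").flow_m3_s *= 2.0
        assert any("flow" in d for d in validate_network(net))


class TestAssembleRhs:
    def test_isothermal_state_without_sources_is_fixed_point(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            net = make_random_network(rng, with_elements=True, zero_sources=True)
            net.environment.temperature_C = 33.0
            rhs = assemble_rhs(net)
            y = np.full(rhs.n_state, 33.0)
            assert np.max(np.abs(rhs(0.0, y))) < 1e-12

    def test_vectorized_rhs_matches_scalar_node_balances(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            net = make_random_network(rng, with_elements=rng.uniform() < 0.5)
            rhs = assemble_rhs(net)
            y = rng.uniform(20.0, 42.0, size=rhs.n_state)
            temps = dict(zip(net.state_ids(), y))
            if net.elements:
                for eid, sol in zip(rhs.element_ids, rhs.element_solutions(y[: rhs.n_t])):
                    temps[eid] = sol.temperature_C
            dy = rhs(0.0, y)
            for k, t in enumerate(net.tissues):
                assert dy[k] == pytest.approx(
                    tissue_node_derivative(t, net, temps), rel=1e-12, abs=1e-15)
            for k, b in enumerate(net.blood):
                assert dy[rhs.n_t + k] == pytest.approx(
                    blood_node_derivative(b, net, temps), rel=1e-12, abs=1e-15)

    def test_wrong_state_length_raises(self, sheep_net):
        rhs = assemble_rhs(sheep_net)
        with pytest.raises(ValueError):
            rhs(0.0, np.zeros(rhs.n_state + 1))


class TestEnergyConservation:
    @pytest.mark.parametrize("with_elements,active", [(False, False), (True, False), (True, True)])
    def test_global_balance_on_random_networks(self, with_elements, active):
        """sum_k C_k dT_k/dt == metabolism - environment flow - collar heat."""
        rng = np.random.default_rng(101 + int(with_elements) + 2 * int(active))
        collar = CollarSpec() if with_elements else None
        for _ in range(40):
            net = make_random_network(rng, with_elements=with_elements)
            rhs = assemble_rhs(net, collar, active=active)
            y = rng.uniform(10.0, 45.0, size=rhs.n_state)
            temps = dict(zip(net.state_ids(), y))
            bal = energy_balance(net, temps, collar, active=active)
            scale = max(1.0, abs(bal["metabolic_W"]), abs(bal["environment_flow_W"]),
                        abs(bal["storage_rate_W"]))
            assert abs(bal["residual_W"]) / scale < 1e-9

    def test_wall_exchange_reciprocity(self):
        """Heat leaving the blood through the vessel wall enters the tissue."""
        net = single_loop_net(g_wall=4.0)
        temps = {"t": 39.0, "v0": 36.0, "v1": 36.5}
        rho_c = net.blood_props.density_kg_m3 * net.blood_props.specific_heat_J_kgC
        q_tissue = (tissue_node_derivative(net.tissues[0], net, temps)
                    * net.tissues[0].heat_capacity_J_C)
        q_blood = sum(
            blood_node_derivative(b, net, temps) * rho_c * b.volume_m3 for b in net.blood
        )
        # no metabolism, no env edges: tissue loss == blood gain
        assert q_tissue + q_blood == pytest.approx(0.0, abs=1e-9)

    def test_maximum_principle_no_sources(self):
        """Without metabolism or cooling, temperatures stay inside the initial hull."""
        from scipy.integrate import solve_ivp

        rng = np.random.default_rng(42)
        for _ in range(100):
            net = make_random_network(rng, zero_sources=True)
            rhs = assemble_rhs(net)
            y0 = rng.uniform(15.0, 42.0, size=rhs.n_state)
            lo = min(y0.min(), net.environment.temperature_C) - 1e-7
            hi = max(y0.max(), net.environment.temperature_C) + 1e-7
            sol = solve_ivp(rhs, (0.0, 2000.0), y0, method="LSODA",
                            rtol=1e-8, atol=1e-10,
                            t_eval=np.linspace(0.0, 2000.0, 21))
            assert sol.success
            assert sol.y.min() >= lo and sol.y.max() <= hi


class TestSerialization:
    def test_round_trip_is_lossless(self, sheep_net):
        data = network_to_dict(sheep_net)
        rebuilt = network_from_dict(data)
        assert network_to_dict(rebuilt) == data
        assert validate_network(rebuilt) == []

    def test_malformed_mapping_raises(self):
        with pytest.raises(NetworkConfigurationError):
            network_from_dict({"tissues": [{"id": "t", "bogus_field": 1.0}]})
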