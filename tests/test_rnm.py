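"""Regulatory-network ODE model: sigmoid normalization, input handling,
steady-state behaviour, and batch simulation contracts."""

import numpy as np
import pandas as pd
import pytest

from oa_stratify.rnm import (Edge, IntegrationError, MappingError,
                             NetworkParseError, NetworkSpec, Node,
                             RegulatoryInput, batch_simulate,
                             default_analyte_mapping, example_network,
                             node_rate, parse_network, regulatory_input,
                             rescale_inputs, sigmoid,
                             simulate_to_steady_state)


class TestSigmoid:
    @pytest.mark.parametrize("h", [1.0, 5.0, 10.0, 50.0])
    def test_anchor_points(self, h):
        assert abs(sigmoid(0.0, h) - 0.0) < 1e-12
        assert abs(sigmoid(0.5, h) - 0.5) < 1e-12
        assert abs(sigmoid(1.0, h) - 1.0) < 1e-12

    @pytest.mark.parametrize("h", [1.0, 10.0])
    def test_strictly_increasing(self, h):
        w = np.linspace(0, 1, 101)
        s = np.array([sigmoid(x, h) for x in w])
        assert np.all(np.diff(s) > 0)
        assert np.all((s >= 0) & (s <= 1))


class TestRegulatoryInput:
    def _spec(self, edges):
        nodes = {}
        for e in edges:
            nodes.setdefault(e.source, Node(e.source, "input"))
        for e in edges:
            nodes[e.target] = Node(e.target, "output_tf")
        return NetworkSpec(nodes=nodes, edges=edges)

    def test_single_activator_saturates_at_one(self):
        spec = self._spec([Edge("A", "B", 1)])
        assert regulatory_input("B", {"A": 1.0}, spec) == pytest.approx(1.0)

    def test_single_activator_at_zero(self):
        spec = self._spec([Edge("A", "B", 1)])
        assert regulatory_input("B", {"A": 0.0}, spec) == pytest.approx(0.0)

    def test_full_inhibition_wins(self):
        spec = self._spec([Edge("A", "B", 1), Edge("I", "B", -1)])
        w = regulatory_input("B", {"A": 1.0, "I": 1.0}, spec)
        assert w == pytest.approx(0.0)

    def test_input_node_rejected(self):
        spec = self._spec([Edge("A", "B", 1)])
        with pytest.raises(ValueError):
            regulatory_input("A", {"A": 0.5}, spec)

    def test_in_unit_interval_for_random_states(self):
        rng = np.random.default_rng(0)
        spec = self._spec([Edge("A", "B", 1), Edge("C", "B", 1, 2.0), Edge("I", "B", -1, 0.5)])
        for _ in range(100):
            st = {"A": rng.random(), "C": rng.random(), "I": rng.random()}
            assert 0 <= regulatory_input("B", st, spec) <= 1


class TestNodeRate:
    def test_fixed_points(self):
        assert node_rate(0.0, 0.0, 10.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert node_rate(1.0, 1.0, 7.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert node_rate(0.5, 0.0, 10.0, 1.0) == pytest.approx(0.5, abs=1e-12)


class TestParseNetwork:
    def test_small_sif(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A\t+\tB\nB\t-\tC\n")
        spec = parse_network(p)
        assert set(spec.nodes) == {"A", "B", "C"}
        assert spec.nodes["A"].role == "input"
        assert len(spec.edges) == 2
        assert spec.nodes["C"].role == "output_tf"

    def test_strict_mode_rejects_undeclared_node(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A\t+\tB\n")
        roles = tmp_path / "roles.yaml"
        roles.write_text("roles:\n  A: input\n")
        with pytest.raises(NetworkParseError, match="line|undeclared|2|1"):
            parse_network(p, roles, strict=True)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A\t+\tB\nA + B\n")
        with pytest.raises(NetworkParseError, match=":2"):
            parse_network(p)

    def test_input_with_incoming_edge_rejected(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A\t+\tB\nB\t+\tA\n")
        roles = tmp_path / "roles.yaml"
        roles.write_text("roles:\n  A: input\n  B: output_tf\n")
        with pytest.raises(NetworkParseError, match="incoming"):
            parse_network(p, roles)

    def test_bundled_example_network(self):
        spec = example_network()
        assert len(spec.nodes) >= 16
        assert sorted(spec.input_nodes) == sorted(
            ["IL-8", "IL-6", "IL-4", "TNFa", "IL-18", "IFNg", "IL-17", "VEGF"])
        assert sorted(spec.output_nodes) == sorted(
            ["CITED2", "CREB", "Runx2", "FOXO", "SOX9", "HIF2a", "NFkB", "AP1"])
        # every analyte in the default mapping feeds an input node
        assert set(default_analyte_mapping().values()) == set(spec.input_nodes)


class TestRescaleInputs:
    def test_min_max_arithmetic(self):
        df = pd.DataFrame({"X": [2.0, 4.0, 6.0]}, index=["a", "b", "c"])
        out = rescale_inputs(df, {"X": "N"})
        assert [ri.values["N"] for ri in out] == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_column_becomes_half(self):
        df = pd.DataFrame({"X": [3.0, 3.0, 3.0]})
        with pytest.warns(UserWarning):
            out = rescale_inputs(df, {"X": "N"})
        assert all(ri.values["N"] == 0.5 for ri in out)

    def test_unmapped_column_errors(self):
        df = pd.DataFrame({"X": [1.0, 2.0]})
        with pytest.raises(MappingError):
            rescale_inputs(df, {"Y": "N"})

    def test_outputs_within_unit_interval(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"X": np.exp(rng.standard_normal(50)),
                           "Y": np.exp(2 * rng.standard_normal(50))})
        out = rescale_inputs(df, {"X": "A", "Y": "B"})
        for ri in out:
            assert 0 <= ri.values["A"] <= 1 and 0 <= ri.values["B"] <= 1


class TestSteadyState:
    def test_clamped_input_one_drives_chain_to_one(self, chain_network):
        ss = simulate_to_steady_state(chain_network, RegulatoryInput("p", {"A": 1.0}))
        assert ss.converged
        assert ss.activations["B"] == pytest.approx(1.0, abs=1e-4)
        assert ss.activations["C"] == pytest.approx(1.0, abs=1e-4)

    def test_clamped_input_zero_drives_chain_to_zero(self, chain_network):
        ss = simulate_to_steady_state(chain_network, RegulatoryInput("p", {"A": 0.0}))
        assert ss.converged
        assert ss.activations["B"] == pytest.approx(0.0, abs=1e-4)
        assert ss.activations["C"] == pytest.approx(0.0, abs=1e-4)

    def test_acyclic_cascade_steady_state_independent_of_x0(self, chain_network):
        tol = 1e-6
        ri = RegulatoryInput("p", {"A": 0.7})
        lo = simulate_to_steady_state(chain_network, ri, x0=[0.0, 0.0], tol=tol)
        hi = simulate_to_steady_state(chain_network, ri, x0=[1.0, 1.0], tol=tol)
        for node in ("B", "C"):
            assert abs(lo.activations[node] - hi.activations[node]) < 10 * tol

    def test_inputs_as_ic_mode_lets_signal_decay(self, chain_network):
        ss = simulate_to_steady_state(chain_network, RegulatoryInput("p", {"A": 1.0}),
                                      inputs_as_ic=True)
        assert ss.activations["A"] == pytest.approx(0.0, abs=1e-3)

    def test_missing_input_value_errors(self, chain_network):
        with pytest.raises(MappingError):
            simulate_to_steady_state(chain_network, RegulatoryInput("p", {}))

    def test_trajectories_stay_in_unit_box(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            n_in, n_mid = rng.integers(1, 4), rng.integers(1, 4)
            nodes, edges = {}, []
            for i in range(n_in):
                nodes[f"I{i}"] = Node(f"I{i}", "input")
            for j in range(n_mid):
                nodes[f"M{j}"] = Node(f"M{j}", "internal",
                                      gain=float(rng.uniform(1, 20)),
                                      decay=float(rng.uniform(0.5, 2)))
            nodes["T"] = Node("T", "output_tf")
            for j in range(n_mid):
                src = f"I{rng.integers(n_in)}"
                edges.append(Edge(src, f"M{j}", int(rng.choice([1, -1])),
                                  float(rng.uniform(0.5, 2))))
                edges.append(Edge(f"M{j}", "T", int(rng.choice([1, -1]))))
            spec = NetworkSpec(nodes=nodes, edges=edges)
            ri = RegulatoryInput("p", {f"I{i}": float(rng.random()) for i in range(n_in)})
            ss = simulate_to_steady_state(spec, ri, t_max=100.0)
            assert all(0 <= v <= 1 for v in ss.activations.values())


class TestBatchSimulate:
    def test_dimensions_and_flag_column(self, study_cohort):
        from oa_stratify.cohort import ANALYTE_NAMES

        spec = example_network()
        sf = study_cohort.data[list(ANALYTE_NAMES)].dropna()
        tf = batch_simulate(spec, rescale_inputs(sf, default_analyte_mapping()))
        assert tf.shape == (25, 9)  # 8 TFs + converged flag
        assert tf["converged"].dtype == bool

    def test_identical_inputs_give_identical_rows(self, chain_network):
        inputs = [RegulatoryInput("a", {"A": 0.3}), RegulatoryInput("b", {"A": 0.3})]
        tf = batch_simulate(chain_network, inputs)
        assert np.allclose(tf.loc["a"].drop("converged").astype(float),
                           tf.loc["b"].drop("converged").astype(float))

    def test_patient_order_only_permutes_rows(self, chain_network):
        inputs = [RegulatoryInput(p, {"A": v}) for p, v in [("a", 0.1), ("b", 0.5), ("c", 0.9)]]
        fwd = batch_simulate(chain_network, inputs)
        rev = batch_simulate(chain_network, inputs[::-1])
        pd.testing.assert_frame_equal(fwd.sort_index(), rev.sort_index())

    def test_monotone_response_to_activating_input(self, chain_network):
        vals = [0.0, 0.25, 0.5, 0.75, 1.0]
        inputs = [RegulatoryInput(i, {"A": v}) for i, v in enumerate(vals)]
        tf = batch_simulate(chain_network, inputs)
        b_vals = [simulate_to_steady_state(chain_network, ri).activations["B"] for ri in inputs]
        assert np.all(np.diff(b_vals) >= -1e-9)

    def test_mapping_failure_aborts_before_integration(self, chain_network):
        inputs = [RegulatoryInput("a", {"A": 0.3}), RegulatoryInput("b", {})]
        with pytest.raises(MappingError):
            batch_simulate(chain_network, inputs)
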