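"""Regulatory-network ODE simulation of transcription-factor activation.

A signed interaction graph is converted into a continuous dynamical system
using the normalized-sigmoid formalism of Mendoza & Xenarios: each
non-input node i evolves as

    dx_i/dt = s(omega_i; h_i) - gamma_i * x_i,

where omega_i in [0, 1] aggregates the node's activators and inhibitors,

    omega = A * (1 - I),
    A = ((1 + sum(alpha)) / sum(alpha)) * (sum(alpha x_a) / (1 + sum(alpha x_a)))
        (A = 1 with no activators), I defined identically over inhibitors
        (I = 0 with none),

and s is the normalized sigmoid

    s(omega; h) = (-exp(h/2) + exp(-h (omega - 1/2)))
                  / ((1 - exp(h/2)) (1 + exp(-h (omega - 1/2)))),

which satisfies s(0) = 0, s(1/2) = 1/2, s(1) = 1 and is strictly
increasing, so trajectories started in [0, 1]^n stay there.

Per-patient synovial-fluid analyte levels, min-max rescaled to [0, 1]
across the cohort, drive the network's input nodes — clamped as a constant
external signal by default, or merely used as initial conditions with
``inputs_as_ic=True`` — and the steady-state activations of the output
transcription-factor nodes are the patient's simulated TF profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "Node",
    "Edge",
    "NetworkSpec",
    "RegulatoryInput",
    "SteadyState",
    "NetworkParseError",
    "MappingError",
    "IntegrationError",
    "parse_network",
    "example_network",
    "default_analyte_mapping",
    "rescale_inputs",
    "regulatory_input",
    "sigmoid",
    "node_rate",
    "simulate_to_steady_state",
    "batch_simulate",
]

DEFAULT_GAIN = 10.0
DEFAULT_DECAY = 1.0
DEFAULT_WEIGHT = 1.0


class NetworkParseError(ValueError):
    pass


class MappingError(KeyError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Node:
    name: str
    role: str  # input | internal | output_tf
    gain: float = DEFAULT_GAIN
    decay: float = DEFAULT_DECAY

    def __post_init__(self):
        if self.role not in ("input", "internal", "output_tf"):
            raise NetworkParseError(f"node {self.name!r}: unknown role {self.role!r}")
        if self.gain <= 0 or self.decay <= 0:
            raise NetworkParseError(f"node {self.name!r}: gain and decay must be > 0")


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: int       # +1 activation, -1 inhibition
    weight: float = DEFAULT_WEIGHT

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise NetworkParseError("edge sign must be +1 or -1")
        if self.weight <= 0:
            raise NetworkParseError("edge weight must be > 0")


@dataclass
class NetworkSpec:
    nodes: dict           # name -> Node
    edges: list           # list[Edge]

    def __post_init__(self):
        names = set(self.nodes)
        for e in self.edges:
            if e.source not in names or e.target not in names:
                raise NetworkParseError(f"dangling edge {e.source}->{e.target}")
        for node in self.nodes.values():
            if node.role == "input" and any(e.target == node.name for e in self.edges):
                raise NetworkParseError(f"input node {node.name!r} has incoming edges")
        if not self.output_nodes:
            raise NetworkParseError("network has no output_tf node")

    @property
    def input_nodes(self) -> list:
        return [n for n, nd in self.nodes.items() if nd.role == "input"]

    @property
    def non_input_nodes(self) -> list:
        return [n for n, nd in self.nodes.items() if nd.role != "input"]

    @property
    def output_nodes(self) -> list:
        return [n for n, nd in self.nodes.items() if nd.role == "output_tf"]

    def regulators(self, node: str):
        acts = [(e.source, e.weight) for e in self.edges if e.target == node and e.sign > 0]
        inhs = [(e.source, e.weight) for e in self.edges if e.target == node and e.sign < 0]
        return acts, inhs

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for name, nd in self.nodes.items():
            g.add_node(name, role=nd.role)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, weight=e.weight)
        return g

    @property
    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_graph())


@dataclass(frozen=True)
class RegulatoryInput:
    patient_id: object
    values: dict  # input node -> activation in [0, 1]

    def __post_init__(self):
        for node, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"input {node!r} activation {v} outside [0, 1]")


@dataclass
class SteadyState:
    patient_id: object
    activations: dict  # non-input node -> value in [0, 1]
    converged: bool
    final_time: float
    residual: float


_SIGNS = {"+": 1, "-": -1, "−": -1, "activates": 1, "inhibits": -1, "1": 1, "-1": -1}


def parse_network(path, roles_path=None, strict: bool = False) -> NetworkSpec:
    """Parse a SIF-like TSV (``source<TAB>sign<TAB>target[<TAB>weight]``).

    Roles, gains and decays may come from a sidecar YAML (keys ``roles``,
    ``gains``, ``decays``, ``outputs``); otherwise nodes without incoming
    edges are inputs, nodes without outgoing edges are output TFs, and the
    rest are internal.  ``strict`` requires every node to appear in the
    sidecar's declarations.
    """
    meta = {}
    if roles_path is not None:
        with open(roles_path) as fh:
            meta = yaml.safe_load(fh) or {}
    declared = set(meta.get("roles", {}))

    edges_raw, names = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise NetworkParseError(f"{path}:{lineno}: expected 3 or 4 tab-separated fields")
            src, sign_s, tgt = parts[0], parts[1], parts[2]
            if sign_s not in _SIGNS:
                raise NetworkParseError(f"{path}:{lineno}: unknown sign {sign_s!r}")
            weight = float(parts[3]) if len(parts) == 4 else DEFAULT_WEIGHT
            if strict and (src not in declared or tgt not in declared):
                missing = src if src not in declared else tgt
                raise NetworkParseError(f"{path}:{lineno}: undeclared node {missing!r}")
            edges_raw.append((src, tgt, _SIGNS[sign_s], weight, lineno))
            for n in (src, tgt):
                if n not in names:
                    names.append(n)
    for n in declared:
        if n not in names:
            names.append(n)

    has_in = {t for _, t, _, _, _ in edges_raw}
    has_out = {s for s, _, _, _, _ in edges_raw}
    roles = dict(meta.get("roles", {}))
    for o in meta.get("outputs", []):
        roles[o] = "output_tf"
    nodes = {}
    for n in names:
        role = roles.get(n)
        if role is None:
            if n not in has_in:
                role = "input"
            elif n not in has_out:
                role = "output_tf"
            else:
                role = "internal"
        nodes[n] = Node(
            name=n, role=role,
            gain=float(meta.get("gains", {}).get(n, DEFAULT_GAIN)),
            decay=float(meta.get("decays", {}).get(n, DEFAULT_DECAY)),
        )
    edges = [Edge(s, t, sg, w) for s, t, sg, w, _ in edges_raw]
    return NetworkSpec(nodes=nodes, edges=edges)


def example_network() -> NetworkSpec:
    """The bundled chondrocyte-like example network (8 analyte inputs, 8
    output TFs).  The topology is illustrative — a plausible signed graph
    in which pro-inflammatory inputs activate NF-kB/AP1-type nodes and
    repress the FOXO/SOX9-type anabolic program — not a validated model."""
    data = resources.files("oa_stratify") / "data"
    return parse_network(str(data / "chondrocyte_example.sif"),
                         str(data / "chondrocyte_example.yaml"))


def default_analyte_mapping() -> dict:
    """Analyte column -> input node mapping for the example network."""
    data = resources.files("oa_stratify") / "data" / "analyte_map.yaml"
    with open(str(data)) as fh:
        return yaml.safe_load(fh)


def rescale_inputs(analyte_table: pd.DataFrame, mapping: dict) -> list:
    """Min-max rescale each analyte across the cohort and map to input nodes.

    ``mapping`` is ``{analyte column -> input node}``.  A constant analyte
    rescales to 0.5 for every subject (with a warning).  Returns one
    RegulatoryInput per table row.
    """
    if len(analyte_table) < 2:
        raise ValueError("need at least 2 subjects to rescale")
    scaled = {}
    for col, node in mapping.items():
        if col not in analyte_table.columns:
            raise MappingError(f"analyte column {col!r} not in table")
        v = analyte_table[col].to_numpy(dtype=float)
        lo, hi = np.nanmin(v), np.nanmax(v)
        if hi == lo:
            warnings.warn(f"constant analyte {col!r}: rescaled to 0.5", stacklevel=2)
            scaled[node] = np.full(len(v), 0.5)
        else:
            scaled[node] = (v - lo) / (hi - lo)
    return [
        RegulatoryInput(pid, {node: float(vals[i]) for node, vals in scaled.items()})
        for i, pid in enumerate(analyte_table.index)
    ]


def regulatory_input(node: str, state: dict, spec: NetworkSpec) -> float:
    """Total regulatory input omega in [0, 1] for a non-input node."""
    if spec.nodes[node].role == "input":
        raise ValueError(f"{node!r} is an input node")
    acts, inhs = spec.regulators(node)
    if not acts and not inhs:
        return 0.0  # unregulated node: pure decay

    def term(pairs):
        total_w = sum(w for _, w in pairs)
        wx = sum(w * state[src] for src, w in pairs)
        return ((1 + total_w) / total_w) * (wx / (1 + wx))

    A = term(acts) if acts else 1.0
    I = term(inhs) if inhs else 0.0
    return A * (1.0 - I)


def sigmoid(omega: float, h: float) -> float:
    """Normalized sigmoid with s(0)=0, s(1/2)=1/2, s(1)=1."""
    num = -np.exp(0.5 * h) + np.exp(-h * (omega - 0.5))
    den = (1.0 - np.exp(0.5 * h)) * (1.0 + np.exp(-h * (omega - 0.5)))
    return num / den


def node_rate(omega: float, x: float, h: float = DEFAULT_GAIN,
              gamma: float = DEFAULT_DECAY) -> float:
    """dx/dt = s(omega; h) - gamma * x."""
    return sigmoid(omega, h) - gamma * x


def _rhs_factory(spec: NetworkSpec, clamped: dict):
    order = spec.non_input_nodes
    idx = {n: i for i, n in enumerate(order)}

    def rhs(t, x):
        state = dict(clamped)
        for n, i in idx.items():
            state[n] = x[i]
        dx = np.empty(len(order))
        for n, i in idx.items():
            nd = spec.nodes[n]
            dx[i] = node_rate(regulatory_input(n, state, spec), x[i], nd.gain, nd.decay)
        return dx

    return order, rhs


def simulate_to_steady_state(spec: NetworkSpec, reg_input: RegulatoryInput,
                             x0=None, tol: float = 1e-6, t_max: float = 500.0,
                             inputs_as_ic: bool = False) -> SteadyState:
    """Integrate the network to steady state for one patient.

    Input nodes are clamped at their RegulatoryInput values for all t
    (default), or — with ``inputs_as_ic`` — only initialized there and then
    treated as ordinary nodes with no regulators, so they decay.  Non-input
    nodes start at ``x0`` (default 0.5).  Integration (LSODA, stiff-capable)
    proceeds in windows until ``max |dx/dt| < tol`` or ``t_max``.
    """
    missing = set(spec.input_nodes) - set(reg_input.values)
    if missing:
        raise MappingError(f"no input value for node(s) {sorted(missing)}")
    if tol <= 0:
        raise ValueError("tol must be > 0")

    if inputs_as_ic:
        # re-cast inputs as free internal nodes initialized at the signal
        free_spec = NetworkSpec(
            nodes={n: (Node(nd.name, "internal", nd.gain, nd.decay) if nd.role == "input" else nd)
                   for n, nd in spec.nodes.items()},
            edges=list(spec.edges),
        )
        order, rhs = _rhs_factory(free_spec, {})
        x = np.full(len(order), 0.5) if x0 is None else np.asarray(x0, dtype=float).copy()
        for n, v in reg_input.values.items():
            x[order.index(n)] = v
    else:
        order, rhs = _rhs_factory(spec, dict(reg_input.values))
        x = np.full(len(order), 0.5) if x0 is None else np.asarray(x0, dtype=float).copy()
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x0 components must lie in [0, 1]")

    t, window = 0.0, 25.0
    residual = float(np.max(np.abs(rhs(t, x)))) if len(x) else 0.0
    while residual >= tol and t < t_max:
        span = (t, min(t + window, t_max))
        sol = solve_ivp(rhs, span, x, method="LSODA", rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise IntegrationError(f"solver failed at t={t}: {sol.message}")
        x = sol.y[:, -1]
        t = sol.t[-1]
        residual = float(np.max(np.abs(rhs(t, x))))
    x = np.clip(x, 0.0, 1.0)  # absorb solver round-off only
    return SteadyState(
        patient_id=reg_input.patient_id,
        activations={n: float(x[i]) for i, n in enumerate(order)},
        converged=residual < tol,
        final_time=t,
        residual=residual,
    )


def batch_simulate(spec: NetworkSpec, inputs, x0_policy=None, tol: float = 1e-6,
                   t_max: float = 500.0, inputs_as_ic: bool = False) -> pd.DataFrame:
    """One steady-state simulation per patient; returns patients x output-TF
    activations with a ``converged`` flag column (non-converged patients are
    flagged, never dropped)."""
    for ri in inputs:
        missing = set(spec.input_nodes) - set(ri.values)
        if missing:
            raise MappingError(f"patient {ri.patient_id!r}: missing input(s) {sorted(missing)}")
    rows = []
    for ri in inputs:
        ss = simulate_to_steady_state(spec, ri, x0=x0_policy, tol=tol, t_max=t_max,
                                      inputs_as_ic=inputs_as_ic)
        row = {tf: ss.activations[tf] for tf in spec.output_nodes}
        row["converged"] = ss.converged
        rows.append(pd.Series(row, name=ri.patient_id))
    df = pd.DataFrame(rows)
    df.index.name = "subject_id"
    return df
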