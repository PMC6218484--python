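"""Deterministic steady-state evaluation of the probabilistic logic network.

Node activities live in [0, 1].  Each node's update is

    a = sum_i k_i * g_i            over incoming activation interactions
    x = a * prod_j (1 - h_j * g_j) over incoming inhibition interactions

where the gate value g is the source activity (single source), the product
of source activities (AND), or the probabilistic union 1 - prod(1 - x)
(OR).  With all parameters at 1 and inputs in {0, 1} this reduces to
classical Boolean evaluation on acyclic networks; intermediate parameter
values give the quantitative, probabilistic generalization.

States are iterated synchronously from a fixed initial value until the
largest per-node change falls below tolerance.  Acyclic networks are
evaluated in one topological pass (the synchronous iteration converges to
exactly that fixed point), which is what the fitting loop uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netmodel import LogicalNetwork, ParameterSet


@dataclass
class SimulationSettings:
    """Convergence control for the synchronous fixed-point iteration."""

    tolerance: float = 1e-6
    max_sweeps: int | None = None  # default 100 * |V|
    init_value: float = 0.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_sweeps is not None and self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if not (0.0 <= self.init_value <= 1.0):
            raise ValueError("init_value must be in [0,1]")


@dataclass
class StateVector:
    """Steady-state activities for one condition."""

    activities: dict[str, float]
    converged: bool
    sweeps_used: int


@dataclass
class _NodeRule:
    """Pre-resolved incoming interactions of one node (index space)."""

    act: list[tuple[int, str, np.ndarray]] = field(default_factory=list)
    inh: list[tuple[int, str, np.ndarray]] = field(default_factory=list)


class CompiledNetwork:
    """Index-space representation of a network for fast batched evaluation.

    Parameters are addressed by their interaction order in the network; a
    batch of conditions is a (B, |V|) state matrix evaluated with numpy.
    """

    def __init__(self, net: LogicalNetwork):
        self.net = net
        self.node_names = net.node_names
        self.index = {n: i for i, n in enumerate(self.node_names)}
        self.param_names = net.parameters
        self.param_index = {p: i for i, p in enumerate(self.param_names)}
        self.rules: list[_NodeRule] = [_NodeRule() for _ in self.node_names]
        for inter in net.interactions:
            pi = self.param_index[inter.parameter]
            srcs = np.array([self.index[s] for s in inter.sources], dtype=np.intp)
            rule = self.rules[self.index[inter.target]]
            entry = (pi, inter.gate, srcs)
            if inter.sign == "activation":
                rule.act.append(entry)
            else:
                rule.inh.append(entry)
        self.clamp_default = np.full(len(self.node_names), np.nan)
        for n in net.nodes:
            if n.constitutive:
                self.clamp_default[self.index[n.name]] = 1.0
        self.topo_order = self._topological_order()
        self._build_sweep_arrays()

    def _build_sweep_arrays(self) -> None:
        """Flatten rules into arrays so one sweep is a few matrix products."""
        nv = len(self.node_names)
        a_src, a_tgt, a_par = [], [], []
        i_src, i_tgt, i_par = [], [], []
        self._gated_act: list[tuple[int, int, str, np.ndarray]] = []
        self._gated_inh: list[tuple[int, int, str, np.ndarray]] = []
        for tgt, rule in enumerate(self.rules):
            for pi, gate, srcs in rule.act:
                if gate == "single":
                    a_src.append(int(srcs[0]))
                    a_tgt.append(tgt)
                    a_par.append(pi)
                else:
                    self._gated_act.append((tgt, pi, gate, srcs))
            for pi, gate, srcs in rule.inh:
                if gate == "single":
                    i_src.append(int(srcs[0]))
                    i_tgt.append(tgt)
                    i_par.append(pi)
                else:
                    self._gated_inh.append((tgt, pi, gate, srcs))
        self._a_src = np.array(a_src, dtype=np.intp)
        self._a_tgt = np.array(a_tgt, dtype=np.intp)
        self._a_par = np.array(a_par, dtype=np.intp)
        self._m_act = np.zeros((len(a_src), nv))
        for e, t in enumerate(a_tgt):
            self._m_act[e, t] = 1.0
        self._i_src = np.array(i_src, dtype=np.intp)
        self._i_tgt = np.array(i_tgt, dtype=np.intp)
        self._i_par = np.array(i_par, dtype=np.intp)
        self._m_inh = np.zeros((len(i_src), nv))
        for e, t in enumerate(i_tgt):
            self._m_inh[e, t] = 1.0
        # longest-path depth: a DAG's synchronous iteration from any init
        # reaches its fixed point after exactly this many sweeps
        if self.topo_order is not None:
            level = np.zeros(nv, dtype=int)
            for idx in self.topo_order:
                rule = self.rules[idx]
                preds = [int(s) for _, _, ss in rule.act + rule.inh for s in ss]
                if preds:
                    level[idx] = 1 + max(level[p] for p in preds)
            self._dag_depth = max(1, int(level.max()))
        else:
            self._dag_depth = None

    def _sweep(
        self, states: np.ndarray, k: np.ndarray, clamped: np.ndarray,
        clamp_vals: np.ndarray,
    ) -> np.ndarray:
        a = (k[self._a_par] * states[:, self._a_src]) @ self._m_act
        for tgt, pi, gate, srcs in self._gated_act:
            a[:, tgt] += k[pi] * self._gate(states, gate, srcs)
        if len(self._i_src):
            v = 1.0 - k[self._i_par] * states[:, self._i_src]
            # floor keeps log finite; exp(log-sum) underflows cleanly to 0
            logf = np.log(np.clip(v, 1e-300, None)) @ self._m_inh
            a *= np.exp(logf)
        for tgt, pi, gate, srcs in self._gated_inh:
            a[:, tgt] *= 1.0 - k[pi] * self._gate(states, gate, srcs)
        np.clip(a, 0.0, 1.0, out=a)
        return np.where(clamped, clamp_vals, a)

    def _topological_order(self) -> np.ndarray | None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.node_names)))
        for tgt, rule in enumerate(self.rules):
            for _, _, srcs in rule.act + rule.inh:
                for s in srcs:
                    g.add_edge(int(s), tgt)
        try:
            return np.array(list(nx.topological_sort(g)), dtype=np.intp)
        except nx.NetworkXUnfeasible:
            return None

    # -- evaluation ------------------------------------------------------
    @staticmethod
    def _gate(states: np.ndarray, gate: str, srcs: np.ndarray) -> np.ndarray:
        if gate == "single":
            return states[:, srcs[0]]
        sub = states[:, srcs]
        if gate == "AND":
            return sub.prod(axis=1)
        return 1.0 - (1.0 - sub).prod(axis=1)  # OR: probabilistic union

    def _node_value(
        self, states: np.ndarray, node_idx: int, k: np.ndarray
    ) -> np.ndarray:
        rule = self.rules[node_idx]
        a = np.zeros(states.shape[0])
        for pi, gate, srcs in rule.act:
            a = a + k[pi] * self._gate(states, gate, srcs)
        for pi, gate, srcs in rule.inh:
            a = a * (1.0 - k[pi] * self._gate(states, gate, srcs))
        return np.clip(a, 0.0, 1.0)

    def _sweep_grad(
        self,
        states: np.ndarray,
        jac: np.ndarray,
        k: np.ndarray,
        clamped: np.ndarray,
        clamp_vals: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        """One synchronous sweep with forward-mode parameter sensitivities.

        ``jac`` is d(states)/d(k), shape (B, |V|, P).
        """
        B, nv = states.shape
        P = len(self.param_names)
        a = (k[self._a_par] * states[:, self._a_src]) @ self._m_act
        ja = np.einsum(
            "bep,en->bnp",
            jac[:, self._a_src, :] * k[self._a_par][None, :, None],
            self._m_act,
        )
        for e in range(len(self._a_src)):
            ja[:, self._a_tgt[e], self._a_par[e]] += states[:, self._a_src[e]]
        for tgt, pi, gate, srcs in self._gated_act:
            g, dg = self._gate_grad(states, jac, gate, srcs)
            a[:, tgt] += k[pi] * g
            ja[:, tgt, :] += k[pi] * dg
            ja[:, tgt, pi] += g
        if len(self._i_src):
            y = states[:, self._i_src]
            v = 1.0 - k[self._i_par] * y
            vc = np.clip(v, 1e-12, None)
            f = np.exp(np.log(vc) @ self._m_inh)
            w = 1.0 / vc
            term = -(k[self._i_par][None, :, None]) * jac[:, self._i_src, :]
            jlog = np.einsum("bep,en->bnp", term * w[:, :, None], self._m_inh)
            for e in range(len(self._i_src)):
                jlog[:, self._i_tgt[e], self._i_par[e]] -= y[:, e] * w[:, e]
            x = a * f
            jx = ja * f[:, :, None] + x[:, :, None] * jlog
        else:
            x, jx = a, ja
        for tgt, pi, gate, srcs in self._gated_inh:
            g, dg = self._gate_grad(states, jac, gate, srcs)
            factor = 1.0 - k[pi] * g
            jx[:, tgt, :] = jx[:, tgt, :] * factor[:, None] + x[:, tgt, None] * (
                -k[pi] * dg
            )
            jx[:, tgt, pi] += x[:, tgt] * (-g)
            x[:, tgt] *= factor
        over = x > 1.0
        x = np.clip(x, 0.0, 1.0)
        jx[over] = 0.0
        jx[clamped] = 0.0
        return np.where(clamped, clamp_vals, x), jx

    def _gate_grad(
        self, states: np.ndarray, jac: np.ndarray, gate: str, srcs: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        sub = states[:, srcs]  # (B, S)
        jsub = jac[:, srcs, :]  # (B, S, P)
        if gate == "AND":
            g = sub.prod(axis=1)
            dg = np.zeros(jac.shape[::2])
            for i in range(len(srcs)):
                others = np.prod(np.delete(sub, i, axis=1), axis=1)
                dg += others[:, None] * jsub[:, i, :]
        else:  # OR
            g = 1.0 - (1.0 - sub).prod(axis=1)
            dg = np.zeros(jac.shape[::2])
            for i in range(len(srcs)):
                others = np.prod(np.delete(1.0 - sub, i, axis=1), axis=1)
                dg += others[:, None] * jsub[:, i, :]
        return g, dg

    def steady_states_with_grad(
        self,
        k: np.ndarray,
        clamp: np.ndarray,
        settings: SimulationSettings | None = None,
    ) -> tuple[np.ndarray, np.ndarray, bool, int]:
        """Batched steady states plus d(states)/d(parameters).

        Returns (states, jacobian (B, |V|, P), converged, sweeps).  For
        cyclic networks the sensitivity of the iterated map is accumulated
        over the executed sweeps, converging to the fixed point's implicit
        sensitivity as the states converge.
        """
        settings = settings or SimulationSettings()
        nv = len(self.node_names)
        P = len(self.param_names)
        clamped = ~np.isnan(clamp)
        clamp_vals = np.where(clamped, clamp, 0.0)
        states = np.full(clamp.shape, settings.init_value)
        states[clamped] = clamp[clamped]
        jac = np.zeros((clamp.shape[0], nv, P))
        if self._dag_depth is not None:
            for _ in range(self._dag_depth):
                states, jac = self._sweep_grad(states, jac, k, clamped, clamp_vals)
            return states, jac, True, self._dag_depth
        max_sweeps = settings.max_sweeps or 100 * nv
        sweeps = 0
        for sweeps in range(1, max_sweeps + 1):
            new, jac = self._sweep_grad(states, jac, k, clamped, clamp_vals)
            delta = np.abs(new - states).max()
            states = new
            if delta < settings.tolerance:
                # let the sensitivities settle a little further
                for _ in range(20):
                    new, jac2 = self._sweep_grad(states, jac, k, clamped, clamp_vals)
                    jdelta = np.abs(jac2 - jac).max()
                    states, jac = new, jac2
                    if jdelta < settings.tolerance:
                        break
                return states, jac, True, sweeps
        return states, jac, False, sweeps

    def clamp_matrix(self, clamps: dict[str, float], batch: int = 1) -> np.ndarray:
        """(B, |V|) matrix of clamp values; NaN where unclamped."""
        row = self.clamp_default.copy()
        for node, v in clamps.items():
            row[self.index[node]] = v
        return np.tile(row, (batch, 1))

    def steady_states(
        self,
        k: np.ndarray,
        clamp: np.ndarray,
        settings: SimulationSettings | None = None,
    ) -> tuple[np.ndarray, bool, int]:
        """Batched steady states.

        ``clamp`` is (B, |V|) with NaN for free nodes.  Returns
        (states, converged, sweeps).
        """
        settings = settings or SimulationSettings()
        nv = len(self.node_names)
        clamped = ~np.isnan(clamp)
        clamp_vals = np.where(clamped, clamp, 0.0)
        states = np.full(clamp.shape, settings.init_value)
        states[clamped] = clamp[clamped]
        if self._dag_depth is not None:
            # acyclic: the synchronous iteration is exact after `depth` sweeps
            for _ in range(self._dag_depth):
                states = self._sweep(states, k, clamped, clamp_vals)
            return states, True, self._dag_depth
        max_sweeps = settings.max_sweeps or 100 * nv
        sweeps = 0
        for sweeps in range(1, max_sweeps + 1):
            new = self._sweep(states, k, clamped, clamp_vals)
            delta = np.abs(new - states).max()
            states = new
            if delta < settings.tolerance:
                return states, True, sweeps
        return states, False, sweeps


def node_update(
    net: LogicalNetwork,
    target: str,
    source_activities: dict[str, float],
    params: dict[str, float],
) -> float:
    """One node's update given its sources' activities (scalar convenience)."""
    comp = CompiledNetwork(net)
    states = np.zeros((1, len(comp.node_names)))
    for node, v in source_activities.items():
        states[0, comp.index[node]] = v
    k = np.array([params[p] for p in comp.param_names])
    return float(comp._node_value(states, comp.index[target], k)[0])


def steady_state(
    net: LogicalNetwork,
    params: dict[str, float] | ParameterSet,
    clamps: dict[str, float],
    settings: SimulationSettings | None = None,
    context: str | None = None,
) -> StateVector:
    """Steady state of *net* for one set of input clamps.

    Input nodes must all be clamped; constitutive nodes clamp to 1 unless
    overridden.  Non-convergence (possible on feedback loops with extreme
    parameters) is reported via ``converged=False``, never raised.
    """
    if isinstance(params, ParameterSet):
        context = context or params.contexts[0]
        params = params.for_context(context)
    comp = CompiledNetwork(net)
    missing = [n for n in net.input_nodes if n not in clamps]
    if missing:
        raise ValueError(f"input nodes not clamped: {missing}")
    k = np.array([params[p] for p in comp.param_names])
    if np.isnan(k).any():
        raise ValueError("NaN parameter value")
    clamp = comp.clamp_matrix(clamps)
    states, converged, sweeps = comp.steady_states(k, clamp, settings)
    if np.isnan(states).any():
        raise FloatingPointError("NaN produced during state update")
    acts = {n: float(states[0, i]) for n, i in comp.index.items()}
    return StateVector(activities=acts, converged=converged, sweeps_used=sweeps)


def simulate_experiments(
    net: LogicalNetwork,
    params: ParameterSet,
    table,
    settings: SimulationSettings | None = None,
):
    """Simulated values for every (context, condition, measured node) row.

    Returns a ``pandas.DataFrame`` aligned with the table's measurement
    rows, with columns ``context condition node simulated converged``.
    """
    import pandas as pd

    table.validate_against(net)
    comp = CompiledNetwork(net)
    conds = table.conditions
    rows = []
    for ctx in table.contexts:
        k = np.array([params.for_context(ctx)[p] for p in comp.param_names])
        clamp = np.vstack([comp.clamp_matrix(c.clamps)[0] for c in conds])
        states, converged, _ = comp.steady_states(k, clamp, settings)
        cond_idx = {c.id: i for i, c in enumerate(conds)}
        for (mctx, mcond, node), _m in table.measurements.items():
            if mctx != ctx:
                continue
            rows.append(
                {
                    "context": ctx,
                    "condition": mcond,
                    "node": node,
                    "simulated": float(states[cond_idx[mcond], comp.index[node]]),
                    "converged": bool(converged),
                }
            )
    return pd.DataFrame(rows)


def export_state(state: StateVector) -> str:
    """Delimited (node, activity, converged) table for one state."""
    lines = ["node\tactivity\tconverged"]
    for node, v in state.activities.items():
        lines.append(f"{node}\t{v:.10g}\t{state.converged}")
    return "\n".join(lines) + "\n"
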