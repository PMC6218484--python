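"""Network and data model: types, interaction-list parsing, constraint groups, measurement I/O.

A signed logical network is written as a plain-text interaction list:

.. code-block:: text

    # header: node declarations (role: input | measured | latent | readout)
    node TRAIL input
    node BRAF  latent constitutive
    node ERK   measured
    # interactions: "->" activation, "-|" inhibition,
    # "&" joins AND sources, "+" joins OR sources
    TRAIL -> TRAILR   k_rec
    A & B -> C        k_and
    X -| Y            k_inh

Undeclared nodes default to role ``latent``.  One parameter per interaction.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import pandas as pd

ROLES = ("input", "measured", "latent", "readout")
GATES = ("single", "AND", "OR")
SIGNS = ("activation", "inhibition")

SUM_TOL = 1e-9


class NetworkError(ValueError):
    """Structural or schema problem in a logical network."""


class ParseError(NetworkError):
    """Malformed interaction-list or measurement text."""


@dataclass(frozen=True)
class NodeSpec:
    """A network node: relative activity of one signalling molecule."""

    name: str
    role: str = "latent"
    constitutive: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise NetworkError(f"unknown node role {self.role!r} for {self.name!r}")


@dataclass(frozen=True)
class Interaction:
    """A signed, gated edge carrying one named proportionality constant."""

    id: str
    sources: tuple[str, ...]
    target: str
    sign: str
    parameter: str
    gate: str = "single"

    def __post_init__(self) -> None:
        if self.gate not in GATES:
            raise NetworkError(f"unknown gate {self.gate!r}")
        if self.sign not in SIGNS:
            raise NetworkError(f"unknown sign {self.sign!r}")
        if (self.gate == "single") != (len(self.sources) == 1):
            raise NetworkError(
                f"interaction {self.id}: gate 'single' iff exactly one source "
                f"(got gate={self.gate}, {len(self.sources)} sources)"
            )


@dataclass
class LogicalNetwork:
    """A validated signed logical network (cycles permitted)."""

    nodes: list[NodeSpec]
    interactions: list[Interaction]

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def input_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.role == "input"]

    @property
    def measured_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.role == "measured"]

    @property
    def readout_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.role == "readout"]

    @property
    def parameters(self) -> list[str]:
        """Parameter names in interaction order (one per interaction)."""
        return [i.parameter for i in self.interactions]

    def incoming(self, target: str) -> list[Interaction]:
        return [i for i in self.interactions if i.target == target]

    def incident(self, node: str) -> list[Interaction]:
        return [
            i for i in self.interactions if i.target == node or node in i.sources
        ]

    def is_acyclic(self) -> bool:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for i in self.interactions:
            for s in i.sources:
                g.add_edge(s, i.target)
        return nx.is_directed_acyclic_graph(g)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NetworkError(f"duplicate node names: {dup}")
        nameset = set(names)
        params = [i.parameter for i in self.interactions]
        if len(set(params)) != len(params):
            dup = sorted({p for p in params if params.count(p) > 1})
            raise NetworkError(f"duplicate parameter names: {dup}")
        clamped = {
            n.name for n in self.nodes if n.role == "input" or n.constitutive
        }
        for i in self.interactions:
            for s in i.sources:
                if s not in nameset:
                    raise NetworkError(f"interaction {i.id}: unknown source {s!r}")
            if i.target not in nameset:
                raise NetworkError(f"interaction {i.id}: unknown target {i.target!r}")
            if i.target in clamped:
                raise NetworkError(
                    f"interaction {i.id}: edge into input/constitutive "
                    f"node {i.target!r}"
                )


def remove_node_interactions(net: LogicalNetwork, node: str) -> LogicalNetwork:
    """Return a copy of *net* with all interactions incident to *node* removed.

    The node itself stays in the node list so that measurement rows for it
    remain addressable (it will simulate to its clamp/init value).
    """
    if node not in net.node_names:
        raise KeyError(node)
    keep = [i for i in net.interactions if i.target != node and node not in i.sources]
    return LogicalNetwork(nodes=list(net.nodes), interactions=keep)


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """One value per (reaction parameter x context).

    ``competition_groups`` are sets of parameter names whose values must sum
    to exactly 1 within each context (competing activators of one node).
    ``context_groups`` maps each parameter name to its per-context instances;
    these are the groups of the cross-context (grouped-L1) penalty.
    """

    contexts: list[str]
    values: dict[tuple[str, str], float]
    competition_groups: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (p, c), v in self.values.items():
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise NetworkError(f"parameter {p!r} in context {c!r}: {v} not in [0,1]")
        for g in self.competition_groups:
            for c in self.contexts:
                s = sum(self.values[(p, c)] for p in g)
                if abs(s - 1.0) > SUM_TOL:
                    raise NetworkError(
                        f"competition group {sorted(g)} sums to {s} in context {c!r}"
                    )

    @property
    def parameter_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p, _ in self.values:
            seen.setdefault(p)
        return list(seen)

    @property
    def context_groups(self) -> dict[str, list[tuple[str, str]]]:
        return {p: [(p, c) for c in self.contexts] for p in self.parameter_names}

    def for_context(self, context: str) -> dict[str, float]:
        return {p: self.values[(p, context)] for p in self.parameter_names}

    @classmethod
    def uniform(
        cls,
        net: LogicalNetwork,
        contexts: Iterable[str],
        value: float = 0.5,
        competition_groups: list[frozenset[str]] | None = None,
    ) -> "ParameterSet":
        """A parameter set with one value everywhere, groups renormalized."""
        contexts = list(contexts)
        groups = (
            competition_groups
            if competition_groups is not None
            else discover_competition_groups(net)
        )
        vals: dict[tuple[str, str], float] = {}
        grouped = {p for g in groups for p in g}
        for i in net.interactions:
            for c in contexts:
                vals[(i.parameter, c)] = value
        for g in groups:
            for c in contexts:
                for p in g:
                    vals[(p, c)] = 1.0 / len(g)
        # keep ungrouped at requested value
        for i in net.interactions:
            if i.parameter not in grouped:
                for c in contexts:
                    vals[(i.parameter, c)] = value
        return cls(contexts=contexts, values=vals, competition_groups=groups)


def discover_competition_groups(net: LogicalNetwork) -> list[frozenset[str]]:
    """Sum-to-one groups: parameters of nodes with >=2 incoming activations.

    A node with a single activator contributes no group (its weight is free
    in [0,1]); inhibitors never compete.
    """
    groups: list[frozenset[str]] = []
    for node in net.node_names:
        acts = [i for i in net.incoming(node) if i.sign == "activation"]
        if len(acts) >= 2:
            groups.append(frozenset(i.parameter for i in acts))
    return groups


# alias matching the operation name used in reports
competition_groups = discover_competition_groups


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    """An experimental condition: a set of input clamps."""

    id: str
    clamps: Mapping[str, float]


@dataclass(frozen=True)
class Measurement:
    mean: float
    sem: float
    n: int


@dataclass
class ExperimentTable:
    """Normalized measurements per (context, condition, measured node)."""

    contexts: list[str]
    conditions: list[Condition]
    measurements: dict[tuple[str, str, str], Measurement]
    time_label: str | None = None

    def __post_init__(self) -> None:
        cond_ids = {c.id for c in self.conditions}
        for (ctx, cond, node), m in self.measurements.items():
            if ctx not in self.contexts:
                raise NetworkError(f"unknown context {ctx!r}")
            if cond not in cond_ids:
                raise NetworkError(f"unknown condition {cond!r}")
            if not (0.0 <= m.mean <= 1.0):
                raise NetworkError(
                    f"measurement ({ctx},{cond},{node}): mean {m.mean} not in [0,1]"
                )
            if m.sem < 0:
                raise NetworkError(f"measurement ({ctx},{cond},{node}): SEM < 0")

    @property
    def n_points(self) -> int:
        """N: total number of fitted data points."""
        return len(self.measurements)

    @property
    def measured_nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, node in self.measurements:
            seen.setdefault(node)
        return list(seen)

    def condition(self, cond_id: str) -> Condition:
        for c in self.conditions:
            if c.id == cond_id:
                return c
        raise KeyError(cond_id)

    def restrict_context(self, context: str) -> "ExperimentTable":
        if context not in self.contexts:
            raise KeyError(context)
        meas = {
            k: m for k, m in self.measurements.items() if k[0] == context
        }
        return ExperimentTable(
            contexts=[context],
            conditions=list(self.conditions),
            measurements=meas,
            time_label=self.time_label,
        )

    def validate_against(self, net: LogicalNetwork) -> None:
        clampable = {
            n.name for n in net.nodes if n.role == "input" or n.constitutive
        }
        for c in self.conditions:
            for node in c.clamps:
                if node not in clampable:
                    raise NetworkError(
                        f"condition {c.id!r} clamps {node!r}, which is neither "
                        "an input nor constitutive"
                    )
        names = set(net.node_names)
        for _, _, node in self.measurements:
            if node not in names:
                raise NetworkError(f"measured node {node!r} not in network")


# ---------------------------------------------------------------------------
# interaction-list parsing / writing
# ---------------------------------------------------------------------------


def _split_sources(expr: str, lineno: int) -> tuple[tuple[str, ...], str]:
    if "&" in expr and "+" in expr:
        raise ParseError(f"line {lineno}: cannot mix '&' and '+' in one interaction")
    if "&" in expr:
        srcs = tuple(s.strip() for s in expr.split("&"))
        gate = "AND"
    elif "+" in expr:
        srcs = tuple(s.strip() for s in expr.split("+"))
        gate = "OR"
    else:
        srcs, gate = (expr.strip(),), "single"
    if any(not s for s in srcs):
        raise ParseError(f"line {lineno}: empty source name")
    return srcs, gate


def parse_network(stream: TextIO | str) -> LogicalNetwork:
    """Parse an interaction-list text into a validated :class:`LogicalNetwork`.

    Raises :class:`ParseError` (with the offending line number) on malformed
    lines and :class:`NetworkError` on schema violations.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    declared: dict[str, NodeSpec] = {}
    interactions: list[Interaction] = []
    mentioned: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if tokens[0] == "node":
            if len(tokens) < 3:
                raise ParseError(
                    f"line {lineno}: node declaration needs 'node NAME ROLE'"
                )
            name, role = tokens[1], tokens[2]
            constitutive = False
            if len(tokens) == 4:
                if tokens[3] != "constitutive":
                    raise ParseError(f"line {lineno}: unknown flag {tokens[3]!r}")
                constitutive = True
            elif len(tokens) > 4:
                raise ParseError(f"line {lineno}: too many tokens in node declaration")
            if role not in ROLES:
                raise ParseError(
                    f"line {lineno}: unknown role {role!r} (expected one of {ROLES})"
                )
            if name in declared:
                raise ParseError(f"line {lineno}: node {name!r} declared twice")
            declared[name] = NodeSpec(name=name, role=role, constitutive=constitutive)
            continue
        # interaction line: "SRC[...] -> TGT param" or "SRC -| TGT param"
        if "->" in line:
            sign, arrow = "activation", "->"
        elif "-|" in line:
            sign, arrow = "inhibition", "-|"
        else:
            raise ParseError(
                f"line {lineno}: expected 'node' declaration or an interaction "
                f"with '->' or '-|', got {line!r}"
            )
        left, _, right = line.partition(arrow)
        rtokens = right.split()
        if len(rtokens) != 2:
            raise ParseError(
                f"line {lineno}: expected 'TARGET parameter' after {arrow!r}, "
                f"got {right.strip()!r}"
            )
        target, param = rtokens
        sources, gate = _split_sources(left, lineno)
        if sign == "inhibition" and gate != "single":
            raise ParseError(
                f"line {lineno}: inhibition edges take a single source"
            )
        interactions.append(
            Interaction(
                id=f"r{len(interactions) + 1}",
                sources=sources,
                target=target,
                sign=sign,
                parameter=param,
                gate=gate,
            )
        )
        mentioned.extend(sources)
        mentioned.append(target)
    nodes = list(declared.values())
    known = set(declared)
    for name in mentioned:
        if name not in known:
            nodes.append(NodeSpec(name=name, role="latent"))
            known.add(name)
    return LogicalNetwork(nodes=nodes, interactions=interactions)


def write_network(net: LogicalNetwork, stream: TextIO | None = None) -> str:
    """Serialize a network back to the interaction-list dialect."""
    out = io.StringIO()
    for n in net.nodes:
        flag = " constitutive" if n.constitutive else ""
        out.write(f"node {n.name} {n.role}{flag}\n")
    joiner = {"single": "", "AND": " & ", "OR": " + "}
    for i in net.interactions:
        left = joiner[i.gate].join(i.sources) if i.gate != "single" else i.sources[0]
        arrow = "->" if i.sign == "activation" else "-|"
        out.write(f"{left} {arrow} {i.target} {i.parameter}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def network_to_json(net: LogicalNetwork) -> str:
    """JSON export of the parsed model (provenance record)."""
    return json.dumps(
        {
            "nodes": [
                {"name": n.name, "role": n.role, "constitutive": n.constitutive}
                for n in net.nodes
            ],
            "interactions": [
                {
                    "id": i.id,
                    "sources": list(i.sources),
                    "target": i.target,
                    "sign": i.sign,
                    "gate": i.gate,
                    "parameter": i.parameter,
                }
                for i in net.interactions
            ],
        },
        indent=2,
    )


# ---------------------------------------------------------------------------
# measurement I/O
# ---------------------------------------------------------------------------


def read_measurements(
    measurements: TextIO | str,
    conditions: TextIO | str,
    time_label: str | None = None,
) -> ExperimentTable:
    """Read a long-format measurement table plus a condition (clamp) sheet.

    The measurement table has columns ``context condition node mean sem n``;
    the condition sheet has columns ``condition node value`` (input clamps).
    Both are whitespace/tab-delimited text.
    """
    if isinstance(measurements, str):
        measurements = io.StringIO(measurements)
    if isinstance(conditions, str):
        conditions = io.StringIO(conditions)
    meas_df = pd.read_csv(measurements, sep=r"\s+", comment="#")
    cond_df = pd.read_csv(conditions, sep=r"\s+", comment="#")
    required = {"context", "condition", "node", "mean", "sem", "n"}
    if not required.issubset(meas_df.columns):
        raise ParseError(
            f"measurement table missing columns {sorted(required - set(meas_df.columns))}"
        )
    if cond_df.empty:
        raise ParseError("no input clamps defined")
    if not {"condition", "node", "value"}.issubset(cond_df.columns):
        raise ParseError("condition sheet needs columns: condition node value")

    conds: list[Condition] = []
    for cid, sub in cond_df.groupby("condition", sort=False):
        conds.append(
            Condition(id=str(cid), clamps=dict(zip(sub["node"], sub["value"])))
        )
    contexts: list[str] = []
    meas: dict[tuple[str, str, str], Measurement] = {}
    for row in meas_df.itertuples(index=False):
        ctx, cond, node = str(row.context), str(row.condition), str(row.node)
        if ctx not in contexts:
            contexts.append(ctx)
        mean = float(row.mean)
        if not (0.0 <= mean <= 1.0):
            raise NetworkError(
                f"measurement ({ctx},{cond},{node}): mean {mean} outside [0,1]"
            )
        meas[(ctx, cond, node)] = Measurement(
            mean=mean, sem=float(row.sem), n=int(row.n)
        )
    return ExperimentTable(
        contexts=contexts, conditions=conds, measurements=meas, time_label=time_label
    )


def write_measurements(table: ExperimentTable) -> tuple[str, str]:
    """Serialize an ExperimentTable to (measurement text, condition text)."""
    rows = [
        {
            "context": ctx,
            "condition": cond,
            "node": node,
            "mean": m.mean,
            "sem": m.sem,
            "n": m.n,
        }
        for (ctx, cond, node), m in table.measurements.items()
    ]
    meas = pd.DataFrame(rows).to_csv(sep="\t", index=False)
    crows = [
        {"condition": c.id, "node": node, "value": v}
        for c in table.conditions
        for node, v in c.clamps.items()
    ]
    cond = pd.DataFrame(crows).to_csv(sep="\t", index=False)
    return meas, cond
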