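"""Intervention prediction from a fitted model.

Supported interventions:

* ``knockout`` — the node is forced to 0 and all incident interactions are
  made inert (protein removal, e.g. siRNA-style XIAP depletion);
* ``clamp`` — the node is held at a fixed activity for all sweeps;
* ``remove_incoming`` — the node loses its incoming *inhibition* edges
  (degradation inputs) while keeping its activation (synthesis) inputs:
  the super-repressor idiom (a non-degradable IkBa mutant keeps being
  synthesized but no longer responds to IKK).  A node with no activation
  inputs instead becomes a constitutive source at its basal simulated
  level.

Readout activities are reported raw in [0, 1].  An optional linear
calibration can map activity to percent apoptosis from user-supplied
anchor points; it is never applied silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .netmodel import (
    ExperimentTable,
    LogicalNetwork,
    ParameterSet,
    remove_node_interactions,
)
from .simulate import SimulationSettings, steady_state

KINDS = ("knockout", "clamp", "remove_incoming")


@dataclass(frozen=True)
class Intervention:
    kind: str
    node: str
    clamp_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if (self.kind == "clamp") != (self.clamp_value is not None):
            raise ValueError("clamp_value must be given iff kind='clamp'")
        if self.clamp_value is not None and not (0.0 <= self.clamp_value <= 1.0):
            raise ValueError("clamp_value must be in [0,1]")

    @property
    def label(self) -> str:
        if self.kind == "clamp":
            return f"clamp({self.node}={self.clamp_value:g})"
        return f"{self.kind}({self.node})"


def apply_intervention(
    net: LogicalNetwork,
    params: ParameterSet,
    iv: Intervention,
    basal: float | None = None,
) -> tuple[LogicalNetwork, ParameterSet, dict[str, float]]:
    """Return the modified (network, params) plus the extra clamps to apply.

    ``basal`` is the node's reference steady-state activity, required for
    ``remove_incoming`` (the caller computes it from the unperturbed model).
    """
    if iv.node not in net.node_names:
        raise KeyError(iv.node)
    if net.node(iv.node).role == "input":
        raise ValueError(f"cannot intervene on input node {iv.node!r}")
    if iv.kind == "knockout":
        net2 = remove_node_interactions(net, iv.node)
        return net2, params, {iv.node: 0.0}
    if iv.kind == "clamp":
        # the clamp overrides incoming edges; outgoing signaling is kept
        return net, params, {iv.node: float(iv.clamp_value)}
    # remove_incoming: drop incoming inhibition (degradation) edges
    has_activation = any(
        i.target == iv.node and i.sign == "activation" for i in net.interactions
    )
    if has_activation:
        keep = [
            i
            for i in net.interactions
            if not (i.target == iv.node and i.sign == "inhibition")
        ]
        net2 = LogicalNetwork(nodes=list(net.nodes), interactions=keep)
        return net2, params, {}
    # no synthesis input modelled: hold the node at its basal level
    if basal is None:
        raise ValueError(
            "remove_incoming on a node without activation inputs needs its "
            "basal activity"
        )
    keep = [i for i in net.interactions if i.target != iv.node]
    net2 = LogicalNetwork(nodes=list(net.nodes), interactions=keep)
    return net2, params, {iv.node: float(basal)}


def _readout_nodes(net: LogicalNetwork) -> list[str]:
    ro = net.readout_nodes
    return ro if ro else net.measured_nodes


def predict(
    net: LogicalNetwork,
    params: ParameterSet,
    table: ExperimentTable,
    interventions: list[Intervention],
    settings: SimulationSettings | None = None,
    basal_condition: str | None = None,
    calibration: "LinearCalibration | None" = None,
) -> "PredictionReport":
    """Full-factorial (context x condition x intervention) readout prediction.

    The baseline ("none") row is always included.  For ``remove_incoming``
    the node's basal activity is taken from the unperturbed steady state
    under ``basal_condition`` (default: the table's first condition,
    typically the untreated one) in the same context.
    """
    seen: list[Intervention] = []
    for iv in interventions:
        if iv in seen:
            warnings.warn(f"duplicate intervention {iv.label} dropped")
        else:
            seen.append(iv)
    basal_cond = (
        table.condition(basal_condition)
        if basal_condition is not None
        else table.conditions[0]
    )
    readouts = _readout_nodes(net)
    rows = []
    for ctx in params.contexts:
        kctx = params.for_context(ctx)
        base_state = steady_state(
            net, kctx, dict(basal_cond.clamps), settings
        )
        variants: list[tuple[str, LogicalNetwork, dict[str, float]]] = [
            ("none", net, {})
        ]
        for iv in seen:
            basal = base_state.activities.get(iv.node)
            net2, _, extra = apply_intervention(net, params, iv, basal=basal)
            variants.append((iv.label, net2, extra))
        for cond in table.conditions:
            for label, net2, extra in variants:
                clamps = dict(cond.clamps)
                clamps.update(extra)
                st = steady_state(net2, kctx, clamps, settings)
                for node in readouts:
                    act = st.activities[node]
                    row = {
                        "context": ctx,
                        "condition": cond.id,
                        "intervention": label,
                        "readout": node,
                        "activity": act,
                        "converged": st.converged,
                    }
                    if calibration is not None:
                        row["percent"] = calibration(act)
                    rows.append(row)
    frame = pd.DataFrame(rows)
    return PredictionReport(table=frame)


@dataclass
class PredictionReport:
    table: pd.DataFrame

    def readout(
        self, context: str, condition: str, intervention: str, node: str | None = None
    ) -> float:
        sub = self.table[
            (self.table.context == context)
            & (self.table.condition == condition)
            & (self.table.intervention == intervention)
        ]
        if node is not None:
            sub = sub[sub.readout == node]
        return float(sub.activity.iloc[0])

    def best_intervention(self, context: str, condition: str) -> str:
        """Which intervention maximizes the (first) readout in a context."""
        sub = self.table[
            (self.table.context == context) & (self.table.condition == condition)
        ]
        node = sub.readout.iloc[0]
        sub = sub[sub.readout == node]
        return str(sub.loc[sub.activity.idxmax()].intervention)


@dataclass(frozen=True)
class LinearCalibration:
    """Linear map from readout activity to a percent scale.

    Defined by two anchor points (activity, percent).  A documented preset
    for the cell-death ELISA used with this model family maps an enrichment
    factor of 2 to 10% apoptosis; since the activity/enrichment relation is
    assay-specific, anchors must always be supplied explicitly.
    """

    a0: tuple[float, float]
    a1: tuple[float, float]

    def __call__(self, activity: float) -> float:
        (x0, y0), (x1, y1) = self.a0, self.a1
        if x1 == x0:
            raise ValueError("degenerate calibration anchors")
        return y0 + (activity - x0) * (y1 - y0) / (x1 - x0)
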