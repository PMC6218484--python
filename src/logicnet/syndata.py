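"""Synthetic ground truth, raw-measurement normalization, melanoma fixture.

The generator emulates the structure of the study data this package is
designed for: two cellular contexts, a handful of stimulation conditions,
five replicates per cell, measurements min-max normalized to [0, 1] per
protein, and a ground-truth parameter set split into shared, zero
(prunable) and context-specific reactions.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netmodel import (
    Condition,
    ExperimentTable,
    Interaction,
    LogicalNetwork,
    Measurement,
    NodeSpec,
    ParameterSet,
    discover_competition_groups,
    parse_network,
)
from .simulate import CompiledNetwork


@dataclass
class TruthSpec:
    """Shape of a synthetic ground truth.

    ``noise_sem`` is the target standard error of the replicate mean on the
    normalized scale; individual replicates get Gaussian noise with sd
    ``noise_sem * sqrt(replicates)`` so that averaging ``replicates`` values
    reproduces that SEM.
    """

    n_nodes: int
    n_reactions: int
    n_contexts: int = 2
    n_zero_reactions: int = 0
    n_specific_reactions: int = 0
    noise_sem: float = 0.0
    replicates: int = 5
    seed: int = 0
    n_inputs: int = 2
    measured_fraction: float = 0.6
    p_inhibition: float = 0.5
    specific_gap: float = 0.3
    raw_scale_range: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_zero_reactions + self.n_specific_reactions > self.n_reactions:
            raise ValueError("n_zero + n_specific must be <= n_reactions")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sem < 0:
            raise ValueError("noise_sem must be >= 0")
        if self.n_inputs < 1 or self.n_inputs >= self.n_nodes:
            raise ValueError("need 1 <= n_inputs < n_nodes")
        if self.n_reactions < self.n_nodes - self.n_inputs:
            raise ValueError(
                "infeasible spec: need at least one incoming reaction per "
                "non-input node"
            )
        if self.specific_gap * (self.n_contexts - 1) > 1.0:
            raise ValueError("specific_gap infeasible for this many contexts")


@dataclass
class RawMeasurements:
    """Per-replicate nonnegative raw intensities (arbitrary units).

    ``data`` columns: context, condition, node, replicate, value, and
    optionally time.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.data.groupby(
            [c for c in ("context", "condition", "node", "time") if c in self.data],
            sort=False,
        )["replicate"].count()
        if counts.nunique() > 1:
            raise ValueError("replicate count must be uniform per cell")
        if (self.data["value"] < 0).any():
            raise ValueError("raw intensities must be nonnegative")


# ---------------------------------------------------------------------------
# ground-truth generation
# ---------------------------------------------------------------------------


def _default_contexts(n: int) -> list[str]:
    if n == 2:
        return ["parental", "conditioned"]
    return [f"ctx{i + 1}" for i in range(n)]


def generate_truth(spec: TruthSpec) -> tuple[LogicalNetwork, ParameterSet]:
    """Random connected signed network plus a ground-truth parameter set.

    The network is acyclic with every non-input node reachable from the
    inputs; >= ``measured_fraction`` of nodes are measured.  Parameters are
    drawn uniform [0.2, 0.9] (competition groups renormalized to sum 1),
    then ``n_zero_reactions`` are zeroed in all contexts and
    ``n_specific_reactions`` are resampled per context with pairwise gaps
    >= ``specific_gap``.  Zero/specific reactions are drawn from parameters
    outside competition groups whose targets have a path to a measured
    node: inside a group a single-member change breaks the exact sum-to-one
    constraint, and an edge with no route to the data is unidentifiable.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    last_err: Exception | None = None
    for _attempt in range(50):
        try:
            return _generate_truth_once(spec, rng)
        except _Retry as err:
            last_err = err
    raise ValueError(f"infeasible spec: {last_err}")


class _Retry(Exception):
    pass


def _generate_truth_once(
    spec: TruthSpec, rng: np.random.Generator
) -> tuple[LogicalNetwork, ParameterSet]:
    n_in = spec.n_inputs
    names = [f"I{i + 1}" for i in range(n_in)] + [
        f"N{i + 1}" for i in range(spec.n_nodes - n_in)
    ]
    non_inputs = names[n_in:]
    n_measured = min(
        math.ceil(spec.measured_fraction * spec.n_nodes), len(non_inputs)
    )
    measured = set(
        rng.choice(non_inputs, size=n_measured, replace=False).tolist()
    )
    # spanning activation edges: node j gets one activator from earlier nodes,
    # cycling through the inputs first so every input drives the network
    edges: list[tuple[str, str, str]] = []  # (source, target, sign)
    edge_set: set[tuple[str, str]] = set()
    mandatory: set[int] = set()
    for j, tgt in enumerate(non_inputs):
        pool = names[: n_in + j]
        src = names[j % n_in] if j < n_in else str(rng.choice(pool))
        edges.append((src, tgt, "activation"))
        edge_set.add((src, tgt))
        mandatory.add(len(edges) - 1)
    # extra edges, forward only (acyclic), random sign
    attempts = 0
    while len(edges) < spec.n_reactions:
        attempts += 1
        if attempts > 200 * spec.n_reactions:
            raise _Retry("cannot place all reactions")
        ti = int(rng.integers(0, len(non_inputs)))
        tgt = non_inputs[ti]
        pool = names[: n_in + ti]
        src = str(rng.choice(pool))
        if (src, tgt) in edge_set or src == tgt:
            continue
        sign = "inhibition" if rng.random() < spec.p_inhibition else "activation"
        edges.append((src, tgt, sign))
        edge_set.add((src, tgt))

    # latent nodes are relays: any latent node with no path to a measured
    # node would carry unidentifiable parameters, so it is observed instead
    kids: dict[str, set[str]] = {}
    for src, tgt, _ in edges:
        kids.setdefault(src, set()).add(tgt)

    def _reaches_set(node: str, target_set: set[str]) -> bool:
        stack, seen = [node], set()
        while stack:
            cur = stack.pop()
            for child in kids.get(cur, ()):
                if child in target_set:
                    return True
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        return False

    for node in reversed(non_inputs):
        if node not in measured and not _reaches_set(node, measured):
            measured.add(node)

    nodes = [NodeSpec(n, "input") for n in names[:n_in]] + [
        NodeSpec(n, "measured" if n in measured else "latent") for n in non_inputs
    ]

    interactions = [
        Interaction(
            id=f"r{i + 1}",
            sources=(src,),
            target=tgt,
            sign=sign,
            parameter=f"k{i + 1}",
        )
        for i, (src, tgt, sign) in enumerate(edges)
    ]
    net = LogicalNetwork(nodes=nodes, interactions=interactions)
    groups = discover_competition_groups(net)
    grouped = {p for g in groups for p in g}

    # reachability of each edge's target to a measured node
    children: dict[str, set[str]] = {}
    for src, tgt, _ in edges:
        children.setdefault(src, set()).add(tgt)
    reach_measured: dict[str, bool] = {}

    def reaches(node: str, seen: frozenset = frozenset()) -> bool:
        if node in reach_measured:
            return reach_measured[node]
        if node in measured:
            reach_measured[node] = True
            return True
        ok = any(
            reaches(c) for c in children.get(node, ()) if c not in seen
        )
        reach_measured[node] = ok
        return ok

    eligible = [
        i
        for i, (src, tgt, _) in enumerate(edges)
        if interactions[i].parameter not in grouped and reaches(tgt)
    ]
    zero_pool = [i for i in eligible if i not in mandatory] or eligible
    if len(set(zero_pool)) < spec.n_zero_reactions:
        raise _Retry("not enough prunable reactions")
    zero_idx = set(
        rng.choice(zero_pool, size=spec.n_zero_reactions, replace=False).tolist()
    )
    spec_pool = [i for i in eligible if i not in zero_idx]
    if len(spec_pool) < spec.n_specific_reactions:
        raise _Retry("not enough context-varying reactions")
    spec_idx = set(
        rng.choice(spec_pool, size=spec.n_specific_reactions, replace=False).tolist()
    )

    contexts = _default_contexts(spec.n_contexts)
    base = rng.uniform(0.2, 0.9, size=len(edges))
    values: dict[tuple[str, str], float] = {}
    for i, inter in enumerate(interactions):
        for c in contexts:
            values[(inter.parameter, c)] = float(base[i])
    for g in groups:
        members = sorted(g)
        w = np.array([base[int(m[1:]) - 1] for m in members])
        w = w / w.sum()
        for m, v in zip(members, w):
            for c in contexts:
                values[(m, c)] = float(v)
    for i in zero_idx:
        for c in contexts:
            values[(interactions[i].parameter, c)] = 0.0
    for i in spec_idx:
        vals = _spread_values(rng, spec.n_contexts, spec.specific_gap)
        order = rng.permutation(spec.n_contexts)
        for ci, c in enumerate(contexts):
            values[(interactions[i].parameter, c)] = float(vals[order[ci]])
    params = ParameterSet(
        contexts=contexts, values=values, competition_groups=groups
    )
    return net, params


def _spread_values(
    rng: np.random.Generator, n: int, gap: float
) -> np.ndarray:
    """n values in [0,1] with all pairwise gaps >= gap."""
    slack = 1.0 - gap * (n - 1)
    offsets = np.sort(rng.uniform(0.0, slack, size=n))
    return offsets + gap * np.arange(n)


def corner_conditions(net: LogicalNetwork, cap: int = 8) -> list[Condition]:
    """All 0/1 input combinations (up to ``cap``), clamping every input."""
    inputs = net.input_nodes
    n = len(inputs)
    conds = []
    total = 2**n
    for b in range(min(total, cap)):
        clamps = {inp: float((b >> i) & 1) for i, inp in enumerate(inputs)}
        conds.append(Condition(id=f"c{b}", clamps=clamps))
    return conds


# ---------------------------------------------------------------------------
# data generation + normalization
# ---------------------------------------------------------------------------


def generate_data(
    net: LogicalNetwork,
    truth: ParameterSet,
    conditions: list[Condition],
    spec: TruthSpec,
    time_label: str | None = None,
) -> RawMeasurements:
    """Steady states plus replicate noise for every measured node.

    Per replicate: value = max(0, steady_state + N(0, noise_sem *
    sqrt(replicates))), optionally scaled by a per-protein raw intensity
    factor (densitometry-style arbitrary units).  Seeded by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    comp = CompiledNetwork(net)
    measured = net.measured_nodes
    lo, hi = spec.raw_scale_range
    scales = {
        node: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if hi > lo
        else float(lo)
        for node in measured
    }
    sd = spec.noise_sem * math.sqrt(spec.replicates)
    rows = []
    for ctx in truth.contexts:
        k = np.array([truth.for_context(ctx)[p] for p in comp.param_names])
        clamp = np.vstack([comp.clamp_matrix(c.clamps)[0] for c in conditions])
        states, _, _ = comp.steady_states(k, clamp)
        for ci, cond in enumerate(conditions):
            for node in measured:
                ss = states[ci, comp.index[node]]
                noise = rng.normal(0.0, sd, size=spec.replicates) if sd > 0 else 0.0
                vals = np.maximum(ss + noise, 0.0) * scales[node]
                vals = np.atleast_1d(vals)
                if vals.size == 1:
                    vals = np.repeat(vals, spec.replicates)
                for r, v in enumerate(vals, start=1):
                    row = {
                        "context": ctx,
                        "condition": cond.id,
                        "node": node,
                        "replicate": r,
                        "value": float(v),
                    }
                    if time_label is not None:
                        row["time"] = time_label
                    rows.append(row)
    return RawMeasurements(data=pd.DataFrame(rows))


def average_raw(
    raw: RawMeasurements,
    conditions: list[Condition],
    time_label: str | None = None,
) -> ExperimentTable:
    """Average replicates without rescaling (values already on [0,1] scale).

    The counterpart of :func:`normalize_measurements` for data generated on
    the model's activity scale: per-cell mean (clipped to [0,1]) and SEM.
    """
    df = raw.data
    if "time" in df.columns and df["time"].nunique() > 1:
        raise ValueError("multi-time raw data: average per time label")
    contexts = list(dict.fromkeys(df["context"]))
    meas: dict[tuple[str, str, str], Measurement] = {}
    for (ctx, cond, node), sub in df.groupby(
        ["context", "condition", "node"], sort=False
    ):
        v = sub["value"].to_numpy()
        sem = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
        meas[(str(ctx), str(cond), str(node))] = Measurement(
            mean=float(np.clip(v.mean(), 0.0, 1.0)), sem=sem, n=len(v)
        )
    return ExperimentTable(
        contexts=contexts,
        conditions=list(conditions),
        measurements=meas,
        time_label=time_label,
    )


def normalize_measurements(
    raw: RawMeasurements,
    conditions: list[Condition],
    time_label: str | None = None,
    average_first: bool = False,
) -> ExperimentTable:
    """Min-max normalize per protein, then average replicates.

    The min and max are pooled over every context, condition (and time
    point, if several tables are normalized together) for that protein; the
    per-cell mean and SEM (std / sqrt(n), ddof=1) are computed on the
    normalized scale.  ``average_first=True`` instead pools the min-max
    over the replicate means.  A protein with zero range raises.
    """
    df = raw.data
    if "time" in df.columns and df["time"].nunique() > 1:
        raise ValueError("multi-time raw data: use normalize_time_course")
    scaled = _minmax_scale(df, average_first=average_first)
    contexts = list(dict.fromkeys(scaled["context"]))
    meas: dict[tuple[str, str, str], Measurement] = {}
    for (ctx, cond, node), sub in scaled.groupby(
        ["context", "condition", "node"], sort=False
    ):
        v = sub["norm"].to_numpy()
        sem = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
        meas[(str(ctx), str(cond), str(node))] = Measurement(
            mean=float(np.clip(v.mean(), 0.0, 1.0)), sem=sem, n=len(v)
        )
    return ExperimentTable(
        contexts=contexts,
        conditions=list(conditions),
        measurements=meas,
        time_label=time_label,
    )


def _minmax_scale(df: pd.DataFrame, average_first: bool) -> pd.DataFrame:
    out = df.copy()
    out["norm"] = np.nan
    for node, sub in df.groupby("node", sort=False):
        if average_first:
            keys = [c for c in ("context", "condition", "time") if c in sub]
            means = sub.groupby(keys, sort=False)["value"].mean()
            lo, hi = float(means.min()), float(means.max())
        else:
            lo, hi = float(sub["value"].min()), float(sub["value"].max())
        if hi <= lo:
            raise ValueError(f"protein {node!r} has zero range; cannot normalize")
        out.loc[sub.index, "norm"] = (sub["value"] - lo) / (hi - lo)
    out["norm"] = out["norm"].clip(0.0, 1.0)
    return out


def normalize_time_course(
    raw: RawMeasurements,
    conditions: list[Condition],
    average_first: bool = False,
) -> dict[str, ExperimentTable]:
    """Normalize a multi-time raw table, pooling min-max across time points."""
    df = raw.data
    if "time" not in df.columns:
        raise ValueError("raw data has no time column")
    scaled = _minmax_scale(df, average_first=average_first)
    tables: dict[str, ExperimentTable] = {}
    for t, sub in scaled.groupby("time", sort=False):
        contexts = list(dict.fromkeys(sub["context"]))
        meas: dict[tuple[str, str, str], Measurement] = {}
        for (ctx, cond, node), cell in sub.groupby(
            ["context", "condition", "node"], sort=False
        ):
            v = cell["norm"].to_numpy()
            sem = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
            meas[(str(ctx), str(cond), str(node))] = Measurement(
                mean=float(np.clip(v.mean(), 0.0, 1.0)), sem=sem, n=len(v)
            )
        tables[str(t)] = ExperimentTable(
            contexts=contexts,
            conditions=list(conditions),
            measurements=meas,
            time_label=str(t),
        )
    return tables


# ---------------------------------------------------------------------------
# melanoma fixture
# ---------------------------------------------------------------------------

MELANOMA_CONTEXTS = ["parental", "conditioned"]
MELANOMA_TIME_LABELS = ["1h", "2h", "4h", "8h", "16h", "24h", "48h"]

# Divergence schedule between the two contexts over the stimulation time
# course: initiation (4h), execution (16h) and adaption (48h) phases are the
# most divergent, matching the phenotype the fixture emulates.
_DIVERGENCE = {
    "1h": 0.15,
    "2h": 0.25,
    "4h": 0.60,
    "8h": 0.35,
    "16h": 1.00,
    "24h": 0.45,
    "48h": 0.80,
}

_MELANOMA_SHARED = {
    "k_izi_trailr": 0.9,
    "k_trailr_casp8": 0.75,
    "k_casp3_casp8": 0.25,
    "k_casp8_casp3": 0.85,
    "k_casp3_parp": 0.8,
    "k_parp_apopt": 0.6,
    "k_casp3_apopt": 0.4,
    "k_casp8_smac": 0.6,
    "k_tak1_ikk": 0.7,
    "k_akt_ikk": 0.3,
    "k_nfkb_ikba": 0.5,
    "k_ikba_nfkb": 0.9,
    "k_nfkb_flip": 0.65,
    "k_erk_flip": 0.35,
    "k_nfkb_xiap": 0.85,
    "k_akt_xiap": 0.15,
    "k_braf_mek": 0.85,
    "k_mek_erk": 0.75,
    "k_pi3k_akt": 0.7,
}
_MELANOMA_ZERO = ["k_flip_casp8", "k_bcl2_casp3", "k_smac_xiap", "k_akt_casp3"]
_MELANOMA_SPECIFIC = {
    # parameter: (parental, conditioned)
    "k_xiap_casp3": (0.0135, 0.8715),
    "k_trailr_tak1": (0.45, 0.80),
    "k_ikk_ikba": (0.30, 0.95),
    "k_ikk_nfkb": (0.35, 0.95),
    "k_nfkb_bcl2": (0.25, 0.70),
    "k_trailr_pi3k": (0.60, 0.30),
}


def melanoma_fixture() -> tuple[LogicalNetwork, dict]:
    """The packaged melanoma signaling network and its condition template.

    19 nodes, 29 interaction parameters, 7 measured proteins (AKT, ERK,
    FLIP, XIAP, IkBa, NFkB, PARP).  The template lists the two contexts
    (parental / conditioned), the untreated and agonist-treated conditions
    and the stimulation time labels.  Edge set beyond the literature-named
    inhibitions is a synthetic reconstruction, not authoritative.
    """
    text = (
        importlib.resources.files("logicnet")
        .joinpath("data/melanoma.net.tsv")
        .read_text()
    )
    net = parse_network(text)
    template = {
        "contexts": list(MELANOMA_CONTEXTS),
        "conditions": [
            Condition(id="untreated", clamps={"IZI": 0.0}),
            Condition(id="IZI", clamps={"IZI": 1.0}),
        ],
        "time_labels": list(MELANOMA_TIME_LABELS),
        "measured": net.measured_nodes,
    }
    return net, template


def melanoma_synthetic_truth() -> ParameterSet:
    """Synthetic ground-truth parameters for the melanoma fixture.

    Emulates the study configuration: 19 shared reactions, 4 reactions at
    zero in both contexts (including the FLIP and BCL2 inhibitions) and 6
    context-specific reactions, dominated by a strong XIAP -| Casp3
    inhibition present only in the conditioned (resistant) context.
    """
    net, _ = melanoma_fixture()
    groups = discover_competition_groups(net)
    values: dict[tuple[str, str], float] = {}
    for p, v in _MELANOMA_SHARED.items():
        for c in MELANOMA_CONTEXTS:
            values[(p, c)] = v
    for p in _MELANOMA_ZERO:
        for c in MELANOMA_CONTEXTS:
            values[(p, c)] = 0.0
    for p, (vp, vc) in _MELANOMA_SPECIFIC.items():
        values[(p, "parental")] = vp
        values[(p, "conditioned")] = vc
    # order values in network parameter order for readability
    ordered = {
        (p, c): values[(p, c)]
        for p in net.parameters
        for c in MELANOMA_CONTEXTS
    }
    return ParameterSet(
        contexts=list(MELANOMA_CONTEXTS), values=ordered, competition_groups=groups
    )


def melanoma_truth_at_time(time_label: str) -> ParameterSet:
    """Truth parameters with context divergence scaled by the time schedule.

    At weight w the conditioned value of each context-specific reaction is
    parental + w * (conditioned - parental); shared and zero reactions are
    unchanged.  Weights peak at 4h, 16h and 48h.
    """
    w = _DIVERGENCE[time_label]
    base = melanoma_synthetic_truth()
    values = dict(base.values)
    for p, (vp, vc) in _MELANOMA_SPECIFIC.items():
        values[(p, "conditioned")] = vp + w * (vc - vp)
    return ParameterSet(
        contexts=list(base.contexts),
        values=values,
        competition_groups=base.competition_groups,
    )


def melanoma_synthetic_tables(
    seed: int = 0,
    noise_sem: float = 0.02,
    replicates: int = 5,
    time_labels: list[str] | None = None,
) -> dict[str, ExperimentTable]:
    """Synthetic melanoma-style time-course measurement tables.

    One table per time label (default: the full 1-48h course), generated
    from the fixture network and the time-scheduled synthetic truth.  The
    generated replicate values are already on the model's normalized
    activity scale, so they are averaged directly (no min-max re-scaling,
    which would amplify replicate noise for proteins that barely vary,
    e.g. the constitutively driven ERK here).
    """
    net, template = melanoma_fixture()
    labels = time_labels or list(MELANOMA_TIME_LABELS)
    conds = template["conditions"]
    tables: dict[str, ExperimentTable] = {}
    for i, t in enumerate(labels):
        truth = melanoma_truth_at_time(t)
        spec = TruthSpec(
            n_nodes=19,
            n_reactions=29,
            noise_sem=noise_sem,
            replicates=replicates,
            seed=seed * 1009 + i,
        )
        raw = generate_data(net, truth, conds, spec, time_label=t)
        raw_single = RawMeasurements(data=raw.data.drop(columns=["time"]))
        tables[t] = average_raw(raw_single, conds, time_label=t)
    return tables
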