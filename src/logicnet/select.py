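"""Model selection: regularization grid scans, AIC/BIC, knockouts, profiling.

The hyper-parameter pair (lambda1, lambda2) is scanned over a half-log grid
(default 1e-10 ... 1e2, 25 values, plus 0 = 26 per axis, 676 cells).  Each
cell is fitted with warm-starting from the neighbouring cell so parameter
estimates move continuously along the regularization path; cells are scored
by BIC with the effective (thresholded, shared-collapsed) parameter count,
and the minimum-BIC cell defines the selected model structure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import FitResult, FitSettings, ObjectiveSpec, fit
from .netmodel import ExperimentTable, LogicalNetwork, ParameterSet

PRUNE_THRESHOLD = 0.01


@dataclass(frozen=True)
class ScanGrid:
    """Ordered regularization strengths for one axis."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = self.values
        if any(x < 0 for x in v):
            raise ValueError("grid values must be >= 0")
        body = v[1:] if v and v[0] == 0.0 else v
        if any(b <= a for a, b in zip(body, body[1:])):
            raise ValueError("grid values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def make_grid(
    vmin: float,
    vmax: float,
    mode: str = "half_log",
    include_zero: bool = True,
    base: float = 10.0,
) -> ScanGrid:
    """Half-log-spaced grid: vmin * base**(i/2) up to vmax inclusive.

    The default span 1e-10 ... 1e2 yields 25 values; with the leading zero,
    26 per axis and 676 (lambda1, lambda2) cells.
    """
    if mode != "half_log":
        raise ValueError(f"unknown grid mode {mode!r}")
    if not (0 < vmin < vmax):
        raise ValueError("need 0 < vmin < vmax")
    vals = []
    i = 0
    while True:
        v = vmin * base ** (0.5 * i)
        if v > vmax * (1 + 1e-12):
            break
        vals.append(float(v))
        i += 1
    if include_zero:
        vals = [0.0] + vals
    return ScanGrid(values=tuple(vals))


# ---------------------------------------------------------------------------
# information criteria & effective parameters
# ---------------------------------------------------------------------------


def _mse_floor(mse_value: float) -> float:
    if mse_value <= 0:
        warnings.warn("MSE <= 0 floored at machine epsilon for AIC/BIC")
        return float(np.finfo(float).eps)
    return mse_value


def aic(n: int, mse_value: float, p: int) -> float:
    """Akaike Information Criterion: N ln(MSE) + 2 P."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * math.log(_mse_floor(mse_value)) + 2 * p


def bic(n: int, mse_value: float, p: int) -> float:
    """Bayesian Information Criterion: N ln(MSE) + ln(N) P."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * math.log(_mse_floor(mse_value)) + math.log(n) * p


def _reaction_label(vals: np.ndarray, threshold: float) -> str:
    if (vals < threshold).all():
        return "inactive"
    if len(vals) == 1:
        return "shared"
    diffs = np.abs(vals[:, None] - vals[None, :])
    if diffs.max() < threshold:
        return "shared"
    return "context_specific"


def classify_reactions(
    params: ParameterSet, threshold: float = PRUNE_THRESHOLD
) -> dict[str, str]:
    """Per-reaction label: inactive (prunable), shared, or context_specific.

    A reaction below *threshold* in every context is inactive; one whose
    per-context values all agree within *threshold* is shared (one effective
    parameter); anything else is context-specific.
    """
    labels = {}
    for p in params.parameter_names:
        vals = np.array([params.values[(p, c)] for c in params.contexts])
        labels[p] = _reaction_label(vals, threshold)
    return labels


def classification_counts(labels: dict[str, str]) -> tuple[int, int, int]:
    """(shared, zero, context_specific) counts."""
    lab = list(labels.values())
    return (
        lab.count("shared"),
        lab.count("inactive"),
        lab.count("context_specific"),
    )


def effective_param_count(
    params: ParameterSet, threshold: float = PRUNE_THRESHOLD
) -> int:
    """Effective number of parameters after pruning and context collapsing.

    inactive reactions contribute 0, shared reactions 1, context-specific
    reactions one per context.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n_ctx = len(params.contexts)
    total = 0
    for label in classify_reactions(params, threshold).values():
        if label == "shared":
            total += 1
        elif label == "context_specific":
            total += n_ctx
    return total


# ---------------------------------------------------------------------------
# grid scan
# ---------------------------------------------------------------------------


@dataclass
class ScanCell:
    lambda1: float
    lambda2: float
    fit: FitResult | None
    mse: float
    p_eff: int
    bic: float
    failed: bool = False


@dataclass
class ScanResult:
    grid1: ScanGrid
    grid2: ScanGrid
    cells: list[list[ScanCell]]  # [i2][i1] — lambda2 rows, lambda1 columns
    best: ScanCell
    classification: dict[str, str]
    n_points: int

    @property
    def n_cells(self) -> int:
        return len(self.grid1) * len(self.grid2)

    def matrix(self, field_name: str) -> pd.DataFrame:
        """Landscape matrix (rows lambda2, columns lambda1) for one panel."""
        getter = {
            "bic": lambda c: c.bic,
            "p_eff": lambda c: c.p_eff,
            "mse": lambda c: c.mse,
            "log_mse": lambda c: math.log10(c.mse) if c.mse > 0 else np.nan,
        }[field_name]
        data = [[getter(c) for c in row] for row in self.cells]
        return pd.DataFrame(
            data, index=list(self.grid2.values), columns=list(self.grid1.values)
        )


def scan(
    net: LogicalNetwork,
    table: ExperimentTable,
    grid1: ScanGrid,
    grid2: ScanGrid,
    settings: FitSettings | None = None,
    threshold: float = PRUNE_THRESHOLD,
    smoothing_eps: float = 1e-8,
) -> ScanResult:
    """Fit every (lambda1, lambda2) cell and select the minimum-BIC model.

    Cells are visited in a snake path over the grid, warm-starting each fit
    from the previous cell's solution; default 3 restarts per cell (warm +
    2 random).  Failed cells are recorded and excluded from the argmin.
    """
    settings = settings or FitSettings(restarts=3)
    n = table.n_points
    rows: list[list[ScanCell]] = []
    prev_params: ParameterSet | None = None
    best: ScanCell | None = None
    for i2, lam2 in enumerate(grid2):
        row: list[ScanCell] = [None] * len(grid1)  # type: ignore[list-item]
        order = (
            list(enumerate(grid1))
            if i2 % 2 == 0
            else list(enumerate(grid1))[::-1]
        )
        for i1, lam1 in order:
            spec = ObjectiveSpec(
                lambda1=lam1, lambda2=lam2, smoothing_eps=smoothing_eps
            )
            try:
                res = fit(net, table, spec, settings, initial=prev_params)
                p_eff = effective_param_count(res.params, threshold)
                cell = ScanCell(
                    lambda1=lam1,
                    lambda2=lam2,
                    fit=res,
                    mse=res.mse,
                    p_eff=p_eff,
                    bic=bic(n, res.mse, p_eff),
                )
                prev_params = res.params
            except Exception:
                cell = ScanCell(
                    lambda1=lam1,
                    lambda2=lam2,
                    fit=None,
                    mse=np.nan,
                    p_eff=0,
                    bic=np.nan,
                    failed=True,
                )
            row[i1] = cell
            if not cell.failed and (best is None or cell.bic < best.bic):
                best = cell
        rows.append(row)
    if best is None:
        raise RuntimeError("all grid cells failed to fit")
    return ScanResult(
        grid1=grid1,
        grid2=grid2,
        cells=rows,
        best=best,
        classification=classify_reactions(best.fit.params, threshold),
        n_points=n,
    )


# ---------------------------------------------------------------------------
# in-silico knockouts
# ---------------------------------------------------------------------------


@dataclass
class KnockoutReport:
    """Signed dAIC per (node, context, time label); reference rows are 0."""

    table: pd.DataFrame  # columns: time, context, node, delta_aic, mse, p_eff, defined

    def max_delta(self, context: str, time_label: str) -> str:
        sub = self.table[
            (self.table.context == context)
            & (self.table.time == time_label)
            & (self.table.node != "(reference)")
            & self.table.defined
        ]
        return str(sub.loc[sub.delta_aic.idxmax()].node)


def knockout_scan(
    net: LogicalNetwork,
    tables: dict[str, ExperimentTable],
    settings: FitSettings | None = None,
    spec: ObjectiveSpec | None = None,
    threshold: float = PRUNE_THRESHOLD,
) -> KnockoutReport:
    """Systematic single-node knockouts per context and time label.

    For each (context, time) a reference model is fitted to that context's
    data; each non-input node is then removed (all incident interactions
    deleted, node forced to 0) and the reduced model refitted.  dAIC =
    AIC_KO - AIC_reference; the reference entry is exactly 0.  Refits are
    plain-MSE (lambda = 0) by default.  A knockout leaving the reduced
    network with no interactions at all (nothing left to refit) is flagged
    with ``defined=False``.
    """
    from .netmodel import remove_node_interactions

    settings = settings or FitSettings(restarts=3)
    spec = spec or ObjectiveSpec(lambda1=0.0, lambda2=0.0)
    rows = []
    for time_label, table in tables.items():
        for ctx in table.contexts:
            sub = table.restrict_context(ctx)
            ref = fit(net, sub, spec, settings)
            p_ref = effective_param_count(ref.params, threshold)
            aic_ref = aic(sub.n_points, ref.mse, p_ref)
            rows.append(
                {
                    "time": time_label,
                    "context": ctx,
                    "node": "(reference)",
                    "delta_aic": 0.0,
                    "mse": ref.mse,
                    "p_eff": p_ref,
                    "defined": True,
                }
            )
            targets = [
                n.name for n in net.nodes if n.role != "input"
            ]
            for node in targets:
                reduced = remove_node_interactions(net, node)
                if node in reduced.node_names:
                    # force the knocked-out node inactive even if constitutive
                    reduced = _clear_constitutive(reduced, node)
                defined = len(reduced.interactions) > 0
                if not defined:
                    rows.append(
                        {
                            "time": time_label,
                            "context": ctx,
                            "node": node,
                            "delta_aic": np.nan,
                            "mse": np.nan,
                            "p_eff": 0,
                            "defined": False,
                        }
                    )
                    continue
                res = fit(reduced, sub, spec, settings)
                p_ko = effective_param_count(res.params, threshold)
                d = aic(sub.n_points, res.mse, p_ko) - aic_ref
                rows.append(
                    {
                        "time": time_label,
                        "context": ctx,
                        "node": node,
                        "delta_aic": d,
                        "mse": res.mse,
                        "p_eff": p_ko,
                        "defined": True,
                    }
                )
    return KnockoutReport(table=pd.DataFrame(rows))


def _clear_constitutive(net: LogicalNetwork, node: str) -> LogicalNetwork:
    from .netmodel import NodeSpec

    nodes = [
        NodeSpec(n.name, n.role, False) if n.name == node else n for n in net.nodes
    ]
    return LogicalNetwork(nodes=nodes, interactions=list(net.interactions))


# ---------------------------------------------------------------------------
# context-difference profiling
# ---------------------------------------------------------------------------


def context_difference_profile(
    tables: dict[str, ExperimentTable],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-time differences between the two contexts' measured profiles.

    Returns a signed (node x time) matrix of mean differences (context2 -
    context1, averaged over conditions) and a per-time score — the summed
    absolute difference over all (node, condition) cells — sorted so the
    most divergent time labels rank first.
    """
    matrices: dict[str, dict[str, float]] = {}
    scores: dict[str, float] = {}
    for time_label, table in tables.items():
        if len(table.contexts) < 2:
            raise ValueError("context_difference_profile needs two contexts")
        c1, c2 = table.contexts[:2]
        per_node: dict[str, list[float]] = {}
        score = 0.0
        for (ctx, cond, node), m in table.measurements.items():
            if ctx != c1:
                continue
            other = table.measurements.get((c2, cond, node))
            if other is None:
                warnings.warn(
                    f"node {node!r} ({cond}) missing in context {c2!r}; excluded"
                )
                continue
            d = other.mean - m.mean
            per_node.setdefault(node, []).append(d)
            score += abs(d)
        matrices[time_label] = {
            node: float(np.mean(ds)) for node, ds in per_node.items()
        }
        scores[time_label] = score
    matrix = pd.DataFrame(matrices)
    ranked = pd.Series(scores).sort_values(ascending=False)
    return matrix, ranked
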