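"""Regularized objective and constrained multi-start parameter fitting.

The fitted quantity is the joint parameter set over all contexts.  The
objective is

    MSE + lambda1 * sum_k sqrt(k) + lambda2 * sum_g sum_j |k_j^g - mean(k^g)|

with the mean squared error taken over every (context, condition, measured
node) data point, the L1/2 semi-norm over every parameter instance (all
contexts), and the grouped L1 term over each reaction's per-context
instances.  The L1/2 semi-norm is what induces sparsity here: under the
sum-to-one constraint on competing activators a plain L1 norm is constant.

Optimization is SLSQP with box bounds [0,1] on every parameter and exact
equality constraints (sum of each competition group = 1 per context), from
several seeded feasible starts.  The non-smooth terms are smoothed as
sqrt(. + eps) inside the optimizer; reported values are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .netmodel import (
    ExperimentTable,
    LogicalNetwork,
    ParameterSet,
    discover_competition_groups,
)
from .simulate import CompiledNetwork, SimulationSettings


@dataclass
class ObjectiveSpec:
    """Regularization strengths for the fitted objective."""

    lambda1: float = 0.0  # L1/2 semi-norm (sparsity / pruning)
    lambda2: float = 0.0  # grouped L1 across contexts (shared values)
    smoothing_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization strengths must be >= 0")
        if self.smoothing_eps <= 0:
            raise ValueError("smoothing_eps must be > 0")


@dataclass
class FitSettings:
    restarts: int = 10
    seed: int = 0
    tol: float = 1e-9
    max_iter: int = 200
    simulation: SimulationSettings = field(default_factory=SimulationSettings)

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class FitResult:
    params: ParameterSet
    mse: float
    objective: float
    l_half: float
    grouped_l1: float
    start_objectives: list[float]
    best_start: int
    converged: bool


# ---------------------------------------------------------------------------
# objective pieces (exact, reporting scale)
# ---------------------------------------------------------------------------


def mse(simulated, table: ExperimentTable) -> float:
    """Mean squared error between simulated values and measurement means.

    ``simulated`` is the frame returned by
    :func:`logicnet.simulate.simulate_experiments`.  Unweighted by SEM.
    """
    if table.n_points == 0:
        raise ValueError("empty measurement table (N = 0)")
    sim = {
        (r.context, r.condition, r.node): r.simulated
        for r in simulated.itertuples(index=False)
    }
    total = 0.0
    for key, m in table.measurements.items():
        total += (m.mean - sim[key]) ** 2
    return total / table.n_points


def l_half_penalty(params: ParameterSet) -> float:
    """L1/2 semi-norm: sum of sqrt(k) over every parameter instance."""
    vals = np.array(list(params.values.values()))
    if (vals < 0).any():
        raise ValueError("negative parameter value in L1/2 penalty")
    return float(np.sqrt(vals).sum())


def grouped_l1_penalty(params: ParameterSet) -> float:
    """Grouped L1 across contexts: sum_g sum_j |k_j^g - mean(k^g)|."""
    total = 0.0
    for _p, members in params.context_groups.items():
        vals = np.array([params.values[m] for m in members])
        total += float(np.abs(vals - vals.mean()).sum())
    return total


def objective(
    net: LogicalNetwork,
    params: ParameterSet,
    table: ExperimentTable,
    spec: ObjectiveSpec,
) -> float:
    """Exact regularized objective for a given parameter set."""
    from .simulate import simulate_experiments

    sim = simulate_experiments(net, params, table)
    return (
        mse(sim, table)
        + spec.lambda1 * l_half_penalty(params)
        + spec.lambda2 * grouped_l1_penalty(params)
    )


# ---------------------------------------------------------------------------
# fast fitting problem
# ---------------------------------------------------------------------------


class FitProblem:
    """Pre-compiled fitting problem: network, data layout, constraints.

    The parameter vector is laid out context-major: theta[c*R + r] is
    reaction r's value in context c, with reactions in network order.
    """

    def __init__(
        self,
        net: LogicalNetwork,
        table: ExperimentTable,
        spec: ObjectiveSpec | None = None,
        simulation: SimulationSettings | None = None,
    ):
        table.validate_against(net)
        if table.n_points == 0:
            raise ValueError("empty measurement table")
        self.net = net
        self.table = table
        self.spec = spec or ObjectiveSpec()
        self.simulation = simulation or SimulationSettings()
        self.comp = CompiledNetwork(net)
        self.contexts = list(table.contexts)
        self.n_reactions = len(self.comp.param_names)
        self.n_theta = self.n_reactions * len(self.contexts)
        # condition clamp matrix (shared across contexts)
        self.cond_ids = [c.id for c in table.conditions]
        self.clamp = np.vstack(
            [self.comp.clamp_matrix(c.clamps)[0] for c in table.conditions]
        )
        cond_idx = {cid: i for i, cid in enumerate(self.cond_ids)}
        # row layout per context
        self._rows: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for ctx in self.contexts:
            ci, ni, y = [], [], []
            for (mctx, mcond, node), m in table.measurements.items():
                if mctx != ctx:
                    continue
                ci.append(cond_idx[mcond])
                ni.append(self.comp.index[node])
                y.append(m.mean)
            self._rows[ctx] = (
                np.array(ci, dtype=np.intp),
                np.array(ni, dtype=np.intp),
                np.array(y),
            )
        self.n_points = table.n_points
        # competition groups as index sets
        self.groups = discover_competition_groups(net)
        pidx = self.comp.param_index
        self._group_idx = [
            np.array(sorted(pidx[p] for p in g), dtype=np.intp) for g in self.groups
        ]

    # -- theta <-> ParameterSet -----------------------------------------
    def theta_from_params(self, params: ParameterSet) -> np.ndarray:
        theta = np.empty(self.n_theta)
        for c, ctx in enumerate(self.contexts):
            for r, p in enumerate(self.comp.param_names):
                theta[c * self.n_reactions + r] = params.values[(p, ctx)]
        return theta

    def params_from_theta(self, theta: np.ndarray) -> ParameterSet:
        theta = np.clip(theta, 0.0, 1.0).copy()
        # re-impose the sum-to-one constraints exactly
        for c in range(len(self.contexts)):
            off = c * self.n_reactions
            for gidx in self._group_idx:
                s = theta[off + gidx].sum()
                if s > 0:
                    theta[off + gidx] /= s
                else:
                    theta[off + gidx] = 1.0 / len(gidx)
        values = {}
        for c, ctx in enumerate(self.contexts):
            for r, p in enumerate(self.comp.param_names):
                values[(p, ctx)] = float(theta[c * self.n_reactions + r])
        return ParameterSet(
            contexts=list(self.contexts), values=values, competition_groups=self.groups
        )

    # -- objective -------------------------------------------------------
    def simulate_rows(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(simulated, measured) vectors over all data points."""
        sims, ys = [], []
        for c, ctx in enumerate(self.contexts):
            k = theta[c * self.n_reactions : (c + 1) * self.n_reactions]
            states, _conv, _ = self.comp.steady_states(k, self.clamp, self.simulation)
            ci, ni, y = self._rows[ctx]
            sims.append(states[ci, ni])
            ys.append(y)
        return np.concatenate(sims), np.concatenate(ys)

    def mse_theta(self, theta: np.ndarray) -> float:
        sim, y = self.simulate_rows(theta)
        return float(np.mean((y - sim) ** 2))

    def penalties_theta(
        self, theta: np.ndarray, smoothed: bool = False
    ) -> tuple[float, float]:
        eps = self.spec.smoothing_eps if smoothed else 0.0
        t = np.clip(theta, 0.0, None)
        p1 = float(np.sqrt(t + eps).sum())
        mat = theta.reshape(len(self.contexts), self.n_reactions)
        dev = mat - mat.mean(axis=0, keepdims=True)
        p2 = float(np.sqrt(dev**2 + eps).sum()) if smoothed else float(
            np.abs(dev).sum()
        )
        return p1, p2

    def objective_theta(self, theta: np.ndarray, smoothed: bool = True) -> float:
        m = self.mse_theta(theta)
        p1, p2 = self.penalties_theta(theta, smoothed=smoothed)
        return m + self.spec.lambda1 * p1 + self.spec.lambda2 * p2

    def objective_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Smoothed objective and its analytic gradient.

        The MSE gradient uses forward-mode sensitivities of the steady
        state; the penalty gradients are closed-form on the smoothed terms.
        """
        R = self.n_reactions
        grad = np.zeros_like(theta)
        sq_sum = 0.0
        for c, ctx in enumerate(self.contexts):
            k = theta[c * R : (c + 1) * R]
            states, jac, _conv, _ = self.comp.steady_states_with_grad(
                k, self.clamp, self.simulation
            )
            ci, ni, y = self._rows[ctx]
            resid = states[ci, ni] - y
            sq_sum += float(resid @ resid)
            grad[c * R : (c + 1) * R] = (2.0 / self.n_points) * (
                resid @ jac[ci, ni, :]
            )
        m = sq_sum / self.n_points
        eps = self.spec.smoothing_eps
        t = np.clip(theta, 0.0, None)
        p1 = float(np.sqrt(t + eps).sum())
        grad += self.spec.lambda1 * 0.5 / np.sqrt(t + eps)
        mat = theta.reshape(len(self.contexts), R)
        dev = mat - mat.mean(axis=0, keepdims=True)
        root = np.sqrt(dev**2 + eps)
        p2 = float(root.sum())
        s = dev / root
        grad += (
            self.spec.lambda2 * (s - s.mean(axis=0, keepdims=True))
        ).reshape(-1)
        return (
            m + self.spec.lambda1 * p1 + self.spec.lambda2 * p2,
            grad,
        )

    # -- constraints -----------------------------------------------------
    def constraints(self) -> list[dict]:
        cons = []
        for c in range(len(self.contexts)):
            off = c * self.n_reactions
            for gidx in self._group_idx:
                idx = off + gidx

                def fun(theta, idx=idx):
                    return theta[idx].sum() - 1.0

                def jac(theta, idx=idx):
                    g = np.zeros_like(theta)
                    g[idx] = 1.0
                    return g

                cons.append({"type": "eq", "fun": fun, "jac": jac})
        return cons

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        theta = rng.uniform(0.0, 1.0, size=self.n_theta)
        for c in range(len(self.contexts)):
            off = c * self.n_reactions
            for gidx in self._group_idx:
                theta[off + gidx] = rng.dirichlet(np.ones(len(gidx)))
        return theta


def fit(
    net: LogicalNetwork,
    table: ExperimentTable,
    spec: ObjectiveSpec | None = None,
    settings: FitSettings | None = None,
    initial: ParameterSet | np.ndarray | None = None,
) -> FitResult:
    """Fit the joint (all-contexts) parameter set by multi-start SLSQP.

    ``initial``, if given, is used as the first start (warm start along a
    regularization path); the remaining ``restarts - 1`` starts are seeded
    uniform feasible points.  Deterministic for fixed seed and settings.
    """
    spec = spec or ObjectiveSpec()
    settings = settings or FitSettings()
    prob = FitProblem(net, table, spec, settings.simulation)
    rng = np.random.default_rng(settings.seed)

    starts: list[np.ndarray] = []
    if initial is not None:
        theta0 = (
            prob.theta_from_params(initial)
            if isinstance(initial, ParameterSet)
            else np.asarray(initial, dtype=float)
        )
        starts.append(theta0)
    while len(starts) < settings.restarts:
        starts.append(prob.random_start(rng))

    cons = prob.constraints()
    bounds = [(0.0, 1.0)] * prob.n_theta
    best_theta, best_obj, best_i = None, np.inf, -1
    start_objs: list[float] = []
    any_converged = False
    for i, x0 in enumerate(starts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                prob.objective_and_grad,
                x0,
                jac=True,
                method="SLSQP",
                bounds=bounds,
                constraints=cons,
                options={"maxiter": settings.max_iter, "ftol": settings.tol},
            )
        obj = prob.objective_theta(res.x, smoothed=False)
        start_objs.append(obj)
        any_converged = any_converged or bool(res.success)
        if obj < best_obj:
            best_theta, best_obj, best_i = res.x, obj, i

    params = prob.params_from_theta(best_theta)
    theta_final = prob.theta_from_params(params)
    m = prob.mse_theta(theta_final)
    p1, p2 = prob.penalties_theta(theta_final, smoothed=False)
    return FitResult(
        params=params,
        mse=m,
        objective=m + spec.lambda1 * p1 + spec.lambda2 * p2,
        l_half=p1,
        grouped_l1=p2,
        start_objectives=start_objs,
        best_start=best_i,
        converged=any_converged,
    )


def fit_report(result: FitResult) -> dict:
    """JSON-serializable fit report."""
    return {
        "contexts": result.params.contexts,
        "parameters": {
            f"{p}@{c}": v for (p, c), v in sorted(result.params.values.items())
        },
        "mse": result.mse,
        "objective": result.objective,
        "l_half_penalty": result.l_half,
        "grouped_l1_penalty": result.grouped_l1,
        "converged": result.converged,
        "best_start": result.best_start,
        "start_objectives": result.start_objectives,
    }
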