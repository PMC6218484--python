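"""Grids, information criteria, effective parameters, knockouts, profiling."""

import math

import numpy as np
import pytest

import logicnet as ln
from logicnet.select import classification_counts


class TestMakeGrid:
    def test_default_span_has_26_values(self):
        grid = ln.make_grid(1e-10, 1e2, include_zero=True)
        assert len(grid) == 26
        assert grid.values[0] == 0.0
        assert grid.values[1] == pytest.approx(1e-10)
        assert grid.values[-1] == pytest.approx(1e2)

    def test_three_half_log_steps(self):
        grid = ln.make_grid(1, 10, include_zero=False)
        assert list(grid.values) == pytest.approx([1.0, math.sqrt(10), 10.0])

    def test_two_axes_give_676_cells(self):
        g = ln.make_grid(1e-10, 1e2)
        assert len(g) * len(g) == 676

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            ln.make_grid(10, 1)

    def test_decreasing_values_rejected(self):
        with pytest.raises(ValueError):
            ln.ScanGrid(values=(0.0, 1.0, 0.5))


class TestInformationCriteria:
    def test_aic_log_identity(self):
        assert ln.aic(100, math.exp(-1), 0) == pytest.approx(-100.0)

    def test_aic_parameter_increment(self):
        assert ln.aic(50, 0.3, 5) - ln.aic(50, 0.3, 4) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 500))
        mse = float(rng.uniform(1e-6, 1.0))
        p = int(rng.integers(0, 60))
        assert ln.aic(n, mse, p) == pytest.approx(n * math.log(mse) + 2 * p)
        assert ln.bic(n, mse, p) == pytest.approx(
            n * math.log(mse) + math.log(n) * p
        )

    def test_bic_penalizes_more_when_n_exceeds_e2(self):
        n = 8  # > e^2
        assert ln.bic(n, 0.1, 3) - ln.bic(n, 0.1, 2) > ln.aic(n, 0.1, 3) - ln.aic(
            n, 0.1, 2
        )

    def test_zero_mse_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            v = ln.aic(10, 0.0, 1)
        assert np.isfinite(v)


class TestEffectiveParameters:
    def test_printed_configuration_counts_31(self, melanoma_truth):
        assert ln.effective_param_count(melanoma_truth) == 31

    def test_all_zero_counts_0(self):
        p = ln.ParameterSet(
            contexts=["a", "b"],
            values={(f"k{i}", c): 0.0 for i in range(5) for c in "ab"},
        )
        assert ln.effective_param_count(p) == 0

    def test_all_specific_two_contexts_counts_double(self):
        vals = {}
        for i in range(29):
            vals[(f"k{i}", "a")] = 0.2
            vals[(f"k{i}", "b")] = 0.8
        p = ln.ParameterSet(contexts=["a", "b"], values=vals)
        assert ln.effective_param_count(p) == 58

    def test_threshold_monotonicity(self, melanoma_truth):
        counts = [
            ln.effective_param_count(melanoma_truth, t)
            for t in [0.001, 0.01, 0.05, 0.2, 0.5]
        ]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize(
        "vals,label",
        [
            ((0.005, 0.003), "inactive"),
            ((0.40, 0.41), "shared"),
            ((0.0135, 0.8715), "context_specific"),
        ],
    )
    def test_classification_examples(self, vals, label):
        p = ln.ParameterSet(
            contexts=["a", "b"], values={("k", "a"): vals[0], ("k", "b"): vals[1]}
        )
        assert ln.classify_reactions(p)["k"] == label

    def test_classification_partitions_reactions(self, melanoma_truth):
        labels = ln.classify_reactions(melanoma_truth)
        assert len(labels) == 29
        assert sum(classification_counts(labels)) == 29


class TestScan:
    @pytest.fixture(scope="class")
    def small_problem(self):
        spec = ln.TruthSpec(
            n_nodes=6, n_reactions=7, n_zero_reactions=1, noise_sem=0.01, seed=8
        )
        net, truth = ln.generate_truth(spec)
        conds = ln.corner_conditions(net)
        table = ln.average_raw(ln.generate_data(net, truth, conds, spec), conds)
        return net, table

    def test_degenerate_zero_grid_equals_single_fit(self, small_problem):
        net, table = small_problem
        grid = ln.ScanGrid(values=(0.0,))
        res = ln.scan(net, table, grid, grid, ln.FitSettings(restarts=2, seed=0))
        assert res.n_cells == 1
        assert res.best.lambda1 == 0.0 and res.best.lambda2 == 0.0
        direct = ln.fit(
            net, table, ln.ObjectiveSpec(0, 0), ln.FitSettings(restarts=2, seed=0)
        )
        assert res.best.mse == pytest.approx(direct.mse, rel=1e-6)

    def test_grid_cell_count_and_landscapes(self, small_problem):
        net, table = small_problem
        g = ln.ScanGrid(values=(0.0, 1e-3, 1e-2))
        res = ln.scan(net, table, g, g, ln.FitSettings(restarts=1, seed=0))
        assert res.n_cells == 9
        for panel in ("bic", "p_eff", "log_mse"):
            m = res.matrix(panel)
            assert m.shape == (3, 3)
        best_bic = res.matrix("bic").min().min()
        assert res.best.bic == pytest.approx(best_bic)

    def test_min_bic_never_more_complex_than_unregularized(self, small_problem):
        net, table = small_problem
        g = ln.ScanGrid(values=(0.0, 1e-4, 1e-3, 1e-2))
        res = ln.scan(net, table, g, g, ln.FitSettings(restarts=2, seed=1))
        unreg = res.cells[0][0]
        assert res.best.p_eff <= unreg.p_eff


class TestKnockout:
    @pytest.fixture(scope="class")
    def bottleneck(self):
        """All signal to the measured nodes passes through one hub node."""
        text = """
        node I input
        node H latent
        node S latent
        node M1 measured
        node M2 measured
        node M3 measured
        node M4 measured
        node M5 measured
        I -> H kh
        I -> S ks
        H -> M1 k1
        H -> M2 k2
        H -> M3 k3
        H -> M4 k4
        H -> M5 k5
        """
        net = ln.parse_network(text)
        truth = ln.ParameterSet(
            contexts=["only"],
            values={
                (p, "only"): v
                for p, v in
                {"kh": 0.95, "ks": 0.5, "k1": 0.9, "k2": 0.85, "k3": 0.9,
                 "k4": 0.8, "k5": 0.88}.items()
            },
        )
        spec = ln.TruthSpec(n_nodes=8, n_reactions=7, noise_sem=0.01, seed=2,
                            n_contexts=1)
        conds = [
            ln.Condition(id="off", clamps={"I": 0.0}),
            ln.Condition(id="on", clamps={"I": 1.0}),
        ]
        raw = ln.generate_data(net, truth, conds, spec)
        table = ln.average_raw(raw, conds)
        return net, table

    def test_reference_row_is_zero_and_bottleneck_maximal(self, bottleneck):
        net, table = bottleneck
        report = ln.knockout_scan(
            net, {"t0": table}, ln.FitSettings(restarts=2, seed=0)
        )
        df = report.table
        ref = df[df.node == "(reference)"]
        assert (ref.delta_aic == 0).all()
        assert report.max_delta("only", "t0") == "H"

    def test_row_count_per_context_time(self, bottleneck):
        net, table = bottleneck
        report = ln.knockout_scan(
            net, {"t0": table}, ln.FitSettings(restarts=1, seed=0)
        )
        df = report.table
        non_ref = df[df.node != "(reference)"]
        n_inputs = len(net.input_nodes)
        assert len(non_ref) == len(net.nodes) - n_inputs

    def test_isolated_latent_node_delta(self, bottleneck):
        """Knocking out a latent node with no path to measured data changes
        nothing in the fit; dAIC is -2 x its (effective) parameter count."""
        net, table = bottleneck
        report = ln.knockout_scan(
            net, {"t0": table}, ln.FitSettings(restarts=2, seed=0)
        )
        df = report.table
        row = df[(df.node == "S")].iloc[0]
        # ks is unidentifiable; it stays at its (>threshold) started value in
        # the reference fit, so removing it drops exactly one parameter
        assert row.delta_aic == pytest.approx(-2.0, abs=0.2)


class TestContextDifferenceProfile:
    def _table(self, diffs, contexts=("p", "c")):
        meas = {}
        for node, d in diffs.items():
            meas[("p", "c0", node)] = ln.Measurement(0.4, 0.0, 1)
            meas[("c", "c0", node)] = ln.Measurement(min(1.0, 0.4 + d), 0.0, 1)
        return ln.ExperimentTable(
            contexts=list(contexts),
            conditions=[ln.Condition(id="c0", clamps={"I": 1.0})],
            measurements=meas,
        )

    def test_identical_contexts_zero_matrix(self):
        tables = {"4h": self._table({"A": 0.0, "B": 0.0})}
        matrix, ranked = ln.context_difference_profile(tables)
        assert (matrix == 0).all().all()

    def test_single_divergent_time_ranks_first(self):
        tables = {
            "1h": self._table({"A": 0.0}),
            "4h": self._table({"A": 0.5}),
            "8h": self._table({"A": 0.1}),
        }
        _, ranked = ln.context_difference_profile(tables)
        assert ranked.index[0] == "4h"

    def test_melanoma_divergence_peaks_at_named_phases(self):
        tables = ln.melanoma_synthetic_tables(seed=0, noise_sem=0.0)
        _, ranked = ln.context_difference_profile(tables)
        assert set(ranked.index[:3]) == {"4h", "16h", "48h"}
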