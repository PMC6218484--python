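"""Synthetic ground truth, raw data generation, normalization, fixture."""

import numpy as np
import pytest

import logicnet as ln
from logicnet.syndata import RawMeasurements, melanoma_truth_at_time


class TestGenerateTruth:
    def test_seed_determinism(self):
        spec = ln.TruthSpec(
            n_nodes=12, n_reactions=16, n_zero_reactions=3,
            n_specific_reactions=3, seed=1,
        )
        net1, p1 = ln.generate_truth(spec)
        net2, p2 = ln.generate_truth(spec)
        assert ln.write_network(net1) == ln.write_network(net2)
        assert p1.values == p2.values

    def test_no_specific_reactions_means_identical_contexts(self):
        spec = ln.TruthSpec(n_nodes=10, n_reactions=13, seed=3)
        _, params = ln.generate_truth(spec)
        for p in params.parameter_names:
            vals = {params.values[(p, c)] for c in params.contexts}
            assert len(vals) == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_effective_count_identity(self, seed):
        """P_eff of the truth equals (reactions - zero) + specific."""
        spec = ln.TruthSpec(
            n_nodes=12, n_reactions=16, n_zero_reactions=3,
            n_specific_reactions=3, seed=seed,
        )
        _, params = ln.generate_truth(spec)
        assert ln.effective_param_count(params) == 16 - 3 + 3

    def test_every_parameter_has_data_sensitivity(self):
        """Latent nodes are relays: every edge has a path to a measured node,
        so no parameter is structurally unidentifiable."""
        import networkx as nx

        spec = ln.TruthSpec(n_nodes=12, n_reactions=16, seed=2)
        net, _ = ln.generate_truth(spec)
        g = nx.DiGraph()
        g.add_nodes_from(net.node_names)
        for i in net.interactions:
            for s in i.sources:
                g.add_edge(s, i.target)
        measured = set(net.measured_nodes)
        for i in net.interactions:
            reach = i.target in measured or (
                measured & nx.descendants(g, i.target)
            )
            assert reach, f"{i.parameter} feeds a dead-end latent chain"

    def test_group_sums_hold_in_truth(self):
        spec = ln.TruthSpec(n_nodes=12, n_reactions=18, seed=7)
        _, params = ln.generate_truth(spec)
        for g in params.competition_groups:
            for c in params.contexts:
                assert sum(params.values[(p, c)] for p in g) == pytest.approx(1.0)

    def test_specific_gap_respected(self):
        spec = ln.TruthSpec(
            n_nodes=12, n_reactions=16, n_specific_reactions=3, seed=4
        )
        _, params = ln.generate_truth(spec)
        gaps = []
        for p in params.parameter_names:
            vals = [params.values[(p, c)] for c in params.contexts]
            if abs(vals[0] - vals[1]) > 1e-12:
                gaps.append(abs(vals[0] - vals[1]))
        assert len(gaps) == 3
        assert all(g >= 0.3 - 1e-9 for g in gaps)

    def test_infeasible_spec_raises(self):
        with pytest.raises(ValueError):
            ln.TruthSpec(n_nodes=10, n_reactions=5, seed=0)


class TestGenerateData:
    def test_zero_noise_replicates_equal_simulation(self):
        spec = ln.TruthSpec(n_nodes=8, n_reactions=10, noise_sem=0.0, seed=5)
        net, truth = ln.generate_truth(spec)
        conds = ln.corner_conditions(net)
        raw = ln.generate_data(net, truth, conds, spec)
        by_cell = raw.data.groupby(["context", "condition", "node"])["value"]
        assert (by_cell.nunique() == 1).all()
        st = ln.steady_state(
            net, truth.for_context("parental"), dict(conds[-1].clamps)
        )
        node = net.measured_nodes[0]
        cell = raw.data[
            (raw.data.context == "parental")
            & (raw.data.condition == conds[-1].id)
            & (raw.data.node == node)
        ]
        assert cell["value"].iloc[0] == pytest.approx(st.activities[node])

    def test_replicate_sem_matches_target(self):
        spec = ln.TruthSpec(
            n_nodes=10, n_reactions=14, noise_sem=0.05, replicates=5, seed=6
        )
        net, truth = ln.generate_truth(spec)
        conds = ln.corner_conditions(net)
        sems = []
        for rep in range(25):
            spec_i = ln.TruthSpec(
                n_nodes=10, n_reactions=14, noise_sem=0.05, replicates=5,
                seed=6 + 1000 * rep,
            )
            raw = ln.generate_data(net, truth, conds, spec_i)
            g = raw.data.groupby(["context", "condition", "node"])["value"]
            stats = g.agg(["mean", "std"])
            # cells near 0 are truncated; check untruncated cells only
            far = stats[stats["mean"] >= 0.4]
            sems.extend((far["std"] / np.sqrt(5)).dropna().tolist())
        assert len(sems) >= 100
        assert np.median(sems) == pytest.approx(0.05, rel=0.3)

    def test_all_zero_inputs_give_zero_means(self):
        spec = ln.TruthSpec(
            n_nodes=8, n_reactions=9, noise_sem=0.0, p_inhibition=0.0, seed=8
        )
        net, truth = ln.generate_truth(spec)
        conds = [ln.Condition(id="off", clamps={i: 0.0 for i in net.input_nodes})]
        raw = ln.generate_data(net, truth, conds, spec)
        assert (raw.data["value"] == 0.0).all()


class TestNormalization:
    def _raw(self, values, node="P1", context="parental", cond="c0"):
        import pandas as pd

        rows = [
            {"context": context, "condition": cond, "node": node,
             "replicate": i + 1, "value": v}
            for i, v in enumerate(values)
        ]
        return RawMeasurements(data=pd.DataFrame(rows))

    def test_minmax_example(self):
        raw = self._raw([10.0, 20.0, 30.0])
        conds = [ln.Condition(id="c0", clamps={"I": 1.0})]
        import pandas as pd

        df = raw.data
        # spread the three values over three conditions to see the mapping
        df["condition"] = ["c0", "c1", "c2"]
        raw = RawMeasurements(data=df)
        conds = [ln.Condition(id=c, clamps={"I": 1.0}) for c in ["c0", "c1", "c2"]]
        table = ln.normalize_measurements(raw, conds)
        means = [table.measurements[("parental", c, "P1")].mean for c in ["c0", "c1", "c2"]]
        assert means == pytest.approx([0.0, 0.5, 1.0])

    def test_scale_invariance(self):
        import pandas as pd

        vals = [3.0, 7.0, 11.0, 5.0]
        rows = [
            {"context": "parental", "condition": f"c{i}", "node": "P1",
             "replicate": 1, "value": v}
            for i, v in enumerate(vals)
        ]
        conds = [ln.Condition(id=f"c{i}", clamps={"I": 1.0}) for i in range(4)]
        t1 = ln.normalize_measurements(
            RawMeasurements(data=pd.DataFrame(rows)), conds
        )
        rows7 = [dict(r, value=r["value"] * 7) for r in rows]
        t2 = ln.normalize_measurements(
            RawMeasurements(data=pd.DataFrame(rows7)), conds
        )
        assert t1.measurements == t2.measurements

    def test_constant_protein_rejected(self):
        raw = self._raw([5.0, 5.0, 5.0])
        conds = [ln.Condition(id="c0", clamps={"I": 1.0})]
        with pytest.raises(ValueError, match="zero range"):
            ln.normalize_measurements(raw, conds)

    def test_roundtrip_zero_noise_minmax_rescaled(self):
        """normalize(generate(noise=0)) equals min-max rescaled steady states."""
        spec = ln.TruthSpec(
            n_nodes=8, n_reactions=11, noise_sem=0.0, seed=9,
            raw_scale_range=(5.0, 50.0),
        )
        net, truth = ln.generate_truth(spec)
        conds = ln.corner_conditions(net)
        raw = ln.generate_data(net, truth, conds, spec)
        table = ln.normalize_measurements(raw, conds)
        sim = ln.simulate_experiments(net, truth, table)
        by_node = {}
        for row in sim.itertuples(index=False):
            by_node.setdefault(row.node, []).append(row)
        for node, rows in by_node.items():
            vals = np.array([r.simulated for r in rows])
            lo, hi = vals.min(), vals.max()
            if hi <= lo:
                continue
            for r in rows:
                expect = (r.simulated - lo) / (hi - lo)
                got = table.measurements[(r.context, r.condition, node)].mean
                assert got == pytest.approx(expect, abs=1e-9)


class TestMelanomaFixture:
    def test_printed_structure(self, melanoma):
        net, template = melanoma
        assert len(net.nodes) == 19
        assert len(net.parameters) == 29
        assert len(net.measured_nodes) == 7
        assert set(net.measured_nodes) == {
            "AKT", "ERK", "FLIP", "XIAP", "IkBa", "NFkB", "PARP"
        }
        assert [c.id for c in template["conditions"]] == ["untreated", "IZI"]
        assert len(template["time_labels"]) == 7

    def test_named_inhibitions_present(self, melanoma):
        net, _ = melanoma
        inh = {
            (i.sources[0], i.target)
            for i in net.interactions
            if i.sign == "inhibition"
        }
        assert {("FLIP", "Casp8"), ("BCL2", "Casp3"), ("XIAP", "Casp3")} <= inh

    def test_truth_classification_structure(self, melanoma_truth):
        from logicnet.select import classification_counts

        counts = classification_counts(ln.classify_reactions(melanoma_truth))
        assert counts == (19, 4, 6)
        assert ln.effective_param_count(melanoma_truth) == 31
        assert len(melanoma_truth.values) == 58

    def test_time_divergence_schedule(self):
        base = melanoma_truth_at_time("16h")
        early = melanoma_truth_at_time("1h")
        gap16 = abs(
            base.values[("k_xiap_casp3", "conditioned")]
            - base.values[("k_xiap_casp3", "parental")]
        )
        gap1 = abs(
            early.values[("k_xiap_casp3", "conditioned")]
            - early.values[("k_xiap_casp3", "parental")]
        )
        assert gap16 > gap1

    def test_synthetic_tables_shape(self):
        tables = ln.melanoma_synthetic_tables(seed=0, time_labels=["4h", "16h"])
        assert set(tables) == {"4h", "16h"}
        assert tables["16h"].n_points == 28  # 2 contexts x 2 conditions x 7
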