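"""NP network reduction, module dissection, hubs and interface genes."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import pulsewave as pw
from pulsewave.npnet import ANTI, CO, ModulePartition, ReducedNetwork


def make_network(nodes, ppi_edges, tfs=()):
    return pw.InteractionNetwork(
        tuple(nodes), tuple((u, v, "PPI") for u, v in ppi_edges), frozenset(tfs))


def deg(x):
    return float(np.degrees(np.arccos(x)))


class TestReduce:
    def test_engineered_pccs_threshold_and_labels(self, angle_expr):
        # star around 'a' with leaf correlations {0.9, 0.5, -0.8, 0.71}
        expr = angle_expr(
            ["a", "b", "c", "d", "e"],
            [0.0, deg(0.9), deg(0.5), 180 - deg(0.8), deg(0.71)],
        )
        net = make_network("abcde", [("a", "b"), ("a", "c"), ("a", "d"), ("a", "e")])
        red = pw.reduce_network(net, expr, threshold=0.7)
        got = {(u, v): (round(p, 3), lab) for u, v, _k, p, lab in red.edges}
        assert got == {
            ("a", "b"): (0.9, CO),
            ("a", "d"): (-0.8, ANTI),
            ("a", "e"): (0.71, CO),
        }
        assert (red.n_edges, red.n_co, red.n_anti) == (3, 2, 1)
        assert red.n_nodes == 4  # 'c' has no retained edge

    def test_zero_threshold_retains_everything(self, angle_expr):
        expr = angle_expr(["a", "b", "c"], [0, 50, 120])
        net = make_network("abc", [("a", "b"), ("b", "c"), ("a", "c")])
        assert pw.reduce_network(net, expr, threshold=0.0).n_edges == 3

    def test_raising_threshold_never_adds_edges(self, grid):
        expr, truth = pw.simulate_expression(pw.np_benchmark_design(2), grid)
        net = pw.simulate_network(truth, 0.3, 0.05, seed=0)
        edge_sets = []
        for thr in (0.5, 0.7, 0.9):
            red = pw.reduce_network(net, expr, threshold=thr)
            edge_sets.append({(u, v) for u, v, *_ in red.edges})
            assert red.n_co + red.n_anti == red.n_edges
        assert edge_sets[2] <= edge_sets[1] <= edge_sets[0]

    def test_sign_flipped_module_labels_match_planted_signs(self, grid):
        mod = pw.ModuleSpec(6, pw.ArchetypeSpec("sustained_up"),
                            signs=[1, 1, 1, -1, -1, -1])
        expr, truth = pw.simulate_expression(
            pw.PlantedDesign(modules=(mod,), noise_sd=0.0, seed=0), grid)
        net = pw.simulate_network(truth, 1.0, 0.0, seed=0)
        red = pw.reduce_network(net, expr)
        assert red.n_edges == 15  # complete K6: every |PCC| is exactly 1
        sign = dict(zip(truth["gene_id"], truth["sign"]))
        for u, v, _k, _p, lab in red.edges:
            assert lab == (CO if sign[u] == sign[v] else ANTI)

    def test_constant_profile_edges_are_skipped_not_fatal(self, tiny_grid):
        values = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0],
                           [2.0, 4.0, 6.0, 8.0]])
        expr = pw.ExpressionSeries(("a", "flat", "b"), values, tiny_grid)
        net = make_network(["a", "flat", "b"], [("a", "flat"), ("a", "b")])
        red = pw.reduce_network(net, expr)
        assert red.n_skipped_constant == 1
        assert red.n_edges == 1

    def test_needs_two_expressed_nodes(self, tiny_grid):
        expr = pw.ExpressionSeries(("a",), np.array([[1.0, 2, 3, 4]]), tiny_grid)
        net = make_network(["x", "y"], [("x", "y")])
        with pytest.raises(ValueError, match="at least 2"):
            pw.reduce_network(net, expr)


class TestFindModules:
    def test_all_coregulated_connected_network_is_one_module(self, angle_expr):
        expr = angle_expr(["a", "b", "c", "d"], [0, 5, 10, 15])
        net = make_network("abcd", [("a", "b"), ("b", "c"), ("c", "d")])
        red = pw.reduce_network(net, expr)
        with pytest.warns(UserWarning, match="single global module"):
            part = pw.find_modules(red, expr)
        assert part.module_labels == ["M1"]
        assert set(part.members("M1")) == set("abcd")

    def test_two_anticorrelated_blocks_split_cleanly(self, grid):
        mods = (
            pw.ModuleSpec(8, pw.ArchetypeSpec("sustained_up")),
            pw.ModuleSpec(8, pw.ArchetypeSpec("sustained_up"), signs=-1),
        )
        expr, truth = pw.simulate_expression(
            pw.PlantedDesign(modules=mods, noise_sd=0.0, seed=0), grid)
        net = pw.simulate_network(truth, 1.0, 1.0, seed=0)  # complete graph
        red = pw.reduce_network(net, expr)
        part = pw.find_modules(red, expr)
        assert len(part.module_labels) == 2
        for label in part.module_labels:
            planted = {truth.set_index("gene_id")["module"][g]
                       for g in part.members(label)}
            assert len(planted) == 1  # pure

    def test_six_node_fixture_matches_subset_enumeration_oracle(self, angle_expr):
        """One anti link inside a 5-node candidate (1/7 of its links) forces a
        split; enumeration over all node subsets confirms the surviving module
        is the largest feasible one."""
        names = list("abcdef")
        angles = [0.0, 5.0, -5.0, 40.0, 175.0, 10.0]
        expr = angle_expr(names, angles)
        ppi = [("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("b", "d"),
               ("c", "d"), ("e", "a"), ("f", "a"), ("f", "b")]
        net = make_network(names, ppi)
        red = pw.reduce_network(net, expr)
        assert red.n_edges == 9 and red.n_anti == 1

        candidate = set("abcde")
        within = [(u, v, lab) for u, v, _k, _p, lab in red.edges
                  if u in candidate and v in candidate]
        assert len(within) == 7
        assert sum(lab == ANTI for *_, lab in within) == 1

        part = pw.find_modules(red, expr, max_anti_frac=0.01)

        retained = {(u, v): lab for u, v, _k, _p, lab in red.edges}

        def feasible(subset):
            edges = [(u, v, lab) for (u, v), lab in retained.items()
                     if u in subset and v in subset]
            n_anti = sum(lab == ANTI for *_, lab in edges)
            if edges and n_anti / len(edges) >= 0.01:
                return False
            # connectivity on retained edges
            comp = {next(iter(subset))}
            frontier = True
            while frontier:
                frontier = False
                for u, v, _ in edges:
                    if (u in comp) != (v in comp):
                        comp |= {u, v}
                        frontier = True
            return comp == set(subset)

        best = max(
            (s for r in range(2, 7) for s in map(frozenset, itertools.combinations(names, r))
             if feasible(s)),
            key=len,
        )
        assert best == frozenset("abcdf")
        assert set(part.members("M1")) == set(best)
        assert part.unclustered == ("e",)
        for label in part.module_labels:
            assert feasible(frozenset(part.members(label)))

    def test_planted_module_recovery_over_seeds(self, grid):
        """ARI >= 0.9 against planted modules across 10 seeded designs."""
        for seed in range(10):
            design = pw.np_benchmark_design(seed)
            expr, truth = pw.simulate_expression(design, grid)
            net = pw.simulate_network(truth, 0.3, 0.02, seed=seed + 1000)
            red = pw.reduce_network(net, expr)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                part = pw.find_modules(red, expr)
            assert (part.modules["anti_frac"] < 0.01).all()
            lookup = dict(zip(truth["gene_id"], truth["module"]))
            common = [g for g in truth["gene_id"] if g in part.assignment]
            assert len(common) >= 0.95 * len(truth)
            ari = adjusted_rand_score(
                [lookup[g] for g in common], [part.assignment[g] for g in common])
            assert ari >= 0.9

    def test_deterministic_given_input_order(self, grid):
        design = pw.np_benchmark_design(1)
        expr, truth = pw.simulate_expression(design, grid)
        net = pw.simulate_network(truth, 0.3, 0.02, seed=5)
        red = pw.reduce_network(net, expr)
        assert pw.find_modules(red, expr).assignment == pw.find_modules(red, expr).assignment

    def test_anti_frac_domain_error(self, angle_expr):
        expr = angle_expr(["a", "b"], [0, 5])
        red = pw.reduce_network(make_network("ab", [("a", "b")]), expr)
        with pytest.raises(ValueError, match="max_anti_frac"):
            pw.find_modules(red, expr, max_anti_frac=1.5)


def hand_reduced(edges, nodes=None, tfs=()):
    """ReducedNetwork from explicit (u, v, pcc) triples."""
    nodes = tuple(nodes or sorted({n for u, v, _ in edges for n in (u, v)}))
    full = tuple((u, v, "PPI", p, CO if p > 0 else ANTI) for u, v, p in edges)
    return ReducedNetwork(nodes=nodes, edges=full, threshold=0.7,
                          tf_set=frozenset(tfs))


def hand_partition(assignment):
    labels = sorted(set(assignment.values()))
    modules = pd.DataFrame(
        [(m, sum(v == m for v in assignment.values()), 0, 0, 0.0) for m in labels],
        columns=["module", "size", "n_edges_within", "n_anti_within", "anti_frac"])
    return ModulePartition(assignment=dict(assignment), modules=modules)


class TestInterModuleSummary:
    def test_opposite_and_duplicate_modules(self, grid):
        mods = (
            pw.ModuleSpec(5, pw.ArchetypeSpec("sustained_up")),
            pw.ModuleSpec(5, pw.ArchetypeSpec("sustained_up"), signs=-1),
            pw.ModuleSpec(5, pw.ArchetypeSpec("sustained_up")),
        )
        expr, truth = pw.simulate_expression(
            pw.PlantedDesign(modules=mods, noise_sd=0.0, seed=0), grid)
        part = hand_partition(dict(zip(truth["gene_id"], truth["module"])))
        summary = pw.inter_module_summary(part, expr)
        entry = {(r.module_a, r.module_b): (r.mean_pcc, r.label)
                 for r in summary.itertuples()}
        assert entry[("M1", "M2")][0] == pytest.approx(-1.0)
        assert entry[("M1", "M2")][1] == "anti-correlated"
        assert entry[("M1", "M3")][0] == pytest.approx(1.0)
        assert entry[("M1", "M3")][1] == "correlated"
        assert ("M1", "M1") not in entry  # no diagonal

    def test_single_module_rejected(self, grid):
        part = hand_partition({"a": "M1", "b": "M1"})
        expr, _ = pw.simulate_expression(
            pw.PlantedDesign(modules=(pw.ModuleSpec(2, pw.ArchetypeSpec("sustained_up")),),
                             noise_sd=0.0, seed=0), grid)
        with pytest.raises(ValueError, match="at least 2"):
            pw.inter_module_summary(part, expr)


class TestClassifyHubs:
    def test_average_pcc_rule(self):
        red = hand_reduced([
            ("h", "x1", 0.9), ("h", "x2", 0.8),
            ("j", "y1", 0.75), ("j", "y2", -0.72),
        ])
        hubs = pw.classify_hubs(red, min_degree=2).set_index("node")
        assert hubs.loc["h", "avg_pcc"] == pytest.approx(0.85)
        assert hubs.loc["h", "hub_class"] == "party"
        assert hubs.loc["j", "avg_pcc"] == pytest.approx(0.015)
        assert hubs.loc["j", "hub_class"] == "date"
        assert "x1" not in hubs.index  # below min_degree

    def test_boundary_avg_pcc_is_date(self):
        # |AvgPCC| exactly at the 0.1 threshold falls to "date"
        red = hand_reduced([("h", "x1", 0.1)])
        hubs = pw.classify_hubs(red, min_degree=1).set_index("node")
        assert hubs.loc["h", "avg_pcc"] == 0.1
        assert hubs.loc["h", "hub_class"] == "date"

    def test_invariant_to_edge_order(self):
        edges = [("h", "x1", 0.9), ("h", "x2", 0.8), ("h", "x3", -0.75),
                 ("x1", "x2", 0.71)]
        a = pw.classify_hubs(hand_reduced(edges), min_degree=1)
        b = pw.classify_hubs(hand_reduced(edges[::-1]), min_degree=1)
        pd.testing.assert_frame_equal(
            a.sort_values("node").reset_index(drop=True),
            b.sort_values("node").reset_index(drop=True))

    def test_tf_and_interface_flags(self):
        red = hand_reduced(
            [("h", "x1", 0.9), ("h", "x2", 0.8)], tfs=("h",))
        part = hand_partition({"h": "M1", "x1": "M1", "x2": "M2"})
        hubs = pw.classify_hubs(red, min_degree=2, partition=part).set_index("node")
        assert bool(hubs.loc["h", "is_tf"]) and bool(hubs.loc["h", "is_interface"])


class TestInterfaceCore:
    def test_three_cross_edges_mark_exactly_touched_nodes(self):
        assignment = {f"a{i}": "A" for i in range(1, 5)}
        assignment.update({f"b{i}": "B" for i in range(1, 5)})
        red = hand_reduced(
            [("a1", "b1", 0.9), ("a1", "b2", 0.8), ("a2", "b3", -0.75),
             ("a3", "a4", 0.9), ("b3", "b4", 0.85)],
            nodes=sorted(assignment), tfs=("a1", "a3"))
        nodes_df, tf_pairs = pw.interface_core(hand_partition(assignment), red)
        nodes_df = nodes_df.set_index("node")
        interface = set(nodes_df.index[nodes_df["is_interface"]])
        assert interface == {"a1", "a2", "b1", "b2", "b3"}
        # edgeless node -> core
        assert not nodes_df.loc["a3", "is_interface"]
        # a1 is the only TF interfacing A -> B; a3 is a TF but core
        pairs = {(r.module, r.partner_module): r.n_tf_interface
                 for r in tf_pairs.itertuples()}
        assert pairs == {("A", "B"): 1}
        assert bool(nodes_df.loc["a3", "is_tf"])
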