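"""Ground-truth properties of the synthetic-data generators."""

import numpy as np
import pytest
from scipy.stats import binom

import pulsewave as pw
from pulsewave.synthetic import BACKGROUND


def corr(a, b):
    return np.corrcoef(a, b)[0, 1]


class TestArchetypes:
    def test_all_shapes_return_to_baseline_outside_window(self, grid):
        for kind in ("immediate_down_recover", "delayed_up", "sustained_up",
                     "sustained_down", "oscillatory", "flat"):
            r = pw.archetype_response(pw.ArchetypeSpec(kind), grid.times)
            assert r[0] == 0.0  # pre-impulse steady state
            assert r[-1] == 0.0  # second steady state, past the 7 h horizon

    def test_shape_specifics(self, grid):
        t = grid.times
        idr = pw.archetype_response(
            pw.ArchetypeSpec("immediate_down_recover", amplitude=2, recovery=1800), t)
        assert idr[1] == pytest.approx(-2 * np.exp(-20 / 1800))
        assert np.all(np.diff(idr[1:14]) > 0)  # monotone recovery

        dup = pw.archetype_response(
            pw.ArchetypeSpec("delayed_up", amplitude=1.5, onset=7200, recovery=3600), t)
        assert np.all(dup[t < 7200] == 0)
        assert dup[t == 25200] > 1.4  # near plateau by 7 h

        sus = pw.archetype_response(pw.ArchetypeSpec("sustained_up", amplitude=1.5), t)
        assert np.all(np.diff(sus[1:14]) > 0)
        assert sus[13] == pytest.approx(1.5, rel=1e-4)

        assert np.all(
            pw.archetype_response(pw.ArchetypeSpec("flat"), t) == 0.0
        )

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            pw.ArchetypeSpec("wiggly")
        with pytest.raises(ValueError):
            pw.ArchetypeSpec("oscillatory", period=0)
        with pytest.raises(ValueError):
            pw.ArchetypeSpec("sustained_up", amplitude=-1)


class TestSimulateExpression:
    def test_bit_reproducible_and_seed_sensitive(self, grid):
        d = pw.default_design(seed=7)
        e1, t1 = pw.simulate_expression(d, grid)
        e2, t2 = pw.simulate_expression(d, grid)
        assert np.array_equal(e1.values, e2.values)
        assert t1.equals(t2)
        e3, _ = pw.simulate_expression(pw.default_design(seed=8), grid)
        assert not np.array_equal(e1.values, e3.values)

    def test_noiseless_flat_gene_is_constant(self, grid):
        d = pw.PlantedDesign(modules=(), noise_sd=0.0, seed=0, n_background_flat=3)
        expr, truth = pw.simulate_expression(d, grid)
        assert np.ptp(expr.values, axis=1).max() == 0.0
        assert set(truth["module"]) == {BACKGROUND}

    def test_opposite_signs_are_exactly_anticorrelated(self, grid):
        mod = pw.ModuleSpec(2, pw.ArchetypeSpec("sustained_up"), signs=[1, -1])
        expr, _ = pw.simulate_expression(
            pw.PlantedDesign(modules=(mod,), noise_sd=0.0, seed=0), grid)
        assert corr(expr.values[0], expr.values[1]) == pytest.approx(-1.0)

    def test_within_module_correlation_exceeds_between(self, grid):
        mods = (
            pw.ModuleSpec(25, pw.ArchetypeSpec("sustained_up")),
            pw.ModuleSpec(25, pw.ArchetypeSpec("oscillatory")),
        )
        expr, truth = pw.simulate_expression(
            pw.PlantedDesign(modules=mods, noise_sd=0.1, seed=3), grid)
        c = np.corrcoef(expr.values)
        lab = truth["module"].to_numpy()
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(len(lab), dtype=bool)
        assert np.abs(c[same & off]).mean() > np.abs(c[~same]).mean()

    def test_truth_labels_cover_every_gene(self, grid):
        d = pw.default_design(seed=0)
        expr, truth = pw.simulate_expression(d, grid)
        assert list(truth["gene_id"]) == list(expr.gene_ids)
        assert set(truth.loc[truth.module != BACKGROUND, "archetype"]) <= set(
            ("immediate_down_recover", "delayed_up", "sustained_up",
             "sustained_down", "oscillatory")
        )


class TestSimulateNetwork:
    def _truth(self, grid, sizes=(3, 3)):
        mods = tuple(pw.ModuleSpec(s, pw.ArchetypeSpec("sustained_up")) for s in sizes)
        _, truth = pw.simulate_expression(
            pw.PlantedDesign(modules=mods, noise_sd=0.0, seed=0), grid)
        return truth

    def test_degenerate_probabilities(self, grid):
        truth = self._truth(grid)
        assert pw.simulate_network(truth, 0.0, 0.0, seed=0).n_edges == 0
        net = pw.simulate_network(truth, 1.0, 0.0, seed=0)
        assert net.n_edges == 6  # two complete K3 blocks

    def test_edge_count_within_binomial_band(self, grid):
        truth = self._truth(grid, sizes=(20,))
        net = pw.simulate_network(truth, 0.5, 0.0, seed=42)
        n_pairs = 20 * 19 // 2
        lo, hi = binom.ppf([0.005, 0.995], n_pairs, 0.5)
        assert lo <= net.n_edges <= hi

    def test_tf_nodes_get_pdi_out_edges(self, grid):
        truth = self._truth(grid, sizes=(10, 10))
        net = pw.simulate_network(truth, 0.2, 0.0, n_tf=3, seed=1)
        assert len(net.tf_set) == 3
        sources = {u for u, _ in net.pdi_edges()}
        assert sources == set(net.tf_set)

    def test_probability_domain_errors(self, grid):
        truth = self._truth(grid)
        with pytest.raises(ValueError):
            pw.simulate_network(truth, 0.2, 0.5, seed=0)  # p_inter > p_intra
        with pytest.raises(ValueError):
            pw.simulate_network(truth, 1.2, 0.0, seed=0)


class TestSimulateAnnotations:
    def test_exact_fractions(self, grid):
        mods = (pw.ModuleSpec(5, pw.ArchetypeSpec("sustained_up")),)
        _, truth = pw.simulate_expression(
            pw.PlantedDesign(modules=mods, noise_sd=0.0, seed=0, n_background_flat=5),
            grid)
        table = pw.simulate_annotations(truth, frac_in=1.0, frac_bg=0.0, seed=0)
        assert table.genes_for_term("TERM_M1") == set(
            truth.loc[truth.module == "M1", "gene_id"])

    def test_background_only_design_yields_empty_table(self, grid):
        d = pw.PlantedDesign(modules=(), noise_sd=0.1, seed=0, n_background_flat=4)
        _, truth = pw.simulate_expression(d, grid)
        assert len(pw.simulate_annotations(truth, seed=0)) == 0

    def test_no_enrichment_signal_when_fracs_equal(self, grid):
        """With frac_in == frac_bg the planted term carries no signal and the
        downstream hypergeometric p is not systematically small."""
        mods = (pw.ModuleSpec(20, pw.ArchetypeSpec("sustained_up")),)
        _, truth = pw.simulate_expression(
            pw.PlantedDesign(modules=mods, noise_sd=0.0, seed=0, n_background_flat=80),
            grid)
        module = set(truth.loc[truth.module == "M1", "gene_id"])
        background = list(truth["gene_id"])
        ps = []
        for seed in range(100):
            ann = pw.simulate_annotations(truth, frac_in=0.3, frac_bg=0.3, seed=seed)
            tab = pw.hypergeom_enrich(module, background, ann)
            if len(tab):
                ps.append(float(tab["p_hyper"].iloc[0]))
        ps = np.array(ps)
        assert np.mean(ps < 0.05) < 0.12
        assert ps.mean() > 0.3

    def test_fraction_domain_error(self, grid):
        mods = (pw.ModuleSpec(3, pw.ArchetypeSpec("sustained_up")),)
        _, truth = pw.simulate_expression(
            pw.PlantedDesign(modules=mods, noise_sd=0.0, seed=0), grid)
        with pytest.raises(ValueError):
            pw.simulate_annotations(truth, frac_in=0.2, frac_bg=0.5, seed=0)
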