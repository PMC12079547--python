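import dataclasses
import json

import numpy as np
import pytest

from modnet.eqtl import classify_eqtl
from modnet.gmad import estimate_rho_bar
from modnet.synthetic import (
    CIS_WINDOW,
    TRANS_MIN_DIST,
    ConfigError,
    SimulationConfig,
    SyntheticTruth,
    build_catalog,
    simulate_compendium,
    simulate_gene_annotations,
    simulate_genotypes_and_effects,
    simulate_markers,
    simulate_regulatory_network,
)


class TestCompendium:
    def test_bitwise_determinism(self):
        cfg = SimulationConfig(seed=1, n_datasets=2, n_genes=200, n_samples_per_dataset=50,
                               n_modules=4, module_size_range=(8, 12),
                               planted_module_pairs=[(0, 1, 1)])
        a = simulate_compendium(cfg)[0]
        b = simulate_compendium(cfg)[0]
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.values, db.values)

    def test_seed_sensitivity(self):
        base = dict(n_datasets=1, n_genes=200, n_samples_per_dataset=50, n_modules=4,
                    module_size_range=(8, 12), planted_module_pairs=[])
        a = simulate_compendium(SimulationConfig(seed=1, **base))[0][0]
        b = simulate_compendium(SimulationConfig(seed=2, **base))[0][0]
        assert not np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("rho,lo,hi", [(0.0, -0.05, 0.05), (0.3, 0.25, 0.35)])
    def test_realized_rho_bar(self, rho, lo, hi):
        cfg = SimulationConfig(seed=3, n_datasets=1, n_genes=200, n_samples_per_dataset=500,
                               n_modules=3, module_size_range=(20, 20), rho_bar_target=rho,
                               planted_module_pairs=[], frac_planted_gene_assoc=0.0)
        datasets, catalog, _ = simulate_compendium(cfg)
        est = estimate_rho_bar(datasets[0], catalog.genes("M00"))
        assert lo <= est.rho_bar <= hi

    def test_oversized_modules_rejected(self):
        cfg = SimulationConfig(n_genes=50, n_modules=10, module_size_range=(20, 20))
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_truth_json_round_trip(self, tmp_path, small_sim):
        truth = small_sim[2]
        truth.to_json(tmp_path / "t.json")
        back = SyntheticTruth.from_json(tmp_path / "t.json")
        assert back.gene_module_assoc == truth.gene_module_assoc
        assert back.module_module_assoc == truth.module_module_assoc


class TestGenetics:
    def test_cis_placement_within_window(self, genetics_sim):
        truth, gt = genetics_sim["truth"], genetics_sim["genotypes"]
        anns = {a.gene_id: a for a in genetics_sim["annotations"]}
        vpos = dict(zip(gt.variant_ids, gt.positions))
        for v, g, cls, _ in truth.eqtl_truth:
            if not v.startswith("vcis"):
                continue
            label, d = classify_eqtl(vpos[v], anns[g])
            assert label == "cis" and d <= CIS_WINDOW

    def test_trans_placement_far(self, genetics_sim):
        truth, gt = genetics_sim["truth"], genetics_sim["genotypes"]
        anns = {a.gene_id: a for a in genetics_sim["annotations"]}
        vpos = dict(zip(gt.variant_ids, gt.positions))
        trans = [(v, g) for v, g, cls, _ in truth.eqtl_truth if v.startswith("vtrans")]
        assert trans
        for v, g in trans:
            label, d = classify_eqtl(vpos[v], anns[g])
            assert label == "trans" and d >= TRANS_MIN_DIST

    def test_planted_class_matches_classifier_everywhere(self, genetics_sim):
        """Placement rules and classification rules agree by construction."""
        truth, gt = genetics_sim["truth"], genetics_sim["genotypes"]
        anns = {a.gene_id: a for a in genetics_sim["annotations"]}
        vpos = dict(zip(gt.variant_ids, gt.positions))
        snp = [(v, g, cls) for v, g, cls, _ in truth.eqtl_truth if v.startswith("v")]
        assert snp and all(classify_eqtl(vpos[v], anns[g])[0] == cls for v, g, cls in snp)

    def test_short_genome_rejected_for_trans(self):
        cfg = SimulationConfig(seed=1, n_genes=50, genome_length=4_000_000, n_variants=20,
                               n_cis=2, n_trans=2, n_modules=4, module_size_range=(5, 8),
                               n_samples_per_dataset=60, n_datasets=1,
                               n_meth_bins=10, planted_module_pairs=[])
        datasets, _, truth = simulate_compendium(cfg)
        anns = simulate_gene_annotations(cfg)
        # no gene on a 4 Mb chromosome has a >= 5 Mb flank on either side
        with pytest.raises(ConfigError):
            simulate_genotypes_and_effects(cfg, anns, datasets[0], truth)


class TestNetworkAndMarkers:
    def test_driver_children_mostly_in_module(self, genetics_sim):
        truth, priors = genetics_sim["truth"], genetics_sim["priors"]
        catalog = genetics_sim["catalog"]
        (driver,) = truth.driver_truth
        module = catalog.genes(truth.driver_module)
        children = {e.target for e in priors.edges if e.source == driver}
        assert len(children & module) >= min(
            genetics_sim["cfg"].driver_out_degree, len(module)
        )

    def test_acyclic_by_construction(self, genetics_sim):
        import networkx as nx

        G = nx.DiGraph()
        G.add_edges_from((e.source, e.target) for e in genetics_sim["priors"].edges)
        assert nx.is_directed_acyclic_graph(G)

    def test_marker_overlap_one_equals_module(self, small_cfg):
        catalog = build_catalog(small_cfg)
        size = len(catalog.genes("M00"))
        cfg = dataclasses.replace(
            small_cfg, marker_overlap=1.0, markers_per_type=size, n_cell_types=1
        )
        markers, truth = simulate_markers(cfg, catalog)
        assert markers["celltype00"] == catalog.genes("M00")

    def test_marker_overlap_half_enriched(self):
        # 40 markers at overlap 0.5 onto a 40-gene module in a 2000-gene
        # universe: the hypergeometric tail is astronomically small
        from scipy import stats

        cfg = SimulationConfig(seed=9, n_genes=2000, n_modules=5,
                               module_size_range=(40, 40), markers_per_type=40,
                               marker_overlap=0.5, n_cell_types=1,
                               planted_module_pairs=[])
        catalog = build_catalog(cfg)
        markers, truth = simulate_markers(cfg, catalog)
        mod, marks = truth.marker_truth["celltype00"]
        k = len(marks & catalog.genes(mod))
        N, K, n = len(catalog.universe), len(catalog.genes(mod)), len(marks)
        p = stats.hypergeom.sf(k - 1, N, K, n)
        assert k == 20 and p < 1e-10
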