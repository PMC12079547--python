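from math import comb

import numpy as np
import pandas as pd
import pytest

from modnet import conservation as cons
from modnet.io_formats import ExpressionDataset, HomologyHitTable


def _hits(rows):
    return HomologyHitTable(
        pd.DataFrame(rows, columns=list(HomologyHitTable.COLUMNS))
    ).validate()


class TestOrthologFilter:
    def test_threshold_retention(self):
        hits = _hits([
            ("q1", "s1", "A", "B", 1e-6, 70.0),   # retained
            ("q2", "s2", "A", "B", 1e-6, 55.0),   # identity too low
            ("q3", "s3", "A", "B", 1e-4, 80.0),   # E-value too high
        ])
        m = cons.filter_orthologs(hits)
        assert m.pairs == {("q1", "s1")}

    def test_reciprocal_best_toy(self):
        # q1<->s1 and q2<->s2 are mutual best; q3's best is s1 but s1 prefers q1
        hits = _hits([
            ("q1", "s1", "A", "B", 1e-30, 90.0),
            ("q2", "s2", "A", "B", 1e-25, 85.0),
            ("q3", "s1", "A", "B", 1e-20, 80.0),
            ("q3", "s3", "A", "B", 1e-10, 70.0),
            ("q1", "s3", "A", "B", 1e-8, 65.0),
        ])
        # q3's best subject is s1, but s1's best query is q1: the asymmetric
        # best hit breaks reciprocity, so exactly 2 pairs survive
        m = cons.filter_orthologs(hits, reciprocal_best=True)
        assert m.pairs == {("q1", "s1"), ("q2", "s2")}

    def test_deterministic_tie_break(self):
        hits = _hits([
            ("q1", "sA", "A", "B", 1e-10, 80.0),
            ("q1", "sB", "A", "B", 1e-10, 80.0),  # tie -> lexicographic subject
        ])
        m = cons.filter_orthologs(hits, reciprocal_best=True)
        assert m.pairs == {("q1", "sA")}


class TestOverlap:
    def test_disjoint_p_is_one(self):
        uni = {f"g{i}" for i in range(100)}
        r = cons.overlap_test({"g0", "g1"}, {"g50", "g51"}, uni)
        assert r.k == 0 and r.p_value == 1.0

    def test_complete_overlap_closed_form(self):
        uni = {f"g{i}" for i in range(100)}
        s = {f"g{i}" for i in range(5)}
        r = cons.overlap_test(s, s, uni)
        assert r.p_value == pytest.approx(1 / comb(100, 5), rel=1e-9)

    def test_matches_brute_force_summation(self):
        # k=5, K=10, n=10, N=100
        expect = sum(comb(10, i) * comb(90, 10 - i) for i in range(5, 11)) / comb(100, 10)
        uni = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(20, 25)}
        r = cons.overlap_test(a, b, uni)
        assert r.k == 5 and r.p_value == pytest.approx(expect, rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            cons.overlap_test(set(), set(), set())


class TestKs:
    def test_identical_samples(self):
        r = cons.ks_one_sided([1, 2, 3], [1, 2, 3])
        assert r.d_statistic == 0.0 and r.p_value == 1.0

    def test_complete_separation(self):
        r = cons.ks_one_sided([11, 12, 13], [1, 2, 3])
        assert r.d_statistic == 1.0 and r.p_value < 0.1

    def test_exact_matches_permutation(self, rng):
        a, b = rng.normal(0.4, 1, 20), rng.normal(0, 1, 20)
        r = cons.ks_one_sided(a, b)
        pool = np.concatenate([a, b])
        B = 100_000
        perm = np.array([rng.permutation(pool) for _ in range(B)])
        aa, bb = perm[:, :20], perm[:, 20:]
        xs = np.sort(pool)
        Fa = (aa[:, :, None] <= xs[None, None, :]).mean(axis=1)
        Fb = (bb[:, :, None] <= xs[None, None, :]).mean(axis=1)
        d = (Fb - Fa).max(axis=1)
        p_perm = np.mean(d >= r.d_statistic - 1e-12)
        assert r.p_value == pytest.approx(p_perm, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cons.ks_one_sided([], [1.0])


def _dataset(values):
    return ExpressionDataset(
        "d", "sp", [f"G{i}" for i in range(values.shape[0])],
        [f"S{j}" for j in range(values.shape[1])], values
    ).validate()


class TestCorrelationNetwork:
    def test_collinear_pair_retained_positive(self, rng):
        x = rng.standard_normal(50)
        ds = _dataset(np.vstack([x, 3 * x + 1e-9 * rng.standard_normal(50)]))
        net = cons.correlation_network(ds, ["G0", "G1"])
        assert len(net.edges) == 1 and net.edges[0].sign == 1

    def test_plug_in_formula_r09_n50(self, rng):
        # r = 0.9 at n = 50: t ~ 14.3, p << 1e-5 -> retained
        z = rng.standard_normal(50)
        x = z
        y = 0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(50)
        ds = _dataset(np.vstack([x, y]))
        r = np.corrcoef(x, y)[0, 1]
        if abs(r) >= 0.85:  # realization close enough to exercise the branch
            net = cons.correlation_network(ds, ["G0", "G1"])
            assert len(net.edges) == 1

    def test_too_few_samples_rejected(self, rng):
        ds = _dataset(rng.standard_normal((3, 3)))
        with pytest.raises(ValueError):
            cons.correlation_network(ds, ["G0", "G1"])

    def test_null_retention_rate(self, rng):
        """Independent pairs at n=100: retained fraction ~ threshold."""
        n_pairs = 20_000
        X = rng.standard_normal((2 * n_pairs, 100))
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        r = (Xs[::2] * Xs[1::2]).mean(axis=1)
        from scipy import stats as sps

        t = r * np.sqrt(98 / (1 - r * r))
        p = 2 * sps.t.sf(np.abs(t), df=98)
        frac = np.mean(p < 1e-3)  # use a milder cut so the rate is estimable
        assert frac == pytest.approx(1e-3, abs=7e-4)

    def test_spearman_option(self, rng):
        x = rng.standard_normal(60)
        ds = _dataset(np.vstack([x, np.exp(x)]))  # monotone, nonlinear
        net = cons.correlation_network(ds, ["G0", "G1"], method="spearman")
        assert len(net.edges) == 1


class TestDensityContrast:
    def test_planted_module_extreme_p(self, small_sim, rng):
        datasets, catalog, _ = small_sim
        p, d_target, d_rand = cons.density_contrast(
            datasets[0], catalog.genes("M00"), n_random=99, p_threshold=1e-3, rng=rng
        )
        assert p == pytest.approx(1 / 100)
        assert d_target > np.max(d_rand)

    def test_zero_random_sets_rejected(self, small_sim, rng):
        datasets, catalog, _ = small_sim
        with pytest.raises(ValueError):
            cons.density_contrast(datasets[0], catalog.genes("M00"), n_random=0, rng=rng)


class TestCrossSpeciesEndToEnd:
    def test_conserved_modules_share_significant_genes(self, small_cfg):
        """Shared planted modules across species -> overlapping G-MAD hits;
        scrambling module membership destroys the overlap."""
        from modnet import gmad
        from modnet.synthetic import simulate_compendium, simulate_species_pair

        datasets_a, catalog_a, _ = simulate_compendium(small_cfg)
        gmas_a, _ = gmad.gmad_matrix(datasets_a, catalog_a)
        datasets_b, catalog_b, hits, ortho = simulate_species_pair(small_cfg, scramble_frac=0.2)
        omap = cons.filter_orthologs(hits, reciprocal_best=True)
        gmas_b, _ = gmad.gmad_matrix(datasets_b, catalog_b)

        def hot(gm, module, ids):
            j = ids.index(module)
            col = gm.values[:, j]
            return {g for g, v in zip(gm.gene_ids, col) if np.isfinite(v) and abs(v) >= 0.5}

        conserved = [
            m for m in catalog_b.module_ids
            if catalog_b.modules[m][0].startswith("conserved")
        ]
        target = conserved[0]
        fwd = omap.forward()
        set_a = hot(gmas_a, target, catalog_a.module_ids)
        set_b = {a for a, b in fwd.items() if b in hot(gmas_b, target, catalog_b.module_ids)}
        r = cons.overlap_test(set_a, set_b, set(gmas_a.gene_ids))
        assert r.p_value < 1e-4
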