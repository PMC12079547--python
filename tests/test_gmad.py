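import numpy as np
import pytest
from scipy import stats as sps

from modnet import gmad
from modnet.io_formats import ExpressionDataset


def _dataset(values, seed_ids=None):
    g = seed_ids or [f"G{i}" for i in range(values.shape[0])]
    return ExpressionDataset(
        "d0", "sp", g, [f"S{j}" for j in range(values.shape[1])], np.asarray(values, float)
    ).validate()


class TestProfile:
    def test_perfectly_collinear_gene_tops_the_vector(self, rng):
        X = rng.standard_normal((20, 50))
        X[1] = 2.0 * X[0]  # identical up to scale -> r = 1, capped
        ds = _dataset(X)
        sv = gmad.gene_correlation_profile(ds, "G0")
        assert sv.genes[int(np.argmax(sv.stats))] == "G1"
        assert np.isfinite(sv.stats).all()

    def test_exact_linear_worked_example(self):
        # x=(1,2,3,4), y=(2,4,6,8): r = 1 exactly before capping
        X = np.array([[1, 2, 3, 4], [2, 4, 6, 8], [1, 0, 2, 1.0]])
        sv = gmad.gene_correlation_profile(_dataset(X), "G0")
        assert sv.stats[sv.genes.index("G1")] == pytest.approx(np.arctanh(gmad.R_CAP))

    def test_independent_noise_centers_at_zero(self, rng):
        X = rng.standard_normal((200, 1000))
        sv = gmad.gene_correlation_profile(_dataset(X), "G0")
        assert abs(sv.stats.mean()) < 0.05

    def test_constant_seed_rejected(self):
        X = np.vstack([np.ones(30), np.random.default_rng(0).standard_normal((3, 30))])
        with pytest.raises(gmad.DegenerateInputError):
            gmad.gene_correlation_profile(_dataset(X), "G0")


class TestRhoBar:
    def test_duplicated_gene_gives_rho_one_vif_two(self, rng):
        x = rng.standard_normal(100)
        ds = _dataset(np.vstack([x, x + 1e-9 * rng.standard_normal(100)]))
        est = gmad.estimate_rho_bar(ds, ["G0", "G1"])
        assert est.rho_bar == pytest.approx(1.0, abs=1e-6)
        assert est.vif == pytest.approx(2.0, abs=1e-5)

    def test_independent_module_vif_near_one(self, rng):
        ds = _dataset(rng.standard_normal((20, 500)))
        est = gmad.estimate_rho_bar(ds, [f"G{i}" for i in range(20)])
        assert abs(est.rho_bar) < 0.05

    def test_single_gene_rejected(self, rng):
        ds = _dataset(rng.standard_normal((5, 50)))
        with pytest.raises(gmad.DegenerateInputError):
            gmad.estimate_rho_bar(ds, ["G0"])

    def test_vif_floor(self):
        est = gmad.CorrelationEstimate(rho_bar=-0.5, m=10, vif_floor=1.0)
        assert est.vif == 1.0


def _statvec(stats, n=100):
    return gmad.GeneStatVector("seed", [f"g{i}" for i in range(len(stats))],
                               np.asarray(stats, float), n)


class TestCamera:
    def test_equal_means_give_null(self, rng):
        stats_ = np.concatenate([np.full(10, 0.5), np.full(40, 0.5)])
        stats_ += rng.standard_normal(50) * 0  # identical values: degenerate
        sv = _statvec(stats_)
        res = gmad.camera_test(sv, {f"g{i}" for i in range(10)},
                               gmad.CorrelationEstimate(0.0, 10))
        assert res.z == 0.0 and res.p_value == 1.0

    def test_attenuation_monotone_in_rho(self, rng):
        stats_ = rng.standard_normal(100)
        stats_[:15] += 0.6
        sv = _statvec(stats_)
        module = {f"g{i}" for i in range(15)}
        ps = [
            gmad.camera_test(sv, module, gmad.CorrelationEstimate(r, 15)).p_value
            for r in (0.0, 0.2, 0.5)
        ]
        assert ps[0] < ps[1] < ps[2]

    def test_matches_permutation_oracle_at_zero_rho(self, rng):
        """Analytic p within +-0.02 of a 10k gene-label permutation p (rho=0)."""
        for _ in range(10):
            N = int(rng.integers(60, 120)); m = int(rng.integers(8, 16))
            x = rng.standard_normal(N)
            members = rng.choice(N, m, replace=False)
            x[members] += rng.uniform(-0.7, 0.7)
            sv = _statvec(x)
            res = gmad.camera_test(sv, {f"g{i}" for i in members},
                                   gmad.CorrelationEstimate(0.0, m))
            obs = abs(x[members].mean() - np.delete(x, members).mean())
            B = 10_000
            pick = np.argpartition(rng.random((B, N)), m, axis=1)[:, :m]
            s_in = x[pick].mean(axis=1)
            s_out = (x.sum() - x[pick].sum(axis=1)) / (N - m)
            p_perm = np.mean(np.abs(s_in - s_out) >= obs - 1e-12)
            assert res.p_value == pytest.approx(p_perm, abs=0.02)

    def test_min_size_and_background_preconditions(self, rng):
        sv = _statvec(rng.standard_normal(12))
        with pytest.raises(gmad.DegenerateInputError):
            gmad.camera_test(sv, {"g0", "g1"}, gmad.CorrelationEstimate(0.0, 2))
        with pytest.raises(gmad.DegenerateInputError):
            gmad.camera_test(sv, {f"g{i}" for i in range(8)},
                             gmad.CorrelationEstimate(0.0, 8))


class TestBindingAndMeta:
    @pytest.mark.parametrize(
        "adj_p,direction,alpha,expected",
        [(0.001, 1, 0.05, 1), (0.2, -1, 0.05, 0), (0.05, 1, 0.05, 0)],
    )
    def test_quantization_rule(self, adj_p, direction, alpha, expected):
        res = gmad.EnrichmentResult(adj_p, direction, float(direction), "m", "g", "d")
        assert gmad.quantize_binding_score(res, alpha, adj_p).value == expected

    def test_meta_single_dataset(self):
        b = [gmad.BindingScore(1, "d0", "g", "m")]
        assert gmad.meta_analyze_gmas(b, [100], [1.0]) == 1.0

    def test_meta_cancellation(self):
        b = [gmad.BindingScore(1, "d0", "g", "m"), gmad.BindingScore(-1, "d1", "g", "m")]
        assert gmad.meta_analyze_gmas(b, [100, 100], [1.0, 1.0]) == 0.0

    def test_meta_weighted_hand_computation(self):
        # n = (100, 400, 100), vif = 1, b = (+1, +1, 0): (10+20+0)/(10+20+10)
        b = [gmad.BindingScore(v, f"d{i}", "g", "m") for i, v in enumerate((1, 1, 0))]
        assert gmad.meta_analyze_gmas(b, [100, 400, 100], [1, 1, 1]) == pytest.approx(0.75)

    def test_empty_is_absent_not_zero(self):
        with pytest.raises(gmad.DegenerateInputError):
            gmad.meta_analyze_gmas([], [], [])


class TestVectorizedScan:
    def test_matches_scalar_camera(self, small_sim):
        """The all-at-once scan equals profile + scalar test, gene by gene."""
        datasets, catalog, _ = small_sim
        ds = datasets[0]
        sc = gmad.score_dataset(ds, catalog)
        rng = np.random.default_rng(0)
        for g in rng.choice(sc.genes, 5, replace=False):
            sv = gmad.gene_correlation_profile(ds, g)
            for mid in ("M00", "M03"):
                est = gmad.estimate_rho_bar(ds, catalog.genes(mid))
                res = gmad.camera_test(
                    sv, catalog.genes(mid), est, module_id=mid, dataset_id=ds.dataset_id
                )
                i = sc.genes.index(g); j = sc.module_ids.index(mid)
                assert sc.z[i, j] == pytest.approx(res.z, rel=1e-6, abs=1e-8)

    def test_gmas_bounded_and_absent_cells(self, small_sim):
        datasets, catalog, _ = small_sim
        gm, _ = gmad.gmad_matrix(datasets, catalog)
        finite = gm.values[np.isfinite(gm.values)]
        assert np.all(np.abs(finite) <= 1.0)
        assert gm.n_contrib[np.isnan(gm.values)].max(initial=0) == 0

    def test_scan_recovers_planted_genes(self, small_sim):
        datasets, catalog, truth = small_sim
        df = gmad.gmad_scan(datasets, catalog, "M00")
        col = df.set_index("gene")["gmas"]
        planted = [g for g, m, s in truth.gene_module_assoc if m == "M00"]
        background = col.drop(index=[g for g, _, _ in truth.gene_module_assoc], errors="ignore")
        thresh = np.nanpercentile(np.abs(background.to_numpy(float)), 95)
        assert planted and all(abs(col[g]) >= thresh for g in planted)

    def test_null_binding_rate_matches_alpha_family(self):
        """With no planted structure, BH-significant cells are rare."""
        from modnet.synthetic import SimulationConfig, simulate_compendium

        cfg = SimulationConfig(seed=77, n_datasets=1, n_genes=300, n_samples_per_dataset=80,
                               n_modules=5, module_size_range=(10, 15), rho_bar_target=0.0,
                               frac_planted_gene_assoc=0.0, planted_module_pairs=[])
        datasets, catalog, _ = simulate_compendium(cfg)
        sc = gmad.quantize_dataset(gmad.score_dataset(datasets[0], catalog), alpha=0.05)
        frac = np.nanmean(np.abs(sc.binding))
        assert frac <= 0.05
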