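"""End-to-end orchestration: simulate -> G-MAD -> M-MAD -> conservation ->
cell types -> eQTL -> key drivers, from a single YAML-able config.

Every stage writes TSV outputs stamped with the config hash and seed, so
reruns with an identical config are byte-identical. A stage failure halts
everything downstream and is recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import causal_kda, celltype, conservation, eqtl, gmad, mmad
from .io_formats import GeneAnnotation, write_gmt
from .synthetic import (
    SimulationConfig,
    simulate_compendium,
    simulate_gene_annotations,
    simulate_genotypes_and_effects,
    simulate_markers,
    simulate_regulatory_network,
    simulate_species_pair,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "gmad", "mmad", "conservation", "celltype", "eqtl", "kda")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results"
    sim: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # every printed threshold is a named key, never a literal in stage code
    gmad_alpha: float = 0.05
    mmad_alpha: float = 0.05
    mmas_threshold: float = 0.3
    celltype_fdr: float = 0.01
    cis_p: float = 2.46e-4
    trans_bh_p: float = 1.51e-13
    meth_bh: float = 0.05
    corr_p: float = 1e-5
    e_value_max: float = 1e-5
    identity_min: float = 60.0
    kda_depth: int = 2
    kda_alpha: float = 0.05
    top_k: int = 20
    gmas_significant: float = 0.5
    scramble_frac: float = 0.2
    n_random_density_sets: int = 99
    target_module_index: int = 0
    max_regulator_features: int = 10
    n_shap_instances: int = 5
    learners: list | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        # hash the scientific configuration only: where outputs land must
        # not change what they contain
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> str:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# modnet config_hash={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.8g")
    return str(path)


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages in dependency order; return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": {}, "outputs": {}}
    state: dict = {}

    def record(stage: str, status: str, paths: list[str] | None = None, note: str = "") -> None:
        manifest["stages"][stage] = {"status": status, "note": note}
        for p in paths or []:
            manifest["outputs"].setdefault(stage, []).append(p)

    halted = False
    for stage in STAGES:
        if halted:
            record(stage, "skipped", note="upstream failure")
            continue
        if not config.stages.get(stage, True):
            record(stage, "disabled")
            continue
        fn = _STAGE_FNS[stage]
        try:
            paths = fn(config, state, out)
            record(stage, "ok", paths, note=state.pop(f"_note_{stage}", ""))
        except _MissingUpstream as exc:
            record(stage, "dependency-error", note=str(exc))
            halted = True
        except Exception as exc:  # noqa: BLE001 - any stage failure halts downstream
            log.exception("stage %s failed", stage)
            record(stage, "failed", note=f"{type(exc).__name__}: {exc}")
            halted = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


class _MissingUpstream(RuntimeError):
    pass


def _need(state: dict, key: str, stage: str):
    if key not in state:
        raise _MissingUpstream(f"stage {stage!r} needs missing upstream output {key!r}")
    return state[key]


def _stage_simulate(cfg: RunConfig, state: dict, out: Path) -> list[str]:
    sim = SimulationConfig(**{"seed": cfg.seed, **cfg.sim})
    datasets, catalog, truth = simulate_compendium(sim)
    annotations = simulate_gene_annotations(sim)
    genotypes, bins, truth = simulate_genotypes_and_effects(sim, annotations, datasets[0], truth)
    priors, tfs, truth = simulate_regulatory_network(sim, catalog, truth)
    markers, truth = simulate_markers(sim, catalog, truth)
    state.update(
        sim=sim, datasets=datasets, catalog=catalog, truth=truth, annotations=annotations,
        genotypes=genotypes, meth_bins=bins, priors=priors, tfs=tfs, markers=markers,
    )
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    gmt_path = out / "modules.gmt"
    write_gmt(catalog, gmt_path)
    return [str(truth_path), str(gmt_path)]


def _stage_gmad(cfg: RunConfig, state: dict, out: Path) -> list[str]:
    datasets = _need(state, "datasets", "gmad")
    catalog = state["catalog"]
    gmas, per_dataset = gmad.gmad_matrix(datasets, catalog, alpha=cfg.gmad_alpha)
    state["gmas"], state["per_dataset"] = gmas, per_dataset
    df = pd.DataFrame(gmas.values, index=gmas.gene_ids, columns=gmas.module_ids)
    df.index.name = "gene"
    return [_write(df, out / "gmas.tsv", cfg, index=True)]


def _stage_mmad(cfg: RunConfig, state: dict, out: Path) -> list[str]:
    per_dataset = _need(state, "per_dataset", "mmad")
    catalog = state["catalog"]
    mm = mmad.mmad_matrix(per_dataset, catalog, alpha=cfg.mmad_alpha)
    state["mmas"] = mm
    net = mmad.build_module_network(mm, cfg.mmas_threshold)
    state["module_network"] = net
    df = pd.DataFrame(mm.values, index=mm.module_ids, columns=mm.module_ids)
    df.index.name = "target"
    p1 = _write(df, out / "mmas.tsv", cfg, index=True)
    edges = pd.DataFrame(net.edges, columns=["target", "candidate", "mmas", "sign"])
    p2 = _write(edges, out / "module_network.tsv", cfg)
    return [p1, p2]


def _stage_conservation(cfg: RunConfig, state: dict, out: Path) -> list[str]:
    sim = _need(state, "sim", "conservation")
    gmas = _need(state, "gmas", "conservation")
    catalog, mm = state["catalog"], state["mmas"]
    datasets_b, catalog_b, hits, ortho = simulate_species_pair(sim, cfg.scramble_frac)
    omap = conservation.filter_orthologs(
        hits, cfg.e_value_max, cfg.identity_min, reciprocal_best=True
    )
    gmas_b, per_b = gmad.gmad_matrix(datasets_b, catalog_b, alpha=cfg.gmad_alpha)
    target = catalog.module_ids[cfg.target_module_index]

    def significant_genes(gm, mod_ids):
        j = mod_ids.index(target)
        col = gm.values[:, j]
        return {
            g for g, v in zip(gm.gene_ids, col)
            if np.isfinite(v) and abs(v) >= cfg.gmas_significant
        }

    set_a = significant_genes(gmas, gmas.module_ids)
    fwd = omap.forward()
    set_b_on_a = {a for a, b in fwd.items() if b in significant_genes(gmas_b, gmas_b.module_ids)}
    ov = conservation.overlap_test(set_a, set_b_on_a, set(gmas.gene_ids))

    coupled = sorted({m for pair in state["truth"].module_module_assoc for m in pair[:2]})
    vals = mm.values[np.isfinite(mm.values)]
    coupled_idx = [mm.module_ids.index(m) for m in coupled if m in mm.module_ids]
    coupled_vals = np.abs(mm.values[coupled_idx].ravel())
    coupled_vals = coupled_vals[np.isfinite(coupled_vals)]
    ks = conservation.ks_one_sided(coupled_vals, np.abs(vals))

    rng = np.random.default_rng([cfg.seed, 11])
    dens_p, d_target, _ = conservation.density_contrast(
        state["datasets"][0],
        catalog.genes(target),
        n_random=cfg.n_random_density_sets,
        p_threshold=cfg.corr_p,
        rng=rng,
    )
    df = pd.DataFrame(
        [
            ("ortholog_pairs", len(omap.pairs)),
            ("overlap_k", ov.k),
            ("overlap_p", ov.p_value),
            ("ks_d", ks.d_statistic),
            ("ks_p", ks.p_value),
            ("density_target", d_target),
            ("density_empirical_p", dens_p),
        ],
        columns=["quantity", "value"],
    )
    state["conservation_overlap"] = ov
    return [_write(df, out / "conservation.tsv", cfg)]


def _stage_celltype(cfg: RunConfig, state: dict, out: Path) -> list[str]:
    markers = _need(state, "markers", "celltype")
    catalog = state["catalog"]
    mc = celltype.MarkerCatalog(markers, catalog.universe).validate()
    modules = {m: catalog.genes(m) for m in catalog.module_ids}
    table = celltype.enrichment_table(mc, modules, catalog.universe, fdr=cfg.celltype_fdr)
    state["celltype_table"] = table
    return [_write(table, out / "celltype_enrichment.tsv", cfg)]


def _stage_eqtl(cfg: RunConfig, state: dict, out: Path) -> list[str]:
    genotypes = _need(state, "genotypes", "eqtl")
    ds, anns, truth = state["datasets"][0], state["annotations"], state["truth"]
    catalog = state["catalog"]
    snp_genes = sorted({g for v, g, c, b in truth.eqtl_truth if not v.startswith("b")})
    records = eqtl.scan_and_classify(genotypes, ds, anns, genes=snp_genes)
    kept = eqtl.apply_thresholds(records, cfg.cis_p, cfg.trans_bh_p)
    meth_genes = sorted({g for v, g, c, b in truth.eqtl_truth if v.startswith("b")})
    meth = eqtl.methylation_eqtl(state["meth_bins"], ds, anns, genes=meth_genes,
                                 bh_alpha=cfg.meth_bh)
    cis_genes = {r.gene for r in kept if r.eqtl_class == "cis"}
    target = catalog.module_ids[cfg.target_module_index]
    enr = eqtl.cis_gene_module_enrichment(
        cis_genes & catalog.universe, catalog.genes(target), catalog.universe
    )
    state["eqtl_kept"] = kept
    state["eqtl_meth"] = meth
    p1 = _write(eqtl.records_frame(kept), out / "eqtl.tsv", cfg)
    p2 = _write(eqtl.records_frame(meth), out / "eqtl_methylation.tsv", cfg)
    p3 = _write(
        pd.DataFrame(
            [("cis_genes", len(cis_genes)), ("module_overlap", enr.a), ("fet_p", enr.p_value)],
            columns=["quantity", "value"],
        ),
        out / "cis_module_enrichment.tsv",
        cfg,
    )
    return [p1, p2, p3]


def _stage_kda(cfg: RunConfig, state: dict, out: Path) -> list[str]:
    priors = _need(state, "priors", "kda")
    tfs, truth, catalog = state["tfs"], state["truth"], state["catalog"]
    ds = state["datasets"][0]
    eqtl_kept = state.get("eqtl_kept")
    note_args = {}
    if eqtl_kept:
        anns = {a.gene_id: a for a in state["annotations"]}
        note_args = dict(
            eqtl_records=eqtl_kept,
            variant_positions={
                v: p for v, p in zip(state["genotypes"].variant_ids, state["genotypes"].positions)
            },
            tf_loci={t: anns[t] for t in tfs if t in anns},
        )
    graph = causal_kda.build_causal_graph(priors, tfs, **note_args)
    module = truth.driver_module or catalog.module_ids[cfg.target_module_index]
    cofunc = set(catalog.genes(module)) | {
        g for g, m, _ in truth.gene_module_assoc if m == module
    }
    universe = set(ds.gene_ids)
    drivers = causal_kda.key_driver_scan(
        graph, cofunc & universe, universe, depth=cfg.kda_depth, alpha=cfg.kda_alpha
    )
    ddf = pd.DataFrame(
        [
            (r.node, r.neighborhood_size, r.overlap, r.p_value, r.p_adjusted,
             r.is_key_driver, r.tested)
            for r in drivers
        ],
        columns=["node", "neighborhood", "overlap", "p_value", "p_adjusted",
                 "is_key_driver", "tested"],
    ).sort_values(["p_value", "node"]).reset_index(drop=True)

    # regulator ranking: best candidates by enrichment p, capped for exact SHAP
    tested = [r for r in drivers if r.tested and r.node in set(tfs)]
    tested.sort(key=lambda r: (r.p_value, r.node))
    feats = [r.node for r in tested[: cfg.max_regulator_features]]
    if len(feats) < 2:
        feats = list(tfs[: cfg.max_regulator_features])
    X = pd.DataFrame(
        ds.values[[ds.gene_index(g) for g in feats]].T, columns=feats
    )
    y = causal_kda.module_response(ds, catalog.genes(module))
    reports = causal_kda.fit_learners(X, y, seed=cfg.seed, learners=cfg.learners)
    rng = np.random.default_rng([cfg.seed, 13])
    bg = X.to_numpy()[rng.choice(len(X), size=min(30, len(X)), replace=False)]
    inst = X.to_numpy()[rng.choice(len(X), size=min(cfg.n_shap_instances, len(X)), replace=False)]
    phi_by_model = {
        rep.name: causal_kda.shap_matrix(rep.model.predict, inst, bg, seed=cfg.seed)
        for rep in reports
    }
    ranking = causal_kda.rank_drivers(phi_by_model, feats, top_k=cfg.top_k)
    cv = pd.DataFrame(
        [(r.name, r.cv_rmse, *r.fold_rmse) for r in reports],
        columns=["model", "cv_rmse"] + [f"fold{i+1}" for i in range(5)],
    )
    state["driver_table"], state["ranking"] = ddf, ranking
    if not eqtl_kept:
        state["_note_kda"] = "degraded evidence: priors only (no eQTL support)"
    paths = [
        _write(ddf, out / "key_drivers.tsv", cfg),
        _write(ranking, out / "regulator_ranking.tsv", cfg),
        _write(cv, out / "learner_cv.tsv", cfg),
    ]
    return paths


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "gmad": _stage_gmad,
    "mmad": _stage_mmad,
    "conservation": _stage_conservation,
    "celltype": _stage_celltype,
    "eqtl": _stage_eqtl,
    "kda": _stage_kda,
}
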