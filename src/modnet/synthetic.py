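"""Synthetic multi-dataset compendia with planted ground truth.

The generator emulates the statistical structure the analysis assumes in
real compendia: co-functional modules with controllable mean inter-gene
correlation, genes planted to associate with a module, coupled module
pairs, cis/trans eQTLs obeying the distance rules, methylation bins
coupled to expression, a TF-rooted regulatory DAG with planted drivers,
and cell-type marker sets overlapping designated modules.

Modules are driven by a shared latent factor: a member gene is
``a * factor + noise`` with unit noise, so for equal loadings the mean
pairwise correlation is rho = a^2 / (a^2 + 1) and ``a`` is solved from the
requested target. Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    Edge,
    EdgeTable,
    ExpressionDataset,
    GeneAnnotation,
    GenotypeMatrix,
    HomologyHitTable,
    MethylationBins,
    ModuleCatalog,
)


class ConfigError(ValueError):
    """Simulation config violates a geometric or size constraint."""


@dataclass
class SimulationConfig:
    seed: int = 0
    # compendium
    n_datasets: int = 10
    n_genes: int = 2000
    n_samples_per_dataset: int | list[int] = 100
    n_modules: int = 20
    module_size_range: tuple[int, int] = (10, 30)
    rho_bar_target: float = 0.3
    # planted gene-module associations
    assoc_effect: float = 0.8
    frac_planted_gene_assoc: float = 0.015
    # planted module-module couplings: (module index i, module index j, sign)
    planted_module_pairs: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(0, 1, 1), (2, 3, -1), (4, 5, 1), (6, 7, -1)]
    )
    coupling_gamma: float = 0.6
    # genome / genotypes
    genome_length: int = 30_000_000
    n_variants: int = 300
    maf_range: tuple[float, float] = (0.1, 0.5)
    cis_effect_beta: float = 0.8
    n_cis: int = 20
    n_trans: int = 10
    # methylation pseudo-genotypes
    n_meth_bins: int = 120
    meth_bin_width: int = 100
    n_meth_coupled: int = 10
    meth_effect: float = 2.0
    # regulatory network
    n_tfs: int = 30
    driver_out_degree: int = 15
    driver_module_index: int = 0
    n_random_edges: int = 200
    # markers
    n_cell_types: int = 5
    markers_per_type: int = 40
    marker_overlap: float = 0.5

    def sample_sizes(self) -> list[int]:
        n = self.n_samples_per_dataset
        return list(n) if isinstance(n, (list, tuple)) else [int(n)] * self.n_datasets

    def validate(self) -> "SimulationConfig":
        for name in ("frac_planted_gene_assoc", "marker_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        if not 0.0 <= self.rho_bar_target < 1.0:
            raise ConfigError(f"rho_bar_target={self.rho_bar_target} outside [0,1)")
        if self.module_size_range[0] < 2:
            raise ConfigError("module sizes must be >= 2")
        if sum(self._module_sizes(np.random.default_rng(0))) > self.n_genes:
            raise ConfigError("module sizes exceed n_genes")
        return self

    def _module_sizes(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.module_size_range
        return rng.integers(lo, hi + 1, size=self.n_modules)


@dataclass
class SyntheticTruth:
    """Planted associations, used as the recovery oracle in tests."""

    gene_module_assoc: set[tuple[str, str, int]] = field(default_factory=set)
    module_module_assoc: set[tuple[str, str, int]] = field(default_factory=set)
    eqtl_truth: set[tuple[str, str, str, float]] = field(default_factory=set)
    driver_truth: set[str] = field(default_factory=set)
    driver_module: str | None = None
    marker_truth: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "gene_module_assoc": sorted(self.gene_module_assoc),
            "module_module_assoc": sorted(self.module_module_assoc),
            "eqtl_truth": sorted(self.eqtl_truth),
            "driver_truth": sorted(self.driver_truth),
            "driver_module": self.driver_module,
            "marker_truth": {
                ct: [mod, sorted(genes)] for ct, (mod, genes) in self.marker_truth.items()
            },
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            gene_module_assoc={(g, m, int(s)) for g, m, s in obj["gene_module_assoc"]},
            module_module_assoc={(a, b, int(s)) for a, b, s in obj["module_module_assoc"]},
            eqtl_truth={(v, g, c, float(b)) for v, g, c, b in obj["eqtl_truth"]},
            driver_truth=set(obj["driver_truth"]),
            driver_module=obj.get("driver_module"),
            marker_truth={
                ct: (mod, frozenset(genes)) for ct, (mod, genes) in obj["marker_truth"].items()
            },
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _gene_ids(config: SimulationConfig) -> list[str]:
    width = max(4, len(str(config.n_genes - 1)))
    return [f"G{i:0{width}d}" for i in range(config.n_genes)]


def _module_ids(config: SimulationConfig) -> list[str]:
    return [f"M{j:02d}" for j in range(config.n_modules)]


def build_catalog(config: SimulationConfig) -> ModuleCatalog:
    """Disjoint module memberships over the synthetic gene universe."""
    rng = _rng(config, 1)
    genes = _gene_ids(config)
    sizes = config._module_sizes(rng)
    modules: dict[str, tuple[str, frozenset[str]]] = {}
    cursor = 0
    for mid, size in zip(_module_ids(config), sizes):
        modules[mid] = (f"synthetic module {mid}", frozenset(genes[cursor : cursor + size]))
        cursor += size
    return ModuleCatalog(modules, frozenset(genes)).validate()


def simulate_compendium(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], ModuleCatalog, SyntheticTruth]:
    """Generate the expression compendium with planted module structure.

    Member genes of a module load on its latent factor; planted associated
    genes get the factor added at ``assoc_effect`` (times the planted sign);
    coupled module pairs share correlated factors; everything else is
    independent unit noise.
    """
    config.validate()
    catalog = build_catalog(config)
    genes = _gene_ids(config)
    mids = _module_ids(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    module_members = {m: sorted(catalog.genes(m)) for m in mids}
    in_module = set().union(*(catalog.genes(m) for m in mids)) if mids else set()

    rho = config.rho_bar_target
    loading = np.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0

    truth = SyntheticTruth()
    rng_plan = _rng(config, 2)
    background = [g for g in genes if g not in in_module]
    n_planted = int(round(config.frac_planted_gene_assoc * config.n_genes))
    planted_genes = [str(g) for g in rng_plan.choice(background, size=n_planted, replace=False)]
    planted_assign: list[tuple[str, str, int]] = []
    for k, g in enumerate(planted_genes):
        mod = mids[k % len(mids)]
        sign = 1 if k % 3 else -1  # roughly one third negative
        planted_assign.append((g, mod, sign))
        truth.gene_module_assoc.add((g, mod, sign))

    couples = []
    for i, j, sign in config.planted_module_pairs:
        if not (0 <= i < len(mids) and 0 <= j < len(mids)):
            raise ConfigError(f"planted module pair ({i},{j}) out of range")
        couples.append((mids[i], mids[j], int(np.sign(sign)) or 1))
        truth.module_module_assoc.add((mids[i], mids[j], int(np.sign(sign)) or 1))

    datasets = []
    for d, n in enumerate(config.sample_sizes()):
        rng = _rng(config, 100 + d)
        factors = {m: rng.standard_normal(n) for m in mids}
        for mi, mj, sign in couples:
            g = config.coupling_gamma
            factors[mj] = sign * g * factors[mi] + np.sqrt(1 - g * g) * rng.standard_normal(n)
        X = rng.standard_normal((config.n_genes, n))
        for m in mids:
            rows = [gene_idx[g] for g in module_members[m]]
            X[rows] += loading * factors[m]
        for g, m, sign in planted_assign:
            X[gene_idx[g]] += sign * config.assoc_effect * factors[m]
        ds = ExpressionDataset(
            dataset_id=f"D{d:02d}",
            species="speciesA",
            gene_ids=list(genes),
            sample_ids=[f"D{d:02d}_S{s:04d}" for s in range(n)],
            values=X,
        )
        datasets.append(ds.validate())
    return datasets, catalog, truth


# ---------------------------------------------------------------------------
# genome, genotypes, methylation
# ---------------------------------------------------------------------------

CIS_WINDOW = 1_000_000
TRANS_MIN_DIST = 5_000_000


def simulate_gene_annotations(
    config: SimulationConfig, gene_length: int = 1000, chrom: str = "chr1"
) -> list[GeneAnnotation]:
    """Genes evenly spaced along one synthetic chromosome."""
    spacing = config.genome_length // (config.n_genes + 1)
    if spacing <= gene_length:
        raise ConfigError("genome too short for the requested gene count")
    return [
        GeneAnnotation(g, chrom, (i + 1) * spacing, (i + 1) * spacing + gene_length)
        for i, g in enumerate(_gene_ids(config))
    ]


def _place_cis(rng: np.random.Generator, ann: GeneAnnotation, genome_length: int) -> int:
    lo = max(0, ann.start - CIS_WINDOW)
    hi = min(genome_length - 1, ann.end + CIS_WINDOW)
    return int(rng.integers(lo, hi))


def _place_trans(rng: np.random.Generator, ann: GeneAnnotation, genome_length: int) -> int:
    left = (0, ann.start - TRANS_MIN_DIST)  # exclusive upper bound
    right = (ann.end + TRANS_MIN_DIST, genome_length)
    spans = [(a, b) for a, b in (left, right) if b - a > 0]
    if not spans:
        raise ConfigError(
            f"genome of {genome_length} bp too short to place a trans variant "
            f">= {TRANS_MIN_DIST} bp from gene {ann.gene_id}"
        )
    widths = np.array([b - a for a, b in spans], dtype=float)
    a, b = spans[int(rng.choice(len(spans), p=widths / widths.sum()))]
    return int(rng.integers(a, b))


def simulate_genotypes_and_effects(
    config: SimulationConfig,
    annotations: list[GeneAnnotation],
    dataset: ExpressionDataset,
    truth: SyntheticTruth | None = None,
) -> tuple[GenotypeMatrix, MethylationBins, SyntheticTruth]:
    """Plant cis/trans eQTLs and methylation-coupled bins into ``dataset``.

    Planted cis variants land within the cis window of their target gene's
    body; trans variants at least the trans distance away. The target
    gene's expression row is incremented by ``beta * dosage`` (or
    ``meth_effect * centered level`` for coupled bins), in place.
    """
    truth = truth or SyntheticTruth()
    rng = _rng(config, 3)
    ann_by_gene = {a.gene_id: a for a in annotations}
    genes = [g for g in dataset.gene_ids if g in ann_by_gene]
    n_target = config.n_cis + config.n_trans
    if n_target > len(genes):
        raise ConfigError("not enough annotated genes for the requested eQTL count")
    targets = list(rng.choice(genes, size=n_target, replace=False))
    cis_targets, trans_targets = targets[: config.n_cis], targets[config.n_cis :]

    chrom = annotations[0].chrom
    positions: list[tuple[str, int]] = []
    variant_ids: list[str] = []
    planted: list[tuple[str, str, str]] = []  # (variant, gene, class)
    for k, g in enumerate(cis_targets):
        positions.append((chrom, _place_cis(rng, ann_by_gene[g], config.genome_length)))
        variant_ids.append(f"vcis{k:03d}")
        planted.append((variant_ids[-1], g, "cis"))
    for k, g in enumerate(trans_targets):
        positions.append((chrom, _place_trans(rng, ann_by_gene[g], config.genome_length)))
        variant_ids.append(f"vtrans{k:03d}")
        planted.append((variant_ids[-1], g, "trans"))
    n_bg = max(0, config.n_variants - len(variant_ids))
    for k in range(n_bg):
        positions.append((chrom, int(rng.integers(0, config.genome_length))))
        variant_ids.append(f"vbg{k:03d}")

    n = dataset.n_samples
    mafs = rng.uniform(*config.maf_range, size=len(variant_ids))
    dosages = rng.binomial(2, mafs[:, None], size=(len(variant_ids), n)).astype(np.int8)
    gm = GenotypeMatrix(variant_ids, positions, list(dataset.sample_ids), dosages).validate()

    vidx = {v: i for i, v in enumerate(variant_ids)}
    beta = config.cis_effect_beta
    for v, g, cls in planted:
        dataset.values[dataset.gene_index(g)] += beta * dosages[vidx[v]]
        truth.eqtl_truth.add((v, g, cls, beta))

    # methylation bins: evenly spaced, non-overlapping, contexts cycled
    mb_rng = _rng(config, 4)
    width = config.meth_bin_width
    step = config.genome_length // (config.n_meth_bins + 1)
    if step <= width:
        raise ConfigError("genome too short for the requested methylation bin count")
    coords = [(chrom, (i + 1) * step, (i + 1) * step + width) for i in range(config.n_meth_bins)]
    bin_ids = [f"b{i:04d}" for i in range(config.n_meth_bins)]
    contexts = [("CG", "CH", "C")[i % 3] for i in range(config.n_meth_bins)]
    levels = mb_rng.beta(2.0, 2.0, size=(config.n_meth_bins, n))
    bins = MethylationBins(bin_ids, coords, list(dataset.sample_ids), levels, contexts, width)

    # couple a subset of bins to the expression of a nearby gene (cis-like)
    coupled_bins = mb_rng.choice(config.n_meth_bins, size=config.n_meth_coupled, replace=False)
    ann_sorted = sorted(annotations, key=lambda a: a.start)
    starts = np.array([a.start for a in ann_sorted])
    for bi in coupled_bins:
        _, s, e = coords[bi]
        gi = int(np.clip(np.searchsorted(starts, s) - 1, 0, len(ann_sorted) - 1))
        g = ann_sorted[gi].gene_id
        if g not in dataset.gene_ids:
            continue
        centered = levels[bi] - levels[bi].mean()
        dataset.values[dataset.gene_index(g)] += config.meth_effect * centered
        truth.eqtl_truth.add((bin_ids[bi], g, "cis", config.meth_effect))
    return gm, bins.validate(), truth


# ---------------------------------------------------------------------------
# regulatory network
# ---------------------------------------------------------------------------


def simulate_regulatory_network(
    config: SimulationConfig,
    catalog: ModuleCatalog,
    truth: SyntheticTruth | None = None,
) -> tuple[EdgeTable, list[str], SyntheticTruth]:
    """TF-rooted DAG with one planted driver into a designated module.

    TFs are real genes from the simulated universe (so their expression
    exists for the learner stage): the planted driver is a gene planted to
    associate with the designated module, the remaining TFs are background
    genes. TFs are ordered and TF->TF edges respect the order, so the
    graph is acyclic by construction. Returns (edges, tfs, updated truth).
    """
    truth = truth or SyntheticTruth()
    rng = _rng(config, 5)
    genes = _gene_ids(config)
    mids = _module_ids(config)
    driver_module = mids[config.driver_module_index]
    module_genes = sorted(catalog.genes(driver_module))
    in_any_module = set().union(*(catalog.genes(m) for m in mids))
    planted_for_driver = sorted(
        g for g, m, _ in truth.gene_module_assoc if m == driver_module
    )
    planted_all = {g for g, _, _ in truth.gene_module_assoc}
    pool = [g for g in genes if g not in in_any_module and g not in planted_all]
    driver = str(planted_for_driver[0]) if planted_for_driver else pool.pop(0)
    others = list(rng.choice(pool, size=config.n_tfs - 1, replace=False))
    tfs = [driver] + [str(g) for g in others]

    edges: list[Edge] = []
    k = min(config.driver_out_degree, len(module_genes))
    for g in rng.choice(module_genes, size=k, replace=False):
        edges.append(Edge(driver, str(g), float(rng.uniform(0.7, 1.0)), 1, "dap_seq"))
    truth.driver_truth.add(driver)
    truth.driver_module = driver_module

    tf_set = set(tfs)
    non_module = [
        g for g in genes if g not in catalog.genes(driver_module) and g not in tf_set
    ]
    for _ in range(config.n_random_edges):
        src = tfs[int(rng.integers(0, config.n_tfs))]
        if rng.random() < 0.15:  # TF -> later TF, order-respecting
            si = tfs.index(src)
            if si == config.n_tfs - 1:
                continue
            tgt = tfs[int(rng.integers(si + 1, config.n_tfs))]
        else:
            tgt = str(rng.choice(non_module))
        w = float(rng.uniform(0.2, 1.0))
        sign = 1 if rng.random() < 0.8 else -1
        edges.append(Edge(src, tgt, w, sign, "dap_seq"))
    table = EdgeTable(edges).validate()
    return table, tfs, truth


# ---------------------------------------------------------------------------
# cell-type markers
# ---------------------------------------------------------------------------


def simulate_markers(
    config: SimulationConfig,
    catalog: ModuleCatalog,
    truth: SyntheticTruth | None = None,
) -> tuple[dict[str, frozenset[str]], SyntheticTruth]:
    """Marker sets overlapping one designated module each at ``marker_overlap``."""
    truth = truth or SyntheticTruth()
    rng = _rng(config, 6)
    mids = _module_ids(config)
    universe = sorted(catalog.universe)
    markers: dict[str, frozenset[str]] = {}
    for t in range(config.n_cell_types):
        mod = mids[t % len(mids)]
        module_genes = sorted(catalog.genes(mod))
        size = config.markers_per_type
        n_overlap = int(round(config.marker_overlap * min(size, len(module_genes))))
        chosen = list(rng.choice(module_genes, size=n_overlap, replace=False))
        background = [g for g in universe if g not in catalog.genes(mod)]
        chosen += list(rng.choice(background, size=size - n_overlap, replace=False))
        ct = f"celltype{t:02d}"
        markers[ct] = frozenset(chosen)
        truth.marker_truth[ct] = (mod, markers[ct])
    return markers, truth


# ---------------------------------------------------------------------------
# second species for conservation tests
# ---------------------------------------------------------------------------


def simulate_species_pair(
    config: SimulationConfig,
    scramble_frac: float = 0.2,
) -> tuple[list[ExpressionDataset], ModuleCatalog, HomologyHitTable, dict[str, str]]:
    """Second 'species' sharing module memberships through a 1:1 ortholog map.

    A ``scramble_frac`` fraction of modules get random memberships instead,
    creating species-specific functions. Returns the second compendium, its
    catalog, a homology hit table (true orthologs pass the standard E-value
    and identity filters; decoys do not), and the true 1:1 map A->B.
    """
    rng = _rng(config, 7)
    genes_a = _gene_ids(config)
    ortho = {g: "B_" + g for g in genes_a}

    catalog_a = build_catalog(config)
    mids = _module_ids(config)
    n_scramble = int(round(scramble_frac * len(mids)))
    scrambled = set(rng.choice(mids, size=n_scramble, replace=False))
    modules_b: dict[str, tuple[str, frozenset[str]]] = {}
    for m in mids:
        if m in scrambled:
            size = len(catalog_a.genes(m))
            pick = rng.choice(genes_a, size=size, replace=False)
            modules_b[m] = (f"scrambled {m}", frozenset(ortho[g] for g in pick))
        else:
            modules_b[m] = (f"conserved {m}", frozenset(ortho[g] for g in catalog_a.genes(m)))
    catalog_b = ModuleCatalog(modules_b, frozenset(ortho.values())).validate()

    cfg_b = SimulationConfig(**{**asdict(config), "seed": config.seed + 7919})
    cfg_b.planted_module_pairs = [tuple(p) for p in config.planted_module_pairs]
    datasets_b, _, _ = simulate_compendium(cfg_b)
    member_map = {m: sorted(catalog_b.genes(m)) for m in mids}
    for ds in datasets_b:
        ds.species = "speciesB"
        ds.gene_ids = [ortho[g] for g in ds.gene_ids]
        if hasattr(ds, "_index"):
            del ds._index
        # re-plant module structure under species-B memberships so that
        # scrambled modules are genuinely species-specific
        rho = config.rho_bar_target
        loading = np.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0
        rs = np.random.default_rng([cfg_b.seed, 8, int(ds.dataset_id[1:])])
        noise = rs.standard_normal(ds.values.shape)
        vals = noise.copy()
        gi = {g: i for i, g in enumerate(ds.gene_ids)}
        factors = {m: rs.standard_normal(ds.n_samples) for m in mids}
        for i, j, sign in config.planted_module_pairs:
            gcoup = config.coupling_gamma
            factors[mids[j]] = (
                np.sign(sign) * gcoup * factors[mids[i]]
                + np.sqrt(1 - gcoup * gcoup) * rs.standard_normal(ds.n_samples)
            )
        for m in mids:
            rows = [gi[g] for g in member_map[m]]
            vals[rows] += loading * factors[m]
        ds.values = vals
        ds.validate()

    rows = []
    for g in genes_a:
        rows.append(
            (g, ortho[g], "speciesA", "speciesB",
             float(10 ** rng.uniform(-30, -10)), float(rng.uniform(65, 95)))
        )
    # decoy hits that fail the filters
    decoys = rng.choice(genes_a, size=max(2, len(genes_a) // 50), replace=False)
    for g in decoys:
        other = "B_" + str(rng.choice(genes_a))
        if rng.random() < 0.5:
            rows.append((g, other, "speciesA", "speciesB", float(10 ** rng.uniform(-4, 0)),
                         float(rng.uniform(65, 95))))
        else:
            rows.append((g, other, "speciesA", "speciesB", float(10 ** rng.uniform(-30, -10)),
                         float(rng.uniform(20, 55))))
    hits = HomologyHitTable(pd.DataFrame(rows, columns=list(HomologyHitTable.COLUMNS)))
    return datasets_b, catalog_b, hits.validate(), ortho
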