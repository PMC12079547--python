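"""Gene-module association determination (G-MAD).

For each dataset, every gene's co-expression profile (Fisher-z Pearson
correlation with the seed gene) is tested against each module with a
correlation-adjusted competitive gene-set test: the standardized
difference between the mean statistic of module genes and background
genes, with the module-side variance inflated by

    VIF = 1 + (m - 1) * rho_bar

where rho_bar is the mean pairwise inter-gene correlation of the module's
genes in that dataset. Significant tests (Benjamini-Hochberg within the
dataset's full gene x module family) are quantized to tri-valued binding
scores {-1, 0, +1} by enrichment direction, and binding scores are
meta-analyzed across datasets with weights sqrt(n_d / vif_d) into
gene-module association scores (GMAS) in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionDataset, ModuleCatalog

#: |r| cap applied before atanh so collinear genes stay finite
R_CAP = 1.0 - 1e-12


class DegenerateInputError(ValueError):
    pass


@dataclass
class GeneStatVector:
    """Per-gene Fisher-z correlation statistics around one seed gene."""

    seed_gene: str
    genes: list[str]  # seed excluded
    stats: np.ndarray
    n_samples: int


@dataclass
class CorrelationEstimate:
    """Mean pairwise inter-gene correlation of a module in one dataset."""

    rho_bar: float
    m: int
    vif_floor: float = 1.0

    @property
    def vif(self) -> float:
        return max(1.0 + (self.m - 1) * self.rho_bar, self.vif_floor)

    def vif_for(self, m_eff: int) -> float:
        """VIF recomputed for an effective module size (seed removed)."""
        return max(1.0 + (m_eff - 1) * self.rho_bar, self.vif_floor)


@dataclass
class EnrichmentResult:
    p_value: float
    direction: int
    z: float
    module_id: str
    seed_gene: str
    dataset_id: str


@dataclass
class BindingScore:
    value: int  # in {-1, 0, +1}
    dataset_id: str
    source: str  # seed gene (G-MAD) or source module (M-MAD)
    module_id: str


@dataclass
class GmasMatrix:
    """Genes x modules association scores; NaN marks absent cells."""

    gene_ids: list[str]
    module_ids: list[str]
    values: np.ndarray
    n_contrib: np.ndarray
    weight_formula: str = "sqrt(n_d / vif_d)"


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def _standardized(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (values - mu) / sd


def gene_correlation_profile(dataset: ExpressionDataset, seed_gene: str) -> GeneStatVector:
    """Fisher-z Pearson correlations of every (non-constant) gene with the seed."""
    if seed_gene not in dataset.gene_ids:
        raise KeyError(f"seed gene {seed_gene!r} not in dataset {dataset.dataset_id}")
    if seed_gene in dataset.constant_genes:
        raise DegenerateInputError(f"seed gene {seed_gene!r} is constant")
    Xs = _standardized(dataset.values)
    si = dataset.gene_index(seed_gene)
    r = Xs @ Xs[si] / dataset.n_samples
    keep = [
        i
        for i, g in enumerate(dataset.gene_ids)
        if i != si and g not in dataset.constant_genes
    ]
    r = np.clip(r[keep], -R_CAP, R_CAP)
    return GeneStatVector(
        seed_gene=seed_gene,
        genes=[dataset.gene_ids[i] for i in keep],
        stats=np.arctanh(r),
        n_samples=dataset.n_samples,
    )


def estimate_rho_bar(
    dataset: ExpressionDataset, module_genes, vif_floor: float = 1.0
) -> CorrelationEstimate:
    """Mean of all pairwise Pearson correlations among a module's genes."""
    usable = [
        g for g in module_genes if g in set(dataset.gene_ids) and g not in dataset.constant_genes
    ]
    if len(usable) < 2:
        raise DegenerateInputError(
            f"module has {len(usable)} usable genes in {dataset.dataset_id}; need >= 2"
        )
    rows = [dataset.gene_index(g) for g in usable]
    Xs = _standardized(dataset.values[rows])
    R = Xs @ Xs.T / dataset.n_samples
    m = len(usable)
    rho = float((R.sum() - np.trace(R)) / (m * (m - 1)))
    return CorrelationEstimate(rho_bar=rho, m=m, vif_floor=vif_floor)


def camera_test(
    statvec: GeneStatVector,
    module_genes,
    corr: CorrelationEstimate,
    module_id: str = "",
    dataset_id: str = "",
    min_size: int = 5,
) -> EnrichmentResult:
    """Correlation-adjusted competitive test of a module against the profile.

    z = (mean_in - mean_out) / (sd_pooled * sqrt(vif/m + 1/m2)); with
    vif = 1 this reduces to the unadjusted two-sample z-test. The seed gene
    is never in the stat vector, so it is excluded from both sides.
    """
    member = np.fromiter((g in set(module_genes) for g in statvec.genes), bool)
    m = int(member.sum())
    m2 = len(statvec.genes) - m
    if m < min_size:
        raise DegenerateInputError(f"module overlap {m} < min_size {min_size}")
    if m2 < 10:
        raise DegenerateInputError(f"background size {m2} < 10")
    s_in, s_out = statvec.stats[member], statvec.stats[~member]
    mean_in, mean_out = s_in.mean(), s_out.mean()
    sd_pooled = np.sqrt(
        ((m - 1) * s_in.var(ddof=1) + (m2 - 1) * s_out.var(ddof=1)) / (m + m2 - 2)
    )
    vif = corr.vif_for(m)
    if sd_pooled == 0:
        z = 0.0
    else:
        z = float((mean_in - mean_out) / (sd_pooled * np.sqrt(vif / m + 1.0 / m2)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return EnrichmentResult(
        p_value=min(p, 1.0),
        direction=int(np.sign(z)) if z != 0 else 0,
        z=z,
        module_id=module_id,
        seed_gene=statvec.seed_gene,
        dataset_id=dataset_id,
    )


def quantize_binding_score(
    result: EnrichmentResult, alpha: float, adjusted_p: float
) -> BindingScore:
    """Tri-valued binding score: direction if adjusted p < alpha (strict), else 0."""
    value = result.direction if adjusted_p < alpha else 0
    return BindingScore(value, result.dataset_id, result.seed_gene, result.module_id)


def meta_weights(n_samples: np.ndarray, vifs: np.ndarray) -> np.ndarray:
    """Effective-sample-size weights sqrt(n_d / vif_d)."""
    return np.sqrt(np.asarray(n_samples, float) / np.maximum(np.asarray(vifs, float), 1.0))


def meta_analyze_gmas(
    scores: list[BindingScore],
    n_samples: list[int],
    vifs: list[float],
) -> float:
    """Weighted average of per-dataset binding scores -> GMAS in [-1, 1]."""
    if not scores:
        raise DegenerateInputError("no contributing datasets; GMAS cell is absent")
    w = meta_weights(np.asarray(n_samples), np.asarray(vifs))
    b = np.array([s.value for s in scores], float)
    return float(np.sum(w * b) / np.sum(w))


# ---------------------------------------------------------------------------
# vectorized per-dataset scan
# ---------------------------------------------------------------------------


@dataclass
class DatasetScores:
    """All gene x module enrichment results for one dataset, plus provenance."""

    dataset_id: str
    n_samples: int
    genes: list[str]
    module_ids: list[str]
    z: np.ndarray  # genes x modules, NaN where untestable
    p: np.ndarray
    rho_bar: np.ndarray  # per module
    vif: np.ndarray  # per module, floored
    binding: np.ndarray | None = None  # filled by quantize_dataset


def score_dataset(
    dataset: ExpressionDataset,
    catalog: ModuleCatalog,
    min_size: int = 5,
    vif_floor: float = 1.0,
) -> DatasetScores:
    """Correlation-adjusted test of every gene against every module at once.

    Equivalent to looping gene_correlation_profile + camera_test, but the
    full Fisher-z correlation matrix is formed once per dataset.
    """
    usable = [g for g in dataset.gene_ids if g not in dataset.constant_genes]
    idx = [dataset.gene_index(g) for g in usable]
    Xs = _standardized(dataset.values[idx])
    n = dataset.n_samples
    R = Xs @ Xs.T / n
    np.clip(R, -R_CAP, R_CAP, out=R)
    Z = np.arctanh(R)
    np.fill_diagonal(Z, 0.0)  # self-correlation excluded from every sum
    N = len(usable)
    pos = {g: i for i, g in enumerate(usable)}

    sum_all = Z.sum(axis=1)
    sumsq_all = (Z**2).sum(axis=1)

    module_ids = catalog.module_ids
    z_mat = np.full((N, len(module_ids)), np.nan)
    p_mat = np.full((N, len(module_ids)), np.nan)
    rho_bars = np.full(len(module_ids), np.nan)
    vifs = np.full(len(module_ids), np.nan)

    for j, mid in enumerate(module_ids):
        members = [pos[g] for g in catalog.genes(mid) if g in pos]
        m_full = len(members)
        if m_full < 2:
            continue
        sub = Z[np.ix_(members, members)]
        rho = float(np.tanh(sub)[np.triu_indices(m_full, 1)].mean())  # back to r scale
        rho_bars[j] = rho
        member_mask = np.zeros(N, bool)
        member_mask[members] = True

        m_eff = np.where(member_mask, m_full - 1, m_full)  # seed excluded when member
        if (m_eff < min_size).all():
            continue
        sum_in = Z[:, members].sum(axis=1)  # diag already zero: self drops out
        sumsq_in = (Z[:, members] ** 2).sum(axis=1)
        m2_eff = (N - 1) - m_eff
        mean_in = sum_in / m_eff
        mean_out = (sum_all - sum_in) / m2_eff
        var_in = (sumsq_in - m_eff * mean_in**2) / np.maximum(m_eff - 1, 1)
        var_out = (sumsq_all - sumsq_in - m2_eff * mean_out**2) / np.maximum(m2_eff - 1, 1)
        sd_pooled = np.sqrt(
            np.maximum(
                ((m_eff - 1) * var_in + (m2_eff - 1) * var_out) / (m_eff + m2_eff - 2), 0.0
            )
        )
        vif_g = np.maximum(1.0 + (m_eff - 1) * rho, vif_floor)
        vifs[j] = max(1.0 + (m_full - 1) * rho, vif_floor)
        denom = sd_pooled * np.sqrt(vif_g / m_eff + 1.0 / m2_eff)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(denom > 0, (mean_in - mean_out) / denom, 0.0)
        z[m_eff < min_size] = np.nan
        z_mat[:, j] = z
        p_mat[:, j] = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)

    return DatasetScores(
        dataset.dataset_id, n, usable, module_ids, z_mat, p_mat, rho_bars, vifs
    )


def quantize_dataset(scores: DatasetScores, alpha: float = 0.05) -> DatasetScores:
    """BH adjustment across the dataset's gene x module family, then tri-value."""
    p = scores.p.ravel()
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    adj = adj.reshape(scores.p.shape)
    binding = np.where(np.isfinite(adj) & (adj < alpha), np.sign(scores.z), 0.0)
    binding[~np.isfinite(scores.z)] = np.nan
    scores.binding = binding
    return scores


def combine_gmas(
    per_dataset: list[DatasetScores],
    gene_ids: list[str],
    module_ids: list[str],
) -> GmasMatrix:
    """Meta-analysis of binding scores across datasets into the GMAS matrix."""
    G, M = len(gene_ids), len(module_ids)
    num = np.zeros((G, M))
    den = np.zeros((G, M))
    n_contrib = np.zeros((G, M), int)
    gpos = {g: i for i, g in enumerate(gene_ids)}
    mpos = {m: j for j, m in enumerate(module_ids)}
    for ds in per_dataset:
        if ds.binding is None:
            raise ValueError(f"dataset {ds.dataset_id} not quantized")
        rows = np.array([gpos[g] for g in ds.genes])
        w_mod = meta_weights(np.full(len(ds.module_ids), ds.n_samples), ds.vif)
        for j_src, mid in enumerate(ds.module_ids):
            if mid not in mpos or not np.isfinite(w_mod[j_src]):
                continue
            j = mpos[mid]
            b = ds.binding[:, j_src]
            ok = np.isfinite(b)
            num[rows[ok], j] += w_mod[j_src] * b[ok]
            den[rows[ok], j] += w_mod[j_src]
            n_contrib[rows[ok], j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / den, np.nan)
    return GmasMatrix(gene_ids, module_ids, values, n_contrib)


def gmad_scan(
    compendium: list[ExpressionDataset],
    catalog: ModuleCatalog,
    target_module: str,
    alpha: float = 0.05,
    min_size: int = 5,
    vif_floor: float = 1.0,
) -> "pd.DataFrame":
    """GMAS column for one target module across the compendium, ranked."""
    import pandas as pd

    if target_module not in catalog:
        raise KeyError(f"module {target_module!r} not in catalog")
    per_dataset = [
        quantize_dataset(score_dataset(ds, catalog, min_size, vif_floor), alpha)
        for ds in compendium
    ]
    gene_ids = sorted({g for ds in per_dataset for g in ds.genes})
    gmas = combine_gmas(per_dataset, gene_ids, catalog.module_ids)
    j = catalog.module_ids.index(target_module)
    df = pd.DataFrame(
        {
            "gene": gene_ids,
            "gmas": gmas.values[:, j],
            "n_datasets": gmas.n_contrib[:, j],
        }
    )
    return df.sort_values("gmas", ascending=False, key=lambda s: s.abs(), kind="stable").reset_index(
        drop=True
    )


def gmad_matrix(
    compendium: list[ExpressionDataset],
    catalog: ModuleCatalog,
    alpha: float = 0.05,
    min_size: int = 5,
    vif_floor: float = 1.0,
) -> tuple[GmasMatrix, list[DatasetScores]]:
    """Full GMAS matrix plus the per-dataset scores (reused by M-MAD)."""
    per_dataset = [
        quantize_dataset(score_dataset(ds, catalog, min_size, vif_floor), alpha)
        for ds in compendium
    ]
    gene_ids = sorted({g for ds in per_dataset for g in ds.genes})
    return combine_gmas(per_dataset, gene_ids, catalog.module_ids), per_dataset
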