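"""Expression-QTL scanning, cis/trans classification, and thresholds.

Associations are simple per-variant linear regressions of expression on
dosage (or methylation level for pseudo-genotype bins). The peak variant
per gene is classified by distance to the gene body: cis within 1 Mb,
trans at or beyond 5 Mb (or another chromosome); the 1-5 Mb gap is left
unclassified. Significance follows the study's convention: raw p below
the cis threshold for cis records, BH-adjusted p within the trans family
below the trans threshold for trans records. The printed threshold
exponents are interpreted on the 1e-4 / 1e-13 scale; both are plain
configurable numbers echoed into run metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .celltype import bh_adjust, fet_enrich
from .io_formats import (
    MISSING_DOSAGE,
    ExpressionDataset,
    GeneAnnotation,
    GenotypeMatrix,
    MethylationBins,
)

log = logging.getLogger(__name__)

CIS_WINDOW_BP = 1_000_000
TRANS_MIN_BP = 5_000_000
CIS_P_DEFAULT = 2.46e-4
TRANS_BH_P_DEFAULT = 1.51e-13
MIN_SHARED_SAMPLES = 20


@dataclass
class EqtlRecord:
    gene: str
    variant: str
    beta: float
    se: float
    p_value: float
    distance_bp: int | None = None
    eqtl_class: str = "unclassified"
    genotype_kind: str = "snp"
    p_adjusted: float = np.nan
    is_peak: bool = False


def _regress(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-row simple linear regression of y on each row of X.

    Returns (beta, se, p) with beta = cov(x, y) / var(x) and a two-sided
    t-test on n-2 degrees of freedom.
    """
    n = y.size
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=1)
    sxy = xc @ yc
    beta = sxy / sxx
    sse = (yc**2).sum() - beta * sxy
    sigma2 = np.maximum(sse, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def association_scan(
    genotypes: GenotypeMatrix,
    dataset: ExpressionDataset,
    gene: str,
) -> list[EqtlRecord]:
    """Regress one gene's expression on every variant's dosage.

    Missing genotypes are excluded pairwise (never imputed); variants
    monomorphic in the shared samples, or with fewer than 20 shared
    samples after exclusion, are skipped with a logged reason.
    """
    shared = [s for s in genotypes.samples if s in set(dataset.sample_ids)]
    if len(shared) < MIN_SHARED_SAMPLES:
        log.warning("gene %s: %d shared samples < %d, scan skipped",
                    gene, len(shared), MIN_SHARED_SAMPLES)
        return []
    scol = {s: j for j, s in enumerate(dataset.sample_ids)}
    gcol = {s: j for j, s in enumerate(genotypes.samples)}
    y_all = dataset.values[dataset.gene_index(gene), [scol[s] for s in shared]]
    G = genotypes.dosages[:, [gcol[s] for s in shared]].astype(float)

    records: list[EqtlRecord] = []
    has_missing = (G == MISSING_DOSAGE).any(axis=1)
    complete = ~has_missing
    if complete.any():
        sub = G[complete]
        poly = sub.max(axis=1) > sub.min(axis=1)
        rows = np.flatnonzero(complete)[poly]
        if rows.size:
            beta, se, p = _regress(y_all, G[rows])
            for r, b, s_, pv in zip(rows, beta, se, p):
                records.append(EqtlRecord(gene, genotypes.variant_ids[r], float(b), float(s_), float(pv)))
    for r in np.flatnonzero(has_missing):
        ok = G[r] != MISSING_DOSAGE
        if ok.sum() < MIN_SHARED_SAMPLES:
            continue
        x = G[r, ok]
        if x.max() == x.min():
            continue
        beta, se, p = _regress(y_all[ok], x[None, :])
        records.append(
            EqtlRecord(gene, genotypes.variant_ids[r], float(beta[0]), float(se[0]), float(p[0]))
        )
    return records


def boundary_distance(position: tuple[str, int], gene: GeneAnnotation) -> int | None:
    """bp from a variant to the nearest gene-body boundary; None if other chrom."""
    chrom, bp = position
    if chrom != gene.chrom:
        return None
    if gene.start <= bp < gene.end:
        return 0
    return int(min(abs(bp - gene.start), abs(bp - (gene.end - 1))))


def classify_eqtl(position: tuple[str, int], gene: GeneAnnotation) -> tuple[str, int | None]:
    """Total, deterministic classification into cis / trans / unclassified.

    Another chromosome is trans outright; on the same chromosome, cis
    within the 1 Mb window and trans at or beyond 5 Mb, with the gap in
    between left unclassified.
    """
    d = boundary_distance(position, gene)
    if d is None:
        return "trans", None
    if d <= CIS_WINDOW_BP:
        return "cis", d
    if d >= TRANS_MIN_BP:
        return "trans", d
    return "unclassified", d


def scan_and_classify(
    genotypes: GenotypeMatrix,
    dataset: ExpressionDataset,
    annotations: list[GeneAnnotation],
    genes: list[str] | None = None,
) -> list[EqtlRecord]:
    """Scan each gene, classify every record, and flag the per-region peak."""
    ann = {a.gene_id: a for a in annotations}
    genes = genes if genes is not None else [g for g in dataset.gene_ids if g in ann]
    vpos = {v: p for v, p in zip(genotypes.variant_ids, genotypes.positions)}
    out: list[EqtlRecord] = []
    for g in genes:
        recs = association_scan(genotypes, dataset, g)
        for r in recs:
            r.eqtl_class, r.distance_bp = classify_eqtl(vpos[r.variant], ann[g])
        # association peak: the minimum-p variant per gene per region class
        for cls in ("cis", "trans"):
            grp = [r for r in recs if r.eqtl_class == cls]
            if grp:
                min(grp, key=lambda r: (r.p_value, r.variant)).is_peak = True
        out.extend(recs)
    return out


def apply_thresholds(
    records: list[EqtlRecord],
    cis_p: float = CIS_P_DEFAULT,
    trans_bh_p: float = TRANS_BH_P_DEFAULT,
) -> list[EqtlRecord]:
    """Keep cis records with raw p < cis_p; trans with BH-adjusted p (within
    the trans family) < trans_bh_p. Unclassified records are dropped."""
    cis = [r for r in records if r.eqtl_class == "cis"]
    trans = [r for r in records if r.eqtl_class == "trans"]
    kept = [r for r in cis if r.p_value < cis_p]
    if trans:
        adj = bh_adjust([r.p_value for r in trans])
        for r, q in zip(trans, adj):
            r.p_adjusted = float(q)
        kept += [r for r in trans if r.p_adjusted < trans_bh_p]
    return kept


def methylation_eqtl(
    bins: MethylationBins,
    dataset: ExpressionDataset,
    annotations: list[GeneAnnotation],
    genes: list[str] | None = None,
    bh_alpha: float = 0.05,
) -> list[EqtlRecord]:
    """Methylation-bin pseudo-genotype scan, BH < alpha per methylation context.

    Constant-level bins are skipped as the monomorphic analogue. Returned
    records carry genotype_kind cg_dmb / ch_dmb / c_dmb and only the
    BH-significant ones survive.
    """
    ann = {a.gene_id: a for a in annotations}
    genes = genes if genes is not None else [g for g in dataset.gene_ids if g in ann]
    shared = [s for s in bins.samples if s in set(dataset.sample_ids)]
    if len(shared) < MIN_SHARED_SAMPLES:
        log.warning("methylation scan: %d shared samples < %d", len(shared), MIN_SHARED_SAMPLES)
        return []
    scol = {s: j for j, s in enumerate(dataset.sample_ids)}
    bcol = {s: j for j, s in enumerate(bins.samples)}
    L = bins.levels[:, [bcol[s] for s in shared]]
    variable = L.std(axis=1) > 0
    ctx = bins.contexts or ["C"] * len(bins.bin_ids)
    kind = {"CG": "cg_dmb", "CH": "ch_dmb", "C": "c_dmb"}

    records: list[EqtlRecord] = []
    rows = np.flatnonzero(variable)
    for g in genes:
        y = dataset.values[dataset.gene_index(g), [scol[s] for s in shared]]
        beta, se, p = _regress(y, L[rows])
        for r, b, s_, pv in zip(rows, beta, se, p):
            pos = (bins.coords[r][0], bins.coords[r][1])
            cls, dist = classify_eqtl(pos, ann[g])
            records.append(
                EqtlRecord(g, bins.bin_ids[r], float(b), float(s_), float(pv),
                           dist, cls, kind.get(ctx[r], "c_dmb"))
            )
    by_ctx: dict[str, list[EqtlRecord]] = {}
    for r in records:
        by_ctx.setdefault(r.genotype_kind, []).append(r)
    significant: list[EqtlRecord] = []
    for grp in by_ctx.values():
        adj = bh_adjust([r.p_value for r in grp])
        for r, q in zip(grp, adj):
            r.p_adjusted = float(q)
        significant += [r for r in grp if r.p_adjusted < bh_alpha]
    return significant


def cis_gene_module_enrichment(
    cis_genes, module_genes, universe, alpha: float = 0.05
):
    """FET enrichment of cis-eQTL genes in a module (adjusted downstream)."""
    return fet_enrich(cis_genes, module_genes, universe)


def records_frame(records: list[EqtlRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene, r.variant, r.beta, r.se, r.p_value, r.p_adjusted,
             r.distance_bp, r.eqtl_class, r.genotype_kind, r.is_peak)
            for r in records
        ],
        columns=["gene", "variant", "beta", "se", "p_value", "p_adjusted",
                 "distance_bp", "eqtl_class", "genotype_kind", "is_peak"],
    )
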