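"""Cell-type specificity of co-functional modules.

Fisher's exact test (one-sided, enrichment) on the 2x2 overlap of
cell-type marker genes with module genes, with Benjamini-Hochberg control
across the whole cell-type x module family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ValidationError


@dataclass
class MarkerCatalog:
    markers: dict[str, frozenset[str]]  # cell type -> marker genes
    universe: frozenset[str]

    def validate(self) -> "MarkerCatalog":
        for ct, genes in self.markers.items():
            if genes - self.universe:
                raise ValidationError(f"cell type {ct!r}: markers outside the universe")
        return self


@dataclass
class CellTypeEnrichment:
    cell_type: str
    module: str
    a: int  # markers & module
    b: int  # markers only
    c: int  # module only
    d: int  # neither
    odds_ratio: float
    continuity_corrected: bool
    p_value: float
    p_adjusted: float = np.nan


def fet_enrich(markers, module_genes, universe, alternative: str = "greater") -> CellTypeEnrichment:
    """One-sided Fisher's exact test for marker-module overlap.

    Odds ratio uses a 0.5 continuity correction when any cell is zero
    (flagged via ``continuity_corrected``).
    """
    uni = set(universe)
    markers, module_genes = set(markers), set(module_genes)
    if markers - uni or module_genes - uni:
        raise ValidationError("input sets not contained in the universe")
    a = len(markers & module_genes)
    b = len(markers - module_genes)
    c = len(module_genes - markers)
    d = len(uni) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 if corrected else x for x in (a, b, c, d))
    odds = (aa * dd) / (bb * cc)
    return CellTypeEnrichment(
        "", "", a, b, c, d, float(odds), corrected, float(min(p, 1.0))
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-stable)."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(
    marker_catalog: MarkerCatalog,
    modules: dict[str, frozenset[str]],
    universe,
    fdr: float = 0.01,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Full cell-type x module enrichment table with a family-wide BH mask."""
    rows = []
    for ct, marks in marker_catalog.markers.items():
        for mid, genes in modules.items():
            res = fet_enrich(marks, genes, universe, alternative)
            res.cell_type, res.module = ct, mid
            rows.append(res)
    if not rows:
        return pd.DataFrame(
            columns=["cell_type", "module", "a", "b", "c", "d", "odds_ratio",
                     "p_value", "p_adjusted", "significant"]
        )
    adj = bh_adjust([r.p_value for r in rows])
    for r, q in zip(rows, adj):
        r.p_adjusted = float(q)
    df = pd.DataFrame(
        [
            (r.cell_type, r.module, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_value, r.p_adjusted)
            for r in rows
        ],
        columns=["cell_type", "module", "a", "b", "c", "d", "odds_ratio", "p_value", "p_adjusted"],
    )
    df["significant"] = df["p_adjusted"] < fdr
    return df
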