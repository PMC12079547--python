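"""Module-module association determination (M-MAD).

A target module's per-gene signed enrichment z-scores (from G-MAD, not the
quantized binding scores) act as the gene-level statistic; every other
module is tested against this profile with the same correlation-adjusted
competitive test, cross-module p-values are condensed to {1, 0, -1} under
a Bonferroni threshold (family = candidate modules per target per
dataset), and condensed scores are meta-analyzed across datasets into
module-module association scores (MMAS) in [-1, 1]. Thresholding |MMAS|
yields the module association network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gmad import (
    CorrelationEstimate,
    DatasetScores,
    DegenerateInputError,
    GeneStatVector,
    camera_test,
    meta_weights,
)


@dataclass
class MmasMatrix:
    """Directional modules x modules scores; row = target, column = candidate."""

    module_ids: list[str]
    values: np.ndarray  # NaN on the diagonal and untestable cells
    n_contrib: np.ndarray

    def symmetrized(self) -> "MmasMatrix":
        """Mean of the two directions (an explicit opt-in; M-MAD is directional)."""
        with np.errstate(invalid="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vals = np.nanmean(np.stack([self.values, self.values.T]), axis=0)
        np.fill_diagonal(vals, np.nan)
        n = np.maximum(self.n_contrib, self.n_contrib.T)
        return MmasMatrix(self.module_ids, vals, n)


@dataclass
class ModuleNetwork:
    nodes: list[str]
    edges: list[tuple[str, str, float, int]]  # (target, candidate, mmas, sign)
    threshold: float


def module_gene_profile(scores: DatasetScores, target_module: str) -> GeneStatVector:
    """The target module's per-gene signed z from G-MAD, one dataset."""
    if target_module not in scores.module_ids:
        raise KeyError(f"module {target_module!r} absent from dataset scores")
    j = scores.module_ids.index(target_module)
    z = scores.z[:, j]
    ok = np.isfinite(z)
    return GeneStatVector(
        seed_gene=target_module,
        genes=[g for g, k in zip(scores.genes, ok) if k],
        stats=z[ok],
        n_samples=scores.n_samples,
    )


def tri_condense(p_value: float, direction: int, alpha: float, n_candidates: int) -> int:
    """Bonferroni condensation of a cross-module p to {1, 0, -1}."""
    return direction if p_value < alpha / max(n_candidates, 1) else 0


def mmad_pair_test(
    profile: GeneStatVector,
    other_module_genes,
    corr: CorrelationEstimate,
    target_module_genes,
    alpha: float = 0.05,
    n_candidates: int = 1,
    min_size: int = 5,
) -> tuple[int, float, int]:
    """Test one candidate module against the target profile and condense.

    Genes shared with the target module are removed from the candidate
    before testing, so trivial self-overlap cannot drive the score.
    Returns (condensed score, raw p, direction).
    """
    candidate = set(other_module_genes) - set(target_module_genes)
    res = camera_test(profile, candidate, corr, min_size=min_size)
    return tri_condense(res.p_value, res.direction, alpha, n_candidates), res.p_value, res.direction


def meta_analyze_mmas(condensed: list[int], n_samples: list[int], vifs: list[float]) -> float:
    """Same weighted-average contract as the G-MAD meta-analysis."""
    if not condensed:
        raise DegenerateInputError("no contributing datasets; MMAS cell is absent")
    w = meta_weights(np.asarray(n_samples), np.asarray(vifs))
    return float(np.sum(w * np.asarray(condensed, float)) / np.sum(w))


def mmad_matrix(
    per_dataset: list[DatasetScores],
    catalog,
    alpha: float = 0.05,
    min_size: int = 5,
) -> MmasMatrix:
    """Full directional MMAS matrix from per-dataset G-MAD scores.

    Vectorized: per dataset and target, all candidate modules are tested at
    once against the target's z profile.
    """
    module_ids = list(per_dataset[0].module_ids)
    M = len(module_ids)
    num = np.zeros((M, M))
    den = np.zeros((M, M))
    n_contrib = np.zeros((M, M), int)

    for ds in per_dataset:
        gpos = {g: i for i, g in enumerate(ds.genes)}
        members = np.zeros((len(ds.genes), M), bool)
        for j, mid in enumerate(module_ids):
            rows = [gpos[g] for g in catalog.genes(mid) if g in gpos]
            members[rows, j] = True
        w_mod = meta_weights(np.full(M, ds.n_samples), ds.vif)

        for t in range(M):
            prof = ds.z[:, t]
            ok = np.isfinite(prof)
            if ok.sum() < min_size + 10:
                continue
            x = prof[ok]
            cand = members[ok] & ~members[ok, t][:, None]  # overlap removed
            m = cand.sum(axis=0)
            N = len(x)
            m2 = N - m
            testable = (m >= min_size) & (m2 >= 10)
            testable[t] = False
            if not testable.any():
                continue
            s_in = x @ cand
            ss_in = (x**2) @ cand
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_in = s_in / m
                mean_out = (x.sum() - s_in) / m2
                var_in = (ss_in - m * mean_in**2) / np.maximum(m - 1, 1)
                var_out = ((x**2).sum() - ss_in - m2 * mean_out**2) / np.maximum(m2 - 1, 1)
                sd_pooled = np.sqrt(
                    np.maximum(((m - 1) * var_in + (m2 - 1) * var_out) / (N - 2), 0.0)
                )
                vif_c = np.maximum(1.0 + (m - 1) * ds.rho_bar, 1.0)
                denom = sd_pooled * np.sqrt(vif_c / np.maximum(m, 1) + 1.0 / np.maximum(m2, 1))
                z = np.where(denom > 0, (mean_in - mean_out) / denom, 0.0)
            p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
            K = int(testable.sum())
            condensed = np.where(p < alpha / K, np.sign(z), 0.0)
            for c in np.flatnonzero(testable):
                w = w_mod[c] if np.isfinite(w_mod[c]) else np.sqrt(ds.n_samples)
                num[t, c] += w * condensed[c]
                den[t, c] += w
                n_contrib[t, c] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(values, np.nan)
    return MmasMatrix(module_ids, values, n_contrib)


def build_module_network(mmas: MmasMatrix, threshold: float = 0.3) -> ModuleNetwork:
    """Edges where |MMAS| >= threshold; isolated modules stay in the node list."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    edges = []
    M = len(mmas.module_ids)
    for t in range(M):
        for c in range(M):
            v = mmas.values[t, c]
            if np.isfinite(v) and abs(v) >= threshold:
                edges.append(
                    (mmas.module_ids[t], mmas.module_ids[c], float(v), int(np.sign(v)))
                )
    return ModuleNetwork(list(mmas.module_ids), edges, threshold)
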