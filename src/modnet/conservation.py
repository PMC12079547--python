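"""Cross-species conservation of co-functional networks.

Covers ortholog filtering from homology hit tables (E-value and percent
identity thresholds, optional reciprocal-best 1:1 reduction), overlap
significance by exact hypergeometric upper tail, one-sided two-sample
Kolmogorov-Smirnov comparison of MMAS distributions, all-pairs
correlation networks over a gene set, and an empirical density contrast
against size-matched random gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import Edge, EdgeTable, ExpressionDataset, HomologyHitTable


@dataclass
class OrthologMap:
    pairs: set[tuple[str, str]]
    e_value_max: float
    identity_min: float
    reciprocal_best: bool

    def forward(self) -> dict[str, str]:
        return dict(sorted(self.pairs))


@dataclass
class OverlapTestResult:
    k: int
    K: int
    n: int
    N: int
    p_value: float


@dataclass
class KsResult:
    d_statistic: float
    p_value: float
    alternative: str  # "greater": first sample stochastically greater


def filter_orthologs(
    hits: HomologyHitTable,
    e_value_max: float = 1e-5,
    identity_min: float = 60.0,
    reciprocal_best: bool = False,
) -> OrthologMap:
    """Retain hits with e_value < e_value_max and pct_identity > identity_min.

    With ``reciprocal_best``, keep only mutual best hits; "best" means
    lowest E-value, ties broken by higher identity then lexicographic
    subject id — fully deterministic.
    """
    df = hits.hits
    kept = df[(df["e_value"] < e_value_max) & (df["pct_identity"] > identity_min)].copy()
    if not reciprocal_best:
        return OrthologMap(
            set(zip(kept["query"], kept["subject"])), e_value_max, identity_min, False
        )

    def best(frame, by: str, other: str) -> dict[str, str]:
        frame = frame.sort_values(
            ["e_value", "pct_identity", other],
            ascending=[True, False, True],
            kind="stable",
        )
        return frame.drop_duplicates(subset=by, keep="first").set_index(by)[other].to_dict()

    best_fwd = best(kept, "query", "subject")
    best_rev = best(
        kept.rename(columns={"query": "subject", "subject": "query"}), "query", "subject"
    )
    pairs = {(q, s) for q, s in best_fwd.items() if best_rev.get(s) == q}
    return OrthologMap(pairs, e_value_max, identity_min, True)


def overlap_test(set_a, set_b, universe) -> OverlapTestResult:
    """Upper-tail hypergeometric p for the overlap of two sets in a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise ValueError("sets not contained in the universe")
    k, K, n, N = len(a & b), len(a), len(b), len(universe)
    # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the exact upper tail
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTestResult(k, K, n, N, min(max(p, 0.0), 1.0))


def ks_one_sided(values_a, values_b) -> KsResult:
    """One-sided two-sample K-S: is sample A stochastically greater than B?

    D+ = sup_x (F_b(x) - F_a(x)). Exact enumeration when m*n <= 1e4,
    otherwise the one-sided asymptotic tail exp(-2 m n D^2 / (m + n)).
    """
    a = np.asarray(list(values_a), float)
    b = np.asarray(list(values_b), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    # scipy's 'greater' alternative: statistic = max(F_a - F_b); we want
    # F_b above F_a, i.e. A shifted right, so swap the arguments
    res = stats.ks_2samp(b, a, alternative="greater", method="auto")
    d = float(res.statistic)
    if a.size * b.size <= 10_000:
        p = float(stats.ks_2samp(b, a, alternative="greater", method="exact").pvalue)
    else:
        m, n = a.size, b.size
        p = float(np.exp(-2.0 * m * n * d * d / (m + n)))
    return KsResult(d, min(p, 1.0), "greater")


def correlation_network(
    dataset: ExpressionDataset,
    gene_set,
    p_threshold: float = 1e-5,
    method: str = "pearson",
) -> EdgeTable:
    """All-pairs correlation edges within a gene set, kept below a p cut.

    Two-sided t-test on r with n-2 degrees of freedom; edge sign follows
    the correlation sign. ``method`` may be "pearson" or "spearman"
    (rank-transformed Pearson).
    """
    genes = sorted(set(gene_set))
    present = [g for g in genes if g in set(dataset.gene_ids) and g not in dataset.constant_genes]
    if len(present) < 2:
        raise ValueError("need >= 2 usable genes")
    n = dataset.n_samples
    if n < 4:
        raise ValueError("need >= 4 samples for the correlation t-test")
    X = dataset.values[[dataset.gene_index(g) for g in present]]
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
    R = Xs @ Xs.T / n
    np.clip(R, -1.0 + 1e-12, 1.0 - 1e-12, out=R)
    iu = np.triu_indices(len(present), 1)
    r = R[iu]
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    edges = [
        Edge(present[i], present[j], float(rv), int(np.sign(rv)) or 1, "correlation")
        for i, j, rv, pv in zip(iu[0], iu[1], r, p)
        if pv < p_threshold
    ]
    return EdgeTable(edges)


def network_density(table: EdgeTable, n_genes: int) -> float:
    """Retained edges over possible pairs."""
    possible = n_genes * (n_genes - 1) / 2
    return len(table.edges) / possible if possible else 0.0


def density_contrast(
    dataset: ExpressionDataset,
    target_set,
    n_random: int = 199,
    p_threshold: float = 1e-5,
    rng: np.random.Generator | None = None,
    method: str = "pearson",
) -> tuple[float, float, np.ndarray]:
    """Empirical p for the target set's correlation-network density.

    Compares against ``n_random`` size-matched random gene sets drawn from
    the dataset's usable genes; p uses the +1 convention so it can never
    be zero. Returns (empirical p, target density, random densities).
    """
    if n_random < 1:
        raise ValueError("need at least one random set")
    rng = rng or np.random.default_rng()
    target = sorted(set(target_set))
    net = correlation_network(dataset, target, p_threshold, method)
    usable = [g for g in dataset.gene_ids if g not in dataset.constant_genes]
    size = len([g for g in target if g in set(usable)])
    d_target = network_density(net, size)
    d_random = np.empty(n_random)
    for k in range(n_random):
        pick = rng.choice(usable, size=size, replace=False)
        d_random[k] = network_density(
            correlation_network(dataset, pick, p_threshold, method), size
        )
    p = (1.0 + np.sum(d_random >= d_target)) / (n_random + 1.0)
    return float(p), float(d_target), d_random
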