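"""Causal network construction, key-driver identification, and regulator
ranking by cross-validated learners with exact Shapley attribution.

The causal graph is rooted in TF->target prior edges (DAP-seq style): TFs
are the only admissible parents, prior edges from non-TF sources are
dropped, eQTL support upgrades edge evidence, and any cycles among TFs
are resolved by removing the minimum-weight edge per cycle. Key drivers
are nodes whose downstream neighborhood (within a configurable depth) is
enriched for co-functional genes by the hypergeometric upper tail with BH
control. A zoo of regression learners predicts the co-functional module's
summary expression (first principal component) from regulator expression
under five-fold cross-validation; regulators are then ranked by mean
absolute Shapley value per model, and by top-k prevalence across models.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .celltype import bh_adjust
from .io_formats import EdgeTable, ExpressionDataset, GeneAnnotation


@dataclass
class CausalGraph:
    graph: nx.DiGraph
    tf_list: list[str]
    n_dropped_nontf: int = 0
    n_removed_cycle_edges: int = 0

    @property
    def nodes(self):
        return self.graph.nodes

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)


@dataclass
class DriverResult:
    node: str
    neighborhood_size: int
    overlap: int
    p_value: float
    p_adjusted: float = np.nan
    is_key_driver: bool = False
    tested: bool = True


@dataclass
class ModelReport:
    name: str
    fold_rmse: list[float]
    cv_rmse: float
    predictions: np.ndarray  # out-of-fold predictions
    features: list[str]
    model: object = None  # fitted on the full data (used for attribution)


@dataclass
class ShapReport:
    phi: np.ndarray  # features, one instance
    baseline: float
    prediction: float
    method: str  # exact_enumeration | closed_form_linear | sampling
    se: np.ndarray | None = None


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def build_causal_graph(
    priors: EdgeTable,
    tf_list,
    eqtl_records=None,
    variant_positions: dict[str, tuple[str, int]] | None = None,
    tf_loci: dict[str, GeneAnnotation] | None = None,
    window_bp: int = 1_000_000,
) -> CausalGraph:
    """Assemble the TF-rooted causal DAG from prior edges and eQTL support.

    Prior edges whose source is not a TF are dropped (and counted); a
    target with a significant eQTL whose peak lies within ``window_bp`` of
    the source TF's locus upgrades that edge's evidence to "both". Cycles
    are resolved by removing, per cycle, the minimum-weight edge (ties by
    lexicographic (source, target)) until the graph is acyclic.
    """
    if not priors.edges:
        raise ValueError("empty prior edge table")
    tfs = set(tf_list)
    G = nx.DiGraph()
    dropped = 0
    for e in priors.edges:
        if e.source not in tfs:
            dropped += 1
            continue
        if e.source == e.target:
            continue
        G.add_edge(e.source, e.target, weight=e.weight, sign=e.sign, evidence=e.evidence)
    for n in G.nodes:
        G.nodes[n]["is_tf"] = n in tfs

    if eqtl_records and variant_positions and tf_loci:
        supported: set[tuple[str, str]] = set()
        for r in eqtl_records:
            pos = variant_positions.get(r.variant)
            if pos is None:
                continue
            for tf, ann in tf_loci.items():
                if pos[0] != ann.chrom:
                    continue
                d = 0 if ann.start <= pos[1] < ann.end else min(
                    abs(pos[1] - ann.start), abs(pos[1] - (ann.end - 1))
                )
                if d <= window_bp:
                    supported.add((tf, r.gene))
        for u, v in G.edges:
            if (u, v) in supported:
                G.edges[u, v]["evidence"] = "both"

    removed = 0
    while not nx.is_directed_acyclic_graph(G):
        cycle = nx.find_cycle(G)
        u, v = min(cycle, key=lambda e: (G.edges[e[0], e[1]]["weight"], e[0], e[1]))[:2]
        G.remove_edge(u, v)
        removed += 1
    return CausalGraph(G, sorted(tfs), dropped, removed)


def key_driver_scan(
    cgraph: CausalGraph,
    cofunctional_set,
    universe,
    depth: int = 2,
    alpha: float = 0.05,
    min_neighborhood: int = 5,
) -> list[DriverResult]:
    """Neighborhood enrichment of co-functional genes around each node.

    The neighborhood is the set of nodes reachable within ``depth`` edges
    downstream (the node itself excluded); enrichment is the upper-tail
    hypergeometric over the universe, BH-adjusted across tested nodes.
    Leaf nodes are flagged as untested.
    """
    uni = set(universe)
    cofunc = set(cofunctional_set)
    if cofunc - uni:
        raise ValueError("co-functional set not contained in the universe")
    results: list[DriverResult] = []
    N, K = len(uni), len(cofunc)
    for node in sorted(cgraph.graph.nodes):
        reach = nx.single_source_shortest_path_length(cgraph.graph, node, cutoff=depth)
        hood = (set(reach) - {node}) & uni
        if not hood:
            results.append(DriverResult(node, 0, 0, 1.0, tested=False))
            continue
        k = len(hood & cofunc)
        p = float(stats.hypergeom.sf(k - 1, N, K, len(hood)))
        results.append(DriverResult(node, len(hood), k, min(p, 1.0)))
    tested = [r for r in results if r.tested]
    if tested:
        adj = bh_adjust([r.p_value for r in tested])
        for r, q in zip(tested, adj):
            r.p_adjusted = float(q)
            r.is_key_driver = q < alpha and r.neighborhood_size >= min_neighborhood
    return results


# ---------------------------------------------------------------------------
# module summary and learner zoo
# ---------------------------------------------------------------------------


def module_response(dataset: ExpressionDataset, module_genes) -> np.ndarray:
    """Per-sample module summary: first PC of the standardized submatrix,
    sign-anchored to correlate positively with the module mean."""
    usable = [
        g for g in module_genes if g in set(dataset.gene_ids) and g not in dataset.constant_genes
    ]
    if len(usable) < 2:
        raise ValueError(f"need >= 2 usable module genes, got {len(usable)}")
    X = dataset.values[[dataset.gene_index(g) for g in usable]]
    Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    if S[0] == 0:
        raise ValueError("rank-zero module submatrix")
    summary = Vt[0] * S[0]
    anchor = np.corrcoef(summary, Xs.mean(axis=0))[0, 1]
    return summary if anchor >= 0 else -summary


LEARNER_NAMES = (
    "linear",
    "penalized_linear",
    "nearest_neighbour",
    "tree_ensemble",
    "kernel_regressor",
    "perceptron",
)


def _learner_zoo(seed: int):
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import ElasticNet, LinearRegression
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.neural_network import MLPRegressor
    from sklearn.svm import SVR

    # fixed small grids per learner, selected by inner cross-validation
    return {
        "linear": (LinearRegression(), {}),
        "penalized_linear": (
            ElasticNet(max_iter=20_000),
            {"est__alpha": [0.01, 0.1, 1.0], "est__l1_ratio": [0.1, 1.0]},  # ridge- and lasso-type
        ),
        "nearest_neighbour": (KNeighborsRegressor(), {"est__n_neighbors": [3, 5, 10]}),
        "tree_ensemble": (RandomForestRegressor(n_estimators=100, random_state=seed), {}),
        "kernel_regressor": (SVR(kernel="rbf"), {"est__C": [1.0, 10.0]}),
        "perceptron": (
            MLPRegressor(hidden_layer_sizes=(32,), max_iter=4000, random_state=seed),
            {},
        ),
    }


def fit_learners(
    features: pd.DataFrame,
    response: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    learners: list[str] | None = None,
) -> list[ModelReport]:
    """Five-fold cross-validated RMSE for each learner, plus full-data fits.

    Features are standardized inside each fold's pipeline; fold assignment
    is deterministic from ``seed``. Grid-bearing learners pick their
    hyperparameters by inner 3-fold CV on the training split.
    """
    from sklearn.model_selection import GridSearchCV, KFold
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(features, float)
    y = np.asarray(response, float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need >= 2 features")
    if n < 5 * folds:
        raise ValueError(f"n={n} too small for {folds}-fold CV")
    names = list(features.columns) if isinstance(features, pd.DataFrame) else [
        f"f{i}" for i in range(p)
    ]
    zoo = _learner_zoo(seed)
    chosen = learners or list(LEARNER_NAMES)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    reports = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in chosen:
            est, grid = zoo[name]
            fold_rmse, preds = [], np.empty(n)
            for train, test in splits:
                pipe = Pipeline([("scale", StandardScaler()), ("est", est)])
                model = (
                    GridSearchCV(pipe, grid, cv=3, scoring="neg_root_mean_squared_error")
                    if grid
                    else pipe
                )
                model.fit(X[train], y[train])
                yhat = model.predict(X[test])
                preds[test] = yhat
                fold_rmse.append(float(np.sqrt(np.mean((yhat - y[test]) ** 2))))
            pipe = Pipeline([("scale", StandardScaler()), ("est", est)])
            full = (
                GridSearchCV(pipe, grid, cv=3, scoring="neg_root_mean_squared_error")
                if grid
                else pipe
            )
            full.fit(X, y)
            reports.append(
                ModelReport(name, fold_rmse, float(np.mean(fold_rmse)), preds, names, full)
            )
    return reports


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------

MAX_EXACT_FEATURES = 12


def _subset_weights(p: int) -> np.ndarray:
    """w[s] = s! (p - s - 1)! / p! for subset size s."""
    from math import factorial

    return np.array([factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)])


def shapley_exact(predict, instance, background, max_features: int = MAX_EXACT_FEATURES) -> ShapReport:
    """Exact Shapley values by full subset enumeration.

    The value of a coalition S is the mean prediction over the background
    sample with features outside S replaced by the background row's values
    (interventional marginalization). Efficiency (sum phi = f(x) -
    baseline) holds to numerical precision by construction.
    """
    x = np.asarray(instance, float).ravel()
    B = np.asarray(background, float)
    p = x.size
    if p > max_features:
        raise ValueError(
            f"{p} features > exact cap {max_features}; use shapley_sampling"
        )
    n_masks = 1 << p
    nb = B.shape[0]
    # rows: for every mask, the background sample with S-features from x
    big = np.tile(B, (n_masks, 1))
    for i in range(p):
        sel = np.array([(m >> i) & 1 for m in range(n_masks)], bool)
        rows = np.repeat(sel, nb)
        big[rows, i] = x[i]
    v = np.asarray(predict(big), float).reshape(n_masks, nb).mean(axis=1)

    w = _subset_weights(p)
    phi = np.zeros(p)
    for m in range(n_masks):
        s = bin(m).count("1")
        for i in range(p):
            if not (m >> i) & 1:
                phi[i] += w[s] * (v[m | (1 << i)] - v[m])
    return ShapReport(phi, float(v[0]), float(v[n_masks - 1]), "exact_enumeration")


def shapley_linear(coef, intercept, instance, background) -> ShapReport:
    """Closed form for a linear model with interventional background:
    phi_i = beta_i * (x_i - mean(background_i))."""
    coef = np.asarray(coef, float)
    x = np.asarray(instance, float).ravel()
    mu = np.asarray(background, float).mean(axis=0)
    phi = coef * (x - mu)
    baseline = float(intercept + coef @ mu)
    return ShapReport(phi, baseline, float(intercept + coef @ x), "closed_form_linear")


def shapley_sampling(
    predict, instance, background, n_permutations: int = 200, seed: int = 0
) -> ShapReport:
    """Monte-Carlo permutation Shapley with a reported standard error."""
    x = np.asarray(instance, float).ravel()
    B = np.asarray(background, float)
    p, nb = x.size, B.shape[0]
    rng = np.random.default_rng(seed)
    contrib = np.zeros((n_permutations, p))
    base = float(np.mean(predict(B)))
    for t in range(n_permutations):
        order = rng.permutation(p)
        cur = B.copy()
        v_prev = base
        for i in order:
            cur[:, i] = x[i]
            v_new = float(np.mean(predict(cur)))
            contrib[t, i] = v_new - v_prev
            v_prev = v_new
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return ShapReport(phi, base, base + float(phi.sum()), "sampling", se)


def shap_matrix(
    predict, instances: np.ndarray, background: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Per-instance Shapley values (instances x features), exact when the
    feature count allows, sampled otherwise."""
    X = np.atleast_2d(np.asarray(instances, float))
    p = X.shape[1]
    rows = []
    for i, x in enumerate(X):
        if p <= MAX_EXACT_FEATURES:
            rows.append(shapley_exact(predict, x, background).phi)
        else:
            rows.append(shapley_sampling(predict, x, background, seed=seed + i).phi)
    return np.vstack(rows)


def rank_drivers(
    phi_by_model: dict[str, np.ndarray],
    features: list[str],
    top_k: int = 20,
) -> pd.DataFrame:
    """Rank regulators by mean |phi| per model; report top-k prevalence.

    prevalence(f) = 100 * (#models with f in their top-k) / (#models),
    rounded to one decimal. Ties break by overall mean |phi|, then
    lexicographic feature name.
    """
    if not phi_by_model:
        raise ValueError("need at least one model's attributions")
    n_models = len(phi_by_model)
    mean_abs = {
        name: np.abs(np.atleast_2d(phi)).mean(axis=0) for name, phi in phi_by_model.items()
    }
    in_top = {f: 0 for f in features}
    for name, scores in mean_abs.items():
        order = sorted(range(len(features)), key=lambda i: (-scores[i], features[i]))
        for i in order[:top_k]:
            in_top[features[i]] += 1
    overall = np.mean([mean_abs[name] for name in phi_by_model], axis=0)
    df = pd.DataFrame(
        {
            "feature": features,
            "prevalence_pct": [round(100.0 * in_top[f] / n_models, 1) for f in features],
            "mean_abs_shap": overall,
        }
    )
    for name in phi_by_model:
        df[f"mean_abs_shap_{name}"] = mean_abs[name]
    return df.sort_values(
        ["prevalence_pct", "mean_abs_shap", "feature"], ascending=[False, False, True]
    ).reset_index(drop=True)
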