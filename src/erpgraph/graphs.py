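"""Weighted-graph features of coherence connectivity matrices.

A trial's coherence matrix is proportionally thresholded (top
``sparsity`` fraction of channel pairs kept), six metrics are computed
on the thresholded graph — node strength and Onnela clustering per
channel (local), spectral graph energy, global efficiency, transitivity
and characteristic path length (global) — and each metric is z-scored
against an ensemble of degree-preserving surrogate graphs that share
the original's degree sequence and edge-weight multiset.

Conventions: shortest-path edge length is 1/weight; clustering and
transitivity use weights normalized by the graph maximum; the
characteristic path length averages over connected ordered pairs only
(the disconnected-pair count is available separately; harmonic
averaging is captured by global efficiency).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import Montage

__all__ = [
    "WeightedGraph",
    "GraphMetricSet",
    "SurrogateEnsemble",
    "FeatureMatrix",
    "proportional_threshold",
    "node_strength",
    "weighted_clustering",
    "transitivity",
    "char_path_length",
    "path_length_stats",
    "global_efficiency",
    "graph_energy",
    "graph_metrics",
    "surrogate_ensemble",
    "surrogate_zscore",
    "assemble_features",
    "tensor_features",
]

GLOBAL_METRICS = ("energy", "efficiency", "transitivity", "path_length")
LOCAL_METRICS = ("strength", "clustering")


def _check_graph(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    if (W < 0).any():
        raise ValueError("weights must be non-negative")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return W


@dataclass
class WeightedGraph:
    """Symmetric non-negative weight matrix with zero diagonal."""

    weights: np.ndarray
    montage: Montage | None = None

    def __post_init__(self):
        self.weights = _check_graph(self.weights)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class GraphMetricSet:
    """The six graph metrics of one graph (raw or surrogate-z-scored)."""

    strength: np.ndarray
    clustering: np.ndarray
    energy: float
    efficiency: float
    transitivity: float
    path_length: float
    variant: str = "raw"

    def vector(self) -> np.ndarray:
        """[strength(1..C), clustering(1..C), energy, efficiency,
        transitivity, path_length] — the per-graph feature layout."""
        return np.concatenate(
            [
                self.strength,
                self.clustering,
                [self.energy, self.efficiency, self.transitivity,
                 self.path_length],
            ]
        )


@dataclass
class SurrogateEnsemble:
    """Degree- and weight-multiset-preserving surrogate graphs."""

    graphs: list
    generator: str
    sparsity: float | None
    seed: int
    fallback_weight_permutation: bool = False


@dataclass
class FeatureMatrix:
    """Trials x features with names and binary labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple
    subject_id: str = "unknown"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (trials x features)")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")


def proportional_threshold(W: np.ndarray, sparsity: float) -> np.ndarray:
    """Keep the ceil(sparsity * n_pairs) largest off-diagonal weights.

    Ties are broken by lexicographic channel-pair order, so the result
    is deterministic.  Returns a symmetric matrix with zero diagonal.
    """
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must be in (0, 1]")
    W = _check_graph(W)
    C = W.shape[0]
    iu, ju = np.triu_indices(C, k=1)
    w = W[iu, ju]
    n_keep = math.ceil(sparsity * w.size)
    if w.size and np.ptp(w) == 0:
        warnings.warn(
            "all pair weights are equal; proportional threshold is degenerate "
            "(lexicographic tie-break applied)"
        )
    # primary: weight descending; then channel-pair lexicographic order
    order = np.lexsort((ju, iu, -w))
    keep = order[:n_keep]
    out = np.zeros_like(W)
    out[iu[keep], ju[keep]] = w[keep]
    out += out.T
    return out


def node_strength(W: np.ndarray) -> np.ndarray:
    """s_i = sum_j w_ij (weighted degree)."""
    return _check_graph(W).sum(axis=1)


def _normalized_cube_diag(W: np.ndarray):
    """Per-node triangle intensity on max-normalized weights, plus degrees."""
    wmax = W.max()
    Wn = W / wmax if wmax > 0 else W
    W13 = np.cbrt(Wn)
    diag = np.einsum("ij,jk,ki->i", W13, W13, W13)
    k = (W > 0).sum(axis=1)
    return diag, k


def weighted_clustering(W: np.ndarray) -> np.ndarray:
    """Onnela per-node clustering coefficient.

    C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3)
    with w' = w / max(w); C_i = 0 for nodes of degree < 2.
    """
    W = _check_graph(W)
    diag, k = _normalized_cube_diag(W)
    out = np.zeros(W.shape[0])
    mask = k >= 2
    out[mask] = diag[mask] / (k[mask] * (k[mask] - 1))
    return out


def transitivity(W: np.ndarray) -> float:
    """Global weighted transitivity: total triangle intensity over total
    triplet count (same max-normalized weights as clustering)."""
    W = _check_graph(W)
    diag, k = _normalized_cube_diag(W)
    triplets = (k * (k - 1)).sum()
    if triplets == 0:
        return 0.0
    return float(diag.sum() / triplets)


@njit(cache=True)
def _floyd_warshall(D):
    n = D.shape[0]
    for k in range(n):
        for i in range(n):
            dik = D[i, k]
            if dik == np.inf:
                continue
            for j in range(n):
                d = dik + D[k, j]
                if d < D[i, j]:
                    D[i, j] = d
    return D


def _distances(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/w."""
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(D, 0.0)
    return _floyd_warshall(D)


def path_length_stats(W: np.ndarray) -> tuple[float, int]:
    """(characteristic path length, number of disconnected ordered pairs).

    L is the mean shortest-path distance over ordered node pairs with a
    finite distance; raises if the graph has no edges.
    """
    W = _check_graph(W)
    if not (W > 0).any():
        raise ValueError("characteristic path length undefined: graph has no edges")
    D = _distances(W)
    off = ~np.eye(W.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    n_disconnected = int(off.sum() - finite.sum())
    return float(D[finite].mean()), n_disconnected


def char_path_length(W: np.ndarray) -> float:
    return path_length_stats(W)[0]


def global_efficiency(W: np.ndarray) -> float:
    """Mean of 1/d_ij over ordered node pairs (1/inf = 0)."""
    W = _check_graph(W)
    D = _distances(W)
    off = ~np.eye(W.shape[0], dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv[off].mean()) if off.any() else 0.0


def graph_energy(W: np.ndarray) -> float:
    """Spectral graph energy: sum of |eigenvalues| of the weight matrix."""
    W = _check_graph(W)
    return float(np.abs(np.linalg.eigvalsh(W)).sum())


def graph_metrics(W: np.ndarray, variant: str = "raw") -> GraphMetricSet:
    """All six metrics of one graph."""
    W = _check_graph(W)
    L, _ = path_length_stats(W) if (W > 0).any() else (0.0, 0)
    return GraphMetricSet(
        strength=node_strength(W),
        clustering=weighted_clustering(W),
        energy=graph_energy(W),
        efficiency=global_efficiency(W),
        transitivity=transitivity(W),
        path_length=L,
        variant=variant,
    )


@njit(cache=True)
def _rewire(edges, n_nodes, n_attempts, seed):
    """Maslov-Sneppen double-edge swaps on an edge list (in place).

    Returns the number of successful swaps.
    """
    np.random.seed(seed)
    n_edges = edges.shape[0]
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    for e in range(n_edges):
        adj[edges[e, 0], edges[e, 1]] = True
        adj[edges[e, 1], edges[e, 0]] = True
    n_success = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(n_edges)
        e2 = np.random.randint(n_edges)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        n_success += 1
    return n_success


_SWAPS_PER_EDGE = 10


def _surrogate_edge_weights(W_thr, n, rng):
    """Yield (edges, weights, fell_back) for n surrogates of W_thr."""
    C = W_thr.shape[0]
    iu, ju = np.triu_indices(C, k=1)
    mask = W_thr[iu, ju] > 0
    base_edges = np.stack([iu[mask], ju[mask]], axis=1).astype(np.int64)
    wts = W_thr[iu, ju][mask]
    n_edges = base_edges.shape[0]
    if n_edges < 2:
        raise ValueError("surrogate generation requires at least 2 edges")
    out = []
    for _ in range(n):
        edges = base_edges.copy()
        seed = int(rng.integers(0, 2**31 - 1))
        n_success = _rewire(edges, C, _SWAPS_PER_EDGE * n_edges, seed)
        fell_back = n_success == 0
        if fell_back:
            edges = base_edges.copy()
        perm = rng.permutation(n_edges)
        out.append((edges, wts[perm], fell_back))
    return out


def surrogate_ensemble(
    W_thr: np.ndarray, n: int = 100, seed: int = 0
) -> SurrogateEnsemble:
    """Build ``n`` degree-preserving surrogates of a thresholded graph.

    Each surrogate rewires the topology by attempted double-edge swaps
    (10 per edge) and reassigns the original edge-weight multiset to
    the rewired edges at random.  Node count, degree sequence and
    weight multiset are preserved.  If rewiring is impossible (no swap
    succeeds, e.g. a star), the surrogate falls back to permuting the
    weights on the original topology (flagged on the ensemble).
    """
    W_thr = _check_graph(W_thr)
    rng = np.random.default_rng(seed)
    graphs = []
    any_fallback = False
    for edges, wts, fell_back in _surrogate_edge_weights(W_thr, n, rng):
        any_fallback |= fell_back
        S = np.zeros_like(W_thr)
        S[edges[:, 0], edges[:, 1]] = wts
        S += S.T
        graphs.append(S)
    if any_fallback:
        warnings.warn(
            "edge rewiring produced no successful swap; surrogate(s) fell "
            "back to weight permutation on the original topology"
        )
    return SurrogateEnsemble(
        graphs=graphs,
        generator="degree-preserving rewiring + weight permutation",
        sparsity=None,
        seed=seed,
        fallback_weight_permutation=any_fallback,
    )


def surrogate_zscore(original: GraphMetricSet, ensemble_metrics) -> GraphMetricSet:
    """z = (m_orig - mean(m_surr)) / sd(m_surr) per metric component.

    A zero surrogate standard deviation yields z = 0 (with a warning).
    """
    ensemble_metrics = list(ensemble_metrics)
    if len(ensemble_metrics) < 2:
        raise ValueError("surrogate ensemble must contain at least 2 members")
    stack = np.stack([m.vector() for m in ensemble_metrics])
    orig = original.vector()
    mu = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} metric component(s) with zero surrogate "
            "standard deviation; z set to 0"
        )
    sd[zero_sd] = np.inf
    z = (orig - mu) / sd
    C = original.strength.size
    return GraphMetricSet(
        strength=z[:C],
        clustering=z[C : 2 * C],
        energy=float(z[2 * C]),
        efficiency=float(z[2 * C + 1]),
        transitivity=float(z[2 * C + 2]),
        path_length=float(z[2 * C + 3]),
        variant="zscored",
    )


# ---------------------------------------------------------------------------
# fast batched path used by the pipeline


@njit(cache=True)
def _fw_batch(D):
    for g in range(D.shape[0]):
        _floyd_warshall(D[g])
    return D


def _metrics_batch(Ws: np.ndarray) -> np.ndarray:
    """Metric vectors (G, 2C + 4) for a stack of graphs (G, C, C)."""
    G, C, _ = Ws.shape
    strength = Ws.sum(axis=2)
    wmax = Ws.max(axis=(1, 2))
    wmax_safe = np.where(wmax > 0, wmax, 1.0)
    W13 = np.cbrt(Ws / wmax_safe[:, None, None])
    diag = np.einsum("gij,gjk,gki->gi", W13, W13, W13)
    k = (Ws > 0).sum(axis=2)
    kk = k * (k - 1)
    clustering = np.where(kk > 0, diag / np.maximum(kk, 1), 0.0)
    trans_den = kk.sum(axis=1)
    trans = np.where(trans_den > 0, diag.sum(axis=1) / np.maximum(trans_den, 1),
                     0.0)
    energy = np.abs(np.linalg.eigvalsh(Ws)).sum(axis=1)
    with np.errstate(divide="ignore"):
        D = np.where(Ws > 0, 1.0 / Ws, np.inf)
    eye = np.eye(C, dtype=bool)
    D[:, eye] = 0.0
    D = _fw_batch(D)
    off = ~eye
    finite = np.isfinite(D) & off[None, :, :]
    n_finite = finite.sum(axis=(1, 2))
    Dz = np.where(finite, D, 0.0)
    L = np.where(n_finite > 0, Dz.sum(axis=(1, 2)) / np.maximum(n_finite, 1),
                 0.0)
    with np.errstate(divide="ignore"):
        inv = np.where(finite & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    eff = inv.sum(axis=(1, 2)) / off.sum()
    return np.concatenate(
        [strength, clustering,
         np.stack([energy, eff, trans, L], axis=1)], axis=1
    )


def _zscored_vector(W: np.ndarray, sparsity: float, n_surrogates: int,
                    rng) -> np.ndarray:
    """Threshold one coherence matrix and return its z-scored metric vector."""
    W_thr = proportional_threshold(W, sparsity)
    stack = [W_thr]
    for edges, wts, _ in _surrogate_edge_weights(W_thr, n_surrogates, rng):
        S = np.zeros_like(W_thr)
        S[edges[:, 0], edges[:, 1]] = wts
        S += S.T
        stack.append(S)
    vecs = _metrics_batch(np.stack(stack))
    mu = vecs[1:].mean(axis=0)
    sd = vecs[1:].std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return (vecs[0] - mu) / sd


def _feature_names(component: str, band: str, channels) -> list:
    names = [f"{component}__{band}__strength__{ch}" for ch in channels]
    names += [f"{component}__{band}__clustering__{ch}" for ch in channels]
    names += [
        f"{component}__{band}__{m}" for m in
        ("energy", "efficiency", "transitivity", "path_length")
    ]
    return names


def assemble_features(
    zsets: dict, combo, band: str, labels, channels, subject_id: str = "unknown"
) -> FeatureMatrix:
    """Concatenate per-trial z-scored metric sets into a feature matrix.

    ``zsets`` maps (component, band) -> sequence over trials of
    GraphMetricSet.  Per trial and component the layout is
    [strength(1..C), clustering(1..C), energy, efficiency, transitivity,
    path_length], giving |combo| * (2C + 4) features with names
    ``component__band__metric__channel``.
    """
    cols, names = [], []
    for comp in combo:
        key = (comp, band)
        if key not in zsets:
            raise KeyError(f"missing metric sets for component {comp!r}, "
                           f"band {band!r}")
        cols.append(np.stack([m.vector() for m in zsets[key]]))
        names.extend(_feature_names(comp, band, channels))
    X = np.concatenate(cols, axis=1)
    return FeatureMatrix(
        X=X, y=np.asarray(labels), feature_names=tuple(names),
        subject_id=subject_id,
    )


def tensor_features(tensor, config, band: str | None = None) -> dict:
    """Z-scored feature matrices for every band of a coherence tensor.

    For each trial, component window and band: proportional threshold at
    ``config.sparsity``, ``config.n_surrogates`` surrogates, z-scoring,
    then per-band assembly over ``config.component_combo``.  Returns
    {band_name: FeatureMatrix}.  Deterministic under ``config.seed``.

    ``labels`` must be attached to the tensor meta as ``meta['labels']``
    (done by the pipeline) or passed via ``tensor.meta``.
    """
    labels = tensor.meta.get("labels")
    if labels is None:
        raise ValueError("tensor.meta['labels'] is required to build features")
    bands = [band] if band is not None else list(tensor.band_names)
    channels = tensor.montage.channel_names
    C = len(channels)
    n_trials = tensor.values.shape[0]
    out = {}
    for bname in bands:
        bi = tensor.band_names.index(bname)
        cols, names = [], []
        for comp in config.component_combo:
            ci = tensor.component_names.index(comp)
            # independent child stream per (component, band) block
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, ci, bi])
            )
            block = np.empty((n_trials, 2 * C + 4))
            for tr in range(n_trials):
                block[tr] = _zscored_vector(
                    tensor.values[tr, ci, bi], config.sparsity,
                    config.n_surrogates, rng,
                )
            cols.append(block)
            names.extend(_feature_names(comp, bname, channels))
        out[bname] = FeatureMatrix(
            X=np.concatenate(cols, axis=1),
            y=np.asarray(labels),
            feature_names=tuple(names),
            subject_id=tensor.meta.get("subject_id", "unknown"),
        )
    return out
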