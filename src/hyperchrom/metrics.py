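"""Spectral quantification and comparison of genomic hypergraphs.

Given an n x m incidence matrix H with node-degree diagonal D and
hyperedge-order diagonal E, the hypergraph Laplacian is

    L = D - H E^-1 H^T,

a symmetric positive semidefinite matrix with zero row sums.  Hypergraph
entropy is the Shannon entropy of the trace-normalized spectrum of L
(von Neumann style): S = -sum_i lam_i_bar * ln(lam_i_bar) with
lam_i_bar = lam_i / sum(lam), using the convention 0 ln 0 = 0.

For comparing two hypergraphs on a shared node universe we form, per
hypergraph, the adjacency A = H E^-1 H^T (diagonal included), the
normalized Laplacian Lt = I - D^-1/2 A D^-1/2, and the fast-belief-
propagation affinity S = (I + eps^2 D^a - eps A)^-1, and measure

* Hamming distance:   (1/n^2) * sum |A1 - A2|              (local)
* spectral distance:  (1/n)   * p-norm of sorted eigenvalue
                      differences of the two Lt              (global)
* DeltaCon distance:  (1/n^2) * Matusita difference of the
                      two affinity matrices                  (both)

Significance of an observed distance is assessed by a permutation test
against randomly generated hypergraphs similar to the first (same
hyperedge-order multiset, node memberships resampled proportional to the
template's node degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypergraph import GenomicBin, Hypergraph, build_incidence

_PSD_TOL = 1e-9


@dataclass
class SpectralBundle:
    """Laplacian of one hypergraph with its (normalized) spectrum."""

    D: np.ndarray              # node degrees (diagonal of D)
    E: np.ndarray              # hyperedge orders (diagonal of E)
    L: np.ndarray              # hypergraph Laplacian, n x n
    eigenvalues: np.ndarray    # ascending, clipped at 0
    normalized_eigenvalues: np.ndarray  # lam / sum(lam); zeros if sum(lam)=0


@dataclass
class ComparisonBundle:
    """Adjacency, normalized Laplacian and affinity matrix of one hypergraph."""

    A: np.ndarray              # H E^-1 H^T, diagonal included
    L_norm: np.ndarray         # I - D^-1/2 A D^-1/2, zero-degree rows zeroed
    S: np.ndarray              # (I + eps^2 D^a - eps A)^-1
    degrees: np.ndarray        # node degrees (row sums of H)
    epsilon: float

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass
class DistanceResult:
    measure: str
    value: float
    p_value: float | None = None
    n_trials: int | None = None
    background: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Laplacian and entropy
# ---------------------------------------------------------------------------

def hypergraph_laplacian(H: np.ndarray) -> SpectralBundle:
    """Compute L = D - H E^-1 H^T and its ascending spectrum.

    D holds node degrees (row sums of H) and E hyperedge orders (column
    sums).  Eigenvalues come from a symmetric eigensolver and are clipped
    at zero (L is positive semidefinite up to round-off).
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1 or H.shape[1] < 1:
        raise ValueError("incidence matrix must be n x m with n, m >= 1")
    orders = H.sum(axis=0)
    if np.any(orders == 0):
        raise ValueError("incidence matrix has an empty hyperedge column")
    degrees = H.sum(axis=1)
    L = np.diag(degrees) - (H / orders) @ H.T
    L = (L + L.T) / 2  # enforce exact symmetry against round-off
    lam = np.linalg.eigvalsh(L)
    if lam.min() < -_PSD_TOL:
        raise ValueError(f"Laplacian not PSD within tolerance (min eig {lam.min():g})")
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    lam_bar = lam / total if total > 0 else np.zeros_like(lam)
    return SpectralBundle(degrees, orders, L, lam, lam_bar)


def hypergraph_entropy(bundle: SpectralBundle) -> float:
    """Shannon entropy of the trace-normalized Laplacian spectrum (0 ln 0 = 0)."""
    total = bundle.eigenvalues.sum()
    if total <= 0:
        raise ValueError("all-zero Laplacian spectrum: entropy undefined")
    lam_bar = bundle.normalized_eigenvalues
    nz = lam_bar[lam_bar > 0]
    return float(-(nz * np.log(nz)).sum())


def entropy_of(hypergraph: Hypergraph, weighted: bool | None = None) -> float:
    """Convenience: entropy of a hypergraph's incidence matrix."""
    H = build_incidence(hypergraph, weighted=weighted)
    return hypergraph_entropy(hypergraph_laplacian(H))


def clique_expansion_laplacian(H: np.ndarray) -> np.ndarray:
    """Ordinary graph Laplacian of the pairwise (clique) expansion.

    Each hyperedge is replaced by its unit-weight pairwise edges (distinct
    pairs only); used as an independent cross-check against the hypergraph
    Laplacian, not in the analysis itself.
    """
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    adj = np.zeros((n, n))
    for j in range(H.shape[1]):
        members = np.flatnonzero(H[:, j])
        for a_i, a in enumerate(members):
            for b in members[a_i + 1 :]:
                adj[a, b] = 1.0
                adj[b, a] = 1.0
    return np.diag(adj.sum(axis=1)) - adj


# ---------------------------------------------------------------------------
# comparison matrices and distances
# ---------------------------------------------------------------------------

def comparison_bundle(H: np.ndarray, epsilon: float = 1e-3) -> ComparisonBundle:
    """Adjacency, normalized Laplacian and affinity matrix for one hypergraph.

    Zero-degree nodes (loci absent from every contact of this sample but
    present in the shared node universe) get zero rows/columns in the
    normalized Laplacian rather than NaNs, so cross-sample comparisons keep
    a common n.
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("incidence matrix must be n x m")
    n = H.shape[0]
    if H.shape[1] == 0:
        A = np.zeros((n, n))
        degrees = np.zeros(n)
    else:
        orders = H.sum(axis=0)
        if np.any(orders == 0):
            raise ValueError("incidence matrix has an empty hyperedge column")
        A = (H / orders) @ H.T
        A = (A + A.T) / 2
        degrees = H.sum(axis=1)
    inv_sqrt = np.zeros(n)
    pos = degrees > 0
    inv_sqrt[pos] = degrees[pos] ** -0.5
    L_norm = -(inv_sqrt[:, None] * A * inv_sqrt[None, :])
    L_norm[np.diag_indices(n)] = 0.0
    L_norm[pos, pos] = 1.0 - (A[pos, pos] / degrees[pos])
    L_norm = (L_norm + L_norm.T) / 2
    D_a = A.sum(axis=1)
    M = np.eye(n) + epsilon**2 * np.diag(D_a) - epsilon * A
    try:
        S = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        raise ValueError("affinity system singular; try a smaller epsilon") from None
    S = (S + S.T) / 2
    return ComparisonBundle(A, L_norm, S, degrees, epsilon)


def _check_same_n(b1: ComparisonBundle, b2: ComparisonBundle) -> int:
    if b1.n != b2.n:
        raise ValueError(
            f"hypergraphs must share a node universe (n={b1.n} vs n={b2.n})"
        )
    return b1.n


def hamming_distance(b1: ComparisonBundle, b2: ComparisonBundle) -> DistanceResult:
    """Mean absolute difference of the two adjacency matrices (local similarity)."""
    n = _check_same_n(b1, b2)
    value = float(np.abs(b1.A - b2.A).sum() / n**2)
    return DistanceResult("hamming", value)


def spectral_distance(
    b1: ComparisonBundle, b2: ComparisonBundle, p: float = 2
) -> DistanceResult:
    """p-norm of the sorted eigenvalue difference of the two normalized Laplacians."""
    if p < 1:
        raise ValueError("p must be >= 1")
    n = _check_same_n(b1, b2)
    lam1 = np.sort(np.linalg.eigvalsh(b1.L_norm))
    lam2 = np.sort(np.linalg.eigvalsh(b2.L_norm))
    value = float((np.abs(lam1 - lam2) ** p).sum() ** (1 / p) / n)
    return DistanceResult("spectral", value)


def deltacon_distance(b1: ComparisonBundle, b2: ComparisonBundle) -> DistanceResult:
    """Matusita difference of the two node-affinity matrices (local + global)."""
    n = _check_same_n(b1, b2)
    for b in (b1, b2):
        if b.S.min() < -_PSD_TOL:
            raise ValueError(
                "negative affinity entries; decrease epsilon "
                f"(min entry {b.S.min():g} at epsilon={b.epsilon:g})"
            )
    s1 = np.sqrt(np.clip(b1.S, 0.0, None))
    s2 = np.sqrt(np.clip(b2.S, 0.0, None))
    value = float(np.sqrt(((s1 - s2) ** 2).sum()) / n**2)
    return DistanceResult("deltacon", value)


_MEASURES = {
    "hamming": hamming_distance,
    "spectral": spectral_distance,
    "deltacon": deltacon_distance,
}


def hypergraph_distance(
    g1: Hypergraph,
    g2: Hypergraph,
    measure: str = "hamming",
    epsilon: float = 1e-3,
    p: float = 2,
    weighted: bool | None = None,
) -> DistanceResult:
    """Distance between two hypergraphs sharing a node universe."""
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(_MEASURES)}")
    if g1.nodes != g2.nodes:
        raise ValueError("hypergraphs must be built on the same node universe")
    b1 = comparison_bundle(build_incidence(g1, weighted), epsilon)
    b2 = comparison_bundle(build_incidence(g2, weighted), epsilon)
    if measure == "spectral":
        return spectral_distance(b1, b2, p)
    return _MEASURES[measure](b1, b2)


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------

def random_similar_hypergraph(
    template: Hypergraph, seed: int | np.random.Generator = 0
) -> Hypergraph:
    """Random hypergraph with the template's hyperedge orders and similar degrees.

    Every hyperedge keeps its order and weight exactly; its node members are
    redrawn without replacement with probability proportional to the
    template's weighted node degrees (a bipartite configuration-style null),
    so expected node degrees match the template.
    """
    if template.m < 1:
        raise ValueError("template must have at least one hyperedge")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    deg = np.zeros(template.n)
    for edge, w in zip(template.hyperedges, template.weights):
        deg[list(edge)] += w
    candidates = np.flatnonzero(deg > 0)
    probs = deg[candidates] / deg[candidates].sum()
    edges = []
    for edge in template.hyperedges:
        k = len(edge)
        if k > template.n:
            raise ValueError("hyperedge order exceeds node count")
        if k > len(candidates):
            raise ValueError("hyperedge order exceeds number of active nodes")
        members = rng.choice(candidates, size=k, replace=False, p=probs)
        edges.append(set(int(i) for i in members))
    return Hypergraph(template.nodes, edges, list(template.weights), template.resolution)


def permutation_test_distance(
    g1: Hypergraph,
    g2: Hypergraph,
    measure: str = "hamming",
    n_trials: int = 1000,
    seed: int = 0,
    epsilon: float = 1e-3,
    p: float = 2,
    weighted: bool | None = None,
) -> DistanceResult:
    """Observed distance plus its permutation p-value.

    The null background is the set of distances from ``g1`` to ``n_trials``
    randomly generated hypergraphs similar to ``g1``; the p-value is the
    proportion of background distances >= the observed one (>= so that ties
    count toward the null; a reported 0 means no background draw reached the
    observed distance).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    observed = hypergraph_distance(g1, g2, measure, epsilon, p, weighted)
    rng = np.random.default_rng(seed)
    b1 = comparison_bundle(build_incidence(g1, weighted), epsilon)
    background = np.empty(n_trials)
    for t in range(n_trials):
        r = random_similar_hypergraph(g1, rng)
        br = comparison_bundle(build_incidence(r, weighted), epsilon)
        if measure == "spectral":
            background[t] = spectral_distance(b1, br, p).value
        else:
            background[t] = _MEASURES[measure](b1, br).value
    alpha = float(np.mean(background >= observed.value))
    return DistanceResult(measure, observed.value, alpha, n_trials, background)
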