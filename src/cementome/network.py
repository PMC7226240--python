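"""Compositional co-occurrence networks: SparCC correlations and centrality.

Label-free abundances are compositional — only relative information
survives normalization — so ordinary Pearson correlations between
components are spurious.  SparCC (Friedman & Alm 2012) instead works from
the variation matrix t_ij = var(log(x_i / x_j)), which is invariant to
per-run scaling.  Under the decomposition

    t_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j

and the sparsity assumption that most basis correlations are ~0, the basis
variances w_i^2 solve a linear system in the row sums of T; correlations
follow as rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j), clipped to
[-1, 1].  Strongly correlated pairs violate the sparsity assumption, so
the pair with the largest |rho| above an exclusion threshold is removed
from the system and the variances re-solved, iterating until no pair
exceeds the threshold.

The network keeps edges with |rho| >= an edge threshold, and ranks
proteins by betweenness centrality (BNC) on shortest paths under the
distance transform d = 1 - |rho| (sign retained as an edge attribute).

The input here is continuous SWATH intensity, not sequencing counts, so
SparCC's Dirichlet resampling step is omitted; a pseudocount guards zeros.
Optional bootstrap over runs yields two-sided p-values per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import QuantMatrix, ValidationError

__all__ = [
    "SparccParams",
    "SparccResult",
    "variation_matrix",
    "sparcc_correlations",
    "sparcc",
    "bootstrap_pvalues",
    "build_network",
    "betweenness_centrality",
    "centrality_table",
]


@dataclass
class SparccParams:
    pseudocount: float = 1.0  # added to every abundance before logs
    exclusion_threshold: float = 0.1  # |rho| above which a pair is excluded
    max_exclusion_iters: int = 10
    n_bootstrap: int = 0  # 0 disables p-values
    seed: int = 0

    def validate(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if not 0.0 < self.exclusion_threshold < 1.0:
            raise ValidationError("exclusion_threshold must be in (0, 1)")


def variation_matrix(matrix: QuantMatrix | pd.DataFrame,
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """T with t_ij = sample variance over runs of log((x_i+pc)/(x_j+pc)).

    Symmetric, zero diagonal, non-negative; invariant to multiplying any
    run by a positive constant (when the pseudocount is negligible or the
    data are already closed).
    """
    values = matrix.values if isinstance(matrix, QuantMatrix) else matrix
    if values.shape[1] < 3:
        raise ValidationError("variation matrix needs at least 3 runs")
    if (values.to_numpy() < 0).any():
        raise ValidationError("abundances must be >= 0")
    logx = np.log(values.to_numpy(dtype=float) + pseudocount)  # n x runs
    # var(log xi - log xj) = var_i + var_j - 2 cov_ij
    cov = np.cov(logx, ddof=1)
    cov = np.atleast_2d(cov)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = np.clip(t, 0.0, None)
    np.fill_diagonal(t, 0.0)
    return pd.DataFrame(t, index=values.index, columns=values.index)


@dataclass
class SparccResult:
    rho: pd.DataFrame
    basis_variance: pd.Series
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)
    unreliable: list[str] = field(default_factory=list)  # components with w^2 <= 0
    p_values: pd.DataFrame | None = None


def _solve_basis(t: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    """Solve the row-sum linear system M w^2 = t-row-sums.

    With no exclusions M = J + (D-2) I, whose solution coincides with the
    least-squares fit of t_ij ~ w_i^2 + w_j^2 over all pairs.  Excluding a
    pair removes its equation: both t_ij contributions and the coupling
    entries of M.
    """
    d = t.shape[0]
    m = np.ones((d, d)) + (d - 2) * np.eye(d)
    t_eff = t.copy()
    for i, j in excluded:
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        t_eff[i, j] = t_eff[j, i] = 0.0
    rowsum = t_eff.sum(axis=1)
    return np.linalg.solve(m, rowsum)


def _rho_from(t: np.ndarray, w2: np.ndarray) -> np.ndarray:
    w2_safe = np.clip(w2, 1e-12, None)
    w = np.sqrt(w2_safe)
    rho = (w2_safe[:, None] + w2_safe[None, :] - t) / (2.0 * np.outer(w, w))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc_correlations(t_frame: pd.DataFrame,
                        params: SparccParams | None = None) -> SparccResult:
    """Estimate basis correlations from a variation matrix."""
    params = params or SparccParams()
    params.validate()
    d = t_frame.shape[0]
    if d < 4:
        raise ValidationError("SparCC needs at least 4 components")
    names = list(t_frame.index)
    t = t_frame.to_numpy(dtype=float)

    excluded: set[tuple[int, int]] = set()
    w2 = _solve_basis(t, excluded)
    rho = _rho_from(t, w2)
    for _ in range(params.max_exclusion_iters):
        cand = np.abs(rho).copy()
        np.fill_diagonal(cand, 0.0)
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
        i, j = np.unravel_index(int(np.argmax(cand)), cand.shape)
        if cand[i, j] <= params.exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        w2 = _solve_basis(t, excluded)
        rho = _rho_from(t, w2)

    unreliable = [names[i] for i in range(d) if w2[i] <= 0]
    rho_frame = pd.DataFrame(rho, index=names, columns=names)
    if unreliable:
        rho_frame.loc[unreliable, :] = np.nan
        rho_frame.loc[:, unreliable] = np.nan
        for u in unreliable:
            rho_frame.loc[u, u] = 1.0
    return SparccResult(
        rho=rho_frame,
        basis_variance=pd.Series(w2, index=names),
        excluded_pairs=[(names[i], names[j]) for i, j in sorted(excluded)],
        unreliable=unreliable,
    )


def sparcc(matrix: QuantMatrix | pd.DataFrame,
           params: SparccParams | None = None) -> SparccResult:
    """variation_matrix + sparcc_correlations (+ optional bootstrap p-values)."""
    params = params or SparccParams()
    result = sparcc_correlations(variation_matrix(matrix, params.pseudocount), params)
    if params.n_bootstrap > 0:
        result.p_values = bootstrap_pvalues(matrix, params, result.rho)
    return result


def bootstrap_pvalues(matrix: QuantMatrix | pd.DataFrame, params: SparccParams,
                      observed_rho: pd.DataFrame) -> pd.DataFrame:
    """Two-sided p-values from independently permuting each component's runs,
    which destroys co-occurrence while preserving marginals."""
    values = matrix.values if isinstance(matrix, QuantMatrix) else matrix
    rng = np.random.default_rng(params.seed)
    arr = values.to_numpy(dtype=float)
    n, r = arr.shape
    exceed = np.zeros((n, n))
    for _ in range(params.n_bootstrap):
        shuffled = np.array([arr[i, rng.permutation(r)] for i in range(n)])
        null_frame = pd.DataFrame(shuffled, index=values.index, columns=values.columns)
        null = sparcc_correlations(
            variation_matrix(null_frame, params.pseudocount),
            SparccParams(pseudocount=params.pseudocount,
                         exclusion_threshold=params.exclusion_threshold,
                         max_exclusion_iters=params.max_exclusion_iters),
        )
        exceed += (np.abs(null.rho.to_numpy()) >= np.abs(observed_rho.to_numpy()))
    p = (exceed + 1.0) / (params.n_bootstrap + 1.0)
    np.fill_diagonal(p, 0.0)
    return pd.DataFrame(p, index=values.index, columns=values.index)


def build_network(rho: pd.DataFrame, edge_threshold: float = 0.6,
                  categories: dict[str, str] | None = None) -> nx.Graph:
    """Graph with one node per protein; edge iff |rho_ij| >= threshold.

    Edge attributes: ``weight`` (signed SparCC correlation) and
    ``distance`` = 1 - |rho| for shortest-path computations.  Node
    attributes: ``bnc`` (unnormalized betweenness centrality) and, when
    provided, the profile ``category``.
    """
    if not 0.0 <= edge_threshold <= 1.0:
        raise ValidationError("edge_threshold must be in [0, 1]")
    g = nx.Graph()
    names = list(rho.index)
    g.add_nodes_from(names)
    arr = rho.to_numpy(dtype=float)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = arr[i, j]
            if r == r and abs(r) >= edge_threshold:
                g.add_edge(names[i], names[j], weight=float(r),
                           distance=float(1.0 - abs(r)))
    bnc = betweenness_centrality(g)
    nx.set_node_attributes(g, bnc, "bnc")
    if categories:
        nx.set_node_attributes(
            g, {n: categories.get(n, "unknown") for n in g.nodes}, "category")
    return g


def betweenness_centrality(graph: nx.Graph, normalized: bool = False) -> dict:
    """Betweenness centrality on 1-|rho| shortest-path distances.

    Unnormalized by default: the score is the number of (unordered) node
    pairs whose shortest paths pass through the node, counting fractional
    credit when shortest paths tie.  Isolated nodes score 0.
    """
    if graph.number_of_nodes() == 0:
        return {}
    weight = "distance" if any("distance" in d for _, _, d in graph.edges(data=True)) \
        else None
    return nx.betweenness_centrality(graph, normalized=normalized, weight=weight)


def centrality_table(graph: nx.Graph) -> pd.DataFrame:
    """Nodes sorted by descending BNC (ties broken by accession)."""
    rows = [{"protein": n, "bnc": d.get("bnc", 0.0),
             "degree": graph.degree(n),
             "category": d.get("category", "")}
            for n, d in graph.nodes(data=True)]
    frame = pd.DataFrame(rows, columns=["protein", "bnc", "degree", "category"])
    return frame.sort_values(["bnc", "protein"],
                             ascending=[False, True]).reset_index(drop=True)
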