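"""Weighted bipartite drug–sample network and its one-mode projections.

The screen's drug × sample potency table becomes, after list-wise deletion of
missing cells and min–max normalisation of an inverse-potency transform, the
incidence matrix of a weighted bipartite graph.  Multiplying the incidence
matrix by its transpose projects that graph onto either node set: the drug
similarity network (DSN) and the sample/patient similarity network (PSN),
whose edge weights sum, over the opposite side, the products of shared
bipartite weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "IncidenceMatrix",
    "SimilarityNetwork",
    "NetworkStats",
    "complete_case_submatrix",
    "minmax_normalize",
    "potency_weight",
    "incidence_from_medians",
    "build_bipartite",
    "project",
    "node_strength",
    "network_stats",
]

DRUG_PREFIX = "drug:"
SAMPLE_PREFIX = "sample:"


@dataclass
class IncidenceMatrix:
    """Complete drug × sample weight matrix with weights in [0, 1]."""

    drug_ids: list[str]
    sample_ids: list[str]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.drug_ids), len(self.sample_ids)):
            raise ValueError("weights shape does not match id lists")
        if np.any(~np.isfinite(self.weights)):
            raise ValueError("incidence matrix must be complete (no NaN)")
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("incidence weights must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.drug_ids, columns=self.sample_ids)


@dataclass
class SimilarityNetwork:
    """One-mode projection: undirected, no self-loops, product-sum weights."""

    side: str  # "drugs" or "samples"
    graph: nx.Graph
    node_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.node_order:
            self.node_order = sorted(self.graph.nodes)

    @property
    def nodes(self) -> list[str]:
        return list(self.node_order)

    def strengths(self) -> dict[str, float]:
        return node_strength(self)

    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.node_order, weight="weight")


@dataclass(frozen=True)
class NetworkStats:
    heterogeneity: float
    degree_centralization: float
    mean_weighted_clustering: float


def complete_case_submatrix(table: pd.DataFrame):
    """List-wise deletion to the largest-greedy complete submatrix.

    Iteratively removes the row or column with the highest missing fraction
    (ties broken towards the larger axis, then lexicographic id) until no
    missing cells remain.  Returns the complete sub-table plus a removal log
    of (axis, id, missing_fraction) tuples.
    """
    df = table.copy()
    removals: list[tuple[str, str, float]] = []
    while df.size and df.isna().to_numpy().any():
        row_miss = df.isna().mean(axis=1)
        col_miss = df.isna().mean(axis=0)
        worst_row = row_miss.sort_index().idxmax()  # idxmax takes first = lexicographic
        worst_col = col_miss.sort_index().idxmax()
        rm, cm = row_miss[worst_row], col_miss[worst_col]
        if rm > cm:
            axis, victim, frac = "row", worst_row, rm
        elif cm > rm:
            axis, victim, frac = "col", worst_col, cm
        else:  # tie: larger axis first, then lexicographic
            if df.shape[0] > df.shape[1]:
                axis, victim, frac = "row", worst_row, rm
            elif df.shape[1] > df.shape[0]:
                axis, victim, frac = "col", worst_col, cm
            else:
                if str(worst_row) <= str(worst_col):
                    axis, victim, frac = "row", worst_row, rm
                else:
                    axis, victim, frac = "col", worst_col, cm
        df = df.drop(index=victim) if axis == "row" else df.drop(columns=victim)
        removals.append((axis, str(victim), float(frac)))
    if df.size == 0:
        raise ValueError("no complete submatrix: all rows/columns removed")
    return df, removals


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """(v − min)/(max − min); an all-equal vector maps to 0.5 with a warning."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("min–max normalisation needs at least 2 values")
    if np.any(~np.isfinite(v)):
        raise ValueError("non-finite values")
    span = v.max() - v.min()
    if span == 0:
        warnings.warn("degenerate span in min–max normalisation; returning 0.5")
        return np.full_like(v, 0.5)
    return (v - v.min()) / span


def potency_weight(medians: np.ndarray, transform: str = "reciprocal") -> np.ndarray:
    """Edge weights from median viabilities, higher weight = more potent.

    reciprocal: min–max of 1/median (medians clipped at 1e-6);
    complement: 1 − min–max of the median.  Both are monotone decreasing in
    the median, so drug/sample rankings agree between the two.
    """
    m = np.asarray(medians, dtype=float)
    if np.any(m < 0):
        raise ValueError("negative median viability")
    if transform == "reciprocal":
        return minmax_normalize(1.0 / np.clip(m, 1e-6, None))
    if transform == "complement":
        return 1.0 - minmax_normalize(m)
    raise ValueError(f"unknown transform: {transform!r}")


def incidence_from_medians(medians: pd.DataFrame, transform: str = "reciprocal") -> IncidenceMatrix:
    """Complete-case deletion + potency weighting of a drug × sample median table."""
    complete, _ = complete_case_submatrix(medians)
    flat = complete.to_numpy().ravel()
    weights = potency_weight(flat, transform=transform).reshape(complete.shape)
    return IncidenceMatrix(
        drug_ids=[str(i) for i in complete.index],
        sample_ids=[str(c) for c in complete.columns],
        weights=weights,
    )


def build_bipartite(incidence: IncidenceMatrix) -> nx.Graph:
    """Weighted bipartite graph with one edge per incidence cell.

    Drug and sample ids are namespaced ("drug:", "sample:") so a shared raw id
    cannot collapse the two sides.
    """
    if set(incidence.drug_ids) & set(incidence.sample_ids):
        overlap = set(incidence.drug_ids) & set(incidence.sample_ids)
        # namespacing keeps them distinct, but flag the collision loudly
        warnings.warn(f"ids appear on both sides (namespaced): {sorted(overlap)[:5]}")
    g = nx.Graph()
    dnodes = [DRUG_PREFIX + d for d in incidence.drug_ids]
    snodes = [SAMPLE_PREFIX + s for s in incidence.sample_ids]
    if len(set(dnodes)) != len(dnodes) or len(set(snodes)) != len(snodes):
        raise ValueError("duplicate ids within a side")
    g.add_nodes_from(dnodes, bipartite="drugs")
    g.add_nodes_from(snodes, bipartite="samples")
    for i, d in enumerate(dnodes):
        for j, s in enumerate(snodes):
            g.add_edge(d, s, weight=float(incidence.weights[i, j]))
    return g


def project(source, side: str = "drugs") -> SimilarityNetwork:
    """One-mode projection with product-sum edge weights.

    ``source`` may be an :class:`IncidenceMatrix` or a bipartite graph built
    by :func:`build_bipartite`.  Edge weight(i, j) = Σ_k w_ik · w_jk over the
    opposite side — the off-diagonal of W Wᵀ (drugs) or Wᵀ W (samples).
    Zero-weight pairs are omitted from the edge list.
    """
    if side not in ("drugs", "samples"):
        raise ValueError(f"side must be 'drugs' or 'samples', got {side!r}")
    if isinstance(source, nx.Graph):
        incidence = _incidence_from_bipartite(source)
    else:
        incidence = source
    W = incidence.weights
    if side == "drugs":
        ids = list(incidence.drug_ids)
        P = W @ W.T
    else:
        ids = list(incidence.sample_ids)
        P = W.T @ W
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    wvals = P[iu, ju]
    mask = wvals > 0
    g.add_weighted_edges_from(
        (ids[i], ids[j], float(w)) for i, j, w in zip(iu[mask], ju[mask], wvals[mask])
    )
    return SimilarityNetwork(side=side, graph=g, node_order=ids)


def _incidence_from_bipartite(g: nx.Graph) -> IncidenceMatrix:
    drugs = sorted(n[len(DRUG_PREFIX):] for n, d in g.nodes(data=True) if d.get("bipartite") == "drugs")
    samples = sorted(n[len(SAMPLE_PREFIX):] for n, d in g.nodes(data=True) if d.get("bipartite") == "samples")
    W = np.zeros((len(drugs), len(samples)))
    didx = {d: i for i, d in enumerate(drugs)}
    sidx = {s: j for j, s in enumerate(samples)}
    for u, v, w in g.edges(data="weight"):
        if u.startswith(SAMPLE_PREFIX):
            u, v = v, u
        W[didx[u[len(DRUG_PREFIX):]], sidx[v[len(SAMPLE_PREFIX):]]] = w
    return IncidenceMatrix(drug_ids=drugs, sample_ids=samples, weights=W)


def node_strength(net: SimilarityNetwork) -> dict[str, float]:
    """Sum of incident edge weights per node; isolated nodes get 0."""
    deg = dict(net.graph.degree(weight="weight"))
    return {n: float(deg.get(n, 0.0)) for n in net.node_order}


def network_stats(net: SimilarityNetwork) -> NetworkStats:
    """Degree heterogeneity, Freeman centralisation and Barrat clustering.

    heterogeneity = sd(degree)/mean(degree); centralisation is Freeman's
    degree centralisation Σ(d_max − d_i) / ((n−1)(n−2)); clustering is the
    Barrat weighted local coefficient averaged over nodes (nodes of degree
    < 2 contribute 0).
    """
    g = net.graph
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("network statistics need at least 3 nodes")
    degrees = np.array([g.degree(v) for v in g.nodes])
    mean_deg = degrees.mean()
    het = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0
    central = float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
    return NetworkStats(
        heterogeneity=het,
        degree_centralization=central,
        mean_weighted_clustering=_barrat_mean_clustering(g),
    )


def _barrat_mean_clustering(g: nx.Graph) -> float:
    # c_i = 1/(s_i (k_i - 1)) Σ_{j,h} (w_ij + w_ih)/2 · a_ij a_ih a_jh
    vals = []
    for i in g.nodes:
        nbrs = list(g.neighbors(i))
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        s = sum(g[i][j].get("weight", 1.0) for j in nbrs)
        acc = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nbrs[a], nbrs[b]
                if g.has_edge(j, h):
                    acc += (g[i][j].get("weight", 1.0) + g[i][h].get("weight", 1.0)) / 2.0
        vals.append(acc / (s * (k - 1)) * 2.0 / 1.0 if s > 0 else 0.0)
    return float(np.mean(vals))
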