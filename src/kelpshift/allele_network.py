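"""Site-level shared-allele network analysis.

Sites are nodes; edge weights are the relative number of shared alleles
(Jaccard similarity of allele sets per locus, averaged over loci typed in
both sites). The analysis chain mirrors a percolation approach:

1. :func:`shared_allele_similarity` — dense similarity matrix;
2. :func:`percolate` — scan edge-weight thresholds, keep edges >= t, and
   retain the network whose leading-eigenvector partition maximises
   weighted modularity Q (ties resolved toward the lower threshold);
3. :func:`leading_eigenvector` — recursive spectral bisection of the
   modularity matrix with single-node fine-tuning;
4. :func:`modularity_permutation_test` — label-shuffle null for Q;
5. :func:`centrality_hubs` — weighted eigenvector centrality (power
   iteration per connected component, global max-normalisation) and the
   strict >95th-percentile hub set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .popgen import AlleleFrequencyTable

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# Similarity
# --------------------------------------------------------------------------- #
def shared_allele_similarity(
    freqs: AlleleFrequencyTable, weighted: bool = False
) -> pd.DataFrame:
    """Pairwise shared-allele similarity between sites.

    Per locus typed in both sites, similarity is the Jaccard index of the
    allele *sets* (or, with ``weighted=True``, the frequency-weighted
    Jaccard sum(min p)/sum(max p)); the site-pair similarity is the mean
    over those loci. Pairs with no commonly typed locus get NaN (warned).
    """
    sites = freqs.sites
    if len(sites) < 2:
        raise ValueError("similarity needs at least 2 sites")
    per_site: Dict[str, Dict[str, pd.Series]] = {
        s: {l: freqs.freqs(s, l) for l in freqs.typed_loci(s)} for s in sites
    }
    sim = pd.DataFrame(np.eye(len(sites)), index=sites, columns=sites)
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            vals = []
            for locus in freqs.loci:
                fa = per_site[a].get(locus)
                fb = per_site[b].get(locus)
                if fa is None or fb is None:
                    continue
                union = fa.index.union(fb.index)
                pa = fa.reindex(union, fill_value=0.0).to_numpy()
                pb = fb.reindex(union, fill_value=0.0).to_numpy()
                if weighted:
                    vals.append(np.minimum(pa, pb).sum() / np.maximum(pa, pb).sum())
                else:
                    both = np.sum((pa > 0) & (pb > 0))
                    either = np.sum((pa > 0) | (pb > 0))
                    vals.append(both / either)
            if not vals:
                warnings.warn(f"sites {a!r}/{b!r} share no typed locus; edge undefined", stacklevel=2)
                val = np.nan
            else:
                val = float(np.mean(vals))
            sim.loc[a, b] = sim.loc[b, a] = val
    return sim


# --------------------------------------------------------------------------- #
# Modularity and leading-eigenvector communities
# --------------------------------------------------------------------------- #
def modularity_q(adj: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a hard partition (zero diagonal adj)."""
    adj = np.asarray(adj, dtype=float)
    two_m = adj.sum()
    if two_m == 0:
        return 0.0
    k = adj.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += adj[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return float(q)


def _fine_tune(s: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Single-node sign flips while s^T B s improves (Newman fine-tuning)."""
    s = s.copy()
    improved = True
    guard = 0
    while improved and guard < 100:
        improved = False
        guard += 1
        bs = b @ s
        for i in range(len(s)):
            # flipping s_i changes s^T B s by -4 s_i (bs_i - B_ii s_i)
            delta = -4.0 * s[i] * (bs[i] - b[i, i] * s[i])
            if delta > 1e-12:
                s[i] = -s[i]
                bs = b @ s
                improved = True
    return s


def leading_eigenvector(adj: np.ndarray, tol: float = 1e-10) -> Tuple[np.ndarray, float]:
    """Communities by recursive spectral bisection of the modularity matrix.

    Splits a group only while the leading eigenvalue of its generalised
    modularity matrix is positive and the split strictly increases Q.
    Returns (labels, Q).
    """
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    adj = adj.copy()
    np.fill_diagonal(adj, 0.0)
    two_m = adj.sum()
    if two_m == 0:
        return np.zeros(n, dtype=int), 0.0
    k = adj.sum(axis=1)
    b_full = adj - np.outer(k, k) / two_m

    labels = np.zeros(n, dtype=int)
    next_label = [1]

    def split(indices: np.ndarray) -> None:
        if indices.size < 2:
            return
        b_sub = b_full[np.ix_(indices, indices)]
        b_g = b_sub - np.diag(b_sub.sum(axis=1))
        vals, vecs = np.linalg.eigh(b_g)
        lead = vals[-1]
        if lead <= tol:
            return
        s = np.where(vecs[:, -1] >= 0, 1.0, -1.0)
        s = _fine_tune(s, b_g)
        if np.all(s == s[0]):
            return
        dq = float(s @ b_g @ s) / (2.0 * two_m)
        if dq <= tol:
            return
        neg = indices[s < 0]
        pos = indices[s > 0]
        labels[neg] = next_label[0]
        next_label[0] += 1
        split(pos)
        split(neg)

    # operate component-wise so disconnected cliques split cleanly
    comp = _components(adj)
    for c in np.unique(comp):
        idx = np.nonzero(comp == c)[0]
        lab = next_label[0]
        labels[idx] = lab
        next_label[0] += 1
        split(idx)
    # relabel compactly
    _, labels = np.unique(labels, return_inverse=True)
    return labels, modularity_q(adj, labels)


def _components(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    comp = -np.ones(n, dtype=int)
    c = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = c
        while stack:
            u = stack.pop()
            for v in np.nonzero(adj[u] > 0)[0]:
                if comp[v] < 0:
                    comp[v] = c
                    stack.append(v)
        c += 1
    return comp


# --------------------------------------------------------------------------- #
# Percolation
# --------------------------------------------------------------------------- #
@dataclass
class SiteNetwork:
    sites: List[str]
    adjacency: np.ndarray  # percolated weighted adjacency, zero diagonal
    threshold: float
    communities: np.ndarray
    modularity: float
    centrality: Optional[pd.Series] = None
    hubs: Optional[List[str]] = None
    scan: Optional[pd.DataFrame] = None

    @property
    def n_communities(self) -> int:
        return int(len(np.unique(self.communities)))


def percolate(sim: pd.DataFrame) -> SiteNetwork:
    """Threshold scan maximising modularity of the leading-eigenvector split.

    Candidate thresholds are the sorted unique off-diagonal edge weights;
    at each, edges with weight >= threshold are kept. Ties in Q resolve to
    the lowest threshold (most edges retained). An all-equal weight matrix
    degenerates to the full graph with a warning.
    """
    sites = list(sim.index)
    if len(sites) < 3:
        raise ValueError("percolation needs at least 3 nodes")
    adj0 = sim.to_numpy(dtype=float).copy()
    np.fill_diagonal(adj0, 0.0)
    adj0 = np.nan_to_num(adj0, nan=0.0)
    weights = np.unique(adj0[np.triu_indices_from(adj0, k=1)])
    weights = weights[weights > 0]
    if weights.size <= 1:
        warnings.warn("all edge weights equal; degenerate threshold scan, returning full graph", stacklevel=2)
        labels, q = leading_eigenvector(adj0)
        return SiteNetwork(sites, adj0, float(weights[0]) if weights.size else 0.0, labels, q)

    best = None
    rows = []
    for t in weights:  # ascending: first maximum wins the tie -> lower threshold
        adj_t = np.where(adj0 >= t, adj0, 0.0)
        labels, q = leading_eigenvector(adj_t)
        rows.append({"threshold": float(t), "Q": q, "n_communities": len(np.unique(labels))})
        if best is None or q > best[1] + 1e-12:
            best = (float(t), q, labels, adj_t)
    t, q, labels, adj_t = best
    n_edges = int((adj_t > 0).sum() / 2)
    if n_edges and _components(adj_t).max() > 0:
        log.info("percolated network fragments into %d components", _components(adj_t).max() + 1)
    return SiteNetwork(sites, adj_t, t, labels, q, scan=pd.DataFrame(rows))


# --------------------------------------------------------------------------- #
# Permutation test
# --------------------------------------------------------------------------- #
def modularity_permutation_test(net: SiteNetwork, n_perm: int = 10_000, seed: int = 0) -> float:
    """P-value of the observed Q under size-preserving label shuffles.

    p = (1 + #{permuted Q >= observed Q}) / (1 + n_perm). A single observed
    community makes the test undefined and returns p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if net.n_communities < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    labels = np.asarray(net.communities)
    q_obs = modularity_q(net.adjacency, labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if modularity_q(net.adjacency, perm) >= q_obs:
            count += 1
    return (1 + count) / (1 + n_perm)


# --------------------------------------------------------------------------- #
# Centrality
# --------------------------------------------------------------------------- #
def eigenvector_centrality(adj: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """Weighted eigenvector centrality by power iteration, per component.

    Values are max-normalised globally; nodes in edgeless components get 0.
    """
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    cent = np.zeros(n)
    comp = _components(adj)
    for c in np.unique(comp):
        idx = np.nonzero(comp == c)[0]
        sub = adj[np.ix_(idx, idx)]
        if sub.sum() == 0:
            continue
        x = np.ones(idx.size) / np.sqrt(idx.size)
        for _ in range(max_iter):
            x_new = sub @ x
            norm = np.linalg.norm(x_new)
            if norm == 0:
                break
            x_new /= norm
            if np.linalg.norm(x_new - x) < tol:
                x = x_new
                break
            x = x_new
        cent[idx] = np.abs(x)
    if cent.max() > 0:
        cent = cent / cent.max()
    return cent


def centrality_hubs(net: SiteNetwork, percentile: float = 95.0) -> Tuple[pd.Series, List[str]]:
    """Eigenvector centrality per site and the strict >percentile hub set."""
    cent = eigenvector_centrality(net.adjacency)
    series = pd.Series(cent, index=net.sites, name="centrality")
    cutoff = np.percentile(cent, percentile)
    hubs = [s for s, v in series.items() if v > cutoff]
    net.centrality = series
    net.hubs = hubs
    return series, hubs


# --------------------------------------------------------------------------- #
# Export
# --------------------------------------------------------------------------- #
def to_networkx(net: SiteNetwork):
    """The percolated network as a networkx Graph (for export/inspection)."""
    import networkx as nx

    g = nx.Graph()
    for i, s in enumerate(net.sites):
        g.add_node(s, community=int(net.communities[i]))
    n = len(net.sites)
    for i in range(n):
        for j in range(i + 1, n):
            w = net.adjacency[i, j]
            if w > 0:
                g.add_edge(net.sites[i], net.sites[j], weight=float(w))
    return g


def write_edge_list(net: SiteNetwork, path) -> None:
    rows = []
    n = len(net.sites)
    for i in range(n):
        for j in range(i + 1, n):
            if net.adjacency[i, j] > 0:
                rows.append({"source": net.sites[i], "target": net.sites[j], "weight": net.adjacency[i, j]})
    pd.DataFrame(rows).to_csv(path, index=False)
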