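"""Meta-clustering workflows: batch-specific initial clusters merged across
batches by hierarchical agglomeration on the similarity matrix.

Two ways to obtain initial clusters:

* de novo ("dn"): per-batch HVG selection, PCA, shared-nearest-neighbour
  graph and Louvain communities; highly similar within-batch cluster pairs
  are pre-merged.
* assisted ("as"): the batch tag concatenated with a curated annotation.

The final step converts similarity to distance (1 - S), agglomerates with
complete linkage so that the most similar initial clusters merge first, and
cuts the tree at a configurable height. The linkage is implemented here
(rather than delegated) to guarantee a deterministic tie-break by sorted
label pair; scipy's implementation serves as an independent check in the
test-suite.
"""
from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .core import CellMeta, ExpressionMatrix, compute_pca, select_hvgs
from .metric import (InitialCluster, SimilarityMatrix, compute_des_pair,
                     ider_similarity, make_label, pairwise_similarity_matrix,
                     substream_seed)

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "snn_louvain",
    "initial_clusters_dn",
    "initial_clusters_as",
    "final_clustering",
    "linkage_to_newick",
    "run_cider",
]


def snn_graph(embedding: np.ndarray, k: int = 20, prune: float = 1 / 15):
    """Shared-nearest-neighbour graph with Jaccard edge weights.

    Each cell is connected to its k nearest neighbours (self included, as in
    the standard Seurat construction); edge weight is the Jaccard overlap of
    the two neighbourhoods, pruned below ``prune``.
    """
    n = embedding.shape[0]
    k_eff = min(k, n)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(embedding)
    a = nn.kneighbors_graph(embedding, mode="connectivity").tocsr()
    shared = (a @ a.T).tocoo()
    cand = ((a + a.T) > 0).tocoo()
    g = ig.Graph()
    g.add_vertices(n)
    edges, weights = [], []
    shared_d = shared.todok()
    for i, j in zip(cand.row, cand.col):
        if i >= j:
            continue
        s = shared_d.get((i, j), 0)
        jac = s / (2 * k_eff - s)
        if jac >= prune:
            edges.append((int(i), int(j)))
            weights.append(float(jac))
    g.add_edges(edges)
    g.es["weight"] = weights
    return g


def snn_louvain(embedding: np.ndarray, k: int = 20, resolution: float = 0.4,
                seed: int = 0, prune: float = 1 / 15) -> np.ndarray:
    """Louvain communities on the SNN graph; deterministic for a fixed seed."""
    g = snn_graph(embedding, k=k, prune=prune)
    ig.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def _union_find_merge(labels: Sequence[str], merge_pairs) -> dict:
    parent = {l: l for l in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in merge_pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    return {l: find(l) for l in labels}


def initial_clusters_dn(em: ExpressionMatrix, meta: CellMeta, n_pcs: int = 10,
                        resolution: float = 0.4,
                        premerge_threshold: float = 0.9, n_hvgs: int = 2000,
                        snn_k: int = 20, target: int = 40, seed: int = 0,
                        extra_covariates: Optional[Sequence[str]] = None
                        ) -> list:
    """De novo initial clusters: per-batch Louvain, then within-batch pre-merge.

    Per batch: HVG selection, PCA on the top components, SNN graph and
    Louvain at the given resolution. Within each batch, cluster pairs whose
    similarity exceeds ``premerge_threshold`` are unioned transitively.
    A batch smaller than the SNN neighbourhood becomes a single cluster.
    """
    batches = meta.batch
    clusters: list[InitialCluster] = []
    for b in sorted(set(batches)):
        idx = np.flatnonzero(batches == b)
        if len(idx) <= snn_k:
            warnings.warn(f"batch {b!r} has {len(idx)} cells (<= k={snn_k}); "
                          "treating it as a single cluster")
            membership = np.zeros(len(idx), dtype=int)
        else:
            em_b = em.subset_cells(idx)
            hvgs = select_hvgs(em_b, n=min(n_hvgs, em_b.n_genes))
            pcs = compute_pca(em_b, hvgs,
                              n_pcs=min(n_pcs, len(idx) - 1, len(hvgs) - 1))
            membership = snn_louvain(pcs, k=snn_k, resolution=resolution,
                                     seed=substream_seed(seed, "louvain", b))
        for m in sorted(set(membership)):
            clusters.append(InitialCluster(
                label=make_label(b, m), batch=b,
                cell_indices=idx[membership == m]))

    if not np.isfinite(premerge_threshold):
        return clusters

    # within-batch pre-merge of highly similar Louvain clusters
    merged: list[InitialCluster] = []
    by_batch: dict[str, list[InitialCluster]] = {}
    for cl in clusters:
        by_batch.setdefault(cl.batch, []).append(cl)
    for b, cls in sorted(by_batch.items()):
        if len(cls) < 2:
            merged.extend(cls)
            continue
        pairs = []
        for i in range(len(cls)):
            for j in range(i + 1, len(cls)):
                d_i, d_j = compute_des_pair(
                    em, meta, cls[i], cls[j], background=clusters,
                    extra_covariates=extra_covariates, target=target, seed=seed)
                if ider_similarity(d_i, d_j) > premerge_threshold:
                    pairs.append((cls[i].label, cls[j].label))
        roots = _union_find_merge([c.label for c in cls], pairs)
        groups: dict[str, list[InitialCluster]] = {}
        for c in cls:
            groups.setdefault(roots[c.label], []).append(c)
        for new_id, root in enumerate(sorted(groups)):
            members = groups[root]
            merged.append(InitialCluster(
                label=make_label(b, new_id), batch=b,
                cell_indices=np.sort(np.concatenate(
                    [m.cell_indices for m in members]))))
    return merged


def initial_clusters_as(meta: CellMeta) -> list:
    """Assisted initial clusters: one per observed (batch, annotation) pair."""
    ann = meta.annotation
    missing = pd.isna(ann)
    if missing.any():
        cells = list(meta.df.index[missing][:5])
        raise ValueError(f"{int(missing.sum())} cells lack an annotation, "
                         f"e.g. {cells}")
    batches = meta.batch
    clusters = []
    for b in sorted(set(batches)):
        for a in sorted(set(ann[batches == b].astype(str))):
            idx = np.flatnonzero((batches == b) & (ann.astype(str) == a))
            clusters.append(InitialCluster(label=make_label(b, a), batch=b,
                                           cell_indices=idx))
    return clusters


@dataclass
class FinalClustering:
    """Result of cutting the complete-linkage tree over initial clusters."""

    labels: list
    assignment: dict            # initial-cluster label -> final cluster id
    linkage: np.ndarray         # scipy-convention (k-1) x 4 merge table
    cut_height: float


def _complete_linkage(dist: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Naive complete-linkage agglomeration with label-sorted tie-breaks.

    Returns a scipy-convention linkage matrix: rows (id_a, id_b, height,
    size), original clusters 0..k-1, merges numbered k, k+1, ...
    Ties in merge distance are broken by the lexicographically smallest
    sorted pair of member-label tuples.
    """
    k = len(labels)
    active = {i: (tuple(sorted([labels[i]])), [i]) for i in range(k)}
    d = {}
    for i in range(k):
        for j in range(i + 1, k):
            d[(i, j)] = dist[i, j]
    z = np.zeros((k - 1, 4))
    sizes = {i: 1 for i in range(k)}
    next_id = k
    for step in range(k - 1):
        best = None
        for (i, j), dij in d.items():
            key_i, key_j = active[i][0], active[j][0]
            pair_key = tuple(sorted([key_i, key_j]))
            cand = (dij, pair_key)
            if best is None or cand < best[0:2] or (cand[0] == best[0] and cand[1] < best[1]):
                best = (dij, pair_key, i, j)
        dij, _, i, j = best
        a, b = sorted([i, j])
        z[step] = [a, b, dij, sizes[a] + sizes[b]]
        new_key = tuple(sorted(active[a][0] + active[b][0]))
        others = [c for c in active if c not in (a, b)]
        for c in others:
            da = d[tuple(sorted([a, c]))]
            db = d[tuple(sorted([b, c]))]
            d[tuple(sorted([next_id, c]))] = max(da, db)
        for c in others:
            d.pop(tuple(sorted([a, c])), None)
            d.pop(tuple(sorted([b, c])), None)
        d.pop((a, b), None)
        active[next_id] = (new_key, active[a][1] + active[b][1])
        sizes[next_id] = sizes[a] + sizes[b]
        del active[a], active[b], sizes[a], sizes[b]
        next_id += 1
    return z


def final_clustering(sim: SimilarityMatrix, cut_height: float = 0.6
                     ) -> FinalClustering:
    """Merge initial clusters by complete linkage on distance 1 - S.

    Masked (uncomputed, e.g. within-batch) entries are imputed as similarity
    0, i.e. distance 1, so that clusters already separated within a batch do
    not merge through missing data. The tree is cut at ``cut_height``:
    merges at distance <= cut_height are applied.
    """
    s = sim.S.copy()
    s[~sim.mask] = 0.0
    np.fill_diagonal(s, 1.0)
    dist = 1.0 - s
    np.fill_diagonal(dist, 0.0)
    labels = list(sim.labels)
    k = len(labels)
    if k == 1:
        return FinalClustering(labels=labels, assignment={labels[0]: 0},
                               linkage=np.zeros((0, 4)), cut_height=cut_height)
    z = _complete_linkage(dist, labels)

    members = {i: [i] for i in range(k)}
    for step in range(k - 1):
        a, b, h, _ = z[step]
        new = k + step
        if h <= cut_height:
            members[new] = members.pop(int(a)) + members.pop(int(b))
        else:
            members[new] = []  # placeholder; children stay as final clusters
    finals = [sorted(v) for v in members.values() if v]
    finals.sort(key=lambda v: labels[v[0]])
    assignment = {}
    for fid, group in enumerate(finals):
        for i in group:
            assignment[labels[i]] = fid
    return FinalClustering(labels=labels, assignment=assignment, linkage=z,
                           cut_height=cut_height)


def linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage matrix as a Newick string with branch lengths."""
    k = len(labels)
    height = {i: 0.0 for i in range(k)}
    node = {i: labels[i] for i in range(k)}
    for step in range(z.shape[0]):
        a, b, h, _ = z[step]
        a, b = int(a), int(b)
        left = f"{node[a]}:{h - height[a]:.6g}"
        right = f"{node[b]}:{h - height[b]:.6g}"
        node[k + step] = f"({left},{right})"
        height[k + step] = h
    root = k + z.shape[0] - 1 if z.shape[0] else 0
    return node[root] + ";"


@dataclass
class ClusterResult:
    """Per-cell initial and final assignments plus the merge dendrogram.

    The final clustering is a coarsening of the initial one: each initial
    cluster maps to exactly one final cluster.
    """

    initial_assignment: pd.Series
    final_assignment: pd.Series
    initial_clusters: list
    final_map: dict
    linkage: np.ndarray
    similarity: SimilarityMatrix

    def to_frame(self, meta: Optional[CellMeta] = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "cell": self.initial_assignment.index,
            "initial": self.initial_assignment.values,
            "final": self.final_assignment.values,
        })
        if meta is not None:
            df.insert(1, "batch", meta.batch)
        return df

    def newick(self) -> str:
        return linkage_to_newick(self.linkage, self.similarity.labels)


def run_cider(em: ExpressionMatrix, meta: CellMeta, mode: str = "dn",
              n_pcs: int = 10, resolution: float = 0.4,
              premerge_threshold: float = 0.9, n_hvgs: int = 2000,
              snn_k: int = 20, target: int = 40, cut_height: float = 0.6,
              extra_covariates: Optional[Sequence[str]] = None,
              n_workers: int = 1, seed: int = 0) -> ClusterResult:
    """Full meta-clustering: initial clusters, similarity matrix, final merge.

    ``mode`` selects de novo ("dn", Louvain-derived) or assisted ("as",
    annotation-derived) initial clusters. Cross-batch similarities drive the
    merge; with a single batch the scope degenerates to all pairs.
    """
    if mode == "dn":
        clusters = initial_clusters_dn(
            em, meta, n_pcs=n_pcs, resolution=resolution,
            premerge_threshold=premerge_threshold, n_hvgs=n_hvgs,
            snn_k=snn_k, target=target, seed=seed,
            extra_covariates=extra_covariates)
    elif mode == "as":
        clusters = initial_clusters_as(meta)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    logger.info("initial clustering: %d clusters", len(clusters))

    n_batches = len(set(c.batch for c in clusters))
    scope = "cross-batch-only" if n_batches > 1 else "all-pairs"
    if len(clusters) == 1:
        sim = SimilarityMatrix(S=np.ones((1, 1)), labels=[clusters[0].label],
                               batches=[clusters[0].batch],
                               mask=np.ones((1, 1), dtype=bool))
    else:
        sim = pairwise_similarity_matrix(
            em, meta, clusters, extra_covariates=extra_covariates,
            scope=scope, target=target, seed=seed, n_workers=n_workers)
    fc = final_clustering(sim, cut_height=cut_height)
    logger.info("final clustering: %d clusters at cut height %.3g",
                len(set(fc.assignment.values())), cut_height)

    initial = np.empty(em.n_cells, dtype=object)
    final = np.empty(em.n_cells, dtype=int)
    for cl in clusters:
        initial[cl.cell_indices] = cl.label
        final[cl.cell_indices] = fc.assignment[cl.label]
    cells = pd.Index(em.cell_ids)
    return ClusterResult(
        initial_assignment=pd.Series(initial, index=cells, name="initial"),
        final_assignment=pd.Series(final, index=cells, name="final"),
        initial_clusters=clusters,
        final_map=fc.assignment,
        linkage=fc.linkage,
        similarity=sim,
    )
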