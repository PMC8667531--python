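"""Ground-truth-free evaluation of an integration result.

A batch-corrected embedding only defines the clusters; the evidence about
whether a cross-batch cluster is a genuine population comes from the original
log-normalised expression. Each corrected-space cluster is split into
batch-specific subclusters and the similarity between cross-batch subcluster
pairs is computed with batch regressed out. A background distribution of
within-population similarity is obtained by repeatedly halving the union of
the mutually-nearest, most-similar subcluster pair (assumed to be one true
population), and each observed pair is scored by an add-one-smoothed
upper-tail empirical probability of rejection: high when the observed
similarity sits below the within-population background. Falsely aligned
(overcorrected) clusters show low similarity and high rejection probability,
in agreement with high cLISI where annotations exist.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .core import CellMeta, ExpressionMatrix
from .cluster import snn_louvain
from .metric import (InitialCluster, SimilarityMatrix, compute_des_pair,
                     ider_similarity, pairwise_similarity_matrix,
                     substream_seed)

logger = logging.getLogger(__name__)

__all__ = [
    "partition_corrected_space",
    "within_cluster_similarity",
    "background_distribution",
    "empirical_rejection_probability",
    "ari",
    "clustering_metrics",
    "clisi",
    "evaluate_integration",
    "EvaluationReport",
]

UNCLUSTERED = "unclustered"


def partition_corrected_space(embedding: np.ndarray, method: str = "louvain",
                              resolution: float = 0.4, k: int = 20,
                              min_cluster_size: int = 75,
                              seed: int = 0) -> np.ndarray:
    """Cluster cells in a corrected embedding (Louvain on SNN, or HDBSCAN).

    HDBSCAN noise points get the label ``"unclustered"`` and are excluded
    from evaluation downstream. Returns one string label per cell.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2 or embedding.shape[1] < 2:
        raise ValueError("embedding must be cells x d with d >= 2")
    if method == "louvain":
        membership = snn_louvain(embedding, k=k, resolution=resolution, seed=seed)
        return membership.astype(str)
    if method == "hdbscan":
        from sklearn.cluster import HDBSCAN

        labels = HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(embedding)
        return np.where(labels < 0, UNCLUSTERED, labels.astype(str))
    raise ValueError(f"unknown method {method!r}")


def _subclusters(cluster_labels: np.ndarray, batches: np.ndarray,
                 min_cells: int = 15):
    """Batch-specific subclusters per corrected-space cluster."""
    subs, skipped = [], []
    for c in sorted(set(cluster_labels)):
        if c == UNCLUSTERED:
            continue
        for b in sorted(set(batches[cluster_labels == c])):
            idx = np.flatnonzero((cluster_labels == c) & (batches == b))
            if len(idx) >= min_cells:
                subs.append(InitialCluster(label=f"{c}|{b}", batch=b,
                                           cell_indices=idx))
            else:
                skipped.append((c, b, len(idx)))
    if skipped:
        logger.info("skipped %d subclusters below min_cells", len(skipped))
    return subs


def within_cluster_similarity(em: ExpressionMatrix, meta: CellMeta,
                              cluster_labels, extra_covariates=None,
                              min_cells: int = 15, target: int = 40,
                              seed: int = 0, n_workers: int = 1):
    """Cross-batch similarity of batch-specific subclusters inside each cluster.

    Returns ``(pairs, sim, subclusters)``: a table of within-cluster
    cross-batch pair scores, the full subcluster similarity matrix (needed to
    find the mutual-nearest anchor pair), and the subclusters themselves.
    Clusters with fewer than two sufficiently large batches are reported as
    non-evaluable rows with missing similarity.
    """
    cluster_labels = np.asarray(cluster_labels).astype(str)
    subs = _subclusters(cluster_labels, meta.batch, min_cells=min_cells)
    if len(subs) < 2:
        raise ValueError("fewer than 2 evaluable subclusters; lower min_cells "
                         "or check the clustering")
    sim = pairwise_similarity_matrix(
        em, meta, subs, extra_covariates=extra_covariates,
        scope="cross-batch-only", target=target, seed=seed,
        n_workers=n_workers)
    rows = []
    clusters = sorted(set(cluster_labels) - {UNCLUSTERED})
    by_cluster = {c: [s for s in subs if s.label.rsplit("|", 1)[0] == c]
                  for c in clusters}
    for c in clusters:
        cl_subs = by_cluster[c]
        pairs = [(a, b) for i, a in enumerate(cl_subs)
                 for b in cl_subs[i + 1:] if a.batch != b.batch]
        if not pairs:
            rows.append({"cluster": c, "subcluster_a": None, "subcluster_b": None,
                         "similarity": np.nan, "n_a": np.nan, "n_b": np.nan,
                         "evaluable": False})
            continue
        for a, b in pairs:
            rows.append({"cluster": c, "subcluster_a": a.label,
                         "subcluster_b": b.label,
                         "similarity": sim.value(a.label, b.label),
                         "n_a": a.size, "n_b": b.size, "evaluable": True})
    return pd.DataFrame(rows), sim, subs


def mutual_nearest_anchor(sim: SimilarityMatrix):
    """Best mutually-nearest cross-batch pair: each is the other's argmax.

    Among all pairs where row argmaxes point at each other, the one with the
    highest similarity is returned (as a pair of label indices).
    """
    s = sim.S.copy()
    s[~sim.mask] = -np.inf
    np.fill_diagonal(s, -np.inf)
    best = None
    argmax = s.argmax(axis=1)
    for i in range(len(sim.labels)):
        j = argmax[i]
        if argmax[j] == i and i < j:
            if best is None or s[i, j] > best[0]:
                best = (s[i, j], i, j)
    if best is None:
        raise ValueError("no mutual-nearest subcluster pair found")
    return best[1], best[2]


def background_distribution(em: ExpressionMatrix, meta: CellMeta,
                            anchor_a: InitialCluster, anchor_b: InitialCluster,
                            background: Sequence[InitialCluster] = (),
                            extra_covariates=None, n_splits: int = 20,
                            min_cells: int = 15, target: int = 40,
                            seed: int = 0) -> np.ndarray:
    """Within-population similarity samples from re-splitting the anchor pair.

    The two anchor subclusters are assumed to be one true population (the
    mutual-nearest and constant-variability hypotheses). Each split draws a
    random half of every batch-specific anchor subcluster and scores the two
    halves against each other, preserving the cross-batch structure of the
    observed statistic — each pseudo-group stays single-batch, exactly like
    a real subcluster pair, while the background cells keep the batch
    covariate estimable. The resulting samples form the null distribution of
    within-population cross-batch similarity.
    """
    union = np.concatenate([anchor_a.cell_indices, anchor_b.cell_indices])
    if len(union) < 2 * min_cells:
        raise ValueError(
            f"anchor union has {len(union)} cells < {2 * min_cells}; "
            "evaluation needs larger clusters")
    samples = np.empty(n_splits)
    others = [c for c in background
              if c.label not in (anchor_a.label, anchor_b.label)]
    for s in range(n_splits):
        rng = np.random.default_rng(substream_seed(seed, "bgsplit", s))
        ha = InitialCluster(
            label=f"__half_a_{s}__", batch=anchor_a.batch,
            cell_indices=rng.permutation(anchor_a.cell_indices)[
                : max(anchor_a.size // 2, 1)])
        hb = InitialCluster(
            label=f"__half_b_{s}__", batch=anchor_b.batch,
            cell_indices=rng.permutation(anchor_b.cell_indices)[
                : max(anchor_b.size // 2, 1)])
        d_a, d_b = compute_des_pair(
            em, meta, ha, hb, background=others,
            extra_covariates=extra_covariates, target=target,
            seed=substream_seed(seed, "bgpair", s))
        samples[s] = ider_similarity(d_a, d_b)
    return samples


def empirical_rejection_probability(observed: float, background) -> float:
    """Add-one-smoothed upper-tail empirical probability of rejection.

    p = (#{b : b > observed} + 1) / (B + 1): high when the observed
    similarity sits below the within-population background; always in (0, 1].
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background distribution is empty")
    return float((np.sum(background > observed) + 1) / (background.size + 1))


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (pair-counting form)."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(labels_a, labels_b))


def clustering_metrics(pred, population=None, batch=None) -> dict:
    """ARI_population and 1 - ARI_batch for a clustering result.

    High ARI_population means accurate recovery of populations; high
    1 - ARI_batch means the clustering is not confounded by batch.
    """
    out = {}
    if population is not None:
        out["ARI_population"] = ari(pred, population)
    if batch is not None:
        ab = ari(pred, batch)
        out["ARI_batch"] = ab
        out["one_minus_ARI_batch"] = 1.0 - ab
    return out


def clisi(embedding: np.ndarray, labels, perplexity: float = 30.0,
          n_neighbors: Optional[int] = None) -> np.ndarray:
    """Cell-type local inverse Simpson index per cell.

    Neighbourhoods are Gaussian-kernel distributions whose bandwidth is tuned
    per cell (bisection on the entropy) to the target perplexity; the index
    is the inverse Simpson concentration of the kernel-weighted label
    frequencies. Ranges from 1 (locally pure) to the number of labels
    (locally fully mixed).
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    n = embedding.shape[0]
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < n_cells {n}")
    uniq, enc = np.unique(labels, return_inverse=True)
    n_lab = len(uniq)
    if n_lab == 1:
        return np.ones(n)
    k = n_neighbors or min(n - 1, int(3 * perplexity))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    dist, idx = dist[:, 1:], idx[:, 1:]            # drop self
    target = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        d2 = dist[i] ** 2
        if d2.max() == 0:
            warnings.warn("duplicate points: falling back to uniform kNN weights")
            p = np.full(k, 1.0 / k)
        else:
            lo, hi = 1e-12, 1e12
            beta = 1.0
            for _ in range(100):
                w = np.exp(-beta * d2)
                sw = w.sum()
                if sw <= 0:
                    hi = beta
                    beta = (lo + hi) / 2
                    continue
                p = w / sw
                h = -(p[p > 0] * np.log(p[p > 0])).sum()
                if abs(h - target) < 1e-7:
                    break
                if h > target:
                    lo = beta
                else:
                    hi = beta
                beta = (lo + hi) / 2
        freq = np.bincount(enc[idx[i]], weights=p, minlength=n_lab)
        out[i] = 1.0 / np.sum(freq ** 2)
    return out


@dataclass
class EvaluationReport:
    """Per-cluster and per-cell integration quality scores.

    ``clusters`` aggregates similarity and rejection probability per
    corrected-space cluster; ``pairs`` holds the underlying cross-batch
    subcluster scores; ``background`` the shared within-population similarity
    samples; ``per_cell`` projects cluster-level scores onto member cells.
    """

    clusters: pd.DataFrame
    pairs: pd.DataFrame
    background: np.ndarray
    per_cell: pd.DataFrame

    def to_tsvs(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        self.clusters.to_csv(outdir / "cluster_report.tsv", sep="\t", index=False)
        self.pairs.to_csv(outdir / "pair_scores.tsv", sep="\t", index=False)
        self.per_cell.to_csv(outdir / "cell_scores.tsv", sep="\t", index=False)
        pd.DataFrame({"background_similarity": self.background}).to_csv(
            outdir / "background.tsv", sep="\t", index=False)


def evaluate_integration(em: ExpressionMatrix, meta: CellMeta,
                         embedding: Optional[np.ndarray] = None,
                         cluster_labels=None, method: str = "louvain",
                         resolution: float = 0.4,
                         min_cluster_size: int = 75, min_cells: int = 15,
                         n_splits: int = 20, target: int = 40,
                         extra_covariates=None, n_workers: int = 1,
                         seed: int = 0) -> EvaluationReport:
    """Full evaluation workflow for one integration result.

    Either a corrected embedding (which is clustered here) or precomputed
    cluster labels must be given. Similarities are computed on the original
    expression with batch regressed out; the embedding only defines clusters.
    """
    if cluster_labels is None:
        if embedding is None:
            raise ValueError("need an embedding or precomputed cluster labels")
        cluster_labels = partition_corrected_space(
            embedding, method=method, resolution=resolution,
            min_cluster_size=min_cluster_size, seed=seed)
    cluster_labels = np.asarray(cluster_labels).astype(str)

    pairs, sim, subs = within_cluster_similarity(
        em, meta, cluster_labels, extra_covariates=extra_covariates,
        min_cells=min_cells, target=target, seed=seed, n_workers=n_workers)

    ia, ib = mutual_nearest_anchor(sim)
    anchor_a, anchor_b = subs[ia], subs[ib]
    logger.info("background anchor pair: %s, %s (similarity %.3f)",
                anchor_a.label, anchor_b.label, sim.S[ia, ib])
    background = background_distribution(
        em, meta, anchor_a, anchor_b, background=subs,
        extra_covariates=extra_covariates, n_splits=n_splits,
        min_cells=min_cells, target=target, seed=seed)

    evaluable = pairs[pairs["evaluable"]].copy()
    evaluable["p_reject"] = [
        empirical_rejection_probability(v, background)
        for v in evaluable["similarity"]
    ]
    pairs = pairs.merge(
        evaluable[["cluster", "subcluster_a", "subcluster_b", "p_reject"]],
        on=["cluster", "subcluster_a", "subcluster_b"], how="left")

    agg = []
    for c, grp in pairs.groupby("cluster"):
        ok = grp["evaluable"].any()
        agg.append({
            "cluster": c,
            "evaluable": bool(ok),
            "n_pairs": int(grp["evaluable"].sum()),
            "mean_similarity": grp["similarity"].mean() if ok else np.nan,
            "min_similarity": grp["similarity"].min() if ok else np.nan,
            "p_reject": grp["p_reject"].max() if ok else np.nan,
        })
    clusters = pd.DataFrame(agg)

    cell_sim = np.full(em.n_cells, np.nan)
    cell_p = np.full(em.n_cells, np.nan)
    lookup = clusters.set_index("cluster")
    for c in lookup.index:
        m = cluster_labels == c
        cell_sim[m] = lookup.loc[c, "mean_similarity"]
        cell_p[m] = lookup.loc[c, "p_reject"]
    per_cell = pd.DataFrame({
        "cell": em.cell_ids,
        "cluster": cluster_labels,
        "similarity": cell_sim,
        "p_reject": cell_p,
    })
    return EvaluationReport(clusters=clusters, pairs=pairs,
                            background=background, per_cell=per_cell)
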