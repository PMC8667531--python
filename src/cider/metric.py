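"""The IDER similarity metric between batch-specific cell groups.

Two groups are compared through the background (all cells belonging to
neither group): each group's differential-expression signature against the
background is estimated from one shared linear model that also carries batch,
optional extra covariates and the scaled cellular detection rate, and the
similarity is the Pearson correlation of the two signatures. Because the
confounders sit in the model, additive batch shifts cancel out of the
signatures — the regress-out property the metric is built on.

All randomness is drawn from named substreams of a global seed: each pair's
downsampling is seeded by a stable hash of (seed, sorted pair labels), so the
similarity matrix does not depend on pair order or worker count.
"""
from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .core import CellMeta, ExpressionMatrix, compute_cdr
from .linmod import DESignature, build_design, contrast_estimates, fit_ols

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedSimilarityError",
    "InitialCluster",
    "SimilarityMatrix",
    "substream_seed",
    "downsample_groups",
    "compute_des_pair",
    "ider_similarity",
    "pairwise_similarity_matrix",
    "similarity_graph",
    "make_label",
    "parse_label",
]

BACKGROUND = "(background)"
MIN_CLUSTER_WARN = 15


class UndefinedSimilarityError(ValueError):
    """Similarity is undefined (a signature has zero variance)."""


def substream_seed(seed: int, *tokens) -> int:
    """Stable sub-seed derived from a global seed and string tokens (< 2^31)."""
    key = "|".join([str(seed), *map(str, tokens)]).encode()
    h = hashlib.sha256(key).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def make_label(batch: str, name) -> str:
    return f"{batch}_{name}"


def parse_label(label: str, batches: Optional[Sequence[str]] = None):
    """Split an initial-cluster label back into (batch, within-batch name).

    If ``batches`` is given the longest matching batch prefix wins; otherwise
    the split is at the first underscore (assumes batch names without one).
    """
    if batches is not None:
        for b in sorted(batches, key=len, reverse=True):
            if label.startswith(b + "_"):
                return b, label[len(b) + 1:]
        raise ValueError(f"label {label!r} matches no known batch")
    batch, _, name = label.partition("_")
    return batch, name


@dataclass
class InitialCluster:
    """A batch-specific cell group that meta-clustering may merge.

    All member cells share the stated batch; the label (batch tag plus
    within-batch cluster id or annotation) is unique across the analysis.
    """

    label: str
    batch: str
    cell_indices: np.ndarray

    def __post_init__(self) -> None:
        self.cell_indices = np.asarray(self.cell_indices, dtype=int)

    @property
    def size(self) -> int:
        return len(self.cell_indices)


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise similarities between initial clusters.

    The diagonal is 1 by convention; ``mask`` marks computed entries
    (out-of-scope pairs, e.g. within-batch pairs in clustering scope, are
    left unmasked and untrusted).
    """

    S: np.ndarray
    labels: list
    batches: list
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        k = len(self.labels)
        if self.S.shape != (k, k):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.S[i, j])


def _sample(cluster: InitialCluster, target: int, rng: np.random.Generator,
            warn: bool = True) -> np.ndarray:
    if cluster.size == 0:
        raise ValueError(f"cluster {cluster.label!r} is empty")
    if cluster.size >= target:
        return rng.choice(cluster.cell_indices, size=target, replace=False)
    if warn and cluster.size < MIN_CLUSTER_WARN:
        warnings.warn(
            f"cluster {cluster.label!r} has {cluster.size} cells "
            f"(< {MIN_CLUSTER_WARN}); sampling with replacement"
        )
    return rng.choice(cluster.cell_indices, size=target, replace=True)


def downsample_groups(clusters: Sequence[InitialCluster], target: int = 40,
                      seed: int = 0) -> dict:
    """Downsample every cluster to exactly ``target`` draws.

    Without replacement when the cluster is large enough, with replacement
    (plus a warning below 15 cells) otherwise. Each cluster uses a seed
    substream keyed by its label, so results do not depend on cluster order.
    """
    if not 35 <= target <= 50:
        logger.info("downsample target %d outside the recommended 35-50 range", target)
    out = {}
    for cl in clusters:
        rng = np.random.default_rng(substream_seed(seed, "downsample", cl.label))
        out[cl.label] = _sample(cl, target, rng)
    return out


def _background_draws(others: Sequence[InitialCluster], target: int,
                      pair_seed: int, cap_factor: int = 10):
    """Equal-size draws from every other cluster, capped at cap_factor * target."""
    others = sorted(others, key=lambda c: c.label)
    if not others:
        return np.array([], dtype=int)
    per = min(target, max(1, (cap_factor * target) // len(others)))
    idx = []
    for cl in others:
        rng = np.random.default_rng(substream_seed(pair_seed, "bg", cl.label))
        take = min(per, cl.size) if cl.size >= per else per
        idx.append(_sample(cl, take, rng, warn=False))
    return np.concatenate(idx)


def compute_des_pair(em: ExpressionMatrix, meta: CellMeta, g_i: InitialCluster,
                     g_j: InitialCluster, background: Sequence[InitialCluster] = (),
                     extra_covariates: Optional[Sequence[str]] = None,
                     gene_set: Optional[np.ndarray] = None, target: int = 40,
                     seed: int = 0, min_detect_frac: float = 0.05):
    """DE signatures of two groups against a shared background.

    The working set is the downsampled union of ``g_i``, ``g_j`` and the
    background (equal draws from every other initial cluster, capped at ten
    times the target). One linear model with group (three levels, background
    as reference) + batch + scaled CDR (+ extras) is fitted over the genes
    detected in at least ``min_detect_frac`` of the working cells, and both
    group contrasts are returned.

    With no background clusters (only two groups exist) the comparison falls
    back to a direct two-group contrast, with a warning.

    Returns
    -------
    (DESignature, DESignature)
        Signatures for ``g_i`` and ``g_j`` in call order. Swapping the call
        order returns the swapped pair, bitwise identical for the same seed.
    """
    if g_i.label == g_j.label:
        raise ValueError("compute_des_pair needs two distinct clusters")
    la, lb = sorted([g_i.label, g_j.label])
    pair_seed = substream_seed(seed, "pair", la, lb)
    draws = {}
    for cl in (g_i, g_j):
        rng = np.random.default_rng(substream_seed(pair_seed, "grp", cl.label))
        draws[cl.label] = _sample(cl, target, rng)
    bg_idx = _background_draws(
        [c for c in background if c.label not in (g_i.label, g_j.label)],
        target, pair_seed)

    two_group = bg_idx.size == 0
    if two_group:
        warnings.warn(
            f"no background clusters for pair ({g_i.label}, {g_j.label}); "
            "falling back to a direct two-group contrast"
        )
    idx = np.concatenate([draws[la], draws[lb]] + ([] if two_group else [bg_idx]))
    group = np.array(
        [la] * target + [lb] * target + [BACKGROUND] * len(bg_idx), dtype=object
    )
    if BACKGROUND in (g_i.label, g_j.label):
        raise ValueError(f"cluster label collides with reserved {BACKGROUND!r}")

    batch = meta.batch[idx]
    extras = None
    if extra_covariates:
        sub = CellMeta(meta.df, batch_col=meta.batch_col,
                       extra_cols=tuple(extra_covariates))
        extras = sub.extras(idx)
    cdr = compute_cdr(em, within=idx)

    if gene_set is None:
        detect = (em.values[idx] > 0).sum(axis=0)
        frac = np.asarray(detect).ravel() / len(idx)
        gene_pos = np.flatnonzero(frac >= min_detect_frac)
    else:
        gene_pos = pd.Index(em.gene_ids).get_indexer(list(gene_set))
        if np.any(gene_pos < 0):
            raise ValueError("gene_set contains unknown genes")
    if gene_pos.size < 3:
        raise ValueError("fewer than 3 genes pass the detection filter")

    ref = lb if two_group else BACKGROUND
    design = build_design(group, batch=batch, cdr=cdr.scaled, extra=extras,
                          group_ref=ref)
    y = em.dense(cells=idx, genes=gene_pos)
    fit = fit_ols(y, design, gene_ids=em.gene_ids[gene_pos])
    if two_group:
        d_a = contrast_estimates(fit, la)
        d_b = DESignature(estimates=-d_a.estimates, gene_ids=d_a.gene_ids,
                          group=lb, background=la)
    else:
        d_a = contrast_estimates(fit, la)
        d_b = contrast_estimates(fit, lb)
    by_label = {la: d_a, lb: d_b}
    return by_label[g_i.label], by_label[g_j.label]


def ider_similarity(d_i: DESignature, d_j: DESignature) -> float:
    """Pearson correlation between two DE signatures; ranges over [-1, 1]."""
    if len(d_i) != len(d_j) or not np.array_equal(d_i.gene_ids, d_j.gene_ids):
        raise ValueError("signatures are not aligned on the same genes")
    if len(d_i) < 3:
        raise ValueError("need at least 3 genes to correlate signatures")
    x, y = d_i.estimates, d_j.estimates
    if x.std() == 0 or y.std() == 0:
        raise UndefinedSimilarityError(
            f"zero-variance signature for ({d_i.group}, {d_j.group}); "
            "similarity is undefined"
        )
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def _pair_similarity(em, meta, clusters, i, j, extra_covariates, gene_set,
                     target, seed, min_detect_frac):
    a, b = clusters[i], clusters[j]
    try:
        d_a, d_b = compute_des_pair(
            em, meta, a, b, background=clusters,
            extra_covariates=extra_covariates, gene_set=gene_set,
            target=target, seed=seed, min_detect_frac=min_detect_frac)
        return i, j, ider_similarity(d_a, d_b)
    except Exception as exc:
        raise RuntimeError(f"pair ({a.label}, {b.label}): {exc}") from exc


def pairwise_similarity_matrix(em: ExpressionMatrix, meta: CellMeta,
                               clusters: Sequence[InitialCluster],
                               extra_covariates: Optional[Sequence[str]] = None,
                               scope: str = "cross-batch-only",
                               target: int = 40, seed: int = 0,
                               n_workers: int = 1,
                               gene_set: Optional[np.ndarray] = None,
                               min_detect_frac: float = 0.05) -> SimilarityMatrix:
    """Similarity matrix over all in-scope cluster pairs.

    ``scope`` is ``"cross-batch-only"`` (pairs from different batches — the
    clustering use) or ``"all-pairs"``. Every pair is computed once and
    mirrored; the result is independent of pair order and worker count
    because each pair's sampling is seeded by (seed, sorted labels).
    """
    clusters = list(clusters)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    labels = [c.label for c in clusters]
    if len(set(labels)) != len(labels):
        raise ValueError("cluster labels are not unique")
    if scope not in ("cross-batch-only", "all-pairs"):
        raise ValueError(f"unknown scope {scope!r}")
    k = len(clusters)
    pairs = [
        (i, j) for i in range(k) for j in range(i + 1, k)
        if scope == "all-pairs" or clusters[i].batch != clusters[j].batch
    ]
    if n_workers == 1:
        results = [
            _pair_similarity(em, meta, clusters, i, j, extra_covariates,
                             gene_set, target, seed, min_detect_frac)
            for i, j in pairs
        ]
    else:
        results = Parallel(n_jobs=n_workers)(
            delayed(_pair_similarity)(em, meta, clusters, i, j, extra_covariates,
                                      gene_set, target, seed, min_detect_frac)
            for i, j in pairs
        )
    s = np.eye(k)
    mask = np.eye(k, dtype=bool)
    for i, j, val in results:
        s[i, j] = s[j, i] = val
        mask[i, j] = mask[j, i] = True
    return SimilarityMatrix(S=s, labels=labels,
                            batches=[c.batch for c in clusters], mask=mask)


def similarity_graph(sim: SimilarityMatrix, edge_threshold: float = 0.0):
    """Weighted undirected graph of initial clusters with edges where S > threshold."""
    import igraph as ig

    g = ig.Graph()
    g.add_vertices(len(sim.labels))
    g.vs["name"] = list(sim.labels)
    g.vs["batch"] = list(sim.batches)
    edges, weights = [], []
    k = len(sim.labels)
    for i in range(k):
        for j in range(i + 1, k):
            if sim.mask[i, j] and sim.S[i, j] > edge_threshold:
                edges.append((i, j))
                weights.append(float(sim.S[i, j]))
    g.add_edges(edges)
    g.es["weight"] = weights
    return g


def write_graph(g, graphml_path=None, edgelist_path=None) -> None:
    """Emit a similarity graph as GraphML and/or an edge-list TSV."""
    if graphml_path is not None:
        g.write_graphml(str(graphml_path))
    if edgelist_path is not None:
        rows = [
            {"from": g.vs[e.source]["name"], "to": g.vs[e.target]["name"],
             "weight": e["weight"]}
            for e in g.es
        ]
        pd.DataFrame(rows, columns=["from", "to", "weight"]).to_csv(
            edgelist_path, sep="\t", index=False)
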