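"""Gene-level interpretation of similarity scores and marker detection.

The influence of a gene on a similarity score is the change in the Fisher
z-transformed correlation when that gene is left out: positive influence
means the gene pushes the two signatures together, negative influence means
it drives them apart. Leave-one-out correlations are obtained by down-dating
the five correlation sufficient sums, so the whole table costs O(G).
"""
from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CellMeta, ExpressionMatrix, compute_cdr
from .linmod import DESignature, build_design, eb_moderate_trend, fit_ols

logger = logging.getLogger(__name__)

__all__ = ["fisher_z", "gene_influence", "find_markers"]


def fisher_z(r) -> np.ndarray:
    """Fisher z-transformation, 0.5 * ln((1 + r) / (1 - r)).

    Maps correlations to an approximately Gaussian scale; odd in r.
    |r| >= 1 is clipped just inside the open interval, with a warning.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(np.abs(r) >= 1):
        warnings.warn("clipping |r| >= 1 for the Fisher z-transformation")
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(r)
    return float(z[0]) if scalar else z


def gene_influence(d_i: DESignature, d_j: DESignature) -> pd.DataFrame:
    """Leave-one-gene-out influence on the similarity of two signatures.

    For every gene the correlation ``r_i`` without that gene is recomputed by
    down-dating the sufficient sums, and the influence is
    ``z(r) - z(r_i)`` where ``r`` is the all-gene correlation. Genes whose
    removal leaves a degenerate (zero-variance) vector get a missing
    influence. The table is sorted by decreasing \\|influence\\|.
    """
    if not np.array_equal(d_i.gene_ids, d_j.gene_ids):
        raise ValueError("signatures are not aligned on the same genes")
    x, y = d_i.estimates, d_j.estimates
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 genes for leave-one-out influence")
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()

    def corr(sx_, sy_, sxx_, syy_, sxy_, n_):
        vx = sxx_ - sx_ ** 2 / n_
        vy = syy_ - sy_ ** 2 / n_
        if vx <= 0 or vy <= 0:
            return np.nan
        return (sxy_ - sx_ * sy_ / n_) / np.sqrt(vx * vy)

    r = corr(sx, sy, sxx, syy, sxy, n)
    if np.isnan(r):
        raise ValueError("overall correlation undefined (zero-variance signature)")
    m = n - 1
    r_loo = np.array([
        corr(sx - x[g], sy - y[g], sxx - x[g] ** 2, syy - y[g] ** 2,
             sxy - x[g] * y[g], m)
        for g in range(n)
    ])
    valid = ~np.isnan(r_loo)
    influence = np.full(n, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # |r_loo| may hit 1 on tiny fixtures
        influence[valid] = fisher_z(r) - fisher_z(np.clip(r_loo[valid], -1, 1))
    out = pd.DataFrame({
        "gene": d_i.gene_ids,
        "d_i": x,
        "d_j": y,
        "r_loo": r_loo,
        "influence": influence,
    })
    out.attrs["r"] = float(r)
    out.attrs["pair"] = (d_i.group, d_j.group)
    order = np.argsort(-np.abs(np.nan_to_num(out["influence"].to_numpy())),
                       kind="stable")
    return out.iloc[order].reset_index(drop=True)


def find_markers(em: ExpressionMatrix, meta: CellMeta, final_assignment,
                 extra_covariates: Optional[Sequence[str]] = None,
                 lfc_min: float = 0.0, adjp_max: float = 0.05,
                 min_detect_frac: float = 0.01) -> dict:
    """Cross-batch marker genes for every final cluster.

    Each cluster is contrasted against all remaining cells in a linear model
    with batch and scaled CDR (plus extras) as covariates; moderated
    statistics are thresholded at ``adjp_max`` (Benjamini-Hochberg-adjusted,
    per cluster) and ``lfc_min``. Returns cluster -> marker table sorted by
    p-value. Clusters of one cell are skipped with a warning.
    """
    labels = np.asarray(final_assignment).astype(str)
    if em.n_cells != len(labels):
        raise ValueError("final_assignment length does not match cells")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 final clusters for marker detection")
    detect = np.asarray((em.values > 0).sum(axis=0)).ravel() / em.n_cells
    gene_pos = np.flatnonzero(detect >= min_detect_frac)
    y = em.dense(genes=gene_pos)
    cdr = compute_cdr(em)
    batch = meta.batch
    extras = None
    if extra_covariates:
        extras = CellMeta(meta.df, batch_col=meta.batch_col,
                          extra_cols=tuple(extra_covariates)).extras()
    out = {}
    for c in uniq:
        n_c = int((labels == c).sum())
        if n_c < 2:
            warnings.warn(f"cluster {c!r} has {n_c} cell(s); skipping markers")
            continue
        group = np.where(labels == c, c, "(background)")
        design = build_design(group, batch=batch, cdr=cdr.scaled, extra=extras,
                              group_ref="(background)")
        fit = fit_ols(y, design, gene_ids=em.gene_ids[gene_pos])
        stats = eb_moderate_trend(fit, coef=f"group[{c}]")
        tab = stats.to_frame()
        tab = tab[(tab["adj_p"] <= adjp_max) & (tab["logFC"] >= lfc_min)]
        out[c] = tab.sort_values(["p", "gene"]).reset_index(drop=True)
    return out
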