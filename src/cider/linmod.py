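"""Per-gene linear modelling: design matrices, OLS fits, contrasts, moderation.

This is the engine behind the similarity metric: expression of each gene is
modelled as an additive combination of a group effect (the two compared
groups and a shared background), a batch effect, optional extra covariates
(donor, treatment, ...) and the scaled cellular detection rate. With the
background as the reference level, a group's contrast against background is
simply its coefficient column: the differential-expression signature.

Empirical-Bayes moderation follows the limma-trend idea: a lowess fit of the
log residual variance against mean expression supplies a per-gene prior
variance, a method-of-moments estimate on the log-variance residuals supplies
the prior degrees of freedom, and the posterior variance is the
df-weighted blend of the two.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AliasedDesignError",
    "DesignMatrix",
    "FitResult",
    "DESignature",
    "ModeratedStats",
    "build_design",
    "fit_ols",
    "contrast_estimates",
    "eb_moderate_trend",
]


class AliasedDesignError(ValueError):
    """A group coefficient of interest is not estimable (aliased columns)."""


@dataclass
class DesignMatrix:
    """Full-column-rank design matrix with named, typed columns.

    ``term_map`` labels each column as intercept / group-level / batch-level /
    covariate-level / cdr. ``group_ref`` records the reference level of the
    group factor (the shared background), whose contrast is identically zero.
    """

    matrix: np.ndarray
    column_names: list
    term_map: dict
    group_ref: str

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def _dummies(values: np.ndarray, prefix: str, term: str, drop_level):
    levels = sorted(set(values))
    cols, names, terms = [], [], []
    for lvl in levels:
        if lvl == drop_level:
            continue
        cols.append((values == lvl).astype(float))
        names.append(f"{prefix}[{lvl}]")
        terms.append(term)
    return cols, names, terms


def build_design(group_labels, batch=None, cdr=None, extra: Optional[dict] = None,
                 group_ref: str = "background") -> DesignMatrix:
    """Treatment-coded design for group + batch + covariates + scaled CDR.

    Parameters
    ----------
    group_labels
        Per-cell group assignment; ``group_ref`` (the background) is the
        reference level and gets no column.
    batch
        Per-cell batch labels; the first (sorted) level is the reference.
        A single-level batch contributes no columns.
    cdr
        Per-cell scaled cellular detection rate (numeric column), or None.
    extra
        Mapping of covariate name -> per-cell categorical labels (e.g. donor
        nested in species: the dummies span within-reference contrasts and
        redundant columns are dropped).

    Notes
    -----
    Columns that are constant or linearly dependent on earlier columns are
    dropped with a warning, scanning in the order intercept, group, batch,
    covariates, cdr — so covariates are dropped before batch and batch before
    group, keeping the group effect of interest estimable whenever possible.
    A dependent *group* column raises :class:`AliasedDesignError`.
    """
    group_labels = np.asarray(group_labels, dtype=object)
    n = len(group_labels)
    cols = [np.ones(n)]
    names = ["intercept"]
    terms = ["intercept"]

    c, nm, t = _dummies(group_labels, "group", "group-level", group_ref)
    cols += c; names += nm; terms += t
    if batch is not None:
        batch = np.asarray(batch, dtype=object)
        blevels = sorted(set(batch))
        c, nm, t = _dummies(batch, "batch", "batch-level", blevels[0])
        cols += c; names += nm; terms += t
    for name, values in (extra or {}).items():
        values = np.asarray(values, dtype=object)
        lv = sorted(set(values))
        c, nm, t = _dummies(values, name, "covariate-level", lv[0])
        cols += c; names += nm; terms += t
    if cdr is not None:
        cols.append(np.asarray(cdr, dtype=float))
        names.append("cdr")
        terms.append("cdr")

    # greedy rank-preserving scan: keep a column iff it adds rank
    kept_q = np.empty((n, 0))
    kept_cols, kept_names, kept_terms = [], [], []
    for col, name, term in zip(cols, names, terms):
        if term != "intercept" and np.ptp(col) == 0:
            _drop(name, term, "constant")
            continue
        resid = col - kept_q @ (kept_q.T @ col)
        if np.linalg.norm(resid) <= 1e-10 * max(np.linalg.norm(col), 1.0):
            _drop(name, term, "linearly dependent")
            continue
        kept_cols.append(col)
        kept_names.append(name)
        kept_terms.append(term)
        kept_q = np.column_stack([kept_q, resid / np.linalg.norm(resid)])
    return DesignMatrix(
        matrix=np.column_stack(kept_cols),
        column_names=kept_names,
        term_map=dict(zip(kept_names, kept_terms)),
        group_ref=group_ref,
    )


def _drop(name: str, term: str, why: str) -> None:
    if term == "group-level":
        raise AliasedDesignError(
            f"group column {name!r} is {why}: the group effect is confounded "
            "with earlier design columns (e.g. batch) and not estimable"
        )
    warnings.warn(f"dropping {why} design column {name!r}")
    logger.info("design: dropped %s column %s", why, name)


@dataclass
class FitResult:
    """Per-gene OLS estimates sharing one design.

    ``coefficients`` is genes x p; ``cov_unscaled`` is (X'X)^-1, shared by all
    genes; ``sigma2`` the residual variance with ``df_residual`` degrees of
    freedom; ``mean_expr`` the per-gene mean of the response.
    """

    coefficients: np.ndarray
    sigma2: np.ndarray
    df_residual: int
    mean_expr: np.ndarray
    design: DesignMatrix
    gene_ids: np.ndarray
    cov_unscaled: np.ndarray


@dataclass
class DESignature:
    """Per-gene contrast estimates (log2 fold-changes) of one group vs background."""

    estimates: np.ndarray
    gene_ids: np.ndarray
    group: str
    background: str

    def __len__(self) -> int:
        return len(self.estimates)


@dataclass
class ModeratedStats:
    """Empirical-Bayes moderated statistics for one contrast."""

    gene_ids: np.ndarray
    logFC: np.ndarray
    t: np.ndarray
    p_value: np.ndarray
    adjusted_p: np.ndarray
    posterior_var: np.ndarray
    prior_df: float
    prior_var: np.ndarray
    df_total: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "gene": self.gene_ids,
            "logFC": self.logFC,
            "t": self.t,
            "p": self.p_value,
            "adj_p": self.adjusted_p,
        })


def fit_ols(y, design: DesignMatrix, gene_ids=None) -> FitResult:
    """Fit ordinary least squares for every gene against a shared design.

    A single QR factorisation of the design is reused across genes.
    ``y`` is cells x genes (dense or sparse).
    """
    if sp.issparse(y):
        y = np.asarray(y.todense())
    y = np.asarray(y, dtype=float)
    x = design.matrix
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError(f"response has {y.shape[0]} rows, design has {n}")
    df = n - p
    if df <= 0:
        raise ValueError(f"df_residual = {n} - {p} <= 0")
    q, r = np.linalg.qr(x)
    qty = q.T @ y
    coef = solve_triangular(r, qty)            # p x genes
    resid = y - q @ qty
    rss = np.einsum("ij,ij->j", resid, resid)
    rinv = solve_triangular(r, np.eye(p))
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(y.shape[1])], dtype=object)
    return FitResult(
        coefficients=coef.T,
        sigma2=rss / df,
        df_residual=df,
        mean_expr=y.mean(axis=0),
        design=design,
        gene_ids=np.asarray(gene_ids, dtype=object),
        cov_unscaled=rinv @ rinv.T,
    )


def _group_col(design: DesignMatrix, group: str) -> int:
    name = f"group[{group}]"
    if name not in design.column_names:
        raise ValueError(f"unknown group label {group!r}; design has "
                         f"{[c for c in design.column_names if c.startswith('group[')]}")
    return design.column_names.index(name)


def contrast_estimates(fit: FitResult, group: str) -> DESignature:
    """Extract the DE signature: the contrast of ``group`` minus background.

    With background as the reference level of treatment coding, this contrast
    equals the group's coefficient column. The background itself contrasts to
    an all-zero signature.
    """
    ref = fit.design.group_ref
    if group == ref:
        est = np.zeros(len(fit.gene_ids))
    else:
        est = fit.coefficients[:, _group_col(fit.design, group)].copy()
    return DESignature(estimates=est, gene_ids=fit.gene_ids, group=group,
                       background=ref)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y (Smyth-style)
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def eb_moderate_trend(fit: FitResult, coef: Optional[str] = None,
                      lowess_frac: float = 0.5) -> ModeratedStats:
    """Moderated t-statistics with a mean-variance trend prior.

    The prior variance for each gene is the lowess fit of log residual
    variance against mean expression evaluated at that gene's mean; the prior
    degrees of freedom come from a method-of-moments fit on the log-variance
    residuals around the trend. The posterior variance is the
    df-weighted average of prior and observed variances, and p-values use a
    t distribution with ``df_residual + prior_df`` degrees of freedom,
    Benjamini-Hochberg adjusted.

    ``coef`` names the tested coefficient (default: the first group column).
    """
    if coef is None:
        group_cols = [c for c in fit.design.column_names
                      if fit.design.term_map[c] == "group-level"]
        if not group_cols:
            raise ValueError("no group coefficient in design; pass coef explicitly")
        coef = group_cols[0]
    if coef not in fit.design.column_names:
        raise ValueError(f"unknown coefficient {coef!r}")
    j = fit.design.column_names.index(coef)
    logfc = fit.coefficients[:, j]
    vc = fit.cov_unscaled[j, j]
    s2 = np.maximum(fit.sigma2, 1e-12)
    df = fit.df_residual
    ngenes = len(s2)

    if ngenes < 10:
        warnings.warn("fewer than 10 genes: falling back to unmoderated t")
        post = s2
        d0 = 0.0
        s02 = s2.copy()
    else:
        z = np.log(s2)
        ztrend = lowess(z, fit.mean_expr, frac=lowess_frac, return_sorted=False)
        s02 = np.exp(ztrend)
        e = z - ztrend
        evar = e.var(ddof=1) - polygamma(1, df / 2.0)
        if evar > 0:
            d0 = 2.0 * _trigamma_inverse(float(evar))
            post = (d0 * s02 + df * s2) / (d0 + df)
        else:
            d0 = np.inf
            post = s02
    df_total = df + d0
    t = logfc / np.sqrt(post * vc)
    p = 2.0 * stats.t.sf(np.abs(t), df_total if np.isfinite(df_total) else np.inf)
    adj = multipletests(p, method="fdr_bh")[1]
    return ModeratedStats(
        gene_ids=fit.gene_ids, logFC=logfc, t=t, p_value=p, adjusted_p=adj,
        posterior_var=post, prior_df=float(d0), prior_var=s02,
        df_total=float(df_total),
    )
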