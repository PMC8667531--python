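"""Gamma-Poisson simulator of multi-batch scRNA-seq counts.

The generative model mirrors the additive-effect view the clustering method
is built on: on the log2 scale, a gene's expected expression is a base level
plus a population (cluster) effect, a batch effect and optional nested
covariate effects, i.e.

    count[i, j] ~ Poisson(L_i * lambda_j * 2^{delta[j, pop(i)]}
                          * 2^{eps[j, batch(i)]} * 2^{nested effects}),

with gene base means lambda_j ~ Gamma, library-size factors L_i ~ LogNormal,
population effects delta nonzero for a DE fraction of genes, and batch
effects eps hitting all genes — the asymmetry that confounds naive
clustering but cancels out of confounder-adjusted DE signatures. Dropout
beyond Poisson sampling, doublets and trajectories are not modelled.

Every scenario is fully reproducible from its seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CellMeta, CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "dataset2_scenario",
    "overcorrection_fixture",
]


@dataclass
class SimConfig:
    """Configuration of one simulation.

    ``composition`` maps batch -> {group -> n_cells}; a missing (batch,
    group) entry means that population is absent from that batch.
    ``de_prob`` is the fraction of genes carrying a population effect
    (log2 effects drawn from N(0, de_sigma)); batch effects N(0, batch_sigma)
    apply to every gene. ``nested`` optionally adds per-batch nested
    covariates, e.g. donors within batch: name -> (levels per batch, sigma).
    """

    composition: dict
    n_genes: int = 1000
    de_prob: float = 0.1
    de_sigma: float = 1.0
    batch_sigma: float = 0.5
    gene_mean_shape: float = 0.6
    gene_mean_scale: float = 4.0
    lib_sigma: float = 0.35
    nested: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in [("de_prob", self.de_prob), ("de_sigma", self.de_sigma),
                          ("batch_sigma", self.batch_sigma),
                          ("lib_sigma", self.lib_sigma)]:
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.de_prob <= 1):
            raise ValueError("de_prob must be in [0, 1]")
        total = sum(n for groups in self.composition.values()
                    for n in groups.values())
        if total <= 0:
            raise ValueError("composition has no cells")

    @property
    def batches(self) -> list:
        return sorted(self.composition)

    @property
    def groups(self) -> list:
        return sorted({g for d in self.composition.values() for g in d})


@dataclass
class SimTruth:
    """Ground truth of one simulation: per-cell labels and per-gene factors."""

    cells: pd.DataFrame                  # population, batch (+ covariates)
    group_log2_effects: pd.DataFrame     # genes x groups (delta)
    batch_log2_effects: pd.DataFrame     # genes x batches (eps)
    gene_base_means: pd.Series = None    # lambda per gene

    @property
    def population(self) -> np.ndarray:
        return self.cells["population"].to_numpy()

    @property
    def batch(self) -> np.ndarray:
        return self.cells["batch"].to_numpy()


def simulate_counts(cfg: SimConfig):
    """Draw a multi-batch count matrix from the additive gamma-Poisson model.

    Returns
    -------
    (CountMatrix, CellMeta, SimTruth)
    """
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"gene{j:04d}" for j in range(cfg.n_genes)], dtype=object)
    lam = rng.gamma(cfg.gene_mean_shape, cfg.gene_mean_scale, size=cfg.n_genes)

    delta = np.zeros((cfg.n_genes, len(cfg.groups)))
    for gi, g in enumerate(cfg.groups):
        mask = rng.random(cfg.n_genes) < cfg.de_prob
        delta[mask, gi] = rng.normal(0.0, cfg.de_sigma, size=int(mask.sum()))
    eps = rng.normal(0.0, cfg.batch_sigma,
                     size=(cfg.n_genes, len(cfg.batches)))

    nested_effects = {}
    if cfg.nested:
        for name, (n_levels, sigma) in cfg.nested.items():
            nested_effects[name] = {
                (b, l): rng.normal(0.0, sigma, size=cfg.n_genes)
                for b in cfg.batches for l in range(n_levels)
            }

    blocks, rows = [], []
    for bi, b in enumerate(cfg.batches):
        for g in sorted(cfg.composition[b]):
            n = cfg.composition[b][g]
            if n == 0:
                continue
            gi = cfg.groups.index(g)
            mu = lam * 2.0 ** (delta[:, gi] + eps[:, bi])
            lib = rng.lognormal(0.0, cfg.lib_sigma, size=n)
            cell_mu = np.outer(lib, mu)
            if cfg.nested:
                for name, (n_levels, _) in cfg.nested.items():
                    lvl = rng.integers(0, n_levels, size=n)
                    for c in range(n):
                        cell_mu[c] *= 2.0 ** nested_effects[name][(b, lvl[c])]
                    lvl_names = [f"{b}_{name}{v}" for v in lvl]
            counts = rng.poisson(cell_mu)
            blocks.append(sp.csr_matrix(counts))
            for c in range(n):
                row = {"population": g, "batch": b}
                if cfg.nested:
                    for name in cfg.nested:
                        row[name] = lvl_names[c]
                rows.append(row)
    counts = sp.vstack(blocks).tocsr()
    cells = np.array([f"cell{i:05d}" for i in range(counts.shape[0])],
                     dtype=object)
    truth_cells = pd.DataFrame(rows, index=cells)
    cm = CountMatrix(counts, cells, genes)
    meta_cols = ["batch"] + (list(cfg.nested) if cfg.nested else [])
    meta = CellMeta(truth_cells[meta_cols].copy(), batch_col="batch",
                    extra_cols=tuple(cfg.nested) if cfg.nested else ())
    truth = SimTruth(
        cells=truth_cells,
        group_log2_effects=pd.DataFrame(delta, index=genes, columns=cfg.groups),
        batch_log2_effects=pd.DataFrame(eps, index=genes, columns=cfg.batches),
        gene_base_means=pd.Series(lam, index=genes),
    )
    return cm, meta, truth


DATASET2_COMPOSITION = {
    # five populations, three batches, with the canonical removal pattern:
    # batch 1 lacks groups 4 and 5, batch 2 lacks 1 and 5, batch 3 lacks 1 and 3
    "batch1": ["group1", "group2", "group3"],
    "batch2": ["group2", "group3", "group4"],
    "batch3": ["group2", "group4", "group5"],
}


def dataset2_scenario(seed: int = 0, cells_per_block: int = 250,
                      n_genes: int = 1000, de_prob: float = 0.1,
                      de_sigma: float = 2.0, batch_sigma: float = 0.5):
    """Non-identical-composition stress scenario: 5 populations x 3 batches.

    Each batch carries only three of the five populations (see
    ``DATASET2_COMPOSITION``); only group 2 is present everywhere, making it
    the cross-batch matchable population. Replicates with different seeds
    share the same truth structure.
    """
    comp = {b: {g: cells_per_block for g in gs}
            for b, gs in DATASET2_COMPOSITION.items()}
    cfg = SimConfig(composition=comp, n_genes=n_genes, de_prob=de_prob,
                    de_sigma=de_sigma, batch_sigma=batch_sigma, seed=seed)
    return simulate_counts(cfg)


def overcorrection_fixture(seed: int = 0, cells_per_block: int = 150,
                           n_genes: int = 1000, de_prob: float = 0.1,
                           de_sigma: float = 2.0, batch_sigma: float = 0.4,
                           blob_sd: float = 0.7):
    """Counts plus a deliberately overcorrected 2-d embedding.

    Four populations in two batches: populations 1 and 2 are shared,
    population 3 exists only in batch A and population 4 only in batch B.
    In the synthetic "corrected" embedding populations 3 and 4 are collapsed
    onto a single blob — the canonical false alignment, where two
    heterogeneous cell types, one from each batch, are merged — while
    populations 1 and 2 stay separate. The collapsed populations are
    guaranteed distinct in expression space: their true DE signatures
    correlate below 0.3 by construction (re-drawn otherwise).

    Returns
    -------
    (CountMatrix, CellMeta, embedding, SimTruth)
    """
    comp = {
        "batchA": {g: cells_per_block for g in ["pop1", "pop2", "pop3"]},
        "batchB": {g: cells_per_block for g in ["pop1", "pop2", "pop4"]},
    }
    for attempt in range(20):
        cfg = SimConfig(composition=comp, n_genes=n_genes, de_prob=de_prob,
                        de_sigma=de_sigma, batch_sigma=batch_sigma,
                        seed=seed + 7919 * attempt)
        cm, meta, truth = simulate_counts(cfg)
        d3 = truth.group_log2_effects["pop3"].to_numpy()
        d4 = truth.group_log2_effects["pop4"].to_numpy()
        if d3.std() == 0 or d4.std() == 0:
            continue
        if abs(np.corrcoef(d3, d4)[0, 1]) < 0.3:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw uncorrelated collapsed populations")

    centers = {"pop1": (0.0, 0.0), "pop2": (8.0, 0.0),
               "pop3": (4.0, 7.0), "pop4": (4.0, 7.0)}
    rng = np.random.default_rng(substream(seed))
    pops = truth.population
    embedding = np.array([centers[p] for p in pops], dtype=float)
    embedding += rng.normal(0.0, blob_sd, size=embedding.shape)
    return cm, meta, embedding, truth


def substream(seed: int) -> int:
    # embedding noise uses its own stream so count draws stay comparable
    return (seed * 2654435761 + 97) % (2 ** 31)
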