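"""Integration evaluation: partitioning, rejection probability, ARI, cLISI."""
import numpy as np
import pandas as pd
import pytest

from cider.core import CellMeta, lognormalize
from cider.evaluate import (ari, background_distribution, clisi,
                            clustering_metrics, empirical_rejection_probability,
                            evaluate_integration, mutual_nearest_anchor,
                            partition_corrected_space,
                            within_cluster_similarity)
from cider.simulate import SimConfig, overcorrection_fixture, simulate_counts


def _blobs(rng, n=200, d=2, sep=10.0):
    a = rng.normal(size=(n // 2, d))
    b = rng.normal(size=(n // 2, d)) + sep
    return np.vstack([a, b])


class TestPartition:
    def test_louvain_clusters_respect_blob_structure(self, rng):
        # communities may subdivide a blob, but never straddle the gap
        emb = _blobs(rng)
        labels = partition_corrected_space(emb, method="louvain", seed=0)
        assert len(set(labels)) >= 2
        assert set(labels[:100]).isdisjoint(set(labels[100:]))

    def test_two_blobs_two_clusters_hdbscan(self, rng):
        emb = _blobs(rng)
        labels = partition_corrected_space(emb, method="hdbscan",
                                           min_cluster_size=75)
        kept = labels[labels != "unclustered"]
        assert len(set(kept)) == 2

    def test_deterministic_given_seed(self, rng):
        emb = _blobs(rng)
        a = partition_corrected_space(emb, seed=5)
        b = partition_corrected_space(emb, seed=5)
        assert np.array_equal(a, b)

    def test_one_dimensional_embedding_rejected(self):
        with pytest.raises(ValueError, match="d >= 2"):
            partition_corrected_space(np.zeros((10, 1)))


class TestRejectionProbability:
    def test_observed_above_all_samples(self):
        bg = np.linspace(0.1, 0.9, 19)
        assert empirical_rejection_probability(0.95, bg) == pytest.approx(0.05)

    def test_observed_below_all_samples(self):
        bg = np.linspace(0.1, 0.9, 19)
        assert empirical_rejection_probability(0.05, bg) == pytest.approx(1.0)

    def test_observed_at_median(self):
        bg = np.linspace(0.1, 0.9, 19)
        p = empirical_rejection_probability(np.median(bg), bg)
        assert abs(p - 0.5) <= 1 / 20

    def test_empty_background_raises(self):
        with pytest.raises(ValueError, match="empty"):
            empirical_rejection_probability(0.5, [])

    def test_antitone_in_observed(self, rng):
        bg = rng.uniform(size=25)
        obs = np.sort(rng.uniform(size=10))
        ps = [empirical_rejection_probability(o, bg) for o in obs]
        assert np.all(np.diff(ps) <= 0)


def _brute_force_ari(a, b):
    """Pair-counting definition: (index - expected) / (max - expected)."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    same_a = np.equal.outer(a, a)
    same_b = np.equal.outer(b, b)
    iu = np.triu_indices(n, 1)
    n11 = int((same_a[iu] & same_b[iu]).sum())
    na = int(same_a[iu].sum())
    nb = int(same_b[iu].sum())
    npairs = n * (n - 1) // 2
    expected = na * nb / npairs
    maximum = (na + nb) / 2
    if maximum == expected:
        return 0.0
    return (n11 - expected) / (maximum - expected)


class TestARI:
    def test_identical_partitions(self):
        assert ari([1, 1, 2, 2], [5, 5, 9, 9]) == pytest.approx(1.0)

    def test_fixture_value_from_pair_enumeration(self):
        a, b = [1, 1, 2, 2], [1, 1, 2, 3]
        assert ari(a, b) == pytest.approx(_brute_force_ari(a, b))
        assert ari(a, b) == pytest.approx(0.571, abs=5e-3)

    def test_matches_bruteforce_on_random_labels(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 31))
            a = rng.integers(0, 4, size=n)
            b = rng.integers(0, 4, size=n)
            assert ari(a, b) == pytest.approx(_brute_force_ari(a, b), abs=1e-12)

    def test_degenerate_partitions_score_zero(self):
        assert ari([1] * 6, list(range(6))) == pytest.approx(0.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            ari([1, 2], [1, 2, 3])

    def test_helper_reports_both_metrics(self):
        out = clustering_metrics([1, 1, 2, 2], population=[1, 1, 2, 2],
                                 batch=[1, 2, 1, 2])
        assert out["ARI_population"] == pytest.approx(1.0)
        assert out["one_minus_ARI_batch"] == 1 - out["ARI_batch"]


def _reference_clisi(emb, labels, perplexity):
    """Independent slow implementation: fresh bisection per cell."""
    emb = np.asarray(emb, float)
    labels = np.asarray(labels)
    n = len(emb)
    uniq = np.unique(labels)
    k = min(n - 1, int(3 * perplexity))
    out = np.empty(n)
    for i in range(n):
        d2 = ((emb - emb[i]) ** 2).sum(1)
        order = np.argsort(d2, kind="stable")
        nb = order[order != i][:k]
        lo, hi, beta = 0.0, np.inf, 1.0
        for _ in range(200):
            w = np.exp(-beta * d2[nb])
            p = w / w.sum()
            h = -(p[p > 0] * np.log(p[p > 0])).sum()
            if abs(h - np.log(perplexity)) < 1e-9:
                break
            if h > np.log(perplexity):
                lo = beta
                beta = beta * 2 if np.isinf(hi) else (lo + hi) / 2
            else:
                hi = beta
                beta = (lo + hi) / 2
        simpson = sum(p[labels[nb] == u].sum() ** 2 for u in uniq)
        out[i] = 1.0 / simpson
    return out


class TestClisi:
    def test_single_label_is_one(self, rng):
        emb = rng.normal(size=(60, 2))
        assert np.allclose(clisi(emb, ["x"] * 60, perplexity=10), 1.0)

    def test_interleaved_two_labels_near_two(self):
        # perfectly interleaved symmetric labels on a line
        emb = np.column_stack([np.arange(100, dtype=float), np.zeros(100)])
        labels = np.array(["a", "b"] * 50)
        vals = clisi(emb, labels, perplexity=15)
        interior = vals[20:80]
        assert np.all(np.abs(interior - 2.0) < 0.05)

    def test_never_exceeds_label_count(self, rng):
        emb = rng.normal(size=(80, 3))
        labels = rng.choice(["a", "b", "c"], size=80)
        vals = clisi(emb, labels, perplexity=12)
        assert np.all(vals <= 3.0 + 1e-9)
        assert np.all(vals >= 1.0 - 1e-9)

    def test_matches_reference_implementation(self, rng):
        emb = rng.normal(size=(50, 2))
        labels = rng.choice(["a", "b"], size=50)
        got = clisi(emb, labels, perplexity=8)
        ref = _reference_clisi(emb, labels, perplexity=8)
        assert np.abs(got - ref).max() < 1e-6

    def test_perplexity_must_be_smaller_than_n(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            clisi(rng.normal(size=(10, 2)), ["a"] * 10, perplexity=10)


class TestWithinClusterSimilarity:
    def test_duplicated_batch_scores_near_one(self):
        """A batch copied verbatim: every cluster compares a group with its
        own duplicate, so similarity is essentially perfect."""
        cfg = SimConfig(composition={"b1": {"popA": 100, "popB": 100}},
                        n_genes=500, de_sigma=2.0, batch_sigma=0.0, seed=5)
        cm, meta, truth = simulate_counts(cfg)
        import scipy.sparse as sp
        from cider.core import CountMatrix
        counts2 = sp.vstack([cm.counts, cm.counts]).tocsr()
        cells2 = np.array([f"{c}_{b}" for b in ("b1", "b2")
                           for c in cm.cell_ids], dtype=object)
        cm2 = CountMatrix(counts2, cells2, cm.gene_ids)
        meta2 = CellMeta(pd.DataFrame(
            {"batch": ["b1"] * cm.n_cells + ["b2"] * cm.n_cells},
            index=cells2))
        em2 = lognormalize(cm2)
        clusters = np.tile(truth.population, 2)
        pairs, _, _ = within_cluster_similarity(em2, meta2, clusters, seed=1)
        assert (pairs["similarity"] > 0.9).all()
        assert (pairs["similarity"] <= 1.0).all()

    def test_single_batch_cluster_reported_non_evaluable(self):
        cfg = SimConfig(composition={"b1": {"popA": 60, "popB": 60},
                                     "b2": {"popA": 60}},
                        n_genes=500, de_sigma=2.0, batch_sigma=0.3, seed=6)
        cm, meta, truth = simulate_counts(cfg)
        em = lognormalize(cm)
        pairs, _, _ = within_cluster_similarity(em, meta, truth.population,
                                                seed=1)
        row = pairs[pairs["cluster"] == "popB"]
        assert not row["evaluable"].any()


class TestBackgroundDistribution:
    def test_deterministic_and_sized(self, sim_two_pop):
        em, meta, truth = sim_two_pop
        labels = truth.population
        _, sim, subs = within_cluster_similarity(em, meta, labels, seed=2)
        ia, ib = mutual_nearest_anchor(sim)
        kw = dict(background=subs, n_splits=5, seed=3)
        b1 = background_distribution(em, meta, subs[ia], subs[ib], **kw)
        b2 = background_distribution(em, meta, subs[ia], subs[ib], **kw)
        assert np.array_equal(b1, b2)
        assert len(b1) == 5

    def test_single_split_still_valid(self, sim_two_pop):
        em, meta, truth = sim_two_pop
        _, sim, subs = within_cluster_similarity(em, meta, truth.population,
                                                 seed=2)
        ia, ib = mutual_nearest_anchor(sim)
        bg = background_distribution(em, meta, subs[ia], subs[ib],
                                     background=subs, n_splits=1, seed=3)
        assert len(bg) == 1 and np.isfinite(bg[0])

    def test_background_sits_above_cross_population_pairs(self, sim_two_pop):
        em, meta, truth = sim_two_pop
        _, sim, subs = within_cluster_similarity(em, meta, truth.population,
                                                 seed=2)
        ia, ib = mutual_nearest_anchor(sim)
        bg = background_distribution(em, meta, subs[ia], subs[ib],
                                     background=subs, n_splits=10, seed=3)
        cross = [sim.S[i, j] for i in range(len(subs))
                 for j in range(i + 1, len(subs))
                 if sim.mask[i, j]
                 and subs[i].label.split("|")[0] != subs[j].label.split("|")[0]]
        assert min(bg) > max(cross)

    def test_too_small_anchor_raises(self, sim_two_pop):
        em, meta, truth = sim_two_pop
        from cider.metric import InitialCluster
        a = InitialCluster("a", "b1", np.arange(10))
        b = InitialCluster("b", "b2", np.arange(10, 20))
        with pytest.raises(ValueError, match="larger clusters"):
            background_distribution(em, meta, a, b, n_splits=2, seed=0)


class TestEvaluateIntegration:
    def test_overcorrected_cluster_flagged(self):
        """The collapsed cluster shows the three-way signal: lowest
        similarity, top rejection probability, highest mean cLISI."""
        cm, meta, emb, truth = overcorrection_fixture(seed=11)
        em = lognormalize(cm)
        rep = evaluate_integration(em, meta, embedding=emb, method="hdbscan",
                                   seed=11)
        pc = rep.per_cell.copy()
        pc["clisi"] = clisi(emb, truth.population)
        df = rep.clusters.set_index("cluster")
        df["mean_clisi"] = pc.groupby("cluster")["clisi"].mean()
        lab = pd.crosstab(pc["cluster"], truth.population)
        collapsed = lab[["pop3", "pop4"]].sum(1).idxmax()
        assert df.loc[collapsed, "mean_similarity"] == df["mean_similarity"].min()
        assert df.loc[collapsed, "p_reject"] == df["p_reject"].max()
        assert df.loc[collapsed, "mean_clisi"] == df["mean_clisi"].max()

    def test_per_cell_scores_constant_within_cluster(self):
        cm, meta, emb, truth = overcorrection_fixture(seed=12)
        em = lognormalize(cm)
        rep = evaluate_integration(em, meta, embedding=emb, method="hdbscan",
                                   seed=12)
        per = rep.per_cell.dropna(subset=["similarity"])
        assert (per.groupby("cluster")["similarity"].nunique() == 1).all()
        assert rep.pairs["p_reject"].dropna().between(0, 1).all()
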