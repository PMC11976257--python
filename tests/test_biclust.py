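import itertools

import numpy as np
import pytest

from methpattern import (
    consensus_biclustering,
    coherence_permutation_p,
    extract_biclusters,
    hypergeometric_overlap_p,
    nmf_factorize,
)
from methpattern.biclust import Bicluster, bicluster_coherence, coherence_gain


class TestNmfFactorize:
    def test_rank1_outer_product_recovered_exactly(self):
        w = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        h = np.array([0.2, 0.4, 0.6, 0.8])
        fr = nmf_factorize(np.outer(w, h), rank=1, seed=0, max_iter=1000, tol=0.0)
        assert fr.error_trace[-1] <= 1e-6

    def test_error_trace_non_increasing(self):
        rng = np.random.default_rng(0)
        for seed in range(3):
            fr = nmf_factorize(rng.uniform(size=(12, 9)), rank=3, seed=seed)
            diffs = np.diff(fr.error_trace)
            assert np.all(diffs <= 1e-10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        V = rng.uniform(size=(10, 8))
        a = nmf_factorize(V, rank=3, seed=11)
        b = nmf_factorize(V, rank=3, seed=11)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    def test_factors_nonnegative(self):
        rng = np.random.default_rng(2)
        fr = nmf_factorize(rng.uniform(size=(15, 6)), rank=4, seed=0)
        assert fr.W.min() >= 0 and fr.H.min() >= 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            nmf_factorize(np.array([[-0.1, 0.2], [0.3, 0.4]]), rank=1)
        with pytest.raises(ValueError, match="rank"):
            nmf_factorize(np.ones((3, 3)), rank=0)


class TestExtractBiclusters:
    def _block_matrix(self):
        V = np.full((10, 10), 0.05)
        V[:5, :5] = 0.9
        V[5:, 5:] = 0.9
        return V

    def test_recovers_planted_blocks(self):
        V = self._block_matrix()
        rows = [f"cg{i}" for i in range(10)]
        cols = [f"S{j}" for j in range(10)]
        fr = nmf_factorize(V, rank=2, seed=0, max_iter=500)
        bics = extract_biclusters(fr, rows, cols, V=V, row_thresh=0.5, col_thresh=0.5)
        found = {(frozenset(b.cpg_ids), frozenset(b.sample_ids)) for b in bics}
        expected = {
            (frozenset(rows[:5]), frozenset(cols[:5])),
            (frozenset(rows[5:]), frozenset(cols[5:])),
        }
        assert found == expected

    def test_zero_thresholds_include_all_loaded(self):
        V = self._block_matrix()
        rows = [f"cg{i}" for i in range(10)]
        cols = [f"S{j}" for j in range(10)]
        fr = nmf_factorize(V, rank=2, seed=0)
        bics = extract_biclusters(fr, rows, cols, row_thresh=0.0, col_thresh=0.0)
        assert all(len(b.cpg_ids) == 10 and len(b.sample_ids) == 10 for b in bics)

    def test_zero_loading_row_excluded(self):
        fr = nmf_factorize(self._block_matrix(), rank=2, seed=0)
        fr.W[3, :] = 0.0
        bics = extract_biclusters(
            fr, [f"cg{i}" for i in range(10)], [f"S{j}" for j in range(10)]
        )
        assert all("cg3" not in b.cpg_ids for b in bics)

    def test_memberships_lie_in_unit_interval(self):
        rng = np.random.default_rng(0)
        fr = nmf_factorize(rng.uniform(size=(20, 12)), rank=3, seed=0)
        bics = extract_biclusters(
            fr,
            [f"cg{i}" for i in range(20)],
            [f"S{j}" for j in range(12)],
            row_thresh=0.3,
            col_thresh=0.3,
        )
        for b in bics:
            assert all(0 <= v <= 1 for v in b.row_membership.values())
            assert all(0 <= v <= 1 for v in b.col_membership.values())


def brute_force_overlap_p(a, b, universe):
    """P(|A & D| >= |A & B|) over all draws D of size |B| from the universe."""
    a, b, u = set(a), set(b), sorted(universe)
    k = len(a & b)
    hits = total = 0
    for draw in itertools.combinations(u, len(b)):
        total += 1
        if len(a & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometricOverlap:
    def test_identical_five_sets_in_ten_universe(self):
        u = list(range(10))
        a = set(range(5))
        p = hypergeometric_overlap_p(a, a, u)
        assert p == pytest.approx(1 / 252, rel=1e-12)
        assert p == pytest.approx(brute_force_overlap_p(a, a, u), rel=1e-12)

    def test_zero_overlap_gives_one(self):
        assert hypergeometric_overlap_p({0, 1}, {2, 3}, set(range(8))) == 1.0

    def test_full_universe_set_gives_one(self):
        u = set(range(9))
        assert hypergeometric_overlap_p(u, {0, 3}, u) == pytest.approx(1.0)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(8):
            n = int(rng.integers(5, 13))
            u = list(range(n))
            a = set(rng.choice(n, size=rng.integers(1, n), replace=False).tolist())
            b = set(rng.choice(n, size=rng.integers(1, n), replace=False).tolist())
            assert hypergeometric_overlap_p(a, b, u) == pytest.approx(
                brute_force_overlap_p(a, b, u), abs=1e-12
            )

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_overlap_p({99}, {1}, {1, 2})


def _manual_bicluster(rows, cols, n, m):
    return Bicluster(
        cpg_ids=[f"r{i}" for i in rows],
        sample_ids=[f"c{j}" for j in cols],
        row_membership={f"r{i}": 1.0 for i in rows},
        col_membership={f"c{j}": 1.0 for j in cols},
        factor=0,
        rank=1,
        row_idx=np.asarray(rows),
        col_idx=np.asarray(cols),
    )


class TestCoherencePermutation:
    def test_constant_matrix_gives_p_one(self):
        V = np.full((12, 12), 0.4)
        bic = _manual_bicluster(range(4), range(4), 12, 12)
        bic.coherence = bicluster_coherence(V[:4, :4])
        assert coherence_permutation_p(bic, V, n_perm=99, seed=0) == 1.0

    def test_planted_block_detected(self):
        rng = np.random.default_rng(123)
        V = rng.uniform(size=(30, 30))
        V[:5, :5] = 0.9
        bic = _manual_bicluster(range(5), range(5), 30, 30)
        bic.coherence = bicluster_coherence(V[:5, :5])
        assert coherence_permutation_p(bic, V, n_perm=999, seed=1) <= 0.01

    def test_single_permutation_add_one_rule(self):
        rng = np.random.default_rng(5)
        V = rng.uniform(size=(10, 10))
        bic = _manual_bicluster(range(3), range(3), 10, 10)
        bic.coherence = bicluster_coherence(V[:3, :3])
        assert coherence_permutation_p(bic, V, n_perm=1, seed=2) in (0.5, 1.0)

    def test_oversized_bicluster_rejected(self):
        V = np.full((4, 4), 0.5)
        bic = _manual_bicluster(range(4), range(4), 4, 4)
        bic.coherence = 0.0
        with pytest.raises(ValueError, match="exceed"):
            coherence_permutation_p(bic, np.full((3, 3), 0.5), n_perm=10)

    def test_gain_zero_for_flat_rows(self):
        V = np.tile(np.linspace(0.1, 0.9, 8)[:, None], (1, 10))
        assert coherence_gain(V, np.arange(3), np.arange(4)) == pytest.approx(0.0)


@pytest.fixture(scope="module")
def planted_consensus(default_cohort):
    """Consensus biclustering of the default planted cohort, ranks 4-8."""
    m, _, truth = default_cohort
    bics, sig = consensus_biclustering(
        m.values.to_numpy(), m.cpg_ids, m.sample_ids, ranks=range(4, 9), seeds=5,
        n_perm=199, master_seed=21,
    )
    return m, truth, bics, sig


class TestConsensusBiclustering:
    def test_recovers_planted_structured_cpgs(self, planted_consensus):
        m, truth, bics, sig = planted_consensus
        structured = set(truth.structured_cpgs())
        pred = set(sig.cpgs)
        assert pred, "no significant CpGs found"
        recall = len(pred & structured) / len(structured)
        contamination = len(pred - structured) / len(pred)
        assert recall >= 0.9
        assert contamination <= 0.1

    def test_shuffled_matrix_yields_nothing(self):
        from methpattern import simulate_cohort

        m, _, _ = simulate_cohort(n_cpgs=500, n_samples=60, seed=13)
        V = m.values.to_numpy().copy()
        rng = np.random.default_rng(31)
        for i in range(V.shape[0]):
            V[i] = V[i, rng.permutation(V.shape[1])]
        bics, sig = consensus_biclustering(
            V, m.cpg_ids, m.sample_ids, ranks=(3, 4, 5), seeds=3,
            n_perm=99, master_seed=17,
        )
        assert sum(b.significant for b in bics) == 0
        assert sig.cpgs == [] and sig.samples == []

    def test_rank_one_boundary(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(size=(30, 20))
        bics, sig = consensus_biclustering(
            V,
            [f"cg{i}" for i in range(30)],
            [f"S{j}" for j in range(20)],
            ranks=(1,),
            seeds=2,
            n_perm=49,
            master_seed=3,
            n_null_shuffles=3,
        )
        assert len(bics) <= 1
        for b in bics:
            assert b.consensus_support is not None

    def test_raising_support_min_never_enlarges_set(self, planted_consensus):
        m, _, bics, sig = planted_consensus
        # Re-derive the significant set at stricter support from the same
        # scored references: the verdict is monotone in support_min.
        for smin in (0.6, 0.8, 0.95):
            tighter = {
                c
                for b in bics
                if b.significant and b.consensus_support >= smin
                for c in b.cpg_ids
            }
            assert tighter <= set(sig.cpgs)

    def test_significant_verdict_respects_thresholds(self, planted_consensus):
        _, _, bics, _ = planted_consensus
        for b in bics:
            if b.significant:
                assert b.p_consensus <= 0.01
                assert b.p_coherence <= 0.01
                assert b.consensus_support >= 0.5
            assert b.cpg_ids and b.sample_ids

    def test_deterministic_given_master_seed(self):
        rng = np.random.default_rng(8)
        V = rng.uniform(size=(40, 25))
        args = dict(ranks=(2, 3), seeds=2, n_perm=49, n_null_shuffles=3)
        ids = ([f"cg{i}" for i in range(40)], [f"S{j}" for j in range(25)])
        b1, s1 = consensus_biclustering(V, *ids, master_seed=5, **args)
        b2, s2 = consensus_biclustering(V, *ids, master_seed=5, **args)
        assert s1.cpgs == s2.cpgs and s1.samples == s2.samples
        assert [b.p_coherence for b in b1] == [b.p_coherence for b in b2]
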