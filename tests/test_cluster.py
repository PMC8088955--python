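from itertools import combinations

import numpy as np
import pytest

from eaccd import (DissimilarityMatrix, EnsembleConfig, build_initial_matrix,
                   cut_dendrogram, ensemble_learn, minimax_linkage, pam)
from eaccd.records import CombinationCohort


def _matrix(values, labels=None):
    values = np.asarray(values, float)
    labels = labels or [str(i) for i in range(values.shape[0])]
    return DissimilarityMatrix(labels=labels, values=values)


def _random_dissim(rng, n):
    a = rng.uniform(0.01, 1.0, (n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def two_block_matrix(n1=4, n2=4, within=0.05, between=0.9):
    n = n1 + n2
    d = np.full((n, n), between)
    d[:n1, :n1] = within
    d[n1:, n1:] = within
    np.fill_diagonal(d, 0.0)
    return _matrix(d)


def _cohort(label, times, events):
    times = np.asarray(times, float)
    return CombinationCohort(label=label, levels={}, times=times,
                             events=np.asarray(events, int),
                             member_ids=[f"{label}-{i}" for i in range(times.size)])


class TestDissimilarityMatrix:
    def test_rejects_asymmetry(self):
        with pytest.raises(ValueError):
            _matrix([[0, 0.2], [0.3, 0]])

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError):
            _matrix([[0.1, 0.2], [0.2, 0]])


class TestInitialMatrix:
    def test_same_distribution_near_zero(self):
        rng = np.random.default_rng(0)
        a = _cohort("a", np.ceil(rng.exponential(30, 3000)), np.ones(3000))
        b = _cohort("b", np.ceil(rng.exponential(30, 3000)), np.ones(3000))
        m = build_initial_matrix([a, b])
        assert m.values[0, 1] < 0.05

    def test_hazard_tier_ordering(self):
        rng = np.random.default_rng(1)
        cohorts = [
            _cohort(f"t{i}", np.ceil(rng.exponential(1 / lam, 2000)), np.ones(2000))
            for i, lam in enumerate([0.01, 0.03, 0.09])
        ]
        m = build_initial_matrix(cohorts)
        assert m.values[0, 2] > m.values[0, 1]
        assert m.values[0, 2] > m.values[1, 2]

    def test_needs_two_cohorts(self):
        with pytest.raises(ValueError):
            build_initial_matrix([_cohort("a", [1.0], [1])])


class TestPam:
    def test_k_equals_n_zero_objective(self):
        d = _matrix(_random_dissim(np.random.default_rng(2), 6))
        labels = pam(d, 6)
        assert len(set(labels)) == 6

    def test_two_block_exact_recovery_vs_enumeration(self):
        m = two_block_matrix()
        labels = pam(m, 2)
        # enumeration oracle over all 2-medoid subsets
        best_obj, best_part = np.inf, None
        D = m.values
        for meds in combinations(range(8), 2):
            assign = np.argmin(D[np.array(meds)], axis=0)
            obj = D[np.array(meds)][assign, np.arange(8)].sum()
            if obj < best_obj - 1e-12:
                best_obj, best_part = obj, assign
        assert (labels == best_part).all()
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_swap_never_worse_than_build(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 15))
            D = _random_dissim(rng, n)
            k = int(rng.integers(2, n))
            labels = pam(_matrix(D), k)
            # final objective must beat every single-medoid-per-cluster bound
            obj = 0.0
            for c in set(labels):
                idx = np.flatnonzero(labels == c)
                obj += D[np.ix_(idx, idx)].sum(axis=1).min()
            # BUILD-only objective
            meds = [int(np.argmin(D.sum(axis=1)))]
            dnear = D[meds[0]].copy()
            while len(meds) < k:
                gains = np.maximum(dnear[None, :] - D, 0).sum(axis=1)
                gains[meds] = -np.inf
                c = int(np.argmax(gains))
                meds.append(c)
                dnear = np.minimum(dnear, D[c])
            assert obj <= dnear.sum() + 1e-9

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            pam(two_block_matrix(), 9)

    def test_deterministic(self):
        D = _matrix(_random_dissim(np.random.default_rng(4), 10))
        assert (pam(D, 3) == pam(D, 3)).all()


class TestEnsemble:
    def test_delta_bounds_and_symmetry(self):
        m = two_block_matrix()
        delta = ensemble_learn(m, EnsembleConfig(runs=50, seed=0))
        v = delta.values
        assert ((v >= 0) & (v <= 1)).all()
        assert np.allclose(v, v.T)
        assert (np.diag(v) == 0).all()

    def test_two_blocks_fixed_k(self):
        m = two_block_matrix()
        delta = ensemble_learn(m, EnsembleConfig(runs=30, k_range=(2, 2), seed=1))
        assert (delta.values[:4, :4] == 0).all()
        assert (delta.values[4:, 4:] == 0).all()
        assert (delta.values[:4, 4:] == 1).all()

    def test_duplicate_rows_never_separated(self):
        # items 1 and 2 are exact duplicates inside the first block
        m = two_block_matrix()
        v = m.values.copy()
        v[1] = v[2]
        v[:, 1] = v[:, 2]
        v[1, 2] = v[2, 1] = 0.0
        v[1, 1] = 0.0
        m = _matrix(v)
        delta = ensemble_learn(m, EnsembleConfig(runs=40, k_range=(2, 3), seed=2))
        assert delta.values[1, 2] == 0.0

    def test_identical_seed_identical_delta(self):
        m = two_block_matrix(3, 5)
        d1 = ensemble_learn(m, EnsembleConfig(runs=25, seed=9))
        d2 = ensemble_learn(m, EnsembleConfig(runs=25, seed=9))
        assert (d1.values == d2.values).all()

    def test_square_transform_leaves_partitions_unchanged(self):
        m = two_block_matrix(4, 5, within=0.1, between=0.8)
        sq = _matrix(m.values ** 2)
        for k in (2, 3, 4):
            assert (pam(m, k) == pam(sq, k)).all()


def brute_force_minimax_merge(D, clusters):
    """Independent recomputation: best merge among current clusters."""
    best = None
    for a, b in combinations(range(len(clusters)), 2):
        union = sorted(clusters[a] + clusters[b])
        r = min(max(D[c][x] for x in union) for c in union)
        key = (r, min(clusters[a][0], clusters[b][0]),
               max(clusters[a][0], clusters[b][0]))
        if best is None or key < best[0]:
            best = (key, a, b, r)
    return best[1], best[2], best[3]


class TestMinimaxLinkage:
    def test_two_items(self):
        d = _matrix([[0, 0.4], [0.4, 0]])
        dend = minimax_linkage(d)
        assert len(dend.merges) == 1
        assert dend.merges[0].height == pytest.approx(0.4)

    def test_three_item_hand_example(self):
        d = _matrix([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        dend = minimax_linkage(d)
        assert dend.merges[0].height == pytest.approx(0.1)
        assert sorted([dend.merges[0].left, dend.merges[0].right]) == [0, 1]
        assert dend.merges[1].height == pytest.approx(0.9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            D = _random_dissim(rng, n)
            dend = minimax_linkage(_matrix(D))
            clusters = [[i] for i in range(n)]
            for step, merge in enumerate(dend.merges):
                a, b, r = brute_force_minimax_merge(D, clusters)
                assert merge.height == pytest.approx(r, abs=1e-12)
                merged = sorted(clusters[a] + clusters[b])
                assert dend.members(n + step) == merged
                clusters = [c for i, c in enumerate(clusters)
                            if i not in (a, b)] + [merged]

    def test_prototype_certificate(self):
        rng = np.random.default_rng(7)
        D = _random_dissim(rng, 8)
        dend = minimax_linkage(_matrix(D))
        for i, m in enumerate(dend.merges):
            members = dend.members(8 + i)
            radius = max(D[m.prototype][x] for x in members)
            assert m.prototype in members
            assert radius == pytest.approx(m.height, abs=1e-12)

    def test_newick_has_all_leaves(self):
        d = two_block_matrix(2, 3)
        nwk = minimax_linkage(d).to_newick()
        assert nwk.endswith(";")
        for lab in d.labels:
            assert lab in nwk


class TestCut:
    dend = minimax_linkage(_matrix([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]]))

    def test_one_group(self):
        cut = cut_dendrogram(self.dend, 1)
        assert len(cut) == 1 and cut[0]["members"] == [0, 1, 2]

    def test_all_singletons(self):
        cut = cut_dendrogram(self.dend, 3)
        assert [c["members"] for c in cut] == [[0], [1], [2]]

    def test_two_groups_from_hand_example(self):
        cut = cut_dendrogram(self.dend, 2)
        assert [c["members"] for c in cut] == [[0, 1], [2]]

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            cut_dendrogram(self.dend, 4)

    def test_cut_refinement_consistency(self):
        rng = np.random.default_rng(11)
        D = _random_dissim(rng, 9)
        dend = minimax_linkage(_matrix(D))
        for k in range(1, 9):
            coarse = cut_dendrogram(dend, k)
            fine = cut_dendrogram(dend, k + 1)
            # each fine cluster lies wholly inside one coarse cluster
            for fc in fine:
                containers = [c for c in coarse
                              if set(fc["members"]) <= set(c["members"])]
                assert len(containers) == 1
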