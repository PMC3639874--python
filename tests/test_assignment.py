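import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oascreen.assignment import (DECAY_AT, DEFAULT_GAMMA, AssignmentResult, VirtualScreen,
                                 atom_similarity, decay, load_weights, normalize_weights,
                                 normalized_similarity, optimal_assignment, pairwise_matrix,
                                 save_weights, weighted_similarity)
from oascreen.chemgraph import molecule_from_smiles


def brute_force_assignment(M):
    """Exhaustive optimum of the assignment problem (oracle)."""
    m, n = M.shape
    if m <= n:
        rows = range(m)
        best = max(sum(M[i, p[i]] for i in rows)
                   for p in itertools.permutations(range(n), m))
    else:
        cols = range(n)
        best = max(sum(M[p[j], j] for j in cols)
                   for p in itertools.permutations(range(m), n))
    return best


def slow_atom_similarity(A, i, B, j, depth, gamma=DEFAULT_GAMMA):
    """Independent top-down recursion of the documented similarity rule."""
    xa, xb = A.atom_descriptors[i], B.atom_descriptors[j]
    c = math.exp(-gamma * float(np.sum((xa - xb) ** 2)))
    if depth == 0:
        return min(1.0, c)
    Ni, Nj = A.neighbors[i], B.neighbors[j]
    k = max(len(Ni), len(Nj))
    if k == 0:
        return min(1.0, c)
    if len(Ni) == 0 or len(Nj) == 0:
        matched = 0.0
    else:
        gb = 1.0 / A.bond_descriptors.shape[1]
        M = np.empty((len(Ni), len(Nj)))
        for a, (na, ea) in enumerate(zip(Ni, A.edge_index[i])):
            for b, (nb, eb) in enumerate(zip(Nj, B.edge_index[j])):
                bond = math.exp(-gb * float(np.sum(
                    (A.bond_descriptors[ea] - B.bond_descriptors[eb]) ** 2)))
                M[a, b] = bond * slow_atom_similarity(A, na, B, nb, depth - 1, gamma)
        matched = brute_force_assignment(M)
    d1 = DECAY_AT[1]
    return min(1.0, (c + d1 * matched) / (1.0 + d1 * k))


class TestDecay:
    def test_values_at_depths(self, mols):
        propane = mols["propane"]
        assert decay(propane, 1, 1) == 1.0
        assert decay(propane, 0, 1) == pytest.approx(4 / 9)
        assert decay(propane, 0, 2) == pytest.approx(1 / 9)

    def test_beyond_depth_is_an_error(self, mols):
        butane = mols["butane"]
        with pytest.raises(ValueError, match="depth"):
            decay(butane, 0, 3)  # distance 3 exceeds the depth-2 contract


class TestAtomSimilarity:
    def test_identical_environment_scores_one(self, mols):
        benzene = mols["benzene"]
        S = pairwise_matrix(benzene, benzene).entries
        assert np.allclose(np.diag(S), 1.0)
        # every benzene carbon is equivalent to every other
        assert np.allclose(S, 1.0)

    def test_isolated_atoms_reduce_to_center_rbf(self, mols):
        methane, ammonia = mols["methane"], mols["ammonia"]
        assert atom_similarity(methane, 0, methane, 0) == pytest.approx(1.0)
        delta2 = float(np.sum((methane.atom_descriptors[0] - ammonia.atom_descriptors[0]) ** 2))
        expected = math.exp(-DEFAULT_GAMMA * delta2)
        assert atom_similarity(methane, 0, ammonia, 0) == pytest.approx(expected, abs=1e-12)

    def test_matrix_symmetry_and_range(self, mols):
        eth, prop = mols["ethanol"], mols["propane"]
        S_ab = pairwise_matrix(eth, prop).entries
        S_ba = pairwise_matrix(prop, eth).entries
        assert S_ab.shape == (3, 3)
        assert np.allclose(S_ab, S_ba.T)
        assert (S_ab >= 0).all() and (S_ab <= 1).all()

    def test_agrees_with_independent_recursion_oracle(self, mols):
        pairs = [("ethanol", "propane"), ("acetone", "phenol"), ("pyridine", "benzene")]
        for a, b in pairs:
            A, B = mols[a], mols[b]
            S = pairwise_matrix(A, B).entries
            for i in range(A.n_atoms):
                for j in range(B.n_atoms):
                    assert S[i, j] == pytest.approx(
                        slow_atom_similarity(A, i, B, j, 2), abs=1e-12)

    def test_methyl_carbon_less_similar_across_molecules(self, mols):
        eth, prop = mols["ethanol"], mols["propane"]
        value = atom_similarity(eth, 0, prop, 0)
        assert 0.0 < value < 1.0


class TestOptimalAssignment:
    def test_identity_matrix(self):
        result = optimal_assignment(np.eye(3))
        assert result.raw_score == pytest.approx(3.0)
        assert result.mapping == {0: 0, 1: 1, 2: 2}

    def test_two_by_two_example(self):
        result = optimal_assignment(np.array([[0.9, 0.1], [0.8, 0.2]]))
        assert result.raw_score == pytest.approx(1.1)
        assert result.mapping == {0: 0, 1: 1}

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(2, 7))
            M = rng.uniform(size=(m, n))
            assert optimal_assignment(M).raw_score == pytest.approx(
                brute_force_assignment(M), abs=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            optimal_assignment(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestNormalizedSimilarity:
    def test_self_similarity_is_one(self, mols):
        for name in ("ethanol", "benzene", "acetone"):
            assert normalized_similarity(mols[name], mols[name]) == pytest.approx(1.0)

    def test_symmetric_and_in_unit_interval(self, mols):
        names = ["ethanol", "propane", "benzene", "acetone", "pyridine"]
        for a, b in itertools.combinations(names, 2):
            f_ab = normalized_similarity(mols[a], mols[b])
            f_ba = normalized_similarity(mols[b], mols[a])
            assert f_ab == pytest.approx(f_ba, abs=1e-12)
            assert 0.0 < f_ab < 1.0

    def test_pipeline_against_stepwise_recomputation(self, mols):
        eth, prop = mols["ethanol"], mols["propane"]
        S = np.array([[slow_atom_similarity(eth, i, prop, j, 2)
                       for j in range(3)] for i in range(3)])
        raw = brute_force_assignment(S)
        self_a = brute_force_assignment(np.array(
            [[slow_atom_similarity(eth, i, eth, j, 2) for j in range(3)] for i in range(3)]))
        self_b = brute_force_assignment(np.array(
            [[slow_atom_similarity(prop, i, prop, j, 2) for j in range(3)] for i in range(3)]))
        expected = raw / math.sqrt(self_a * self_b)
        assert normalized_similarity(eth, prop) == pytest.approx(expected, abs=1e-10)


class TestNormalizeWeights:
    def test_worked_examples(self):
        assert np.allclose(normalize_weights(np.zeros(5)), np.ones(5))
        assert np.allclose(normalize_weights(np.array([0.5, -0.5])), [2.0, 0.0])
        assert np.allclose(normalize_weights(np.full(4, -0.5)), np.ones(4))

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_weights(np.array([]))

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(min_value=-0.5, max_value=0.5), min_size=1, max_size=20))
    def test_constraints_always_hold(self, raw):
        w = normalize_weights(np.array(raw))
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(len(raw), abs=1e-9)


class TestWeightedSimilarity:
    def test_uniform_weights_reproduce_unweighted(self, small_fixture):
        _, dataset, query = small_fixture
        m = query.n_atoms
        for mol in dataset.molecules[:20]:
            S = pairwise_matrix(query, mol)
            unweighted = optimal_assignment(S)
            weighted = weighted_similarity(query, mol, np.ones(m), S=S)
            assert weighted.raw_score == pytest.approx(unweighted.raw_score, abs=1e-12)
            assert weighted.mapping == unweighted.mapping

    def test_concentrated_weight_takes_best_single_edge(self, mols):
        eth, prop = mols["ethanol"], mols["propane"]
        m = eth.n_atoms
        S = pairwise_matrix(eth, prop)
        w = np.zeros(m)
        w[0] = m
        result = weighted_similarity(eth, prop, w, S=S)
        assert result.raw_score == pytest.approx(m * S.entries[0].max(), abs=1e-12)

    def test_zero_weight_row_is_inert(self, mols):
        eth, prop = mols["ethanol"], mols["propane"]
        S = pairwise_matrix(eth, prop)
        w = normalize_weights(np.array([0.5, 0.5, -0.5]))
        assert w[2] == 0.0
        perturbed = pairwise_matrix(eth, prop)
        perturbed.entries[2] = np.random.default_rng(0).uniform(size=3)
        a = weighted_similarity(eth, prop, w, S=S)
        b = weighted_similarity(eth, prop, w, S=perturbed)
        assert a.raw_score == pytest.approx(b.raw_score, abs=1e-12)

    def test_weight_length_mismatch_errors(self, mols):
        with pytest.raises(ValueError, match="length"):
            weighted_similarity(mols["ethanol"], mols["propane"], np.ones(5))

    def test_raising_a_weight_never_lowers_the_score(self, rng):
        # monotonicity with renormalization off: scale one row upward
        for _ in range(50):
            S = rng.uniform(size=(5, 6))
            w = rng.uniform(0.1, 2.0, size=5)
            base = optimal_assignment(w[:, None] * S).raw_score
            i = int(rng.integers(5))
            w2 = w.copy()
            w2[i] += rng.uniform(0.1, 1.0)
            assert optimal_assignment(w2[:, None] * S).raw_score >= base - 1e-12


class TestVirtualScreen:
    def test_scores_match_direct_weighted_similarity(self, small_fixture):
        _, dataset, query = small_fixture
        screen = VirtualScreen(query, dataset.molecules[:5])
        w = normalize_weights(np.linspace(-0.4, 0.4, query.n_atoms))
        scores = screen.scores(w)
        for k, mol in enumerate(dataset.molecules[:5]):
            direct = weighted_similarity(query, mol, w)
            assert scores[k] == pytest.approx(direct.normalized_score, abs=1e-12)


def test_weight_file_roundtrip(tmp_path):
    w = normalize_weights(np.linspace(-0.5, 0.5, 7))
    path = tmp_path / "weights.json"
    save_weights(path, w, "query-1")
    loaded, qid = load_weights(path)
    assert qid == "query-1"
    assert np.allclose(loaded, w)
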