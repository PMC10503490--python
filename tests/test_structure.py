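import io
import math

import numpy as np
import pytest

from conftest import island, make_matrix
from msatpop.qc import NullAlleleEstimate
from msatpop.structure import (DistanceMatrix, broken_stick, chord_distance,
                               chord_distance_matrix, fca, nj_tree)
from oracles import broken_stick_oracle, chord_oracle, random_additive_tree

MAX_CHORD = (2.0 / math.pi) * math.sqrt(2.0)


def _patristic(newick, labels):
    """Tip-to-tip path lengths of a Newick tree via scikit-bio."""
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.find(labels[i]).distance(tree.find(labels[j]))
            out[i, j] = out[j, i] = d
    return out


def test_chord_identical_and_disjoint():
    assert chord_distance({1: 0.5, 2: 0.5}, {1: 0.5, 2: 0.5}) == \
        pytest.approx(0.0)
    assert chord_distance({1: 1.0}, {2: 1.0}) == \
        pytest.approx(MAX_CHORD, abs=1e-9)
    with pytest.raises(ValueError):
        chord_distance({}, {1: 1.0})


def test_chord_matches_oracle_random():
    rng = np.random.default_rng(12)
    for _ in range(50):
        k = int(rng.integers(2, 8))
        fx = dict(enumerate(rng.dirichlet(np.ones(k))))
        fy = dict(enumerate(rng.dirichlet(np.ones(k))))
        d = chord_distance(fx, fy)
        assert d == pytest.approx(chord_oracle(fx, fy), abs=1e-12)
        assert 0.0 <= d <= MAX_CHORD + 1e-12
        assert chord_distance(fy, fx) == pytest.approx(d, abs=1e-12)


def test_chord_matrix_ina_reduces_when_r_zero():
    m, _ = island(seed=40, sizes=(15, 15, 15), n_loci=4)
    zero = {
        l: NullAlleleEstimate(locus=l, by_group={
            g: {"r": 0.0, "n": 15, "observed_blanks": 0,
                "expected_blanks": 0.0, "visible_freqs": None}
            for g in m.subsamples()})
        for l in m.loci
    }
    plain = chord_distance_matrix(m)
    ina = chord_distance_matrix(m, null_estimates=zero)
    assert np.allclose(plain.values, ina.values, atol=1e-12)


def test_chord_matrix_individual_level():
    m, _ = island(seed=41, sizes=(5, 5), n_loci=3)
    dm = chord_distance_matrix(m, level="individual")
    assert dm.labels == m.individuals
    assert np.allclose(dm.values, dm.values.T)


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(["a", "b"], np.array([[0.1, 1.0], [1.0, 0.0]]))


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    newick = nj_tree(DistanceMatrix(list("XYZ"), d))
    pat = _patristic(newick, list("XYZ"))
    assert np.allclose(pat, d, atol=1e-9)


def test_nj_equal_distances_star():
    d = np.full((4, 4), 2.0)
    np.fill_diagonal(d, 0.0)
    newick = nj_tree(DistanceMatrix(list("ABCD"), d))
    pat = _patristic(newick, list("ABCD"))
    assert np.allclose(pat, d, atol=1e-9)


def test_nj_recovers_additive_trees():
    """On an additive matrix NJ must reproduce the generating tree exactly
    (path lengths match the input to 1e-9); scikit-bio's NJ is the
    independent cross-check."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(77)
    for rep in range(50):
        n = int(rng.integers(4, 9))
        labels, dist = random_additive_tree(n, rng)
        dm = DistanceMatrix(labels, dist)
        newick = nj_tree(dm)
        pat = _patristic(newick, labels)
        assert np.allclose(pat, dist, atol=1e-9)
        if rep < 10:  # cross-check a subset against the reference library
            sk = skbio_nj(SkbioDM(dist, ids=labels))
            sk_pat = np.zeros_like(dist)
            for i in range(n):
                for j in range(i + 1, n):
                    sk_pat[i, j] = sk_pat[j, i] = (
                        sk.find(labels[i]).distance(sk.find(labels[j])))
            assert np.allclose(sk_pat, pat, atol=1e-6)


def test_nj_needs_three():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["a", "b"],
                               np.array([[0.0, 1.0], [1.0, 0.0]])))


def test_fca_block_structure_separates_groups():
    # two groups with fully disjoint alleles
    g1 = [[(100, 102), (200, 202)]] * 6
    g2 = [[(110, 112), (210, 212)]] * 6
    m = make_matrix([g1, g2])
    res = fca(m)
    axis1 = res.coordinates[:, 0]
    assert (axis1[:6] * axis1[6:] < 0).all()  # groups on opposite sides
    assert res.percent_inertia[0] == pytest.approx(100.0, abs=1e-6)


def test_fca_inertia_sums_to_100():
    m, _ = island(seed=42, sizes=(10, 10, 10), n_loci=5)
    res = fca(m)
    assert res.percent_inertia.sum() == pytest.approx(100.0, abs=0.01)
    assert (np.diff(res.eigenvalues) <= 1e-12).all()


def test_fca_invariant_to_column_permutation():
    m, _ = island(seed=43, sizes=(8, 8), n_loci=4)
    res1 = fca(m)
    # permuting loci permutes indicator columns; coordinates match up to sign
    m2 = m.select_loci(m.loci[::-1])
    res2 = fca(m2)
    assert np.allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-9)
    for k in range(min(3, res1.coordinates.shape[1])):
        c1, c2 = res1.coordinates[:, k], res2.coordinates[:, k]
        assert (np.allclose(c1, c2, atol=1e-8)
                or np.allclose(c1, -c2, atol=1e-8))


def test_fca_separates_island_groups():
    ok = 0
    for seed in range(20):
        m, _ = island(seed=seed, sizes=(20, 20, 20), n_loci=6, fst=0.2)
        res = fca(m)
        coords = res.coordinates[:, :2]
        labels = m.labels("subsample")
        # silhouette of group centroids on the first two axes
        from sklearn.metrics import silhouette_score

        ok += silhouette_score(coords, labels) > 0
    assert ok >= 18


@pytest.mark.parametrize("lams,expected", [
    ((0.7, 0.2, 0.1), 1),
    ((1.0, 1.0, 1.0), 0),
    ((0.99, 0.005, 0.005), 1),
])
def test_broken_stick_known_cases(lams, expected):
    assert broken_stick(lams) == expected


def test_broken_stick_matches_oracle_random():
    rng = np.random.default_rng(9)
    for _ in range(50):
        p = int(rng.integers(2, 12))
        lams = np.sort(rng.random(p))[::-1]
        assert broken_stick(lams, k=10) == broken_stick_oracle(lams, k=10)
    with pytest.raises(ValueError):
        broken_stick([])
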