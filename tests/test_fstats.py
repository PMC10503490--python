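import numpy as np
import pytest

from conftest import island, make_matrix
from msatpop.core import MISSING
from msatpop.fstats import (bootstrap_ci_loci, by_adjust, f_statistics,
                            g_test_differentiation,
                            jackknife_fis_populations, ld_pairwise_tests,
                            permute_fis_test, wc_components)
from oracles import by_oracle, g_oracle, wc_oracle


def _random_pops(rng, n_pops=3, n=10, k=4):
    """Random per-subsample genotype lists for one locus."""
    sizes = 100 + 2 * np.arange(k)
    pops = []
    for _ in range(n_pops):
        p = rng.dirichlet(np.ones(k))
        g = sizes[rng.choice(k, size=(n, 2), p=p)]
        pops.append([tuple(sorted(int(v) for v in x)) for x in g])
    return pops


def test_wc_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    for _ in range(50):
        pops = _random_pops(rng, n_pops=int(rng.integers(2, 5)),
                            n=int(rng.integers(4, 15)),
                            k=int(rng.integers(2, 6)))
        m = make_matrix([[ [g] for g in pop] for pop in pops])
        v = wc_components(m, 0)
        a, b, c = wc_oracle(pops)
        assert v.a == pytest.approx(a, abs=1e-10)
        assert v.b == pytest.approx(b, abs=1e-10)
        assert v.c == pytest.approx(c, abs=1e-10)


def test_complete_fixation_gives_fst_one():
    m = make_matrix([[[(100, 100)]] * 10, [[(102, 102)]] * 10])
    assert f_statistics(m).fst == pytest.approx(1.0)


def test_panmictic_split_gives_fst_near_zero():
    # one population in exact HWE proportions, split into two identical halves
    half = ([[(100, 100)]] * 16 + [[(100, 102)]] * 48 + [[(102, 102)]] * 36)
    m = make_matrix([half, half])
    assert abs(f_statistics(m).fst) < 0.01


def test_all_heterozygote_fis_minus_one():
    m = make_matrix([[[(100, 102)]] * 10])
    assert f_statistics(m).fis == pytest.approx(-1.0)


def test_fit_identity_exact():
    for seed in range(5):
        m, _ = island(seed=seed, sizes=(12, 9, 7), n_loci=4)
        fs = f_statistics(m)
        assert (1 - fs.fit) == pytest.approx((1 - fs.fis) * (1 - fs.fst),
                                             abs=1e-12)


def test_monomorphic_locus_flagged():
    m = make_matrix([[[(100, 100)]] * 5, [[(100, 100)]] * 5])
    assert wc_components(m, 0).uninformative
    with pytest.raises(ValueError, match="polymorphism"):
        f_statistics(m)


def test_permutation_extreme_fis():
    m = make_matrix([[[(100, 102)]] * 12, [[(104, 106)]] * 12])
    obs, p = permute_fis_test(m, n_perm=1000, seed=3)
    assert obs == pytest.approx(-1.0)
    assert p <= 0.01


def test_permutation_degenerate_single_individuals():
    # one genotyped individual per subsample: no within-group freedom
    m = make_matrix([[[(100, 102)]], [[(100, 104)]], [[(102, 104)]]])
    stat, p = permute_fis_test(m, n_perm=50, seed=1)
    assert p == 1.0 and np.isnan(stat)


def test_permutation_seed_reproducible():
    m, _ = island(seed=8, sizes=(15, 15, 15), n_loci=3)
    r1 = permute_fis_test(m, n_perm=100, seed=42)
    r2 = permute_fis_test(m, n_perm=100, seed=42)
    assert r1 == r2


def test_g_zero_for_identical_counts():
    pop = [[(100, 102)], [(100, 100)], [(102, 102)], [(100, 102)]]
    m = make_matrix([pop, list(pop)])
    g, p, _ = g_test_differentiation(m, n_perm=200, seed=0)
    assert g == pytest.approx(0.0, abs=1e-12)
    assert p == 1.0


def test_g_disjoint_alleles_significant():
    m = make_matrix([[[(100, 102)]] * 12, [[(104, 106)]] * 12])
    g, p, _ = g_test_differentiation(m, n_perm=1000, seed=0)
    assert p <= 0.001


def test_g_matches_hand_table():
    # allele counts per subsample: {10, 0} vs {5, 5}
    m = make_matrix([[[(100, 100)]] * 5,
                     [[(100, 100)], [(100, 100)], [(100, 102)],
                      [(102, 102)], [(102, 102)], [(100, 102)],
                      [(100, 102)], [(102, 102)], [(100, 102)],
                      [(100, 102)]][:5]])
    # build explicit table from the data and compare against the oracle
    g, _, per_locus = g_test_differentiation(m, n_perm=1, seed=0)
    table = np.zeros((2, 2))
    labels = m.labels()
    for i in range(m.n_individuals):
        for a in m.calls[i, 0]:
            table[0 if labels[i] == "S1" else 1, 0 if a == 100 else 1] += 1
    assert g == pytest.approx(g_oracle(table), abs=1e-9)
    assert table[0, 0] == 10 and table[0, 1] == 0


def test_bootstrap_zero_width_for_identical_loci():
    # same genotype column repeated -> identical components per locus
    pop1 = [[(100, 102)] * 3, [(100, 100)] * 3, [(102, 102)] * 3]
    pop2 = [[(100, 100)] * 3, [(100, 102)] * 3, [(100, 102)] * 3]
    m = make_matrix([pop1, pop2])
    lo, hi = bootstrap_ci_loci(m, "fst", n_boot=500, seed=0)
    assert lo == pytest.approx(hi, abs=1e-12)
    assert lo == pytest.approx(f_statistics(m).fst, abs=1e-12)


def test_bootstrap_ci_contains_estimate():
    inside = 0
    for seed in range(100):
        m, _ = island(seed=seed, sizes=(12, 12, 12), n_loci=6)
        fs = f_statistics(m)
        lo, hi = bootstrap_ci_loci(m, "fst", n_boot=400, seed=seed)
        inside += lo - 1e-12 <= fs.fst <= hi + 1e-12
    assert inside >= 99


def test_bootstrap_single_locus_error():
    m, _ = island(seed=1, sizes=(10, 10), n_loci=1)
    with pytest.raises(ValueError, match="CI"):
        bootstrap_ci_loci(m, "fst", n_boot=10, seed=0)


def test_jackknife_identical_subsamples():
    pop = [[(100, 102)], [(100, 100)], [(102, 102)], [(100, 102)]]
    m = make_matrix([list(pop), list(pop), list(pop)])
    fis, se, li, ls = jackknife_fis_populations(m, 0)
    assert se == pytest.approx(0.0, abs=1e-12)
    assert li == pytest.approx(fis) and ls == pytest.approx(fis)


def test_jackknife_matches_direct_formula():
    m, _ = island(seed=9, sizes=(10, 8, 12, 9), n_loci=1)
    fis, se, li, ls = jackknife_fis_populations(m, 0)
    labels = m.labels("subsample")
    thetas = []
    for drop in m.subsamples():
        sub = m.select_individuals(labels != drop)
        thetas.append(wc_components(sub, 0).fis)
    g = len(thetas)
    direct = np.sqrt((g - 1) / g * ((np.array(thetas)
                                     - np.mean(thetas)) ** 2).sum())
    assert se == pytest.approx(direct, abs=1e-12)
    assert li <= fis <= ls


def test_jackknife_needs_three_subsamples():
    m, _ = island(seed=2, sizes=(10, 10), n_loci=1)
    with pytest.raises(ValueError, match=">=3"):
        jackknife_fis_populations(m, 0)


def test_ld_pair_count_and_duplicate_locus():
    m, _ = island(seed=4, sizes=(15, 15), n_loci=9)
    res = ld_pairwise_tests(m, n_perm=50, seed=0)
    assert len(res) == 36  # C(9, 2)
    # a locus paired with its own copy is maximally associated
    dup = np.concatenate([m.calls, m.calls[:, :1, :]], axis=1)
    from msatpop.core import GenotypeMatrix

    m2 = GenotypeMatrix(m.individuals, m.loci + ["COPY"], dup, m.groups)
    res2 = ld_pairwise_tests(m2.select_loci([m.loci[0], "COPY"]),
                             n_perm=1000, seed=0)
    assert res2[0].p <= 0.001
    assert res2[0].p_adjusted >= res2[0].p


@pytest.mark.parametrize("ps,expected", [
    ((0.01, 0.02, 0.04), (0.055, 0.055, 11 / 6 * 0.04)),
    ((0.5,), (0.5,)),
    ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)),
])
def test_by_adjust_known_values(ps, expected):
    adj = by_adjust(ps)
    assert adj == pytest.approx(expected, abs=1e-9)


def test_by_adjust_matches_oracle_random():
    rng = np.random.default_rng(3)
    for _ in range(50):
        ps = rng.random(int(rng.integers(1, 12)))
        assert by_adjust(ps) == pytest.approx(by_oracle(ps), abs=1e-9)
    assert len(by_adjust([])) == 0
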