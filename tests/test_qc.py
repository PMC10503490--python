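import numpy as np
import pytest

from conftest import island, make_matrix
from msatpop.core import GenotypeMatrix
from msatpop.qc import (_em_single, blank_binomial_test, em_null_frequency,
                        fis_blank_regression, fis_fst_correlation, qc_report,
                        sad_test, stuttering_test)
from msatpop.simulate import SimConfig, inject_sad, simulate_island


def test_em_exact_hwe_no_blanks_gives_zero():
    # exact HWE genotype counts for two alleles at p = 0.5, no blanks
    pop = ([[(100, 100)]] * 25 + [[(100, 102)]] * 50 + [[(102, 102)]] * 25)
    m = make_matrix([pop])
    est = em_null_frequency(m, 0)
    assert est.by_group["S1"]["r"] < 1e-6
    assert est.expected_blanks < 1e-6


def test_em_all_blank_gives_one():
    m = make_matrix([[[None]] * 10])
    est = em_null_frequency(m, 0)
    assert est.by_group["S1"]["r"] == pytest.approx(1.0)


def test_em_recovers_injected_null_frequency():
    # single panmictic sample of 200, true r = 0.2
    r_hats = []
    for seed in range(100):
        cfg = SimConfig(subsample_sizes=(200,), n_loci=1,
                        alleles_per_locus=(8,), target_fst=0.0,
                        null_freqs=(0.2,), seed=seed,
                        sites=("s",), countries=("c",))
        m, _ = simulate_island(cfg)
        r_hats.append(em_null_frequency(m, 0).by_group["S1"]["r"])
    assert 0.17 <= np.mean(r_hats) <= 0.23


@pytest.mark.parametrize("r_true", [0.05, 0.1, 0.2, 0.3])
def test_em_bias_small_across_null_levels(r_true):
    r_hats = []
    for seed in range(40):
        cfg = SimConfig(subsample_sizes=(200,), n_loci=1,
                        alleles_per_locus=(8,), target_fst=0.0,
                        null_freqs=(r_true,), seed=seed,
                        sites=("s",), countries=("c",))
        m, _ = simulate_island(cfg)
        r_hats.append(em_null_frequency(m, 0).by_group["S1"]["r"])
    assert abs(np.mean(r_hats) - r_true) < 0.03


def test_em_loglik_monotone():
    trace = []
    _em_single({(0, 1): 20, (1, 2): 10}, {0: 30, 1: 8, 2: 4}, 6,
               loglik_trace=trace)
    diffs = np.diff(trace)
    assert (diffs >= -1e-9).all()
    assert len(trace) < 10_000


def test_blank_binomial_values():
    assert blank_binomial_test(3, 30, np.sqrt(0.1)) == \
        pytest.approx(0.6474, abs=1e-4)
    assert blank_binomial_test(30, 30, 0.3) == pytest.approx(1.0)
    assert blank_binomial_test(0, 100, 0.5) < 1e-10
    # vacuous fit when no nulls estimated
    assert blank_binomial_test(5, 30, 0.0) == 1.0


def test_fis_blank_regression_exact_line():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    y = 0.1 + 0.02 * x
    slope, intercept, r2 = fis_blank_regression(y, x)
    assert slope == pytest.approx(0.02)
    assert intercept == pytest.approx(0.1)
    assert r2 == pytest.approx(1.0)


def test_fis_blank_regression_null_behavior():
    rng = np.random.default_rng(0)
    x = rng.random(9)
    y = rng.random(9)
    r2s = []
    for _ in range(200):
        yy = rng.permutation(y)
        _, _, r2 = fis_blank_regression(yy, x)
        r2s.append(r2)
    assert np.mean(r2s) < 0.2


def test_fis_blank_regression_errors():
    with pytest.raises(ValueError, match="3 loci"):
        fis_blank_regression([0.1, 0.2], [1, 2])
    with pytest.raises(ValueError, match="variance"):
        fis_blank_regression([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])


def test_sad_monotone_fit_gives_rho_minus_one():
    # seed chosen so that maximal-strength dropout yields strictly
    # decreasing per-allele F_IT across the ladder
    cfg = SimConfig(subsample_sizes=(150,), n_loci=1, alleles_per_locus=(6,),
                    motif_lengths=(2,), target_fst=0.0, seed=3,
                    sites=("s",), countries=("c",))
    m, truth = simulate_island(cfg)
    m2 = inject_sad(m, 1.0, rng=3 + 999, truth=truth)
    rho, p_s, slope, p_w = sad_test(m2, 0)
    assert rho == pytest.approx(-1.0)
    assert slope < 0
    assert p_w < 0.05


def test_sad_insufficient_alleles():
    m = make_matrix([[[(100, 102)], [(100, 100)], [(102, 102)]]])
    with pytest.raises(ValueError, match="insufficient"):
        sad_test(m, 0)


def test_stuttering_not_testable_when_no_one_step_pairs():
    # alleles 4 bp apart on a dinucleotide ladder: no one-step pairs
    pop = [[(100, 104)], [(100, 100)], [(104, 104)], [(100, 104)],
           [(108, 108)], [(104, 108)]]
    m = make_matrix([pop])
    stat, p, verdict = stuttering_test(m, 0, motif_length=2)
    assert verdict == "not testable"
    assert p == 1.0


def test_fis_fst_correlation_monotone_cases():
    fis = np.array([0.01, 0.05, 0.10, 0.20, 0.30])
    rho, p = fis_fst_correlation(fis, 2 * fis)
    assert rho == pytest.approx(1.0)
    assert p < 0.05
    rho2, p2 = fis_fst_correlation(fis, -fis)
    assert rho2 == pytest.approx(-1.0)
    assert p2 > 0.5


def test_fis_fst_correlation_null_behavior():
    rhos = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        rho, _ = fis_fst_correlation(rng.random(9), rng.random(9))
        rhos.append(rho)
    assert abs(np.mean(rhos)) < 0.15


def test_qc_report_clean_panel_retains_all():
    m, _ = island(seed=17, sizes=(25, 25, 25, 25), n_loci=6)
    reports = qc_report(m)
    assert all(r.decision == "retain" for r in reports)
    assert all(not r.reasons for r in reports)


def test_qc_report_low_read_success_excluded():
    m, _ = island(seed=18, sizes=(20, 20), n_loci=3)
    calls = m.calls.copy()
    from msatpop.core import MISSING

    calls[:16, 1, :] = MISSING  # 40% success at locus 2
    m2 = GenotypeMatrix(m.individuals, m.loci, calls, m.groups)
    reports = qc_report(m2, read_success_threshold=0.7)
    verdicts = {r.locus: r.reasons for r in reports}
    assert "low_read_success" in verdicts[m.loci[1]]
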