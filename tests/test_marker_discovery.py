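import numpy as np
import pytest

from msatpop.discovery import (canonical_motif, exclude_duplicates,
                               filter_candidates, revcomp, scan_ssrs)
from msatpop.simulate import simulate_genome_with_ssrs, write_fasta


def test_planted_repeat_found():
    contigs, truth = simulate_genome_with_ssrs(
        length=5000, planted=[{"motif": "AG", "n_repeats": 14}], seed=1)
    cands = scan_ssrs(contigs, min_repeats=10)
    hit = [c for c in cands if (c.start, c.end) ==
           (truth[0]["start"], truth[0]["end"])]
    assert len(hit) == 1
    assert hit[0].motif == canonical_motif("AG")
    assert hit[0].n_repeats == 14


def test_below_threshold_not_reported():
    contigs, _ = simulate_genome_with_ssrs(
        length=5000, planted=[{"motif": "AT", "n_repeats": 9}], seed=2)
    cands = scan_ssrs(contigs, min_repeats=10)
    assert all(c.n_repeats >= 10 for c in cands)
    assert not any(c.start == 0 and c.n_repeats == 9 for c in cands)


def test_twenty_planted_repeats_recovered_exactly():
    rng = np.random.default_rng(3)
    motifs = ["AG", "AC", "AT", "ATC", "ACG"]
    planted = [{"motif": motifs[i % 5], "n_repeats": int(rng.integers(10, 16))}
               for i in range(20)]
    contigs, truth = simulate_genome_with_ssrs(
        length=50_000, planted=planted, seed=3)
    cands = scan_ssrs(contigs, min_repeats=10)
    found = {(c.contig, c.start, c.end) for c in cands}
    for rec in truth:
        assert (rec["contig"], rec["start"], rec["end"]) in found


def test_random_sequence_rarely_repeats():
    contigs, _ = simulate_genome_with_ssrs(length=50_000, planted=[], seed=4)
    assert scan_ssrs(contigs, min_repeats=10) == []


def test_homopolymer_disguise_excluded():
    contigs = {"c1": "GCT" + "A" * 60 + "TCGATCGGACTA" * 4}
    assert scan_ssrs(contigs, min_repeats=10) == []


def test_n_never_matches():
    contigs = {"c1": "GCATTACA" + "AG" * 8 + "NN" + "AG" * 8 + "CCGATTA"}
    cands = scan_ssrs(contigs, min_repeats=10)
    assert cands == []  # each clean run is only 8 units


def test_scan_strand_symmetric():
    contigs, _ = simulate_genome_with_ssrs(
        length=20_000,
        planted=[{"motif": "AG", "n_repeats": 12},
                 {"motif": "ATC", "n_repeats": 11}], seed=5)
    fwd = scan_ssrs(contigs, min_repeats=10)
    L = len(next(iter(contigs.values())))
    rc = {k: revcomp(v) for k, v in contigs.items()}
    rev = scan_ssrs(rc, min_repeats=10)
    fwd_set = {(c.contig, c.start, c.end, c.motif) for c in fwd}
    rev_set = {(c.contig, L - c.end, L - c.start, c.motif) for c in rev}
    assert fwd_set == rev_set


def test_duplicate_flanks_excluded():
    contigs, truth = simulate_genome_with_ssrs(
        length=30_000,
        planted=[{"motif": "AG", "n_repeats": 13},
                 {"motif": "AC", "n_repeats": 12},
                 {"motif": "AT", "n_repeats": 11}],
        seed=6, duplicate_flanks=1)
    cands = scan_ssrs(contigs, min_repeats=10)
    unique, excluded = exclude_duplicates(cands, contigs)
    assert len(unique) + len(excluded) == len(cands)
    # the duplicated locus and its copy are both excluded: 2 exclusions
    assert len(excluded) == 2
    assert all(c.reason == "duplicate_flank" for c in excluded)


def test_all_unique_flanks_nothing_excluded():
    contigs, _ = simulate_genome_with_ssrs(
        length=30_000,
        planted=[{"motif": "AG", "n_repeats": 13},
                 {"motif": "AC", "n_repeats": 12}], seed=7)
    cands = scan_ssrs(contigs, min_repeats=10)
    unique, excluded = exclude_duplicates(cands, contigs)
    assert excluded == []
    assert len(unique) == len(cands)


def test_contig_edge_flank_excluded():
    contigs = {"c1": "AG" * 15 + "GCTTACGGATCAGTACGGATCAAT" * 3}
    cands = scan_ssrs(contigs, min_repeats=10)
    assert len(cands) == 1
    unique, excluded = exclude_duplicates(cands, contigs)
    assert excluded and excluded[0].reason == "edge"


def test_filter_candidates_rules():
    contigs, _ = simulate_genome_with_ssrs(
        length=20_000,
        planted=[{"motif": "AG", "n_repeats": 14},
                 {"motif": "AC", "n_repeats": 12}], seed=8)
    cands = scan_ssrs(contigs, min_repeats=10)
    kept = filter_candidates(cands, size_range=(10, 500), min_repeats=13)
    assert all(c.n_repeats >= 13 for c in kept)
    assert [c.n_repeats for c in kept] == \
        sorted((c.n_repeats for c in kept), reverse=True)
    with pytest.raises(ValueError, match="inverted"):
        filter_candidates(cands, size_range=(300, 180))


def test_filter_matches_brute_force_and_is_monotone():
    rng = np.random.default_rng(9)
    from msatpop.discovery import SSRCandidate

    cands = []
    for i in range(100):
        n_rep = int(rng.integers(10, 20))
        motif = "AG"
        start = i * 100
        cands.append(SSRCandidate(
            contig="c", start=start, end=start + 2 * n_rep, motif=motif,
            motif_observed=motif, n_repeats=n_rep,
            product_size=int(rng.integers(120, 400))))
    kept = filter_candidates(cands, (180, 300), 13)
    brute = [c for c in cands
             if 180 <= c.product_size <= 300 and c.n_repeats >= 13]
    assert len(kept) == len(brute)
    assert {id(c) for c in kept} == {id(c) for c in brute}
    # monotone funnel: relaxing the repeat cutoff can only add candidates
    for a, b in [(15, 13), (13, 10)]:
        hi = {id(c) for c in filter_candidates(cands, (180, 300), a)}
        lo = {id(c) for c in filter_candidates(cands, (180, 300), b)}
        assert hi <= lo


def test_fasta_round_trip(tmp_path):
    contigs, truth = simulate_genome_with_ssrs(
        length=8000, planted=[{"motif": "AG", "n_repeats": 12}], seed=10)
    path = tmp_path / "genome.fa"
    write_fasta(contigs, path)
    cands = scan_ssrs(path, min_repeats=10)
    assert any((c.start, c.end) == (truth[0]["start"], truth[0]["end"])
               for c in cands)
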