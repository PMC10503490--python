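"""Candidate microsatellite discovery from assembled sequence.

The funnel mirrors common SSR-screening practice: scan for maximal perfect
di-/trinucleotide repeats (minimum ten units), drop candidates whose
flanking sequence is not unique in the genome (a proxy for primer pairs
hitting multiple genomic sites), then keep candidates whose predicted
product size and repeat count pass the final thresholds, ranked by repeat
count.  Product size is approximated as the repeat span plus both flanks,
since primer design proper is out of scope.

Coordinates are 0-based half-open throughout; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SSRCandidate", "scan_ssrs", "exclude_duplicates", "filter_candidates",
    "canonical_motif",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation among the motif's rotations and
    the rotations of its reverse complement."""
    rc = revcomp(motif)
    forms = [motif[i:] + motif[:i] for i in range(len(motif))]
    forms += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(forms)


@dataclass
class SSRCandidate:
    contig: str
    start: int            # 0-based half-open
    end: int
    motif: str            # canonical repeat unit
    motif_observed: str   # unit as it appears on the forward strand
    n_repeats: int
    product_size: int
    flank_up: str = ""
    flank_down: str = ""
    status: str = "candidate"
    reason: str = ""

    def __post_init__(self):
        if self.end - self.start != len(self.motif) * self.n_repeats:
            raise ValueError("span must equal motif_length * n_repeats")


def _load_fasta(source) -> dict:
    if isinstance(source, dict):
        return {k: v.upper() for k, v in source.items()}
    from Bio import SeqIO

    contigs = {}
    for rec in SeqIO.parse(str(source), "fasta"):
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        # distinguish empty file (no candidates) from unparseable content
        with open(source) as fh:
            head = fh.read(1)
        if head and head != ">":
            raise ValueError(f"malformed FASTA: {source}")
    return contigs


def scan_ssrs(fasta, motif_lengths=(2, 3), min_repeats: int = 10,
              flank_len: int = 20) -> list:
    """Scan for maximal perfect SSRs.

    ``fasta`` is a path or a dict of contig -> sequence.  Homopolymer
    disguises (units like "AA") are excluded and N never matches.  Each
    physical repeat run yields exactly one candidate (rotated re-reports
    collapse by construction: one maximal run per period).
    """
    contigs = _load_fasta(fasta)
    out = []
    for name, seq in contigs.items():
        L = len(seq)
        for k in sorted(motif_lengths):
            i = 0
            # walk maximal runs of seq[i] == seq[i+k], N never matching
            run_start = None
            for i in range(L - k + 1):
                match = (i + k < L and seq[i] == seq[i + k]
                         and seq[i] != "N")
                if match and run_start is None:
                    run_start = i
                elif not match and run_start is not None:
                    out.extend(_emit(name, seq, run_start, i, k,
                                     min_repeats, flank_len))
                    run_start = None
            if run_start is not None:
                out.extend(_emit(name, seq, run_start, L - k, k,
                                 min_repeats, flank_len))
    # a run that is periodic at 2 is also periodic at any multiple; with
    # lengths {2,3} no collapse across k is needed, but guard duplicates
    seen, unique = set(), []
    for cand in sorted(out, key=lambda c: (c.contig, c.start, -c.n_repeats)):
        key = (cand.contig, cand.start, cand.end)
        if key in seen:
            continue
        seen.add(key)
        unique.append(cand)
    return unique


def _emit(name, seq, s, e, k, min_repeats, flank_len):
    span = e - s + k          # s..e is the maximal equality run at lag k
    n_rep = span // k
    if n_rep < min_repeats:
        return []
    unit = seq[s:s + k]
    if len(set(unit)) == 1:
        return []             # homopolymer disguise
    end = s + k * n_rep
    up = seq[max(s - flank_len, 0):s]
    down = seq[end:end + flank_len]
    return [SSRCandidate(
        contig=name, start=s, end=end,
        motif=canonical_motif(unit), motif_observed=unit,
        n_repeats=n_rep,
        product_size=(end - s) + len(up) + len(down),
        flank_up=up, flank_down=down,
    )]


def _count_occurrences(needle: str, haystacks) -> int:
    total = 0
    rc = revcomp(needle)
    for seq in haystacks:
        for pat in {needle, rc}:
            start = 0
            while True:
                pos = seq.find(pat, start)
                if pos < 0:
                    break
                total += 1
                start = pos + 1
    return total


def exclude_duplicates(candidates, genome, flank_len: int = 20):
    """Partition candidates by flank uniqueness.

    A candidate is excluded iff either flank occurs at more than one
    genomic position (exact match, both strands), or a flank is shorter
    than ``flank_len`` (contig edge).  Returns ``(unique, excluded)``;
    excluded candidates carry status/reason.
    """
    contigs = _load_fasta(genome)
    seqs = list(contigs.values())
    unique, excluded = [], []
    for cand in candidates:
        if len(cand.flank_up) < flank_len or len(cand.flank_down) < flank_len:
            cand.status, cand.reason = "excluded", "edge"
            excluded.append(cand)
            continue
        if (_count_occurrences(cand.flank_up, seqs) > 1
                or _count_occurrences(cand.flank_down, seqs) > 1):
            cand.status, cand.reason = "excluded", "duplicate_flank"
            excluded.append(cand)
        else:
            unique.append(cand)
    return unique, excluded


def filter_candidates(candidates, size_range=(180, 300),
                      min_repeats: int = 13) -> list:
    """Final size/repeat filter, ranked by descending repeat count."""
    lo, hi = size_range
    if lo > hi:
        raise ValueError("inverted size range")
    kept = [c for c in candidates
            if lo <= c.product_size <= hi and c.n_repeats >= min_repeats]
    return sorted(kept, key=lambda c: -c.n_repeats)


def report_tsv(candidates, path) -> None:
    """TSV report (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tmotif\tn_repeats\tproduct_size"
                 "\tstatus\treason\n")
        for c in candidates:
            fh.write(f"{c.contig}\t{c.start + 1}\t{c.end}\t{c.motif}\t"
                     f"{c.n_repeats}\t{c.product_size}\t{c.status}\t"
                     f"{c.reason}\n")
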