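"""Synthetic genotype and sequence data with controlled population structure.

The genotype generator follows the Balding-Nichols island model: ancestral
allele frequencies are drawn from a symmetric Dirichlet, and each subsample's
frequencies from Dirichlet(p * (1 - F_ST) / F_ST), which has mean p and
variance p(1-p) * F_ST — so the target F_ST is controlled directly without a
coalescent simulation.  Within subsamples genotypes are drawn with an
inbreeding coefficient F_IS (probability of identical-by-descent gene
copies).  Allele sizes sit on a motif-length ladder starting at 180 bp,
matching typical dinucleotide microsatellite fragment ranges.

Default design mirrors a small field study: six subsamples of sizes
20/10/30/9/7/4, ten loci with 5-14 alleles each on mostly-dinucleotide
ladders, and target F_ST = 0.10.  Genotyping artifacts (null alleles, short
allele dominance, stuttering, random dropout) are injected explicitly so the
truth record always knows which cells were corrupted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, LocusInfo

_BASE_SIZE = 180


@dataclass
class SimConfig:
    """Parameters of the island-model genotype simulator."""

    subsample_sizes: tuple = (20, 10, 30, 9, 7, 4)
    n_loci: int = 10
    alleles_per_locus: tuple = None      # default: cycle through 5..14
    motif_lengths: tuple = None          # default: dinucleotide, one trinucleotide
    target_fst: float = 0.10
    target_fis: float = 0.0
    null_freqs: tuple = None             # per locus, default all zero
    sad_strength: float = 0.0
    stutter_prob: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0
    # grouping: first two subsamples = site A / country 1, rest site B / country 2,
    # loosely mirroring a two-country field design
    sites: tuple = None
    countries: tuple = None

    def __post_init__(self):
        n = self.n_loci
        if self.alleles_per_locus is None:
            self.alleles_per_locus = tuple(5 + (i * 3) % 10 for i in range(n))
        if self.motif_lengths is None:
            self.motif_lengths = tuple(3 if i == 4 else 2 for i in range(n))
        if self.null_freqs is None:
            self.null_freqs = tuple(0.0 for _ in range(n))
        k = len(self.subsample_sizes)
        if self.sites is None:
            self.sites = tuple("siteA" if i < 2 else "siteB" for i in range(k))
        if self.countries is None:
            self.countries = tuple("SA" if i < 2 else "MZ" for i in range(k))
        if not (0.0 <= self.target_fst < 0.95):
            raise ValueError("target_fst must lie in [0, 0.95)")
        for p in (*self.null_freqs, self.sad_strength, self.stutter_prob,
                  self.dropout_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.subsample_sizes) < 1:
            raise ValueError("subsample sizes must be >= 1")


def study_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-like conditions: six subsamples 20/10/30/9/7/4, ten loci,
    F_ST = 0.10, and locus-specific null alleles on four of the ten loci
    (the pattern reported for field microsatellite panels)."""
    nulls = [0.0] * 10
    for j, r in zip((0, 2, 6, 8), (0.15, 0.10, 0.08, 0.05)):
        nulls[j] = r
    cfg = dict(null_freqs=tuple(nulls), seed=seed)
    cfg.update(overrides)
    return SimConfig(**cfg)


def _ladder(motif_length: int, n_alleles: int) -> np.ndarray:
    return _BASE_SIZE + motif_length * np.arange(n_alleles)


def simulate_island(config: SimConfig):
    """Draw a GenotypeMatrix under the island model.

    Returns ``(matrix, truth)`` where truth retains ancestral and subsample
    allele frequencies, locus metadata, and the config itself.  F_ST = 0
    short-circuits the Dirichlet draw so subsample frequencies equal the
    ancestral ones exactly.

    Loci with a nonzero configured null-allele frequency carry the null as
    one more allele class inside the Dirichlet draw (it drifts jointly with
    the visible alleles, as a real primer-site mutation would); masking is
    applied at draw time: null homozygotes become MISSING, visible/null
    heterozygotes become apparent homozygotes for the visible allele.
    """
    rng = np.random.default_rng(config.seed)
    k_pops = len(config.subsample_sizes)
    n_total = sum(config.subsample_sizes)
    fst, fis = config.target_fst, config.target_fis

    loci_info, anc_freqs, pop_freqs = [], [], []
    null_mask = np.zeros((n_total, config.n_loci), dtype=bool)
    calls = np.empty((n_total, config.n_loci, 2), dtype=np.int64)
    for j in range(config.n_loci):
        K = config.alleles_per_locus[j]
        mlen = config.motif_lengths[j]
        sizes = _ladder(mlen, K)
        r_null = config.null_freqs[j]
        p = rng.dirichlet(np.ones(K))
        if r_null > 0.0:
            p = np.append(p * (1.0 - r_null), r_null)  # null = class K
        if fst == 0.0:
            sub = np.tile(p, (k_pops, 1))
        else:
            conc = p * (1.0 - fst) / fst
            if (conc <= 0).any():
                raise ValueError("degenerate Dirichlet concentration")
            sub = rng.dirichlet(conc, size=k_pops)
        anc_freqs.append(p)
        pop_freqs.append(sub)
        n_classes = p.size
        row = 0
        for g, n_g in enumerate(config.subsample_sizes):
            a1 = rng.choice(n_classes, size=n_g, p=sub[g])
            a2 = rng.choice(n_classes, size=n_g, p=sub[g])
            if fis > 0:
                ibd = rng.random(n_g) < fis
                a2[ibd] = a1[ibd]
            if r_null > 0.0:
                is_null1, is_null2 = a1 == K, a2 == K
                null_mask[row:row + n_g, j] = is_null1 | is_null2
                # visible/null heterozygote: apparent visible homozygote
                a1 = np.where(is_null1 & ~is_null2, a2, a1)
                a2 = np.where(is_null2 & ~is_null1, a1, a2)
                blank = is_null1 & is_null2
            else:
                blank = np.zeros(n_g, dtype=bool)
            lo = sizes[np.minimum(np.minimum(a1, a2), K - 1)]
            hi = sizes[np.minimum(np.maximum(a1, a2), K - 1)]
            lo[blank] = MISSING
            hi[blank] = MISSING
            calls[row:row + n_g, j, 0] = lo
            calls[row:row + n_g, j, 1] = hi
            row += n_g
        loci_info.append(LocusInfo(
            name=f"L{j + 1:02d}", motif="AC"[:mlen] if mlen == 2 else "ATC",
            motif_length=mlen, allele_range=(int(sizes[0]), int(sizes[-1]))))

    individuals, groups = [], {}
    row = 0
    for g, n_g in enumerate(config.subsample_sizes):
        sub_label = f"S{g + 1}"
        for i in range(n_g):
            uid = f"{sub_label}_{i + 1:03d}"
            individuals.append(uid)
            groups[uid] = (sub_label, config.sites[g], config.countries[g])
        row += n_g
    matrix = GenotypeMatrix(individuals, [li.name for li in loci_info],
                            calls, groups)
    truth = {
        "config": config,
        "loci": loci_info,
        "ancestral_freqs": anc_freqs,
        "subsample_freqs": pop_freqs,
        "null_mask": null_mask,
        "sad_mask": np.zeros((n_total, config.n_loci), dtype=bool),
        "stutter_mask": np.zeros((n_total, config.n_loci), dtype=bool),
        "dropout_mask": np.zeros((n_total, config.n_loci), dtype=bool),
    }
    return matrix, truth


def simulate_study(config: SimConfig):
    """simulate_island (null alleles included in the joint draw) plus the
    config's remaining artifact injections: SAD -> stuttering -> dropout."""
    matrix, truth = simulate_island(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 9151)))
    if config.sad_strength > 0:
        matrix = inject_sad(matrix, config.sad_strength, rng=rng, truth=truth)
    if config.stutter_prob > 0:
        matrix = inject_stutter(matrix, config.stutter_prob,
                                motif_lengths=config.motif_lengths,
                                rng=rng, truth=truth)
    if config.dropout_rate > 0:
        matrix = inject_dropout(matrix, config.dropout_rate, rng=rng,
                                truth=truth)
    return matrix, truth


def _as_rng(rng_or_seed):
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def inject_nulls(matrix: GenotypeMatrix, truth, r_per_locus, rng=0,
                 fst=None) -> GenotypeMatrix:
    """Overlay a segregating null allele of overall frequency r per locus.

    The null allele drifts like any other allele: its per-subsample
    frequency is drawn from the island-model Beta with mean r and
    differentiation ``fst`` (taken from the truth record's config when not
    given), then each gene copy independently mutates to the null with the
    subsample's frequency.  Null homozygotes become MISSING; visible/null
    heterozygotes become apparent homozygotes for the visible allele.
    """
    rng = _as_rng(rng)
    if np.isscalar(r_per_locus):
        r_per_locus = [float(r_per_locus)] * matrix.n_loci
    if fst is None:
        fst = truth["config"].target_fst if truth is not None else 0.0
    labels = matrix.labels("subsample")
    subs = list(dict.fromkeys(labels))
    sub_idx = np.array([subs.index(x) for x in labels])
    calls = matrix.calls.copy()
    for j, r in enumerate(r_per_locus):
        if not (0.0 <= r < 1.0):
            raise ValueError("null frequency must lie in [0, 1)")
        if r == 0.0:
            continue
        if fst > 0.0:
            c = (1.0 - fst) / fst
            r_g = rng.beta(r * c, (1.0 - r) * c, size=len(subs))
        else:
            r_g = np.full(len(subs), r)
        r_ind = r_g[sub_idx]
        present = calls[:, j, 0] != MISSING
        null1 = rng.random(matrix.n_individuals) < r_ind
        null2 = rng.random(matrix.n_individuals) < r_ind
        both = present & null1 & null2
        only1 = present & null1 & ~null2
        only2 = present & ~null1 & null2
        calls[both, j, :] = MISSING
        calls[only1, j, 0] = calls[only1, j, 1]
        calls[only2, j, 1] = calls[only2, j, 0]
        if truth is not None:
            truth["null_mask"][:, j] |= present & (null1 | null2)
            truth.setdefault("null_freqs", {})[j] = r_g
    return GenotypeMatrix(matrix.individuals, matrix.loci, calls, matrix.groups)


def inject_sad(matrix: GenotypeMatrix, strength: float, rng=0, truth=None
               ) -> GenotypeMatrix:
    """Short allele dominance: in each heterozygote the larger allele drops
    out (call becomes an apparent homozygote for the smaller allele) with
    probability strength * rank_difference / max_rank_difference, where ranks
    order the locus's observed allele ladder by fragment size."""
    rng = _as_rng(rng)
    if not (0.0 <= strength <= 1.0):
        raise ValueError("strength must lie in [0, 1]")
    calls = matrix.calls.copy()
    for j in range(matrix.n_loci):
        alleles = matrix.alleles(j)
        if alleles.size < 2:
            continue
        rank = {int(a): k for k, a in enumerate(alleles)}
        max_diff = alleles.size - 1
        lo = np.minimum(calls[:, j, 0], calls[:, j, 1])
        hi = np.maximum(calls[:, j, 0], calls[:, j, 1])
        het = (lo != hi) & (lo != MISSING)
        for i in np.flatnonzero(het):
            d = rank[int(hi[i])] - rank[int(lo[i])]
            if rng.random() < strength * d / max_diff:
                calls[i, j, :] = lo[i]
                if truth is not None:
                    truth["sad_mask"][i, j] = True
    return GenotypeMatrix(matrix.individuals, matrix.loci, calls, matrix.groups)


def inject_stutter(matrix: GenotypeMatrix, prob: float, motif_lengths,
                   rng=0, truth=None) -> GenotypeMatrix:
    """Stuttering: heterozygotes whose alleles are exactly one motif unit
    apart are miscalled homozygous for the smaller allele with probability
    ``prob``."""
    rng = _as_rng(rng)
    if not (0.0 <= prob <= 1.0):
        raise ValueError("prob must lie in [0, 1]")
    if np.isscalar(motif_lengths):
        motif_lengths = [int(motif_lengths)] * matrix.n_loci
    calls = matrix.calls.copy()
    for j in range(matrix.n_loci):
        step = motif_lengths[j]
        lo = np.minimum(calls[:, j, 0], calls[:, j, 1])
        hi = np.maximum(calls[:, j, 0], calls[:, j, 1])
        one_step = (lo != MISSING) & (hi - lo == step)
        hit = one_step & (rng.random(matrix.n_individuals) < prob)
        calls[hit, j, 0] = lo[hit]
        calls[hit, j, 1] = lo[hit]
        if truth is not None:
            truth["stutter_mask"][:, j] |= hit
    return GenotypeMatrix(matrix.individuals, matrix.loci, calls, matrix.groups)


def inject_dropout(matrix: GenotypeMatrix, rate: float, rng=0, truth=None
                   ) -> GenotypeMatrix:
    """Random whole-genotype dropout: each call becomes MISSING with
    probability ``rate`` (amplification failure unrelated to genotype)."""
    rng = _as_rng(rng)
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    calls = matrix.calls.copy()
    hit = rng.random((matrix.n_individuals, matrix.n_loci)) < rate
    calls[hit] = MISSING
    if truth is not None:
        truth["dropout_mask"] |= hit
    return GenotypeMatrix(matrix.individuals, matrix.loci, calls, matrix.groups)


def simulate_wright_fisher(ne: int = 50, n_loci: int = 10,
                           n_alleles: int = 8, n_sample: int = 50,
                           generations: int = 20, motif_length: int = 2,
                           seed: int = 0):
    """Forward Wright-Fisher simulation of one isolated population.

    ``ne`` diploid individuals mate randomly (two parents drawn with
    replacement per offspring; each parent transmits one random allele per
    locus, loci unlinked).  Drift over ``generations`` generations creates
    the identity-by-descent and mixture LD that the Ne estimators read;
    ``n_sample`` individuals (with replacement if n_sample > ne) are
    genotyped.  Returns ``(GenotypeMatrix, truth)`` with the true Ne in
    truth.
    """
    rng = np.random.default_rng(seed)
    # founder population: each gene copy an independent draw from a uniform
    # allele pool, so initial diversity is high and LD zero
    pop = rng.integers(0, n_alleles, size=(ne, n_loci, 2))
    for _ in range(generations):
        mothers = rng.integers(0, ne, size=ne)
        fathers = rng.integers(0, ne, size=ne)
        new = np.empty_like(pop)
        pick_m = rng.integers(0, 2, size=(ne, n_loci))
        pick_f = rng.integers(0, 2, size=(ne, n_loci))
        rows = np.arange(ne)[:, None]
        cols = np.arange(n_loci)[None, :]
        new[:, :, 0] = pop[mothers[:, None], cols, pick_m]
        new[:, :, 1] = pop[fathers[:, None], cols, pick_f]
        del rows
        pop = new
    take = rng.choice(ne, size=n_sample, replace=n_sample > ne)
    sizes = _ladder(motif_length, n_alleles)
    calls = sizes[pop[take]]
    calls = np.sort(calls, axis=2).astype(np.int64)
    individuals = [f"wf_{i + 1:03d}" for i in range(n_sample)]
    groups = {ind: ("WF", "WF", "WF") for ind in individuals}
    matrix = GenotypeMatrix(
        individuals, [f"L{j + 1:02d}" for j in range(n_loci)], calls, groups)
    return matrix, {"ne": ne, "generations": generations}


# -- sequence simulation for marker discovery --------------------------------

def simulate_genome_with_ssrs(n_contigs: int = 1, length: int = 50_000,
                              planted=None, seed: int = 0,
                              duplicate_flanks: int = 0):
    """Random background sequence with planted perfect repeats.

    ``planted`` is a list of dicts with keys motif, n_repeats and optionally
    contig/offset; unplaced repeats get non-overlapping random offsets.
    ``duplicate_flanks`` copies the 40 bp context around that many planted
    repeats elsewhere in the genome, creating non-unique flanks.

    Returns ``(contigs, truth)``: contigs maps contig ID -> sequence string,
    truth is a list of records with exact 0-based half-open spans.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    contigs = {
        f"contig{c + 1}": rng.choice(bases, size=length)
        for c in range(n_contigs)
    }
    planted = list(planted or [])
    truth = []
    used = {name: [] for name in contigs}

    def free_offset(name, span):
        for _ in range(1000):
            off = int(rng.integers(100, length - span - 100))
            if all(off + span + 50 < s or off > e + 50 for s, e in used[name]):
                used[name].append((off, off + span))
                return off
        raise RuntimeError("could not place repeat without overlap")

    for spec_rec in planted:
        motif = spec_rec["motif"].upper()
        n_rep = int(spec_rec["n_repeats"])
        name = spec_rec.get("contig") or f"contig{1 + len(truth) % n_contigs}"
        span = len(motif) * n_rep
        off = spec_rec.get("offset")
        if off is None:
            off = free_offset(name, span)
        else:
            used[name].append((off, off + span))
        arr = contigs[name]
        arr[off:off + span] = list(motif * n_rep)
        # break accidental extension at both edges
        if off > 0 and arr[off - 1] == motif[-1]:
            arr[off - 1] = "G" if motif[-1] != "G" else "T"
        tail = off + span
        if tail < length and arr[tail] == motif[0]:
            arr[tail] = "G" if motif[0] != "G" else "T"
        truth.append({"contig": name, "start": int(off),
                      "end": int(off + span), "motif": motif,
                      "n_repeats": n_rep})

    for rec in truth[:duplicate_flanks]:
        arr = contigs[rec["contig"]]
        s = max(rec["start"] - 20, 0)
        e = min(rec["end"] + 20, length)
        block = arr[s:e].copy()
        tgt = free_offset(rec["contig"], e - s)
        contigs[rec["contig"]][tgt:tgt + (e - s)] = block
        rec["duplicated"] = True

    return {k: "".join(v) for k, v in contigs.items()}, truth


def write_fasta(contigs: dict, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in contigs.items()]
    SeqIO.write(records, path, "fasta")


def config_to_json(config: SimConfig) -> dict:
    return dataclasses.asdict(config)
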