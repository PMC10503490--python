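"""Data model and I/O for codominant microsatellite genotypes.

Genotypes are unordered diploid pairs of allele sizes (fragment lengths in
bp).  A call is either complete (two positive integer sizes) or MISSING;
half-missing calls are normalized to MISSING on input, because every
downstream estimator treats data as complete-diploid-or-blank.

Samples carry a fixed three-level grouping hierarchy
(subsample / site / country), matching the trap-as-subpopulation convention
of field studies where each trap (or pooled nearby traps) is treated as one
subpopulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

#: Reserved sentinel for a missing (blank) genotype; never a valid allele size.
MISSING = -1

#: Allele code used when blanks are recoded as null-allele homozygotes.
NULL_ALLELE = 999

_LEVELS = ("subsample", "site", "country", "all")


@dataclass(frozen=True)
class LocusInfo:
    """Descriptive metadata for one microsatellite locus."""

    name: str
    motif: str = ""
    motif_length: int = 2
    allele_range: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if not (1 <= self.motif_length <= 6):
            raise ValueError("motif_length must be in 1..6")
        lo, hi = self.allele_range
        if lo > hi:
            raise ValueError("allele_range min must be <= max")


class GenotypeMatrix:
    """Diploid allele-size calls for individuals x loci with grouping labels.

    Parameters
    ----------
    individuals : sequence of str
        Unique individual identifiers.
    loci : sequence of str
        Locus names.
    calls : ndarray of shape (n_individuals, n_loci, 2)
        Allele sizes in bp (positive integers) or ``MISSING`` in both slots.
    groups : mapping individual -> (subsample, site, country)
        Hierarchical sample labels.  Site/country default to the subsample
        label when a flat design is supplied.
    """

    ploidy = 2

    def __init__(self, individuals, loci, calls, groups):
        self.individuals = list(individuals)
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        # normalize half-missing to MISSING; forbid nonpositive allele codes
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            calls = calls.copy()
            calls[half] = MISSING
        valid = (calls > 0) | (calls == MISSING)
        if not valid.all():
            bad = calls[~valid].ravel()[0]
            raise ValueError(f"invalid allele code {bad}: sizes must be positive")
        self.calls = calls
        self.groups = {}
        for ind in self.individuals:
            g = groups[ind]
            if isinstance(g, str):
                g = (g, g, g)
            g = tuple(g)
            if len(g) != 3:
                raise ValueError("group labels must be (subsample, site, country)")
            self.groups[ind] = g

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def labels(self, level: str = "subsample") -> np.ndarray:
        """Group label per individual at the requested hierarchy level."""
        if level == "all":
            return np.array(["all"] * self.n_individuals)
        if level not in _LEVELS:
            raise ValueError(f"unknown grouping level {level!r}")
        idx = _LEVELS.index(level)
        return np.array([self.groups[i][idx] for i in self.individuals])

    def subsamples(self) -> list[str]:
        """Distinct subsample labels in order of first appearance."""
        return list(dict.fromkeys(self.labels("subsample")))

    def missing_mask(self) -> np.ndarray:
        """(n_individuals, n_loci) boolean mask of MISSING calls."""
        return self.calls[:, :, 0] == MISSING

    def alleles(self, locus) -> np.ndarray:
        """Sorted distinct allele sizes observed at a locus."""
        j = self._locus_index(locus)
        vals = self.calls[:, j, :].ravel()
        return np.unique(vals[vals != MISSING])

    def _locus_index(self, locus) -> int:
        if isinstance(locus, str):
            return self.loci.index(locus)
        return int(locus)

    # -- subsetting ----------------------------------------------------------

    def select_loci(self, loci) -> "GenotypeMatrix":
        idx = [self._locus_index(l) for l in loci]
        return GenotypeMatrix(
            self.individuals,
            [self.loci[j] for j in idx],
            self.calls[:, idx, :],
            self.groups,
        )

    def select_individuals(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            keep = np.flatnonzero(mask_or_ids)
        else:
            pos = {ind: i for i, ind in enumerate(self.individuals)}
            keep = [pos[i] for i in mask_or_ids]
        inds = [self.individuals[i] for i in keep]
        return GenotypeMatrix(inds, self.loci, self.calls[keep], self.groups)

    def __eq__(self, other):
        return (
            isinstance(other, GenotypeMatrix)
            and self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and self.groups == other.groups
        )

    def __repr__(self):
        return (
            f"GenotypeMatrix({self.n_individuals} individuals, "
            f"{self.n_loci} loci, {len(self.subsamples())} subsamples)"
        )


@dataclass
class AlleleFrequencyTable:
    """Relative allele frequencies per (group, locus).

    ``freqs[(group, locus)]`` maps allele size -> relative frequency among
    counted gene copies; ``sizes[(group, locus)]`` is the number of gene
    copies counted (2 x non-missing calls).  Empty cells have size 0 and no
    frequency entry.
    """

    groups: list[str]
    loci: list[str]
    freqs: dict = field(default_factory=dict)
    sizes: dict = field(default_factory=dict)

    def frequency(self, group, locus, allele) -> float:
        return self.freqs.get((group, locus), {}).get(allele, 0.0)


def allele_frequencies(matrix: GenotypeMatrix, grouping_level: str = "subsample"
                       ) -> AlleleFrequencyTable:
    """Tally relative allele frequencies at a grouping level.

    MISSING calls contribute zero gene copies; a (group, locus) cell where
    every call is missing gets sample size 0 and an empty frequency map.
    """
    labels = matrix.labels(grouping_level)
    group_order = list(dict.fromkeys(labels))
    table = AlleleFrequencyTable(groups=group_order, loci=list(matrix.loci))
    for g in group_order:
        rows = np.flatnonzero(labels == g)
        for j, locus in enumerate(matrix.loci):
            vals = matrix.calls[rows, j, :].ravel()
            vals = vals[vals != MISSING]
            table.sizes[(g, locus)] = vals.size
            if vals.size:
                alleles, counts = np.unique(vals, return_counts=True)
                table.freqs[(g, locus)] = {
                    int(a): c / vals.size for a, c in zip(alleles, counts)
                }
            else:
                table.freqs[(g, locus)] = {}
    return table


def recode_missing_as_null(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Recode blanks as homozygotes for the null allele (999/999).

    This is the convention used before null-allele-aware differentiation
    estimates: a blank is interpreted as a null homozygote, so the null
    allele joins the allele universe of every locus that had blanks.
    """
    for j, locus in enumerate(matrix.loci):
        if NULL_ALLELE in matrix.alleles(locus):
            raise ValueError(
                f"allele {NULL_ALLELE} already present at locus {locus}: "
                "cannot recode missing as null"
            )
    calls = matrix.calls.copy()
    calls[calls == MISSING] = NULL_ALLELE
    return GenotypeMatrix(matrix.individuals, matrix.loci, calls, matrix.groups)


# -- Genepop dialect ---------------------------------------------------------

def read_genepop(path) -> GenotypeMatrix:
    """Read a Genepop file (2- or 3-digit allele codes).

    One subsample per POP block; the all-zero genotype becomes MISSING.
    Subsample labels are taken from the last comma-separated token of each
    block's first individual ID (the Genepop convention) when distinct,
    otherwise POP blocks are numbered.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 2:
        raise ValueError("Genepop file too short: missing title or locus names")
    it = iter(enumerate(lines, start=1))
    next(it)  # title line
    loci: list[str] = []
    pops: list[list[tuple[str, list[str]]]] = []
    for lineno, ln in it:
        stripped = ln.strip()
        if stripped.upper() == "POP":
            pops.append([])
            continue
        if not pops:
            # locus-name section: one per line, or comma-separated
            loci.extend(tok.strip() for tok in stripped.split(",") if tok.strip())
            continue
        if "," not in ln:
            raise ValueError(f"line {lineno}: expected 'id , genotypes' format")
        ident, _, geno = ln.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"line {lineno}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        pops[-1].append((ident.strip(), tokens))
    if not pops:
        raise ValueError("no POP blocks found")
    widths = {len(t) for blk in pops for _, toks in blk for t in toks}
    if not widths <= {4, 6}:
        raise ValueError(
            f"unknown allele-code width: genotype token lengths {sorted(widths)}"
        )

    individuals, groups, rows = [], {}, []
    pop_names = []
    for k, blk in enumerate(pops):
        name = blk[0][0].split(",")[-1].strip() if blk else f"pop{k + 1}"
        pop_names.append(name or f"pop{k + 1}")
    if len(set(pop_names)) != len(pop_names):
        pop_names = [f"pop{k + 1}" for k in range(len(pops))]
    seen = set()
    for name, blk in zip(pop_names, pops):
        for ident, tokens in blk:
            uid = ident
            while uid in seen:
                uid += "_"
            seen.add(uid)
            row = []
            for tok in tokens:
                w = len(tok) // 2
                a1, a2 = int(tok[:w]), int(tok[w:])
                if a1 == 0 or a2 == 0:
                    row.append((MISSING, MISSING))
                else:
                    row.append((a1, a2))
            individuals.append(uid)
            groups[uid] = (name, name, name)
            rows.append(row)
    calls = np.array(rows, dtype=np.int64).reshape(len(individuals), len(loci), 2)
    return GenotypeMatrix(individuals, loci, calls, groups)


def write_genepop(matrix: GenotypeMatrix, path, digits: int = 3,
                  title: str = "msatpop export") -> None:
    """Write Genepop with fixed-width allele codes; MISSING as zeros."""
    limit = 10 ** digits
    vals = matrix.calls[matrix.calls != MISSING]
    if vals.size and vals.max() >= limit:
        raise ValueError(
            f"allele size {vals.max()} does not fit in {digits} digits"
        )
    labels = matrix.labels("subsample")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in matrix.loci:
            fh.write(locus + "\n")
        for sub in matrix.subsamples():
            fh.write("POP\n")
            for i in np.flatnonzero(labels == sub):
                toks = []
                for j in range(matrix.n_loci):
                    a1, a2 = matrix.calls[i, j]
                    if a1 == MISSING:
                        a1 = a2 = 0
                    toks.append(f"{a1:0{digits}d}{a2:0{digits}d}")
                fh.write(f"{sub} , " + " ".join(toks) + "\n")


# -- CSV convenience dialect -------------------------------------------------

def read_csv(path) -> GenotypeMatrix:
    """Read the CSV dialect: header id,subsample,site,country,<locus>_1,<locus>_2,...

    Missing alleles are coded 0; a half-missing pair is normalized to MISSING.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype={"id": str, "subsample": str,
                                  "site": str, "country": str})
    meta = ["id", "subsample", "site", "country"]
    if list(df.columns[:4]) != meta:
        raise ValueError(f"CSV header must start with {','.join(meta)}")
    allele_cols = list(df.columns[4:])
    loci = []
    for c in allele_cols:
        base, _, slot = c.rpartition("_")
        if slot not in {"1", "2"} or not base:
            raise ValueError(f"bad allele column {c!r}: expected <locus>_1/_2")
        if base not in loci:
            loci.append(base)
    expected = [f"{l}_{s}" for l in loci for s in ("1", "2")]
    if allele_cols != expected:
        raise ValueError("allele columns must come in <locus>_1,<locus>_2 pairs")
    calls = df[allele_cols].to_numpy(dtype=np.int64).reshape(len(df), len(loci), 2)
    calls[calls == 0] = MISSING
    groups = {r.id: (r.subsample, r.site, r.country) for r in df.itertuples()}
    return GenotypeMatrix(df["id"].tolist(), loci, calls, groups)


def write_csv(matrix: GenotypeMatrix, path) -> None:
    import pandas as pd

    cols = {"id": matrix.individuals,
            "subsample": matrix.labels("subsample"),
            "site": matrix.labels("site"),
            "country": matrix.labels("country")}
    flat = matrix.calls.reshape(matrix.n_individuals, -1).copy()
    flat[flat == MISSING] = 0
    for k, name in enumerate(
            itertools.chain.from_iterable(
                ((f"{l}_1", f"{l}_2") for l in matrix.loci))):
        cols[name] = flat[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)
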