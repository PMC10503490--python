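"""Between-population structure: chord distances, NJ trees, and FCA.

Cavalli-Sforza & Edwards chord distances treat allele frequency vectors as
points on a hypersphere (square-root transform) and measure the angular
separation; the per-locus form used here is

    D_l = (2/pi) * sqrt(2 * (1 - sum_a sqrt(x_a * y_a)))

averaged over loci, which is the variant propagated by the FreeNA lineage
of software.  The "including null alleles" (INA) correction appends the
estimated null allele as an extra allele class of frequency r_hat per
subsample and rescales visible frequencies by (1 - r_hat).

The neighbour-joining implementation follows Saitou & Nei's agglomeration
with the usual guard for negative branch lengths (clamped to zero, deficit
transferred to the sister branch so path lengths are preserved).

Factorial correspondence analysis operates on the individuals x alleles
copy-count indicator table (0/1/2 coding) under the chi-square metric;
axis significance uses the broken-stick criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, allele_frequencies

__all__ = [
    "DistanceMatrix", "OrdinationResult",
    "chord_distance", "chord_distance_matrix", "nj_tree", "fca",
    "broken_stick",
]

_MAX_LOCUS_CHORD = (2.0 / math.pi) * math.sqrt(2.0)


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(self.values) != 0).any():
            raise ValueError("diagonal must be exactly 0")
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")


@dataclass
class OrdinationResult:
    coordinates: np.ndarray       # individuals x axes
    eigenvalues: np.ndarray
    percent_inertia: np.ndarray
    row_labels: list
    significant_axes: int = 0
    dropped_rows: list = field(default_factory=list)


def chord_distance(freqs_x: dict, freqs_y: dict) -> float:
    """Single-locus chord distance between two allele-frequency maps."""
    if not freqs_x or not freqs_y:
        raise ValueError("empty frequency vector")
    alleles = set(freqs_x) | set(freqs_y)
    s = sum(math.sqrt(freqs_x.get(a, 0.0) * freqs_y.get(a, 0.0))
            for a in alleles)
    return (2.0 / math.pi) * math.sqrt(2.0 * max(1.0 - s, 0.0))


def _ina_correct(freqs: dict, r: float) -> dict:
    if r <= 0:
        return dict(freqs)
    out = {a: f * (1.0 - r) for a, f in freqs.items()}
    out["__null__"] = r
    return out


def chord_distance_matrix(matrix: GenotypeMatrix, level: str = "subsample",
                          null_estimates=None) -> DistanceMatrix:
    """Pairwise multilocus chord distances between groups (or individuals).

    ``level`` may be a grouping level or "individual" (frequencies 0 / 0.5
    / 1 per individual).  ``null_estimates`` (locus -> NullAlleleEstimate)
    switches on the INA correction; with r_hat = 0 everywhere it reduces
    to the uncorrected distance.
    """
    if level == "individual":
        units = list(matrix.individuals)
        freq_of = {}
        for i, ind in enumerate(units):
            for j, locus in enumerate(matrix.loci):
                a1, a2 = matrix.calls[i, j]
                if a1 == MISSING:
                    freq_of[(ind, locus)] = {}
                elif a1 == a2:
                    freq_of[(ind, locus)] = {int(a1): 1.0}
                else:
                    freq_of[(ind, locus)] = {int(a1): 0.5, int(a2): 0.5}
        null_r = {}
    else:
        table = allele_frequencies(matrix, level)
        units = table.groups
        freq_of = {(g, l): table.freqs[(g, l)]
                   for g in units for l in matrix.loci}
        null_r = {}
        if null_estimates:
            for locus, est in null_estimates.items():
                for g, rec in est.by_group.items():
                    null_r[(g, locus)] = rec["r"]
    n = len(units)
    d = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            per_locus = []
            for locus in matrix.loci:
                fx = freq_of[(units[i], locus)]
                fy = freq_of[(units[k], locus)]
                if not fx or not fy:
                    continue
                fx = _ina_correct(fx, null_r.get((units[i], locus), 0.0))
                fy = _ina_correct(fy, null_r.get((units[k], locus), 0.0))
                per_locus.append(chord_distance(fx, fy))
            d[i, k] = d[k, i] = float(np.mean(per_locus)) if per_locus else 0.0
    return DistanceMatrix(list(units), d)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbour-joining tree (Saitou-Nei), returned as a Newick string.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.  The result is unrooted (trifurcating root).
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need >=3 taxa")
    d = dm.values.astype(float).copy()
    nodes = [f"{_escape(l)}" for l in labels]
    active = list(range(n))

    def join(i, j, li, lj):
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        return f"({nodes[i]}:{li:.17g},{nodes[j]}:{lj:.17g})"

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        newick = join(i, j, li, lj)
        # distances from the new node u to every other active node
        du = {}
        for ak in active:
            if ak in (i, j):
                continue
            du[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for ak, val in du.items():
            d[u, ak] = d[ak, u] = max(val, 0.0)
        nodes.append(newick)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    parts = []
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        parts.append(f"{nodes[idx]}:{max(ln, 0.0):.17g}")
    return "(" + ",".join(parts) + ");"


def _escape(label: str) -> str:
    if any(ch in label for ch in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def indicator_table(matrix: GenotypeMatrix):
    """Individuals x alleles copy-count table (0/1/2 coding).

    MISSING calls contribute zeros for that locus's columns, which shrinks
    the individual toward the origin on the affected axes.
    Returns ``(X, column_labels)``.
    """
    cols, blocks = [], []
    for j, locus in enumerate(matrix.loci):
        alleles = matrix.alleles(j)
        lut = {int(a): k for k, a in enumerate(alleles)}
        block = np.zeros((matrix.n_individuals, len(alleles)))
        for i in range(matrix.n_individuals):
            a1, a2 = matrix.calls[i, j]
            if a1 != MISSING:
                block[i, lut[int(a1)]] += 1
                block[i, lut[int(a2)]] += 1
        blocks.append(block)
        cols.extend(f"{locus}:{int(a)}" for a in alleles)
    return np.hstack(blocks), cols


def fca(matrix: GenotypeMatrix, k_axes: int = 10) -> OrdinationResult:
    """Factorial correspondence analysis of the genotype indicator table.

    Correspondence analysis under the chi-square metric on row profiles;
    returns individual coordinates, eigenvalues (squared singular values),
    percent inertia per axis, and the broken-stick significant-axis count.
    All-zero rows (no genotypes at all) are dropped with a record.
    """
    X, cols = indicator_table(matrix)
    row_tot = X.sum(axis=1)
    keep = row_tot > 0
    dropped = [ind for ind, k in zip(matrix.individuals, keep) if not k]
    X = X[keep]
    labels = [ind for ind, k in zip(matrix.individuals, keep) if k]
    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    pos = c > 0
    P, c = P[:, pos], c[pos]
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sing, Vt = np.linalg.svd(S, full_matrices=False)
    lam = sing ** 2
    nz = lam > lam[0] * 1e-12 if lam.size and lam[0] > 0 else lam > 0
    lam = lam[nz]
    U, sing = U[:, nz], sing[nz]
    coords = (U * sing) / np.sqrt(r)[:, None]
    pct = 100.0 * lam / lam.sum()
    n_sig = broken_stick(lam, k=min(k_axes, lam.size))
    return OrdinationResult(coords, lam, pct, labels, n_sig, dropped)


def broken_stick(eigenvalues, k: int = 10) -> int:
    """Count of leading axes whose inertia share beats the broken stick.

    With p axes total, the expected share of the i-th largest stick piece
    is b_i = (1/p) * sum_{j=i..p} 1/j; axis i is significant iff
    lambda_i / sum(lambda) > b_i, and counting stops at the first failure.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or lam.sum() <= 0:
        raise ValueError("eigenvalue sum must be positive")
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    p = lam.size
    rel = lam / lam.sum()
    b = np.array([(1.0 / p) * sum(1.0 / j for j in range(i, p + 1))
                  for i in range(1, p + 1)])
    count = 0
    for i in range(min(k, p)):
        if rel[i] > b[i]:
            count += 1
        else:
            break
    return count
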