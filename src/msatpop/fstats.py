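"""Weir & Cockerham F-statistics with resampling inference.

Implements the three-level ANOVA variance decomposition of allele-frequency
variation (Weir & Cockerham 1984): for every allele at every locus the
among-subsample (a), among-individual-within-subsample (b) and
within-individual (c) components are estimated and summed over alleles.

Single- and multilocus statistics are ratios of summed components
("ratio of sums", the FSTAT convention)::

    F_IS = 1 - sum(c) / sum(b + c)
    F_ST = sum(a) / sum(a + b + c)
    F_IT = 1 - sum(c) / sum(a + b + c)

which preserves the identity (1 - F_IT) = (1 - F_IS)(1 - F_ST) exactly.

Inference follows field practice: permutation of gene copies among
individuals within subsamples for F_IS, permutation of whole individuals
among subsamples with a log-likelihood-ratio G statistic for differentiation,
bootstrap over loci for confidence intervals, and delete-one-subsample
jackknife for per-locus standard errors.  Missing calls exclude the
individual locus-wise; unbiased estimates may legitimately be negative and
are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import MISSING, GenotypeMatrix

__all__ = [
    "VarianceComponents", "FStatResult", "LDTestResult",
    "wc_components", "wc_per_allele", "f_statistics", "permute_fis_test",
    "g_test_differentiation", "bootstrap_ci_loci",
    "jackknife_fis_populations", "ld_pairwise_tests", "by_adjust",
]


@dataclass
class VarianceComponents:
    """Summed-over-alleles variance components for one locus."""

    locus: str
    a: float          # among subsamples
    b: float          # among individuals within subsamples
    c: float          # within individuals
    n_individuals: int
    n_subsamples: int
    uninformative: bool = False

    @property
    def fis(self) -> float:
        return 1.0 - self.c / (self.b + self.c) if (self.b + self.c) else np.nan

    @property
    def fst(self) -> float:
        tot = self.a + self.b + self.c
        return self.a / tot if tot else np.nan

    @property
    def fit(self) -> float:
        tot = self.a + self.b + self.c
        return 1.0 - self.c / tot if tot else np.nan


@dataclass
class FStatResult:
    """Per-locus and multilocus F-statistics with optional inference."""

    components: list
    fis: float = np.nan
    fst: float = np.nan
    fit: float = np.nan
    fis_ci: tuple = None
    fst_ci: tuple = None
    fit_ci: tuple = None
    fis_p: float = None
    fst_p: float = None
    per_locus: dict = field(default_factory=dict)


@dataclass
class LDTestResult:
    locus_a: str
    locus_b: str
    g: float
    p: float
    p_adjusted: float = None


# -- internal fast representation -------------------------------------------

class _LocusData:
    """Per-locus arrays for individuals with a complete call.

    Carries everything W&C needs: subsample index, allele indices, and the
    frequency-dependent quantities that are invariant under within-subsample
    gene-copy permutation (allele counts per subsample do not change, only
    which copies pair up inside individuals).
    """

    __slots__ = ("pop", "g1", "g2", "n_alleles", "n_i", "r", "nbar", "nc",
                 "pbar", "s2", "n_total", "pop_slices", "order",
                 "allele_sizes")

    def __init__(self, pop, g1, g2, n_alleles, allele_sizes=None):
        self.allele_sizes = allele_sizes
        self.pop = pop
        self.g1 = g1
        self.g2 = g2
        self.n_alleles = n_alleles
        counts = np.bincount(pop)
        keep = counts > 0
        # reindex pops compactly (pops with no data at this locus drop out)
        remap = np.cumsum(keep) - 1
        self.pop = remap[pop]
        self.n_i = counts[keep].astype(float)
        self.r = int(keep.sum())
        if self.r >= 1:
            n_i = self.n_i
            self.nbar = n_i.mean()
            # r = 1 limit: no among-subsample component, nc degenerates to nbar
            self.nc = (self.nbar if self.r == 1 else
                       (self.r * self.nbar -
                        (n_i ** 2).sum() / (self.r * self.nbar)) / (self.r - 1))
            C = np.zeros((self.r, n_alleles))
            np.add.at(C, (self.pop, self.g1), 1.0)
            np.add.at(C, (self.pop, self.g2), 1.0)
            self.n_total = n_i.sum()
            p_i = C / (2.0 * n_i[:, None])
            self.pbar = C.sum(axis=0) / (2.0 * self.n_total)
            self.s2 = (np.zeros_like(self.pbar) if self.r == 1 else
                       (n_i[:, None] * (p_i - self.pbar) ** 2).sum(axis=0)
                       / ((self.r - 1) * self.nbar))
        order = np.argsort(self.pop, kind="stable")
        self.order = order
        bounds = np.searchsorted(self.pop[order], np.arange(self.r + 1))
        self.pop_slices = [(bounds[k], bounds[k + 1]) for k in range(self.r)]

    def het_counts(self, g1=None, g2=None) -> np.ndarray:
        """Heterozygote-for-allele counts summed over subsamples."""
        if g1 is None:
            g1, g2 = self.g1, self.g2
        het = g1 != g2
        return np.bincount(
            np.concatenate([g1[het], g2[het]]), minlength=self.n_alleles
        ).astype(float)

    def abc_arrays(self, hbar_counts) -> tuple:
        """Per-allele component arrays given total het-for-allele counts."""
        nbar, nc, r = self.nbar, self.nc, self.r
        hbar = hbar_counts / self.n_total
        pbar, s2 = self.pbar, self.s2
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        if r == 1:
            a = np.zeros_like(pbar)
        else:
            a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        return a, b, c

    def abc(self, hbar_counts) -> tuple:
        """Summed components given total het-for-allele counts."""
        a, b, c = self.abc_arrays(hbar_counts)
        return a.sum(), b.sum(), c.sum()


def _locus_data(matrix: GenotypeMatrix, j: int, level: str = "subsample"
                ) -> _LocusData:
    labels = matrix.labels(level)
    pop_order = list(dict.fromkeys(labels))
    pop_idx = np.array([pop_order.index(x) for x in labels])
    calls = matrix.calls[:, j, :]
    present = calls[:, 0] != MISSING
    alleles = np.unique(calls[present])
    lut = {a: k for k, a in enumerate(alleles)}
    g1 = np.array([lut[a] for a in calls[present, 0]], dtype=np.intp)
    g2 = np.array([lut[a] for a in calls[present, 1]], dtype=np.intp)
    return _LocusData(pop_idx[present], g1, g2, max(len(alleles), 1),
                      allele_sizes=alleles)


def wc_per_allele(matrix: GenotypeMatrix, locus, level: str = "subsample"):
    """Per-allele (a, b, c) component arrays plus allele sizes.

    Returns ``(allele_sizes, a, b, c)`` with one entry per observed allele;
    the allele-vs-rest biallelic decomposition that the size-dependent
    dropout (SAD) diagnostics regress on.
    """
    j = matrix._locus_index(locus)
    ld = _locus_data(matrix, j, level)
    if ld.r < 1:
        raise ValueError("no subsample with data")
    if ld.n_alleles < 2 or ld.nbar <= 1:
        raise ValueError("locus uninformative for per-allele components")
    a, b, c = ld.abc_arrays(ld.het_counts())
    return ld.allele_sizes, a, b, c


# -- public estimators -------------------------------------------------------

def wc_components(matrix: GenotypeMatrix, locus, level: str = "subsample"
                  ) -> VarianceComponents:
    """Weir-Cockerham variance components for one locus.

    Individuals with a MISSING call at this locus are excluded locus-wise.
    A monomorphic locus yields (0, 0, 0) flagged uninformative.
    """
    j = matrix._locus_index(locus)
    ld = _locus_data(matrix, j, level)
    if ld.r < 1:
        raise ValueError(
            f"locus {matrix.loci[j]}: no subsample with data"
        )
    if ld.n_alleles < 2:
        return VarianceComponents(matrix.loci[j], 0.0, 0.0, 0.0,
                                  int(ld.n_total), ld.r, uninformative=True)
    if ld.nbar <= 1:
        raise ValueError(
            f"locus {matrix.loci[j]}: mean sample size <=1, components undefined"
        )
    a, b, c = ld.abc(ld.het_counts())
    return VarianceComponents(matrix.loci[j], a, b, c,
                              int(ld.n_total), ld.r)


def f_statistics(matrix: GenotypeMatrix, loci=None, level: str = "subsample"
                 ) -> FStatResult:
    """Per-locus and multilocus F_IS / F_ST / F_IT (ratio of sums)."""
    loci = list(matrix.loci) if loci is None else list(loci)
    comps = [wc_components(matrix, l, level) for l in loci]
    informative = [v for v in comps if not v.uninformative]
    if not informative:
        raise ValueError("no polymorphism: all loci uninformative")
    A = sum(v.a for v in informative)
    B = sum(v.b for v in informative)
    C = sum(v.c for v in informative)
    res = FStatResult(
        components=comps,
        fis=1.0 - C / (B + C) if (B + C) != 0 else np.nan,
        fst=A / (A + B + C) if (A + B + C) != 0 else np.nan,
        fit=1.0 - C / (A + B + C) if (A + B + C) != 0 else np.nan,
    )
    res.per_locus = {
        v.locus: {"fis": v.fis, "fst": v.fst, "fit": v.fit} for v in comps
    }
    return res


def permute_fis_test(matrix: GenotypeMatrix, n_perm: int = 10_000,
                     seed=0, level: str = "subsample",
                     alternative: str = "two-sided"):
    """Permutation test of F_IS: alleles shuffled among individuals within
    subsamples, independently per locus, preserving the missingness pattern.

    Returns ``(fis_observed, p)``.  With no within-subsample freedom (every
    subsample holds <=1 genotyped individual) every permutation reproduces
    the observed statistic and p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    every = [_locus_data(matrix, j) for j in range(matrix.n_loci)]
    data = [ld for ld in every
            if ld.r >= 1 and ld.n_alleles >= 2 and ld.nbar > 1]
    if not data:
        if any(ld.n_alleles >= 2 for ld in every):
            # polymorphism exists but every subsample holds <=1 genotyped
            # individual: no within-group freedom, every permutation is a
            # no-op and the test is vacuous
            return np.nan, 1.0
        raise ValueError("no informative loci")

    def multilocus_fis(hbars):
        B = C = 0.0
        for ld, h in zip(data, hbars):
            _, b, c = ld.abc(h)
            B += b
            C += c
        return 1.0 - C / (B + C)

    obs = multilocus_fis([ld.het_counts() for ld in data])
    count = 0
    for _ in range(n_perm):
        hbars = []
        for ld in data:
            copies = np.empty(2 * ld.g1.size, dtype=np.intp)
            copies[0::2] = ld.g1[ld.order]
            copies[1::2] = ld.g2[ld.order]
            for lo, hi in ld.pop_slices:
                seg = copies[2 * lo:2 * hi]
                rng.shuffle(seg)
            hbars.append(ld.het_counts(copies[0::2], copies[1::2]))
        stat = multilocus_fis(hbars)
        if alternative == "two-sided":
            hit = abs(stat) >= abs(obs) - 1e-12
        elif alternative == "greater":
            hit = stat >= obs - 1e-12
        elif alternative == "less":
            hit = stat <= obs + 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        count += hit
    return obs, (count + 1) / (n_perm + 1)


def _g_from_table(table: np.ndarray) -> float:
    """Log-likelihood-ratio G for one contingency table (zero cells skipped)."""
    n = table.sum()
    if n == 0:
        return 0.0
    expected = table.sum(axis=1, keepdims=True) * table.sum(axis=0) / n
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def g_test_differentiation(matrix: GenotypeMatrix, n_perm: int = 10_000,
                           seed=0, level: str = "subsample"):
    """G-based test of differentiation: subsample x allele tables per locus,
    G summed over loci; randomization relocates whole individuals between
    subsamples.

    Returns ``(G, p, per_locus_g)``.
    """
    labels = matrix.labels(level)
    pop_order = list(dict.fromkeys(labels))
    if len(pop_order) < 2:
        raise ValueError("need >=2 subsamples")
    pop_idx = np.array([pop_order.index(x) for x in labels])
    r = len(pop_order)
    rng = np.random.default_rng(seed)

    per_locus = []
    for j in range(matrix.n_loci):
        calls = matrix.calls[:, j, :]
        present = calls[:, 0] != MISSING
        alleles = np.unique(calls[present])
        lut = {a: k for k, a in enumerate(alleles)}
        g1 = np.array([lut[a] for a in calls[present, 0]], dtype=np.intp)
        g2 = np.array([lut[a] for a in calls[present, 1]], dtype=np.intp)
        per_locus.append((present, g1, g2, len(alleles)))

    def total_g(pidx):
        tot, glist = 0.0, []
        for present, g1, g2, K in per_locus:
            pp = pidx[present]
            table = np.zeros((r, K))
            np.add.at(table, (pp, g1), 1.0)
            np.add.at(table, (pp, g2), 1.0)
            g = _g_from_table(table)
            glist.append(g)
            tot += g
        return tot, glist

    g_obs, g_by_locus = total_g(pop_idx)
    count = 0
    for _ in range(n_perm):
        g_perm, _ = total_g(rng.permutation(pop_idx))
        count += g_perm >= g_obs - 1e-12
    p = (count + 1) / (n_perm + 1)
    return g_obs, p, dict(zip(matrix.loci, g_by_locus))


def bootstrap_ci_loci(matrix: GenotypeMatrix, statistic: str = "fst",
                      n_boot: int = 5000, seed=0, alpha: float = 0.05,
                      level: str = "subsample"):
    """Percentile bootstrap-over-loci CI of a multilocus ratio-of-sums
    statistic (``fis`` | ``fst`` | ``fit``)."""
    comps = [wc_components(matrix, l, level) for l in matrix.loci]
    comps = [v for v in comps if not v.uninformative]
    if len(comps) < 2:
        raise ValueError("CI undefined with a single informative locus")
    abc = np.array([[v.a, v.b, v.c] for v in comps])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(comps), size=(n_boot, len(comps)))
    sums = abc[idx].sum(axis=1)  # (n_boot, 3)
    A, B, C = sums[:, 0], sums[:, 1], sums[:, 2]
    if statistic == "fst":
        vals = A / (A + B + C)
    elif statistic == "fis":
        vals = 1.0 - C / (B + C)
    elif statistic == "fit":
        vals = 1.0 - C / (A + B + C)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def jackknife_fis_populations(matrix: GenotypeMatrix, locus,
                              conf: float = 0.95):
    """Delete-one-subsample jackknife of per-locus F_IS.

    Returns ``(fis, std_err, Li, Ls)`` where Li/Ls = F_IS -/+ SE x t with t
    the Student quantile at (1+conf)/2 and df = n_subsamples - 1.
    """
    subs = matrix.subsamples()
    g = len(subs)
    if g < 3:
        raise ValueError("jackknife over populations needs >=3 subsamples")
    labels = matrix.labels("subsample")
    full = wc_components(matrix, locus)
    theta = []
    for drop in subs:
        sub = matrix.select_individuals(labels != drop)
        v = wc_components(sub, locus)
        theta.append(v.fis)
    theta = np.array(theta, dtype=float)
    se = float(np.sqrt((g - 1) / g * ((theta - theta.mean()) ** 2).sum()))
    t = sps.t.ppf(0.5 + conf / 2, df=g - 1)
    return full.fis, se, full.fis - se * t, full.fis + se * t


def ld_pairwise_tests(matrix: GenotypeMatrix, n_perm: int = 10_000, seed=0,
                      level: str = "subsample") -> list:
    """Genotypic-association G tests for every unordered locus pair.

    The statistic is G on the genotype(l1) x genotype(l2) contingency table
    summed over subsamples; the randomization shuffles single-locus genotypes
    among individuals within subsamples.  BY-adjusted p-values fill the
    ``p_adjusted`` field.
    """
    if matrix.n_loci < 2:
        raise ValueError("need >=2 loci")
    rng = np.random.default_rng(seed)
    labels = matrix.labels(level)
    pop_order = list(dict.fromkeys(labels))
    pop_idx = np.array([pop_order.index(x) for x in labels])

    # genotype codes per locus (unordered pairs), MISSING -> -1
    codes, sizes = [], []
    for j in range(matrix.n_loci):
        calls = np.sort(matrix.calls[:, j, :], axis=1)
        pairs = [tuple(x) for x in calls]
        distinct = sorted({p for p in pairs if p[0] != MISSING})
        lut = {p: k for k, p in enumerate(distinct)}
        codes.append(np.array([lut.get(p, -1) for p in pairs]))
        sizes.append(max(len(distinct), 1))

    def pair_g(c1, c2, k1, k2, mask):
        tot = 0.0
        for p in range(len(pop_order)):
            m = mask & (pop_idx == p)
            if not m.any():
                continue
            joint = np.bincount(c1[m] * k2 + c2[m], minlength=k1 * k2)
            tot += _g_from_table(joint.reshape(k1, k2).astype(float))
        return tot

    results = []
    for i in range(matrix.n_loci):
        for j in range(i + 1, matrix.n_loci):
            mask = (codes[i] >= 0) & (codes[j] >= 0)
            if sizes[i] < 2 or sizes[j] < 2 or mask.sum() < 4:
                continue  # degenerate pair, skipped
            obs = pair_g(codes[i], codes[j], sizes[i], sizes[j], mask)
            cj = codes[j].copy()
            count = 0
            for _ in range(n_perm):
                for p in range(len(pop_order)):
                    m = mask & (pop_idx == p)
                    cj[m] = rng.permutation(cj[m])
                count += pair_g(codes[i], cj, sizes[i], sizes[j], mask) >= obs - 1e-12
            p_val = (count + 1) / (n_perm + 1)
            results.append(LDTestResult(matrix.loci[i], matrix.loci[j],
                                        obs, p_val))
    if results:
        adj = by_adjust([r.p for r in results])
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
    return results


def by_adjust(p_values):
    """Benjamini-Yekutieli step-up FDR adjustment (arbitrary dependence)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_by")[1]
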