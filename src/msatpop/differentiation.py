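"""Corrected and standardized genetic differentiation.

Raw F_ST understates differentiation at highly polymorphic loci (its
maximum is bounded by within-population diversity) and is biased by null
alleles.  This module provides:

* Nei gene diversities H_S (unbiased within-subsample mean) and H_T;
* ENA-corrected F_ST: the null-allele class is excluded from the
  estimator's allele loop while visible allele frequencies are EM-corrected
  (blanks having been recoded as null homozygotes);
* F_ST_max via subsample-private allele recoding: every allele is tagged
  with its subsample so all alleles become private, which preserves the
  genotype structure but maximizes the estimator given the data layout;
* the standardized ratio F_ST' = F_ST_ENA / F_ST_max and Hedrick-style
  G_ST'' = n(H_T - H_S) / ((n H_T - H_S)(1 - H_S));
* the G_ST ~ H_S Spearman diagnostic deciding which standardized measure
  is preferable (F_ST' when the correlation is negative, G_ST'' otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import MISSING, NULL_ALLELE, GenotypeMatrix, recode_missing_as_null
from .fstats import f_statistics
from .qc import em_null_frequency

__all__ = [
    "DiversityEstimates", "DifferentiationResult",
    "nei_diversities", "gst_double_prime", "fst_ena", "fst_max",
    "fst_prime", "gst_hs_correlation", "pairwise_fst_prime",
]


@dataclass
class DiversityEstimates:
    loci: list
    h_s: dict            # locus -> mean within-subsample unbiased diversity
    h_t: dict            # locus -> total diversity from mean frequencies
    g_st: dict           # locus -> (H_T - H_S) / H_T
    n_subsamples: int

    @property
    def mean_h_s(self) -> float:
        return float(np.mean(list(self.h_s.values())))

    @property
    def mean_h_t(self) -> float:
        return float(np.mean(list(self.h_t.values())))


@dataclass
class DifferentiationResult:
    fst_ena: float = None
    fst_ena_ci: tuple = None
    fst_max: float = None
    fst_prime: float = None
    gst: float = None
    gst_double_prime: float = None
    h_s: float = None
    h_t: float = None
    per_locus: dict = field(default_factory=dict)


def nei_diversities(matrix: GenotypeMatrix, level: str = "subsample"
                    ) -> DiversityEstimates:
    """Per-locus H_S (unbiased, Nei small-sample correction) and H_T.

    H_S averages 2n/(2n-1) * (1 - sum p^2) over subsamples with data; H_T
    is 1 - sum(p_bar^2) with p_bar the unweighted mean of subsample
    frequencies.  A monomorphic locus scores H_S = H_T = 0.
    """
    labels = matrix.labels(level)
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("need >=2 subsamples")
    h_s, h_t, g_st = {}, {}, {}
    for j, locus in enumerate(matrix.loci):
        alleles = matrix.alleles(j)
        lut = {int(a): i for i, a in enumerate(alleles)}
        per_group_h, per_group_p = [], []
        for g in groups:
            calls = matrix.calls[np.flatnonzero(labels == g), j, :]
            vals = calls[calls != MISSING]
            if vals.size == 0:
                continue
            p = np.zeros(len(alleles))
            uniq, counts = np.unique(vals, return_counts=True)
            for a, c in zip(uniq, counts):
                p[lut[int(a)]] = c / vals.size
            ng = vals.size  # gene copies
            per_group_h.append(ng / (ng - 1) * (1.0 - (p ** 2).sum())
                               if ng > 1 else 0.0)
            per_group_p.append(p)
        hs = float(np.mean(per_group_h)) if per_group_h else 0.0
        pbar = np.mean(per_group_p, axis=0) if per_group_p else np.array([1.0])
        ht = float(1.0 - (pbar ** 2).sum())
        h_s[locus], h_t[locus] = hs, ht
        g_st[locus] = (ht - hs) / ht if ht > 0 else 0.0
    return DiversityEstimates(list(matrix.loci), h_s, h_t, g_st, len(groups))


def gst_double_prime(h_t: float, h_s: float, n: int) -> float:
    """G_ST'' = n(H_T - H_S) / ((n H_T - H_S)(1 - H_S))."""
    if n < 2:
        raise ValueError("need n >= 2 subsamples")
    if h_s >= 1.0:
        raise ValueError("G_ST'' undefined at H_S = 1")
    denom = (n * h_t - h_s) * (1.0 - h_s)
    if denom == 0:
        return 0.0
    return n * (h_t - h_s) / denom


# -- ENA-corrected F_ST ------------------------------------------------------

def _ena_components(matrix: GenotypeMatrix, j: int, null_est,
                    level: str = "subsample"):
    """W&C components for one locus with the null-allele class excluded.

    Sample sizes count all individuals (blanks are null homozygotes);
    the per-allele loop runs over visible alleles only, with per-subsample
    visible frequencies replaced by their EM-corrected values (which sum to
    1 - r_hat, shifting mass to the excluded null class).
    """
    labels = matrix.labels(level)
    groups = list(dict.fromkeys(labels))
    calls = matrix.calls[:, j, :]
    alleles = [int(a) for a in np.unique(calls[calls != MISSING])
               if a != NULL_ALLELE]
    K = len(alleles)
    lut = {a: i for i, a in enumerate(alleles)}
    n_i, C, Hm = [], [], []
    by_group = null_est.by_group if null_est is not None else {}
    for g in groups:
        rows = np.flatnonzero(labels == g)
        sub = calls[rows]
        n_g = rows.size
        if n_g == 0:
            continue
        r_g = by_group.get(g, {}).get("r", 0.0)
        if r_g > 0.999:
            raise ValueError(f"null frequency ~1 in subsample {g}")
        p = np.zeros(K)
        freqs = by_group.get(g, {}).get("visible_freqs")
        if freqs:
            for a, f in freqs.items():
                if a in lut:
                    p[lut[a]] = f
        else:
            vis = sub[(sub != MISSING) & (sub != NULL_ALLELE)]
            if vis.size:
                uniq, counts = np.unique(vis, return_counts=True)
                denom = 2 * n_g
                for a, c in zip(uniq, counts):
                    p[lut[int(a)]] = c / denom
        h = np.zeros(K)
        het = (sub[:, 0] != sub[:, 1])
        for a1, a2 in sub[het]:
            for a in (int(a1), int(a2)):
                if a in lut:
                    h[lut[a]] += 1
        # visible/null heterozygotes are observed as visible homozygotes;
        # restore their expected count (HWE: 2 x_A r per individual) so the
        # within-individual component is not deflated.  Vanishes at r = 0.
        h += 2.0 * p * r_g * n_g
        n_i.append(n_g)
        C.append(p * 2 * n_g)
        Hm.append(h)
    n_i = np.array(n_i, dtype=float)
    keep = n_i > 0
    n_i, C, Hm = n_i[keep], np.array(C)[keep], np.array(Hm)[keep]
    r = len(n_i)
    if r < 2 or K < 2:
        return None
    nbar = n_i.mean()
    if nbar <= 1:
        return None
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    n_total = n_i.sum()
    p_i = C / (2 * n_i[:, None])
    pbar = C.sum(axis=0) / (2 * n_total)
    s2 = ((n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar))
    hbar = Hm.sum(axis=0) / n_total
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return float(a.sum()), float(b.sum()), float(c.sum())


def fst_ena(matrix: GenotypeMatrix, null_estimates=None, n_boot: int = 5000,
            seed=0, level: str = "subsample", alpha: float = 0.05):
    """Multilocus ENA-corrected F_ST with a bootstrap-over-loci CI.

    ``matrix`` may carry blanks either as MISSING or already recoded as
    999/999 null homozygotes (recoding is applied if needed).
    ``null_estimates`` maps locus -> NullAlleleEstimate; when omitted the
    EM runs internally per subsample.  Returns
    ``(fst, (lo, hi), per_locus_fst)``.
    """
    work = matrix
    if matrix.missing_mask().any():
        work = recode_missing_as_null(matrix)
    if null_estimates is None:
        null_estimates = {l: em_null_frequency(matrix, l, grouping=level)
                          for l in matrix.loci}
    abc, per_locus = [], {}
    for j, locus in enumerate(work.loci):
        comp = _ena_components(work, j, null_estimates.get(locus), level)
        if comp is None:
            continue
        a, b, c = comp
        if a + b + c != 0:
            per_locus[locus] = a / (a + b + c)
        abc.append(comp)
    if not abc:
        raise ValueError("no usable loci for ENA F_ST")
    abc = np.array(abc)
    A, B, C = abc.sum(axis=0)
    fst = A / (A + B + C)
    ci = None
    if len(abc) >= 2 and n_boot:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(abc), size=(n_boot, len(abc)))
        sums = abc[idx].sum(axis=1)
        vals = sums[:, 0] / sums.sum(axis=1)
        ci = tuple(float(x) for x in
                   np.quantile(vals, [alpha / 2, 1 - alpha / 2]))
    return float(fst), ci, per_locus


def fst_max(matrix: GenotypeMatrix, level: str = "subsample") -> float:
    """F_ST after recoding every allele as private to its subsample.

    Genotype structure (het/hom pattern and counts) is preserved; only
    allele identities change, so the result is the estimator's maximum for
    this sampling layout and within-population diversity.
    """
    labels = matrix.labels(level)
    groups = list(dict.fromkeys(labels))
    gidx = {g: k for k, g in enumerate(groups)}
    calls = matrix.calls.copy()
    offset = int(calls.max()) + 1 if calls.size else 1
    for i, ind in enumerate(matrix.individuals):
        g = gidx[labels[i]]
        for j in range(matrix.n_loci):
            if calls[i, j, 0] != MISSING:
                calls[i, j, 0] += offset * (g + 1)
                calls[i, j, 1] += offset * (g + 1)
    recoded = GenotypeMatrix(matrix.individuals, matrix.loci, calls,
                             matrix.groups)
    return f_statistics(recoded, level=level).fst


def fst_prime(fst_ena_value: float, fst_max_value: float) -> float:
    """Standardized F_ST' = F_ST_ENA / F_ST_max (may be negative)."""
    if fst_max_value <= 0:
        raise ValueError("F_ST' undefined: F_ST_max must be > 0")
    return fst_ena_value / fst_max_value


def gst_hs_correlation(gst_values, hs_values):
    """One-sided (negative) Spearman test of G_ST against H_S.

    Returns ``(rho, p, preferred)`` where preferred is "fst_prime" when the
    correlation is negative (Wang's rule) and "gst_double_prime" otherwise.
    """
    gst = np.asarray(gst_values, dtype=float)
    hs = np.asarray(hs_values, dtype=float)
    if gst.size < 4:
        raise ValueError("need >=4 loci")
    if np.ptp(hs) == 0:
        raise ValueError("constant H_S")
    res = sps.spearmanr(gst, hs, alternative="less")
    rho = float(res.statistic)
    preferred = "fst_prime" if rho < 0 else "gst_double_prime"
    return rho, float(res.pvalue), preferred


def pairwise_fst_prime(matrix: GenotypeMatrix, pairs="cross-country",
                       n_boot: int = 5000, seed=0):
    """Average standardized differentiation over subsample pairs.

    ``pairs`` is "cross-country" (every pair with different country
    labels), "all", or an explicit list of (subsample, subsample) tuples.
    For each pair: ENA F_ST with per-pair bootstrap CI, F_ST_max on the
    recoded pair, F_ST' = ratio; means of estimates and of CI bounds are
    averaged across pairs.  Returns a dict with per-pair and averaged
    results.
    """
    subs = matrix.subsamples()
    labels = matrix.labels("subsample")
    country = {s: matrix.groups[matrix.individuals[
        int(np.flatnonzero(labels == s)[0])]][2] for s in subs}
    if pairs == "cross-country":
        pair_list = [(a, b) for a, b in itertools.combinations(subs, 2)
                     if country[a] != country[b]]
    elif pairs == "all":
        pair_list = list(itertools.combinations(subs, 2))
    else:
        pair_list = list(pairs)
    if not pair_list:
        raise ValueError("no subsample pairs selected")
    per_pair = {}
    rng = np.random.default_rng(seed)
    for a, b in pair_list:
        keep = (labels == a) | (labels == b)
        sub = matrix.select_individuals(keep)
        try:
            fst, ci, _ = fst_ena(sub, n_boot=n_boot,
                                 seed=int(rng.integers(2 ** 31)))
            fmax = fst_max(sub)
            prime = fst_prime(fst, fmax)
        except ValueError:
            continue
        prime_ci = (ci[0] / fmax, ci[1] / fmax) if ci else None
        per_pair[(a, b)] = {"fst_ena": fst, "fst_max": fmax,
                            "fst_prime": prime, "fst_prime_ci": prime_ci}
    if not per_pair:
        raise ValueError("no estimable pairs")
    primes = [v["fst_prime"] for v in per_pair.values()]
    cis = [v["fst_prime_ci"] for v in per_pair.values() if v["fst_prime_ci"]]
    out = {
        "per_pair": per_pair,
        "mean_fst_prime": float(np.mean(primes)),
        "mean_ci": (float(np.mean([c[0] for c in cis])),
                    float(np.mean([c[1] for c in cis]))) if cis else None,
    }
    return out
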