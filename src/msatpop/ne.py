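"""Effective population size estimators and the weighted grand average.

Three estimators are computed from genotype data:

* **heterozygote excess** (closed form): in a small dioecious population
  allele frequencies differ between breeders, producing an excess of
  heterozygotes in the offspring; the expected within-subsample F_IS is
  negative and maps to Ne via ``Ne = -1/(2 F_IS) - F_IS / (2(1 + F_IS))``.
  Only a heterozygote *excess* (F_IS < 0) carries signal.
* **linkage disequilibrium**: drift in a finite population generates
  association between unlinked loci; Burrows' composite disequilibrium
  gives a mean squared correlation r^2 whose excess over the sampling
  expectation yields Ne (Waples-style bias correction, per-pair sample
  sizes accommodate missing data).
* **molecular coancestry**: the mean chance-corrected allele sharing
  between individuals of a cohort estimates the coancestry of their
  parents, f_1, and Ne = 1/(2 f_1).

Methods whose estimate falls outside the usable domain (zero, negative or
infinite) return UNUSABLE (None).  Per-method summaries across subsamples
(average / min / max, weight = number of usable values) feed a weighted
grand average; externally computed methods (sibship likelihood, identity
probabilities) can join the average as plain records.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix

__all__ = [
    "NeEstimate", "UNUSABLE", "ne_het_excess", "ne_ld", "ne_coancestry",
    "ne_weighted_average", "ne_table",
]

#: Sentinel for estimates outside the usable domain (0 or infinity).
UNUSABLE = None


@dataclass
class NeEstimate:
    """Per-method Ne summary across subsamples."""

    method: str
    average: float
    ne_min: float
    ne_max: float
    weight: int


def ne_het_excess(fis: float):
    """Closed-form Ne from a within-subsample heterozygote excess.

    Returns ``-1/(2 fis) - fis / (2 (1 + fis))`` for -1 < fis < 0, and
    UNUSABLE otherwise (a heterozygote deficit or an infinite estimate
    carries no Ne signal).
    """
    if not (-1.0 < fis < 0.0):
        return UNUSABLE
    return -1.0 / (2.0 * fis) - fis / (2.0 * (1.0 + fis))


def _r2_expected(s: float) -> float:
    # sampling expectation of r^2 (Waples 2006 regressions)
    if s >= 30:
        return 1.0 / s + 3.19 / s ** 2
    return 0.0018 + 0.907 / s + 4.44 / s ** 2


def _ne_from_r2prime(r2p: float, s: float):
    if r2p <= 0:
        return UNUSABLE
    if s >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2p
        if disc < 0:
            return 1.0 / (3.0 * r2p)
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2p)
    disc = 0.308 ** 2 - 2.08 * r2p
    if disc < 0:
        return 1.0 / (3.0 * r2p)
    return (0.308 + math.sqrt(disc)) / (2.0 * r2p)


def ne_ld(matrix: GenotypeMatrix, subsample: str, rare_cutoff: float = 0.05):
    """LD-method Ne for one subsample (random-mating model).

    Burrows' composite disequilibrium across all locus pairs; alleles with
    frequency below ``rare_cutoff`` are excluded; r^2 values are averaged
    with per-pair sample sizes as weights (missing-data correction) and
    the sampling expectation subtracted before solving for Ne.
    Returns UNUSABLE when the corrected mean r^2 is not positive.
    """
    labels = matrix.labels("subsample")
    rows = np.flatnonzero(labels == subsample)
    if rows.size < 2:
        raise ValueError("need >=2 individuals")
    calls = matrix.calls[rows]
    loci_data = []
    for j in range(matrix.n_loci):
        c = calls[:, j, :]
        present = c[:, 0] != MISSING
        vals = c[present]
        if vals.size == 0:
            continue
        uniq, counts = np.unique(vals, return_counts=True)
        freqs = counts / vals.size
        usable = uniq[(freqs >= rare_cutoff) & (freqs <= 1 - rare_cutoff)]
        if usable.size < 2:
            continue
        # copy counts per individual per usable allele
        X = np.zeros((rows.size, usable.size))
        for k, a in enumerate(usable):
            X[:, k] = (c[:, 0] == a).astype(float) + (c[:, 1] == a)
        loci_data.append((present, X, usable.size))
    if len(loci_data) < 2:
        raise ValueError("fewer than 2 usable loci")

    r2_vals, weights, sizes = [], [], []
    for (pa, Xa, ka), (pb, Xb, kb) in itertools.combinations(loci_data, 2):
        both = pa & pb
        n = int(both.sum())
        if n < 3:
            continue
        xa, xb = Xa[both], Xb[both]
        pA = xa.mean(axis=0) / 2.0
        pB = xb.mean(axis=0) / 2.0
        pair_r2 = []
        for i in range(ka):
            for k in range(kb):
                va = pA[i] * (1 - pA[i])
                vb = pB[k] * (1 - pB[k])
                if va <= 0 or vb <= 0:
                    continue
                cov = (xa[:, i] * xb[:, k]).mean() / 2.0 - 2.0 * pA[i] * pB[k]
                delta = cov * n / (n - 1)
                pair_r2.append(delta * delta / (va * vb))
        if pair_r2:
            r2_vals.append(float(np.mean(pair_r2)))
            weights.append(n)
            sizes.append(n)
    if not r2_vals:
        return UNUSABLE
    w = np.asarray(weights, dtype=float)
    r2_bar = float(np.average(r2_vals, weights=w))
    s_bar = float(np.average(sizes, weights=w))
    r2_prime = r2_bar - _r2_expected(s_bar)
    return _ne_from_r2prime(r2_prime, s_bar)


def ne_coancestry(matrix: GenotypeMatrix, subsample: str):
    """Molecular-coancestry Ne for one subsample.

    Allele sharing between individuals i,j at a locus,
    s = (1/4) sum of the four cross-comparisons, is corrected for chance
    identity with the subsample allele frequencies,
    f = (s - s0)/(1 - s0) with s0 = sum p^2, averaged over loci and pairs;
    Ne = 1/(2 f_bar).  UNUSABLE when f_bar <= 0 or nothing is comparable.
    """
    labels = matrix.labels("subsample")
    rows = np.flatnonzero(labels == subsample)
    if rows.size < 2:
        raise ValueError("need >=2 individuals")
    calls = matrix.calls[rows]
    n = rows.size
    locus_f = []  # per locus: (n x n) pair coancestry and validity
    for j in range(matrix.n_loci):
        c = calls[:, j, :]
        present = c[:, 0] != MISSING
        vals = c[present]
        if vals.size == 0:
            continue
        uniq, counts = np.unique(vals, return_counts=True)
        nc_copies = vals.size
        # unbiased chance identity: two copies drawn without replacement
        s0 = float((counts * (counts - 1)).sum()
                   / (nc_copies * (nc_copies - 1))) if nc_copies > 1 else 1.0
        if s0 >= 1.0:
            continue  # monomorphic: no information
        a1, a2 = c[:, 0], c[:, 1]
        share = np.zeros((n, n))
        for u, v in ((a1, a1), (a1, a2), (a2, a1), (a2, a2)):
            share += (u[:, None] == v[None, :])
        share /= 4.0
        f = (share - s0) / (1.0 - s0)
        valid = present[:, None] & present[None, :]
        locus_f.append((f, valid))
    if not locus_f:
        return UNUSABLE
    iu = np.triu_indices(n, k=1)
    num = np.zeros(len(iu[0]))
    den = np.zeros(len(iu[0]))
    for f, valid in locus_f:
        ok = valid[iu]
        num[ok] += f[iu][ok]
        den[ok] += 1
    usable = den > 0
    if not usable.any():
        return UNUSABLE
    f_bar = float((num[usable] / den[usable]).mean())
    if f_bar <= 0:
        return UNUSABLE
    return 1.0 / (2.0 * f_bar)


def ne_weighted_average(estimates):
    """Weighted grand average of per-method Ne summaries.

    Weights are each method's number of usable values; zero-weight entries
    drop out, so the result is invariant to their presence and to method
    order.  Returns ``(grand_avg, grand_min, grand_max)`` as floats.
    """
    usable = [e for e in estimates if e.weight > 0]
    if not usable:
        raise ValueError("no usable estimates")
    w = np.array([e.weight for e in usable], dtype=float)
    avg = float(np.average([e.average for e in usable], weights=w))
    lo = float(np.average([e.ne_min for e in usable], weights=w))
    hi = float(np.average([e.ne_max for e in usable], weights=w))
    return avg, lo, hi


def ne_table(matrix: GenotypeMatrix, methods=("FIS", "LD", "Coancestry"),
             rare_cutoff: float = 0.05, extra_estimates=()):
    """Per-method Ne across subsamples plus the weighted grand average.

    For each method the per-subsample estimates are computed; usable
    values (finite, > 0) define the weight, the average, and the
    across-subsample min/max.  ``extra_estimates`` appends externally
    computed NeEstimate records (e.g. sibship-likelihood or
    identity-probability results from dedicated software) before
    averaging.  Returns ``(list of NeEstimate, (grand_avg, min, max))``.
    """
    subs = matrix.subsamples()
    labels = matrix.labels("subsample")
    table = []
    for method in methods:
        values = []
        for s in subs:
            sub = matrix.select_individuals(labels == s)
            try:
                if method == "FIS":
                    values.append(ne_het_excess(_single_sample_fis(sub)))
                elif method == "LD":
                    values.append(ne_ld(matrix, s, rare_cutoff))
                elif method == "Coancestry":
                    values.append(ne_coancestry(matrix, s))
                else:
                    raise ValueError(f"unknown method {method!r}")
            except ValueError:
                values.append(UNUSABLE)
        usable = [v for v in values if v is not UNUSABLE and np.isfinite(v)
                  and v > 0]
        if usable:
            table.append(NeEstimate(method, float(np.mean(usable)),
                                    float(np.min(usable)),
                                    float(np.max(usable)), len(usable)))
        else:
            table.append(NeEstimate(method, np.nan, np.nan, np.nan, 0))
    table.extend(extra_estimates)
    grand = ne_weighted_average(table)
    return table, grand


def _single_sample_fis(matrix: GenotypeMatrix) -> float:
    """Within-sample F_IS: 1 - H_obs / H_exp with Nei's unbiased H_exp,
    ratio-of-sums over loci."""
    num = den = 0.0
    for j in range(matrix.n_loci):
        c = matrix.calls[:, j, :]
        present = c[:, 0] != MISSING
        vals = c[present]
        n = int(present.sum())
        if n < 2:
            continue
        uniq, counts = np.unique(vals, return_counts=True)
        p = counts / vals.size
        h_exp = (2 * n / (2 * n - 1)) * (1.0 - (p ** 2).sum())
        h_obs = float((vals[:, 0] != vals[:, 1]).mean())
        num += h_obs
        den += h_exp
    if den == 0:
        raise ValueError("no polymorphism")
    return 1.0 - num / den
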