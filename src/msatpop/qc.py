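"""Locus-quality triage for microsatellite panels.

Departures from Hardy-Weinberg equilibrium can reflect real structure
(Wahlund effect) or genotyping artifacts.  This module implements the
standard artifact diagnostics:

* **null alleles** — EM estimation of the frequency of an unamplifiable
  allele, treating observed blanks as putative null homozygotes, plus an
  exact binomial goodness-of-fit of observed blanks to the expected
  n * r^2, and the regression of per-locus F_IS on expected null
  homozygotes whose intercept estimates the null-free F_IS;
* **short allele dominance (SAD)** — preferential amplification of the
  shorter allele, detected as a negative trend of per-allele F_IT against
  fragment size (one-sided Spearman, and a weighted least-squares slope
  test with p(1-p) weights);
* **stuttering** — slippage miscalls between alleles one repeat unit
  apart, detected as a specific deficit of one-step heterozygotes among
  all heterozygotes (exact binomial, conditional on the total het count so
  an overall het deficit does not masquerade as stuttering);
* **F_IS-F_ST correlation** — a positive correlation across loci suggests
  null alleles inflate both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import MISSING, GenotypeMatrix
from .fstats import wc_per_allele

__all__ = [
    "NullAlleleEstimate", "LocusQCReport",
    "em_null_frequency", "blank_binomial_test", "fis_blank_regression",
    "sad_test", "stuttering_test", "fis_fst_correlation", "qc_report",
]


@dataclass
class NullAlleleEstimate:
    """EM null-allele estimate for one locus, per group and pooled."""

    locus: str
    by_group: dict = field(default_factory=dict)
    # by_group[group] = dict(r=.., n=.., observed_blanks=.., expected_blanks=..,
    #                        visible_freqs={allele: freq})

    @property
    def pooled_r(self) -> float:
        tot_n = sum(g["n"] for g in self.by_group.values())
        if tot_n == 0:
            return 0.0
        return sum(g["r"] * g["n"] for g in self.by_group.values()) / tot_n

    @property
    def expected_blanks(self) -> float:
        return sum(g["expected_blanks"] for g in self.by_group.values())

    @property
    def observed_blanks(self) -> int:
        return sum(g["observed_blanks"] for g in self.by_group.values())


def _em_single(het_counts, hom_counts, n_blank, tol=1e-8, max_iter=10_000,
               loglik_trace=None):
    """EM for null-allele frequency in one group.

    het_counts: {(i, j): count} with i < j visible allele indices;
    hom_counts: {i: count} apparent homozygotes (true i/i or i/null);
    n_blank: observed blanks, treated as null homozygotes.

    Returns (r_hat, visible_freqs_array) with freqs summing to 1 - r_hat.
    Log-likelihood is monotone non-decreasing across iterations (EM
    guarantee); after convergence a boundary check compares against the
    r = 0 solution so exact-HWE data yields r_hat = 0 rather than the
    slow-EM residual.
    """
    k = 1 + max([i for i in hom_counts] +
                [j for _, j in het_counts] + [0])
    n = sum(het_counts.values()) + sum(hom_counts.values()) + n_blank
    if n == 0:
        raise ValueError("empty group")
    visible_n = n - n_blank
    if visible_n == 0:
        return 1.0, np.zeros(k)

    def loglik(p, r):
        ll = 2.0 * n_blank * math.log(max(r, 1e-300))
        for (i, j), c in het_counts.items():
            ll += c * math.log(max(2.0 * p[i] * p[j], 1e-300))
        for i, c in hom_counts.items():
            ll += c * math.log(max(p[i] ** 2 + 2.0 * p[i] * r, 1e-300))
        return ll

    # init: observed visible gene frequencies scaled by a small r
    counts = np.zeros(k)
    for (i, j), c in het_counts.items():
        counts[i] += c
        counts[j] += c
    for i, c in hom_counts.items():
        counts[i] += 2 * c
    p_obs = counts / counts.sum()
    r = max(n_blank / n, 0.05)
    p = p_obs * (1.0 - r)
    for _ in range(max_iter):
        if loglik_trace is not None:
            loglik_trace.append(loglik(p, r))
        null_genes = 2.0 * n_blank
        gene = np.zeros(k)
        for (i, j), c in het_counts.items():
            gene[i] += c
            gene[j] += c
        for i, c in hom_counts.items():
            denom = p[i] + 2.0 * r
            if denom <= 0:
                continue
            w_null = 2.0 * r / denom        # expected i/null fraction
            gene[i] += c * (2.0 - w_null)
            null_genes += c * w_null
        total = gene.sum() + null_genes
        r_new = null_genes / total
        p = gene / total
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    # boundary polish: prefer r = 0 when it is at least as likely
    if r < 0.05 and loglik(p_obs, 0.0) >= loglik(p, r) - 1e-9:
        return 0.0, p_obs
    return float(r), p


def em_null_frequency(matrix: GenotypeMatrix, locus,
                      grouping: str = "subsample") -> NullAlleleEstimate:
    """Estimate per-group null-allele frequencies at a locus by EM.

    Observed blanks are treated as putative null homozygotes (the FreeNA
    convention), HWE is assumed within groups.  Groups with no individuals
    are skipped.  Expected blank count per group is n * r_hat^2.
    """
    j = matrix._locus_index(locus)
    labels = matrix.labels(grouping)
    est = NullAlleleEstimate(locus=matrix.loci[j])
    alleles = matrix.alleles(j)
    lut = {int(a): i for i, a in enumerate(alleles)}
    for g in dict.fromkeys(labels):
        rows = np.flatnonzero(labels == g)
        if rows.size == 0:
            continue
        calls = matrix.calls[rows, j, :]
        blanks = int((calls[:, 0] == MISSING).sum())
        het, hom = {}, {}
        for a1, a2 in calls[calls[:, 0] != MISSING]:
            i1, i2 = lut[int(a1)], lut[int(a2)]
            if i1 == i2:
                hom[i1] = hom.get(i1, 0) + 1
            else:
                key = (min(i1, i2), max(i1, i2))
                het[key] = het.get(key, 0) + 1
        n = len(rows)
        if het or hom:
            r, p = _em_single(het, hom, blanks)
        else:
            r, p = (1.0, np.zeros(1)) if blanks else (0.0, np.zeros(1))
        est.by_group[g] = {
            "r": float(r),
            "n": n,
            "observed_blanks": blanks,
            "expected_blanks": n * r * r,
            "visible_freqs": {int(a): float(p[lut[int(a)]])
                              for a in alleles if lut[int(a)] < p.size},
        }
    return est


def blank_binomial_test(observed_blanks: int, n: int, r_hat: float) -> float:
    """One-sided exact binomial tail P(X <= observed | n, r_hat^2).

    Small p flags a *deficit* of blanks relative to the null-homozygote
    expectation (loci are accepted when blanks are plentiful).  With
    r_hat = 0 and observed blanks the fit question is vacuous: p = 1.
    """
    q = r_hat * r_hat
    if q == 0.0:
        return 1.0
    return float(sps.binom.cdf(observed_blanks, n, q))


def fis_blank_regression(fis_values, expected_null_homozygotes):
    """OLS of per-locus F_IS on expected null homozygotes.

    Returns ``(slope, intercept, r_squared)``; the intercept is the
    null-free F_IS estimate.
    """
    y = np.asarray(fis_values, dtype=float)
    x = np.asarray(expected_null_homozygotes, dtype=float)
    if y.size < 3:
        raise ValueError("need >=3 loci")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    import statsmodels.api as sm

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.rsquared)


def _wls_slope(x, y, w):
    W = w.sum()
    xb = (w * x).sum() / W
    yb = (w * y).sum() / W
    return (w * (x - xb) * (y - yb)).sum() / (w * (x - xb) ** 2).sum()


def sad_test(matrix: GenotypeMatrix, locus, n_perm: int = 9999, seed: int = 0):
    """Short-allele-dominance diagnostics for one locus.

    Per-allele F_IT (allele-vs-rest) is regressed on fragment size:
    a one-sided Spearman test (negative alternative: larger alleles drop
    out) and a weighted least-squares slope with p(1-p) weights whose
    one-sided p-value is calibrated by permuting allele sizes (under the
    no-SAD null, sizes are exchangeable with respect to per-allele F_IT,
    whereas the analytic WLS p-value ignores the correlation between
    per-allele components and is anti-conservative).

    Returns ``(rho, p_spearman, slope, p_weighted)``; raises ValueError
    with "insufficient alleles" for loci with fewer than 4 usable alleles.
    """
    sizes, a, b, c = wc_per_allele(matrix, locus)
    tot = a + b + c
    ok = tot > 0
    if ok.sum() < 4:
        raise ValueError(f"insufficient alleles at locus {locus}")
    fit_allele = 1.0 - c[ok] / tot[ok]
    sizes = np.asarray(sizes, dtype=float)[ok]
    res = sps.spearmanr(sizes, fit_allele, alternative="less")
    rho, p_s = float(res.statistic), float(res.pvalue)

    # allele frequencies for weights
    j = matrix._locus_index(locus)
    calls = matrix.calls[:, j, :]
    vals = calls[calls != MISSING]
    uniq, counts = np.unique(vals, return_counts=True)
    freq = dict(zip(uniq.astype(float), counts / vals.size))
    p_a = np.array([freq[s] for s in sizes])
    w = p_a * (1.0 - p_a)

    slope = float(_wls_slope(sizes, fit_allele, w))
    rng = np.random.default_rng(seed)
    k = sizes.size
    W = w.sum()
    wy = w * (fit_allele - (w * fit_allele).sum() / W)
    perms = np.argsort(rng.random((n_perm, k)), axis=1)
    X = sizes[perms]                                   # (n_perm, k)
    xb = (X * w).sum(axis=1, keepdims=True) / W
    num = ((X - xb) * wy).sum(axis=1)
    den = (w * (X - xb) ** 2).sum(axis=1)
    hits = int((num / den <= slope + 1e-15).sum())
    p_w = (hits + 1) / (n_perm + 1)
    return rho, p_s, slope, float(p_w)


def stuttering_test(matrix: GenotypeMatrix, locus, motif_length=None,
                    level: str = "subsample"):
    """Test for a specific deficit of one-step heterozygotes.

    Observed heterozygotes are classified by whether their two alleles sit
    one motif unit apart on the repeat ladder.  Under HWE (within
    subsamples) the one-step share of heterozygotes has a known
    expectation; stuttering collapses one-step heterozygotes into
    homozygotes, depressing that share specifically.  The test is an exact
    binomial on the pooled one-step heterozygote count, conditional on the
    total heterozygote count.

    Returns ``(observed_one_step, p, verdict)``; verdict is "not testable"
    when the ladder admits no one-step pairs.
    """
    j = matrix._locus_index(locus)
    alleles = matrix.alleles(j)
    if motif_length is None:
        diffs = np.diff(alleles)
        motif_length = int(np.gcd.reduce(diffs)) if diffs.size else 0
    if motif_length == 0:
        return 0, 1.0, "not testable"
    labels = matrix.labels(level)
    exp_one = exp_all = 0.0
    obs_one = obs_all = 0
    for g in dict.fromkeys(labels):
        rows = np.flatnonzero(labels == g)
        calls = matrix.calls[rows, j, :]
        present = calls[:, 0] != MISSING
        calls = calls[present]
        n_g = calls.shape[0]
        if n_g == 0:
            continue
        vals = calls.ravel()
        uniq, counts = np.unique(vals, return_counts=True)
        p = counts / vals.size
        for ia in range(len(uniq)):
            for ib in range(ia + 1, len(uniq)):
                e = 2.0 * p[ia] * p[ib] * n_g
                exp_all += e
                if uniq[ib] - uniq[ia] == motif_length:
                    exp_one += e
        het = calls[:, 0] != calls[:, 1]
        obs_all += int(het.sum())
        obs_one += int((het & (calls[:, 1] - calls[:, 0] == motif_length)).sum())
    if exp_one == 0.0 or exp_all == 0.0:
        return obs_one, 1.0, "not testable"
    frac = exp_one / exp_all
    if obs_all == 0:
        return 0, 1.0, "not testable"
    p_val = float(sps.binom.cdf(obs_one, obs_all, frac))
    verdict = "stuttering" if p_val < 0.05 else "ok"
    return obs_one, p_val, verdict


def fis_fst_correlation(fis_values, fst_values):
    """One-sided Spearman correlation of per-locus F_IS and F_ST.

    The positive alternative reflects the null-allele syndrome (both
    statistics inflate together); ties get average ranks.
    """
    fis = np.asarray(fis_values, dtype=float)
    fst = np.asarray(fst_values, dtype=float)
    if fis.size < 4:
        raise ValueError("need >=4 loci")
    res = sps.spearmanr(fis, fst, alternative="greater")
    return float(res.statistic), float(res.pvalue)


@dataclass
class LocusQCReport:
    """QC verdicts and statistics for one locus."""

    locus: str
    read_success: float = 1.0
    null_estimate: NullAlleleEstimate = None
    blank_p: float = None
    sad_rho: float = None
    sad_p_spearman: float = None
    sad_slope: float = None
    sad_p_weighted: float = None
    stutter_stat: float = None
    stutter_p: float = None
    stutter_verdict: str = None
    decision: str = "retain"
    reasons: list = field(default_factory=list)


def qc_report(matrix: GenotypeMatrix, motif_lengths=None, alpha: float = 0.05,
              read_success_threshold: float = 0.7,
              by_correct: bool = True) -> list:
    """Run the full QC battery and apply the exclusion rules.

    Rules (each configurable): low fragment-read success
    (< read_success_threshold), SAD (weighted-regression p < alpha even if
    the Spearman p is not significant), stuttering (p < alpha).  With
    ``by_correct`` the SAD and stuttering p-values are BY-adjusted across
    loci before the alpha comparison, controlling the false-exclusion rate
    over the panel.
    """
    from .fstats import by_adjust

    if motif_lengths is None:
        motif_lengths = [None] * matrix.n_loci
    reports = []
    miss = matrix.missing_mask()
    for j, locus in enumerate(matrix.loci):
        rep = LocusQCReport(locus=locus)
        rep.read_success = 1.0 - miss[:, j].mean()
        rep.null_estimate = em_null_frequency(matrix, locus)
        n = matrix.n_individuals
        rep.blank_p = blank_binomial_test(
            rep.null_estimate.observed_blanks, n,
            math.sqrt(max(rep.null_estimate.expected_blanks, 0.0) / n))
        try:
            (rep.sad_rho, rep.sad_p_spearman,
             rep.sad_slope, rep.sad_p_weighted) = sad_test(matrix, locus)
        except ValueError:
            pass
        rep.stutter_stat, rep.stutter_p, rep.stutter_verdict = \
            stuttering_test(matrix, locus, motif_lengths[j])
        reports.append(rep)

    sad_ps = [r.sad_p_weighted for r in reports]
    stu_ps = [r.stutter_p if r.stutter_verdict != "not testable" else None
              for r in reports]
    if by_correct:
        def adjust(ps):
            idx = [i for i, p in enumerate(ps) if p is not None]
            if not idx:
                return ps
            adj = by_adjust([ps[i] for i in idx])
            out = list(ps)
            for i, a in zip(idx, adj):
                out[i] = float(a)
            return out
        sad_ps = adjust(sad_ps)
        stu_ps = adjust(stu_ps)

    for rep, sp, tp in zip(reports, sad_ps, stu_ps):
        if rep.read_success < read_success_threshold:
            rep.reasons.append("low_read_success")
        if sp is not None and sp < alpha:
            rep.reasons.append("sad")
        if tp is not None and tp < alpha:
            rep.reasons.append("stuttering")
        rep.decision = "exclude" if rep.reasons else "retain"
    return reports
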