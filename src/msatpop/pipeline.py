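"""End-to-end analysis pipeline: QC -> locus retention -> F-statistics ->
differentiation -> effective size -> structure.

Stages run in the order a marker-validation study applies them; the locus
set surviving QC feeds every downstream stage.  All resampling randomness
derives from one integer seed via fixed offsets, so a config reproduces
its report exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import differentiation as diff_mod
from . import fstats as fstats_mod
from . import ne as ne_mod
from . import qc as qc_mod
from . import structure as struct_mod
from .core import GenotypeMatrix, read_csv, read_genepop

log = logging.getLogger("msatpop")

__all__ = ["AnalysisConfig", "RunReport", "run_full", "write_report"]


@dataclass
class AnalysisConfig:
    input_path: str = None            # Genepop or CSV; or pass matrix to run_full
    grouping_level: str = "subsample"
    n_perm: int = 10_000
    n_boot: int = 5_000
    alpha: float = 0.05
    by_correct: bool = True
    read_success_threshold: float = 0.7
    ne_methods: tuple = ("FIS", "LD", "Coancestry")
    rare_cutoff: float = 0.05
    fst_prime_pairs: str = "cross-country"
    seed: int = 0

    def __post_init__(self):
        if self.n_perm < 1 or self.n_boot < 1:
            raise ValueError("resampling sizes must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class RunReport:
    config: AnalysisConfig
    qc: list = None
    retained_loci: list = None
    excluded_loci: dict = None        # locus -> primary reason
    fstat: dict = None
    ld: list = None
    differentiation: dict = None
    ne: dict = None
    structure: dict = None
    errors: list = field(default_factory=list)


def _load(config: AnalysisConfig) -> GenotypeMatrix:
    path = Path(config.input_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        return read_csv(path)
    return read_genepop(path)


def run_full(config: AnalysisConfig, matrix: GenotypeMatrix = None
             ) -> RunReport:
    """Execute all stages; on stage failure the report is partial and the
    failure recorded in ``errors``."""
    report = RunReport(config=config)
    if matrix is None:
        matrix = _load(config)
    seed = int(config.seed)

    # -- stage 1: QC and locus retention
    try:
        report.qc = qc_mod.qc_report(
            matrix, alpha=config.alpha,
            read_success_threshold=config.read_success_threshold,
            by_correct=config.by_correct)
        report.retained_loci = [r.locus for r in report.qc
                                if r.decision == "retain"]
        report.excluded_loci = {r.locus: r.reasons[0] for r in report.qc
                                if r.decision == "exclude"}
    except Exception as exc:  # pragma: no cover - defensive
        report.errors.append(("qc", repr(exc)))
        return report
    if not report.retained_loci:
        report.errors.append(("qc", "all loci excluded"))
        return report
    work = matrix.select_loci(report.retained_loci)

    # -- stage 2: F-statistics with inference
    try:
        fs = fstats_mod.f_statistics(work)
        fis_obs, fis_p = fstats_mod.permute_fis_test(
            work, n_perm=config.n_perm, seed=seed + 1)
        g_obs, g_p, g_by_locus = fstats_mod.g_test_differentiation(
            work, n_perm=config.n_perm, seed=seed + 2)
        fis_ci = fstats_mod.bootstrap_ci_loci(
            work, "fis", n_boot=config.n_boot, seed=seed + 3)
        fst_ci = fstats_mod.bootstrap_ci_loci(
            work, "fst", n_boot=config.n_boot, seed=seed + 4)
        jack = {}
        if len(work.subsamples()) >= 3:
            for locus in work.loci:
                try:
                    fis_l, se, li, ls = fstats_mod.jackknife_fis_populations(
                        work, locus)
                    jack[locus] = {"fis": fis_l, "se": se, "li": li, "ls": ls}
                except ValueError:
                    pass
        report.fstat = {
            "fis": fs.fis, "fst": fs.fst, "fit": fs.fit,
            "fis_p": fis_p, "g": g_obs, "g_p": g_p,
            "fis_ci": fis_ci, "fst_ci": fst_ci,
            "per_locus": fs.per_locus, "jackknife": jack,
        }
        report.ld = fstats_mod.ld_pairwise_tests(
            work, n_perm=max(config.n_perm // 10, 100), seed=seed + 5)
    except Exception as exc:
        report.errors.append(("fstats", repr(exc)))
        return report

    # -- stage 3: differentiation
    try:
        div = diff_mod.nei_diversities(work)
        nulls = {l: qc_mod.em_null_frequency(work, l) for l in work.loci}
        fst_e, fst_e_ci, _ = diff_mod.fst_ena(
            work, nulls, n_boot=config.n_boot, seed=seed + 6)
        fmax = diff_mod.fst_max(work)
        prime = diff_mod.fst_prime(fst_e, fmax) if fmax > 0 else None
        n_sub = len(work.subsamples())
        gpp = diff_mod.gst_double_prime(div.mean_h_t, div.mean_h_s, n_sub)
        rho, rho_p, preferred = diff_mod.gst_hs_correlation(
            [div.g_st[l] for l in work.loci],
            [div.h_s[l] for l in work.loci])
        report.differentiation = {
            "h_s": div.mean_h_s, "h_t": div.mean_h_t,
            "fst_ena": fst_e, "fst_ena_ci": fst_e_ci,
            "fst_max": fmax, "fst_prime": prime,
            "gst_double_prime": gpp,
            "gst_hs_rho": rho, "gst_hs_p": rho_p, "preferred": preferred,
        }
        countries = set(work.labels("country"))
        if len(countries) >= 2:
            pw = diff_mod.pairwise_fst_prime(
                work, pairs=config.fst_prime_pairs,
                n_boot=min(config.n_boot, 1000), seed=seed + 7)
            report.differentiation["cross_country_fst_prime"] = \
                pw["mean_fst_prime"]
            report.differentiation["cross_country_ci"] = pw["mean_ci"]
    except Exception as exc:
        report.errors.append(("differentiation", repr(exc)))
        return report

    # -- stage 4: effective population size
    try:
        table, grand = ne_mod.ne_table(
            work, methods=config.ne_methods, rare_cutoff=config.rare_cutoff)
        report.ne = {
            "methods": [dataclasses.asdict(e) for e in table],
            "grand_average": grand[0], "grand_min": grand[1],
            "grand_max": grand[2],
        }
    except Exception as exc:
        report.errors.append(("ne", repr(exc)))
        return report

    # -- stage 5: structure
    try:
        dm = struct_mod.chord_distance_matrix(work, null_estimates=nulls)
        newick = struct_mod.nj_tree(dm) if len(dm.labels) >= 3 else None
        ord_res = struct_mod.fca(work)
        report.structure = {
            "chord_labels": dm.labels,
            "chord_matrix": dm.values.tolist(),
            "newick": newick,
            "percent_inertia": ord_res.percent_inertia[:10].tolist(),
            "significant_axes": ord_res.significant_axes,
        }
    except Exception as exc:
        report.errors.append(("structure", repr(exc)))
    return report


def write_report(report: RunReport, outdir) -> None:
    """Write the report as JSON + per-stage TSVs in a run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "config": dataclasses.asdict(report.config),
        "retained_loci": report.retained_loci,
        "excluded_loci": report.excluded_loci,
        "fstat": report.fstat,
        "differentiation": report.differentiation,
        "ne": report.ne,
        "structure": report.structure,
        "errors": report.errors,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    if report.qc:
        with open(out / "qc.tsv", "w") as fh:
            fh.write("locus\tread_success\tnull_r_pooled\tobserved_blanks\t"
                     "expected_blanks\tblank_p\tsad_rho\tsad_p_spearman\t"
                     "sad_slope\tsad_p_weighted\tstutter_p\tdecision\treasons\n")
            for r in report.qc:
                est = r.null_estimate
                fh.write("\t".join(str(x) for x in (
                    r.locus, round(r.read_success, 4),
                    round(est.pooled_r, 4) if est else "",
                    est.observed_blanks if est else "",
                    round(est.expected_blanks, 2) if est else "",
                    r.blank_p, r.sad_rho, r.sad_p_spearman, r.sad_slope,
                    r.sad_p_weighted, r.stutter_p, r.decision,
                    ";".join(r.reasons))) + "\n")
    if report.structure and report.structure.get("newick"):
        (out / "tree.nwk").write_text(report.structure["newick"] + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)
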