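"""End-to-end orchestration of the analysis stages from a single config.

Stages run in dependency order: simulate → call-editing → call-snps →
polarize → coding-scan → popstats/afs → sweep-scan → profiles → report.
Every stage logs its parameters and writes plain TSV outputs into the run
directory; identical configs and seeds reproduce identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coding, editing, popstats, selection, variants
from .io_formats import write_edit_bed
from .sim import (
    SimulationParams,
    generate_population,
    generate_reference,
    generate_rna_pileups,
    write_bundle,
)
from .variants import write_polarized_tsv

logger = logging.getLogger(__name__)

_ALL_STAGES = [
    "simulate", "call_editing", "call_snps", "polarize",
    "coding_scan", "popstats", "sweep_scan", "profiles",
]


@dataclass
class PipelineConfig:
    outdir: str = "editsweep_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_ALL_STAGES))
    sim: dict = field(default_factory=dict)        # SimulationParams overrides
    n_rna_samples: int = 10
    n_resamples: int = 10_000
    n_spectrum_bins: int = 10
    window_size: int = 10_000
    min_g_fraction: float = 0.01
    min_sample_fraction: float = 0.5
    snp_freq_cutoff: float = 0.5
    min_coverage: int = 10
    min_alt_reads: int = 2
    profile_flank: int = 10
    profile_resamples: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a report dict (also written as JSON).

    A failed stage halts its dependents; outputs written so far are kept.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report: dict = {"stages": {}, "outputs": {}}
    enabled = set(config.stages)

    def skip(stage: str, reason: str):
        report["stages"][stage] = {"status": "skipped", "reason": reason}
        logger.info("stage %s skipped: %s", stage, reason)

    # ---- simulate -------------------------------------------------------
    if "simulate" not in enabled:
        skip("simulate", "disabled")
        for dep in _ALL_STAGES[1:]:
            skip(dep, "upstream stage 'simulate' unavailable")
        _write_report(report, outdir)
        return report

    params = SimulationParams(**{"seed": config.seed, **config.sim})
    logger.info("simulate: %s", params)
    ref = generate_reference(params)
    pop = generate_population(ref, params)
    pileups = generate_rna_pileups(ref, pop.truth, config.n_rna_samples, params)
    paths = write_bundle(ref, pop, outdir / "data", pileups)
    report["stages"]["simulate"] = {
        "status": "ok",
        "n_snps": int(len(pop.snps)),
        "n_edit_sites": int(len(ref.edits)),
    }
    report["outputs"].update(paths)

    # ---- editing caller -------------------------------------------------
    called = None
    if "call_editing" in enabled:
        known = {
            (row.chrom, row.pos): row.freq
            for row in pop.snps.itertuples(index=False)
        }
        calls = editing.call_edited_sites(
            pileups, ref.genome, known,
            config.min_g_fraction, config.min_sample_fraction, config.snp_freq_cutoff,
        )
        called = calls[calls["called"]].reset_index(drop=True)
        write_edit_bed(
            called.assign(level=called["editing_level"],
                          n_samples=called["n_supporting_samples"]),
            outdir / "called_edits.bed",
        )
        report["stages"]["call_editing"] = {
            "status": "ok",
            "n_called": int(len(called)),
            "n_tested": int(len(calls)),
        }
        report["outputs"]["called_edits"] = str(outdir / "called_edits.bed")
    else:
        skip("call_editing", "disabled")

    # ---- pool SNP calling ----------------------------------------------
    if "call_snps" in enabled:
        pool_called = variants.call_pool_snps(
            pop.pool, config.min_coverage, config.min_alt_reads
        )
        diag = variants.coverage_diagnostics(
            pop.pool, pop.pool["is_edited"].to_numpy()
        )
        report["stages"]["call_snps"] = {
            "status": "ok",
            "n_called": int(len(pool_called)),
            "coverage_ranksum_p": diag.ranksum_p,
            "coverage_freq_corr": diag.corr,
        }
    else:
        skip("call_snps", "disabled")

    # ---- polarization ---------------------------------------------------
    polarized = None
    if "polarize" in enabled:
        outgroup_map = {
            (r.chrom, r.pos): frozenset(r.outgroup_alleles)
            for r in pop.outgroup.itertuples(index=False)
        }
        from .io_formats import Outgroup

        og = Outgroup(outgroup_map)
        snps = variants.add_frequencies(
            pop.snps.assign(gt_alt=pop.snps["count"],
                            gt_ref=params.n_lines - pop.snps["count"]),
            "panel",
        )
        polarized = variants.polarize(snps, og, "AG")
        write_polarized_tsv(polarized, outdir / "polarized_sites.tsv")
        report["stages"]["polarize"] = {
            "status": "ok",
            "n_pass": int(polarized["passes"].sum()),
            "n_fail": int((~polarized["passes"]).sum()),
        }
        report["outputs"]["polarized"] = str(outdir / "polarized_sites.tsv")
    else:
        skip("polarize", "disabled")

    # ---- coding scan ----------------------------------------------------
    if "coding_scan" in enabled:
        contexts = coding.classify_A_sites(ref.genome, ref.genes)
        ag = pop.snps[pop.snps["sense_alt"] == "G"]
        rt = coding.compute_rate_table(contexts, ag, ref.edits)
        rt.to_frame().to_csv(outdir / "rate_table.tsv", sep="\t", index=False,
                             float_format="%.6f")
        report["stages"]["coding_scan"] = {
            "status": "ok",
            "S": rt.S, "N": rt.N,
            "f_s": rt.f_s, "f_n": rt.f_n,
            "f_s_edited": rt.f_s_edited, "f_n_edited": rt.f_n_edited,
        }
        report["outputs"]["rate_table"] = str(outdir / "rate_table.tsv")
    else:
        skip("coding_scan", "disabled")

    # ---- population statistics -----------------------------------------
    if "popstats" in enabled and polarized is not None:
        n_edited_total = len(ref.edits)
        n_at = sum(
            int((ref.genome.char_array(c) == b"A").sum()
                + (ref.genome.char_array(c) == b"T").sum())
            for c in ref.genome.chroms
        )
        table = popstats.tabulate(
            pop.snps, ref.edits, n_edited_total, n_at - n_edited_total
        )
        table.to_frame().to_csv(outdir / "table2_like.tsv", sep="\t", index=False)
        ok = polarized[polarized["passes"]]
        edited_keys = set(zip(ref.edits["chrom"], ref.edits["pos"]))
        em = np.fromiter(
            ((c, p) in edited_keys for c, p in zip(ok["chrom"], ok["pos"])),
            bool, len(ok),
        )
        e_freqs = ok.loc[em, "derived_freq"].to_numpy()
        u_freqs = ok.loc[~em, "derived_freq"].to_numpy()
        spec = popstats.resampled_spectrum(
            e_freqs, u_freqs, config.n_spectrum_bins, config.n_resamples,
            seed=np.random.default_rng(np.random.SeedSequence([config.seed, 10])),
        )
        popstats.write_spectrum_tsv(spec, outdir / "spectrum.tsv")
        matches = popstats.match_nearest_controls(
            ok[em].reset_index(drop=True), ok[~em].reset_index(drop=True)
        )
        matches.to_csv(outdir / "matches.tsv", sep="\t", index=False)
        _, p_shift = popstats.compare_spectra(e_freqs, u_freqs, "a_greater")
        report["stages"]["popstats"] = {
            "status": "ok",
            "edited_polymorphic_pct": table.edited_polymorphic_pct,
            "unedited_polymorphic_pct": table.unedited_polymorphic_pct,
            "edited_AG_pct": table.type_pct("edited", "AG"),
            "mean_shift": spec.mean_shift,
            "shift_ranksum_p": p_shift,
            "mean_control_distance": float(np.nanmean(matches["distance"])),
        }
        report["outputs"]["table2_like"] = str(outdir / "table2_like.tsv")
        report["outputs"]["spectrum"] = str(outdir / "spectrum.tsv")
        report["outputs"]["matches"] = str(outdir / "matches.tsv")
    elif "popstats" in enabled:
        skip("popstats", "upstream stage 'polarize' unavailable")
    else:
        skip("popstats", "disabled")

    # ---- sweep scan -----------------------------------------------------
    if "sweep_scan" in enabled and polarized is not None:
        ok = polarized[polarized["passes"]].reset_index(drop=True)
        edited_keys = set(zip(ref.edits["chrom"], ref.edits["pos"]))
        centers = ok.assign(
            is_edited=[(c, p) in edited_keys for c, p in zip(ok["chrom"], ok["pos"])]
        )
        windows = selection.window_snp_counts(
            centers, pop.snps, config.window_size, ref.genome.lengths
        )
        windows = selection.poly_div_windows(windows, pop.divergence,
                                             config.window_size)
        windows = selection.annotate_windows(
            windows, ref.recomb, ref.genome, config.window_size
        )
        windows_out = windows.copy()
        windows_out["pos1"] = windows_out["pos"] + 1
        windows_out.drop(columns=["pos"]).to_csv(
            outdir / "windows.tsv", sep="\t", index=False, float_format="%.6f"
        )
        e = windows[windows["is_edited"]]["snp_count"]
        u = windows[~windows["is_edited"]]["snp_count"]
        from scipy import stats as _st

        p_win = float(
            _st.mannwhitneyu(e, u, alternative="less").pvalue
        ) if len(e) and len(u) else None
        report["stages"]["sweep_scan"] = {
            "status": "ok",
            "mean_snps_edited_windows": float(e.mean()) if len(e) else None,
            "mean_snps_unedited_windows": float(u.mean()) if len(u) else None,
            "window_test_p": p_win,
        }
        report["outputs"]["windows"] = str(outdir / "windows.tsv")
    elif "sweep_scan" in enabled:
        skip("sweep_scan", "upstream stage 'polarize' unavailable")
    else:
        skip("sweep_scan", "disabled")

    # ---- nucleotide profiles -------------------------------------------
    if "profiles" in enabled:
        from . import profiles as prof

        fg = prof.site_profile(ref.genome, ref.edits, config.profile_flank)
        n_a = int((ref.edits["strand"] == "+").sum())
        n_t = int((ref.edits["strand"] == "-").sum())
        bg = prof.background_profile(
            ref.genome, max(n_a, 1), max(n_t, 1), config.profile_flank,
            config.profile_resamples,
            seed=np.random.default_rng(np.random.SeedSequence([config.seed, 11])),
        )
        prof.write_profile_tsv(fg, bg, outdir / "profile.tsv")
        report["stages"]["profiles"] = {"status": "ok", "n_sites": fg.n_sites}
        report["outputs"]["profile"] = str(outdir / "profile.tsv")
    else:
        skip("profiles", "disabled")

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    report["checksums"] = {
        name: _checksum(Path(p))
        for name, p in sorted(report["outputs"].items())
        if Path(p).is_file()
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)


def reproduce_printed_tables(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute the packaged published-count tables and write the checks."""
    from . import reference_tables as rt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t2 = rt.check_site_class_table()
    t3 = rt.check_rate_table()
    t2.to_csv(outdir / "table2_check.tsv", sep="\t", index=False, float_format="%.6f")
    t3.to_csv(outdir / "table3_check.tsv", sep="\t", index=False, float_format="%.6f")
    for name, df in (("table2", t2), ("table3", t3)):
        bad = df[~df["match"]]
        for row in bad.itertuples(index=False):
            logger.warning(
                "%s: printed value %s for %s/%s disagrees with its own counts "
                "(computed %.4g)", name, row.printed if hasattr(row, "printed")
                else row.printed_pct, row.population, row.cell,
                row.computed if hasattr(row, "computed") else row.computed_pct,
            )
    return t2, t3
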