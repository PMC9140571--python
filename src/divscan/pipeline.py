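"""End-to-end orchestration: QC -> diversity -> structure -> Ne -> ROH ->
d_i scan -> XPEHH scan -> region overlap, from one YAML config.

Every stage writes TSV/BED artifacts plus a JSON run log (parameters,
counts in/out, warnings); ``make_report`` collates them into a markdown
summary. Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diversity, ne_ld, popstructure, qc, roh, selection_fst, selection_xpehh
from .genotype_io import (
    GenotypeMatrix,
    HaplotypeSet,
    apply_population_labels,
    match_haplotypes,
    read_haplotypes,
    read_plink_bed,
    read_plink_text,
    read_population_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    focal: str
    out_dir: str
    seed: int = 0
    # inputs: either plink text/bed paths or a haplotype source (which
    # also supplies genotypes by collapsing)
    ped: str | None = None
    map: str | None = None
    bed: str | None = None
    bim: str | None = None
    fam: str | None = None
    haplotypes: str | None = None
    haplotype_format: str = "haps"
    population_tsv: str | None = None
    l_auto_bp: float = roh.OVINE_L_AUTO_BP
    qc_params: qc.QcParams = field(default_factory=qc.QcParams)
    ld_params: qc.LdPruneParams = field(default_factory=qc.LdPruneParams)
    roh_params: roh.RohParams = field(default_factory=roh.RohParams)
    ne_params: ne_ld.NeParams = field(default_factory=ne_ld.NeParams)
    window_bp: int = 1_000_000
    min_window_snps: int = 5
    top_fraction: float = 0.01
    pxpehh_threshold: float = 5.0
    rarefaction_g: int | None = None
    mds_axes: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (
            ("qc_params", qc.QcParams),
            ("ld_params", qc.LdPruneParams),
            ("roh_params", roh.RohParams),
            ("ne_params", ne_ld.NeParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


def _load_inputs(cfg: PipelineConfig) -> tuple[GenotypeMatrix, HaplotypeSet | None]:
    pops = read_population_tsv(cfg.population_tsv) if cfg.population_tsv else None
    hs = None
    if cfg.haplotypes:
        hs = read_haplotypes(cfg.haplotypes, cfg.haplotype_format, populations=pops)
    if cfg.ped and cfg.map:
        gm = read_plink_text(cfg.ped, cfg.map)
    elif cfg.bed and cfg.bim and cfg.fam:
        gm = read_plink_bed(cfg.bed, cfg.bim, cfg.fam)
    elif hs is not None:
        gm = hs.to_genotypes()
    else:
        raise ValueError("no genotype input configured")
    if pops:
        gm = apply_population_labels(gm, pops)
    return gm, hs


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the consolidated report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": _config_dict(cfg), "stages": {}}
    report: dict = {}
    stage = "load"
    try:
        gm, hs = _load_inputs(cfg)
        if cfg.focal not in gm.population_labels:
            raise ValueError(f"focal population {cfg.focal!r} not among labels {gm.population_labels}")
        log["stages"]["load"] = {"samples": gm.n_samples, "snps": gm.n_snps}

        stage = "qc"
        gm_qc, reports = qc.run_qc(gm, cfg.qc_params)
        _write_tsv(
            out / "qc_removals.tsv",
            ["stage", "n_before", "n_after", "removed"],
            [[r.stage, r.n_before, r.n_after, ",".join(r.removed) or "."] for r in reports],
        )
        log["stages"]["qc"] = {r.stage: {"before": r.n_before, "after": r.n_after} for r in reports}
        if hs is not None:
            hs = match_haplotypes(hs, gm_qc)

        stage = "ld_prune"
        gm_ld, ld_rep = qc.ld_prune(gm_qc, cfg.ld_params)
        log["stages"]["ld_prune"] = {"before": ld_rep.n_before, "after": ld_rep.n_after}

        stage = "diversity"
        div = diversity.diversity_table(gm_qc, g=cfg.rarefaction_g)
        _write_tsv(
            out / "diversity.tsv",
            ["population", "n", "Ho", "He", "F_IS", "A_R", "pA_R", "g"],
            [
                [d.population, d.n, f"{d.h_obs:.4f}", f"{d.h_exp:.4f}", f"{d.f_is:.4f}",
                 f"{d.allelic_richness:.4f}", f"{d.private_allelic_richness:.4f}", d.g]
                for d in div
            ],
        )
        report["diversity"] = div

        stage = "structure"
        dist = popstructure.ibs_matrix(gm_ld)
        mds_res = popstructure.mds(dist, cfg.mds_axes)
        _write_tsv(
            out / "mds.tsv",
            ["sample", "population"] + [f"axis{a+1}" for a in range(cfg.mds_axes)],
            [
                [s, p] + [f"{mds_res.coordinates[i, a]:.6f}" for a in range(cfg.mds_axes)]
                for i, (s, p) in enumerate(zip(mds_res.samples, mds_res.populations))
            ],
        )
        report["mds_variance_pct"] = mds_res.variance_explained.tolist()

        stage = "ne"
        ne_rows = []
        report["ne"] = {}
        for pop in gm_qc.population_labels:
            traj = ne_ld.ne_trajectory(gm_qc, pop, cfg.ne_params)
            try:
                at = ne_ld.ne_at_generations(traj, (5.0, 50.0))
                report["ne"][pop] = {f"Ne_{int(t)}": v for t, (v, _) in at.items()}
            except ValueError:
                report["ne"][pop] = {}
            for b in traj.bins:
                ne_rows.append(
                    [pop, f"{b.c_morgans:.6f}", f"{b.t_generations:.2f}", b.n_pairs,
                     f"{b.mean_r2_adj:.5f}" if np.isfinite(b.mean_r2_adj) else "NA",
                     f"{b.ne:.1f}" if np.isfinite(b.ne) else "NA"]
                )
        _write_tsv(out / "ne_trajectory.tsv", ["population", "c_morgans", "t", "n_pairs", "r2_adj", "Ne"], ne_rows)

        stage = "roh"
        p_roh = cfg.roh_params
        het = roh.cohort_mean_het(gm_qc)
        l_val = roh.min_snps_l(p_roh.alpha_fp, gm_qc.n_snps, gm_qc.n_samples, het)
        p_roh = dataclasses.replace(p_roh, min_snps_l=l_val)
        segments = roh.detect_roh(gm_qc, p_roh)
        sample_sum, pop_sum = roh.summarize_roh(gm_qc, segments, cfg.l_auto_bp)
        _write_tsv(
            out / "roh_segments.tsv",
            ["sample", "chromosome", "start_bp", "end_bp", "n_snps", "length_bp"],
            [[s.sample, s.chromosome, s.start_bp, s.end_bp, s.n_snps, s.length_bp] for s in segments],
        )
        _write_tsv(
            out / "roh_by_population.tsv",
            ["population", "n", "mean_n_roh", "mean_length_mb", "F_ROH_1Mb", "F_ROH_5Mb",
             "F_ROH_10Mb", "class_1_5", "class_5_10", "class_gt10", "recent_pct"],
            [
                [r.population, r.n_samples, f"{r.mean_n_roh:.2f}", f"{r.mean_total_length_mb:.2f}",
                 f"{r.mean_f_roh_1mb:.4f}", f"{r.mean_f_roh_5mb:.4f}", f"{r.mean_f_roh_10mb:.4f}",
                 f"{r.class_frequencies[0]:.3f}", f"{r.class_frequencies[1]:.3f}",
                 f"{r.class_frequencies[2]:.3f}", f"{r.recent_inbreeding_pct:.2f}"]
                for r in pop_sum
            ],
        )
        report["roh"] = {"l": l_val, "n_segments": len(segments), "by_population": pop_sum}

        stage = "di_scan"
        scan = selection_fst.fst_scan(gm_qc, cfg.focal)
        windows = selection_fst.window_scores(scan.d_i, gm_qc.map, cfg.window_bp, cfg.min_window_snps)
        di_regions = selection_fst.top_windows(windows, cfg.top_fraction) if windows else []
        _write_tsv(
            out / "di_windows.tsv",
            ["chromosome", "start_bp", "end_bp", "n_snps", "mean_d_i"],
            [[w.chromosome, w.start_bp, w.end_bp, w.n_snps, f"{w.mean_d_i:.4f}"] for w in windows],
        )
        _write_bed(out / "di_regions.bed", di_regions)
        report["di"] = {"n_windows": len(windows), "regions": di_regions}

        stage = "xpehh"
        xp_regions: list[selection_fst.SelectionRegion] = []
        if hs is not None:
            others = [p for p in gm_qc.population_labels if p != cfg.focal]
            rate = cfg.ne_params.rec_rate_cm_per_mb
            h_focal = hs.restrict_population(cfg.focal)
            ies_focal = selection_xpehh._ies_all(h_focal, rate, 0.05, 250_000)
            sig_sets = []
            for o in others:
                h_o = hs.restrict_population(o)
                scores = selection_xpehh.xpehh(h_focal, h_o, rate, ies_a=ies_focal)
                _write_tsv(
                    out / f"xpehh_{cfg.focal}_vs_{o}.tsv",
                    ["snp_id", "chromosome", "position_bp", "raw", "xpehh", "pxpehh"],
                    [
                        [scores.snp_id[j], scores.map.chromosome[j], scores.map.position_bp[j],
                         f"{scores.raw[j]:.4f}", f"{scores.xpehh[j]:.4f}", f"{scores.pxpehh[j]:.4f}"]
                        for j in range(scores.map.n_snps)
                        if np.isfinite(scores.raw[j])
                    ],
                )
                if not scores.degenerate:
                    sig_sets.append(selection_xpehh.significant_snps(scores, cfg.pxpehh_threshold))
            if len(sig_sets) >= 2:
                xp_regions = selection_xpehh.common_regions(sig_sets, hs.map)
            _write_bed(out / "xpehh_regions.bed", xp_regions)
        report["xpehh_regions"] = xp_regions

        stage = "overlap"
        overlap = selection_xpehh.overlap_regions(di_regions, xp_regions)
        _write_bed(out / "overlap_regions.bed", overlap)
        report["overlap_regions"] = overlap
    except Exception as exc:
        log["failed_stage"] = stage
        log["error"] = str(exc)
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    (out / "report.md").write_text(make_report(report, out))
    return report


def _write_bed(path: Path, regions: list[selection_fst.SelectionRegion]) -> None:
    """Regions as BED (0-based half-open starts per the BED convention)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{r.source}\t{r.n_snps}\n")


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["ne_params"]["distance_bins_bp"] = list(map(float, d["ne_params"]["distance_bins_bp"]))
    return d


def make_report(report: dict, out_dir: Path | None = None) -> str:
    """Markdown summary of the stage outputs; missing stages are marked
    skipped and empty region lists are stated explicitly."""
    lines = ["# divscan run report", ""]
    if "diversity" in report:
        lines += ["## Diversity", "", "| population | n | Ho | He | F_IS | A_R | pA_R |", "|---|---|---|---|---|---|---|"]
        for d in report["diversity"]:
            lines.append(
                f"| {d.population} | {d.n} | {d.h_obs:.3f} | {d.h_exp:.3f} | "
                f"{d.f_is:.3f} | {d.allelic_richness:.3f} | {d.private_allelic_richness:.3f} |"
            )
        lines.append("")
    else:
        lines += ["## Diversity", "", "_skipped_", ""]
    if "mds_variance_pct" in report:
        pcts = ", ".join(f"{v:.1f}%" for v in report["mds_variance_pct"])
        lines += ["## Structure", "", f"MDS variance explained per axis: {pcts}", ""]
    if "ne" in report:
        lines += ["## Effective population size", ""]
        for pop, vals in report["ne"].items():
            desc = ", ".join(f"{k} = {v:.0f}" for k, v in vals.items()) or "not estimable"
            lines.append(f"- {pop}: {desc}")
        lines.append("")
    if "roh" in report:
        r = report["roh"]
        lines += ["## Runs of homozygosity", "", f"Minimum SNPs per run l = {r['l']}; {r['n_segments']} segments.", ""]
        for p in r["by_population"]:
            lines.append(
                f"- {p.population}: mean F_ROH(1 Mb) = {p.mean_f_roh_1mb:.3f}, "
                f"mean {p.mean_n_roh:.1f} runs, recent-inbreeding share {p.recent_inbreeding_pct:.2f}%"
            )
        lines.append("")
    for key, title in (
        ("di", "d_i selection scan"),
        ("xpehh_regions", "XPEHH common regions"),
        ("overlap_regions", "Overlap of both scans"),
    ):
        lines += [f"## {title}", ""]
        if key not in report:
            lines += ["_skipped_", ""]
            continue
        regions = report[key]["regions"] if key == "di" else report[key]
        if not regions:
            lines += ["No regions called.", ""]
        else:
            for r in regions:
                lines.append(f"- chr{r.chromosome}:{r.start_bp}-{r.end_bp} ({r.n_snps} SNPs, {r.source})")
            lines.append("")
    return "\n".join(lines)
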