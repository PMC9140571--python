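"""Runs of homozygosity: sliding-window detection, F_ROH, length classes.

The detector reproduces the classic SNP-chip window scan: a 50-SNP
window slides one SNP at a time along each chromosome of each sample; a
window "passes" when it contains at most one heterozygous and at most
one missing call; a SNP is flagged homozygous-run when at least 5% of
the windows covering it pass. Maximal stretches of flagged SNPs become
candidate runs — a run admits at most one heterozygous call, is split
at inter-SNP gaps above 250 kb, and must satisfy the length (>= 1 Mb),
SNP-count (>= l) and density (<= 1 SNP / 100 kb on average) minima.

The per-cohort minimum SNP count l controls the expected number of
false-positive runs:

    l = ln(alpha / (ns * ni)) / ln(1 - het)   (floored)

with ns SNPs per individual, ni individuals and het the cohort mean
heterozygosity. F_ROH is the summed run length over the autosomal SNP
coverage L_AUTO (2.648 Gb for the ovine 50K map).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: total autosomal SNP coverage of the ovine 50K map, bp
OVINE_L_AUTO_BP: float = 2.648e9


@dataclass
class RohParams:
    window_snps: int = 50
    het_allowed_per_window: int = 1
    missing_allowed_per_window: int = 1
    window_hit_threshold: float = 0.05
    max_gap_bp: int = 250_000
    min_density_bp_per_snp: float = 100_000.0
    min_length_bp: int = 1_000_000
    min_snps_l: int = 1
    alpha_fp: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must be in (0, 1]")
        for name in (
            "window_snps",
            "max_gap_bp",
            "min_density_bp_per_snp",
            "min_length_bp",
            "min_snps_l",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RohSegment:
    sample: str
    chromosome: int
    start_bp: int  # 1-based inclusive
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def min_snps_l(alpha: float, ns: int, ni: int, het: float) -> int:
    """Minimum SNPs per run from the false-positive-rate formula (floored)."""
    if not 0.0 < het < 1.0:
        raise ValueError("het must be in (0, 1)")
    if ns < 1 or ni < 1 or not 0.0 < alpha < 1.0:
        raise ValueError("need ns, ni >= 1 and alpha in (0, 1)")
    return int(math.floor(math.log(alpha / (ns * ni)) / math.log(1.0 - het)))


def cohort_mean_het(gm: GenotypeMatrix) -> float:
    """Mean observed heterozygosity across all samples and retained SNPs."""
    obs = gm.calls != MISSING
    return float(((gm.calls == 1) & obs).sum() / obs.sum())


def detect_roh(gm: GenotypeMatrix, p: RohParams) -> list[RohSegment]:
    """Window-scan ROH detection for every sample on every chromosome."""
    segments: list[RohSegment] = []
    for chrom in gm.map.chromosomes():
        cidx = gm.map.chrom_index(chrom)
        pos = gm.map.position_bp[cidx]
        if cidx.size < p.window_snps:
            logger.info(
                "chromosome %d has %d SNPs (< window %d): single shortened window",
                chrom,
                cidx.size,
                p.window_snps,
            )
        for i, sample in enumerate(gm.samples):
            calls = gm.calls[i, cidx]
            segments.extend(_scan_sample_chrom(sample, int(chrom), pos, calls, p))
    return segments


def _window_flags(calls: np.ndarray, p: RohParams) -> np.ndarray:
    """Per-SNP homozygous-run flag from sliding-window pass rates."""
    m = calls.size
    w = min(p.window_snps, m)
    het = (calls == 1).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    n_windows = m - w + 1
    het_c = np.convolve(het, np.ones(w, dtype=np.int32), mode="valid")
    mis_c = np.convolve(mis, np.ones(w, dtype=np.int32), mode="valid")
    passing = (het_c <= p.het_allowed_per_window) & (mis_c <= p.missing_allowed_per_window)
    # windows covering SNP j: starts in [max(0, j-w+1), min(j, n_windows-1)]
    hits = np.zeros(m)
    total = np.zeros(m)
    cum_pass = np.concatenate([[0], np.cumsum(passing)])
    for j in range(m):
        lo = max(0, j - w + 1)
        hi = min(j, n_windows - 1)
        total[j] = hi - lo + 1
        hits[j] = cum_pass[hi + 1] - cum_pass[lo]
    return hits / total >= p.window_hit_threshold


def _scan_sample_chrom(
    sample: str, chrom: int, pos: np.ndarray, calls: np.ndarray, p: RohParams
) -> list[RohSegment]:
    flagged = _window_flags(calls, p)
    runs = _flag_runs(flagged)
    pieces: list[tuple[int, int]] = []
    for s, e in runs:
        pieces.extend(_split_by_het(calls, s, e, p.het_allowed_per_window))
    final: list[tuple[int, int]] = []
    for s, e in pieces:
        final.extend(_split_by_gap(pos, s, e, p.max_gap_bp))
    out = []
    for s, e in final:
        seg = RohSegment(sample, chrom, int(pos[s]), int(pos[e]), e - s + 1)
        if _segment_ok(seg, p):
            out.append(seg)
    return out


def _flag_runs(flagged: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True."""
    runs = []
    m = flagged.size
    j = 0
    while j < m:
        if flagged[j]:
            s = j
            while j + 1 < m and flagged[j + 1]:
                j += 1
            runs.append((s, j))
        j += 1
    return runs


def _split_by_het(
    calls: np.ndarray, s: int, e: int, het_allowed: int
) -> list[tuple[int, int]]:
    """Enforce the per-run het allowance, splitting at excess hets.

    Scanning left to right, a run keeps up to ``het_allowed``
    heterozygous calls; the het that would exceed the allowance ends the
    run before it and a fresh run (with a reset allowance) starts after
    it.
    """
    out = []
    start = s
    hets = 0
    for j in range(s, e + 1):
        if calls[j] == 1:
            hets += 1
            if hets > het_allowed:
                if j > start:
                    out.append((start, j - 1))
                start = j + 1
                hets = 0
    if start <= e:
        out.append((start, e))
    return out


def _split_by_gap(pos: np.ndarray, s: int, e: int, max_gap: int) -> list[tuple[int, int]]:
    out = []
    start = s
    for j in range(s, e):
        if pos[j + 1] - pos[j] > max_gap:
            out.append((start, j))
            start = j + 1
    out.append((start, e))
    return out


def _segment_ok(seg: RohSegment, p: RohParams) -> bool:
    if seg.length_bp < p.min_length_bp:
        return False
    if seg.n_snps < p.min_snps_l:
        return False
    if seg.length_bp / seg.n_snps > p.min_density_bp_per_snp:
        return False
    return True


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def f_roh(
    segments: list[RohSegment], l_auto_bp: float = OVINE_L_AUTO_BP, min_len_bp: int = 1_000_000
) -> float:
    """Genomic inbreeding: summed length of runs >= min_len_bp over L_AUTO."""
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    total = sum(s.length_bp for s in segments if s.length_bp >= min_len_bp)
    return total / l_auto_bp


_CLASS_EDGES_MB = (1.0, 5.0, 10.0)


def roh_class_frequencies(segments: list[RohSegment]) -> tuple[float, float, float]:
    """Frequencies of runs in the [1-5], (5-10], (10, inf) Mb classes.

    The first class is closed at 5 Mb (a 5 Mb run is "1-5"); the second
    open at 5 and closed at 10. Empty input returns all zeros.
    """
    if not segments:
        logger.warning("roh_class_frequencies on empty segment list")
        return (0.0, 0.0, 0.0)
    mb = np.array([s.length_bp for s in segments]) / 1e6
    c1 = int(((mb >= _CLASS_EDGES_MB[0]) & (mb <= _CLASS_EDGES_MB[1])).sum())
    c2 = int(((mb > _CLASS_EDGES_MB[1]) & (mb <= _CLASS_EDGES_MB[2])).sum())
    c3 = int((mb > _CLASS_EDGES_MB[2]).sum())
    n = len(segments)
    return (c1 / n, c2 / n, c3 / n)


def recent_inbreeding_fraction(f_roh_10mb: float, f_roh_1mb: float) -> float:
    """Share of inbreeding from the last ~5 generations, as a percentage.

    100 * F_ROH(10 Mb) / F_ROH(1 Mb), rounded to 2 decimals.
    """
    if f_roh_1mb == 0:
        raise ValueError("recent-inbreeding fraction undefined: F_ROH(1 Mb) = 0")
    return round(100.0 * f_roh_10mb / f_roh_1mb, 2)


@dataclass
class RohSampleSummary:
    sample: str
    population: str
    n_roh: int
    total_length_bp: int
    f_roh_1mb: float
    f_roh_5mb: float
    f_roh_10mb: float


@dataclass
class RohPopulationSummary:
    population: str
    n_samples: int
    mean_n_roh: float
    mean_total_length_mb: float
    mean_f_roh_1mb: float
    mean_f_roh_5mb: float
    mean_f_roh_10mb: float
    class_frequencies: tuple[float, float, float]
    recent_inbreeding_pct: float


def summarize_roh(
    gm: GenotypeMatrix,
    segments: list[RohSegment],
    l_auto_bp: float = OVINE_L_AUTO_BP,
) -> tuple[list[RohSampleSummary], list[RohPopulationSummary]]:
    """Per-sample and per-population ROH summaries (the Table-2 analog)."""
    by_sample: dict[str, list[RohSegment]] = {s: [] for s in gm.samples}
    for seg in segments:
        by_sample[seg.sample].append(seg)
    sample_rows = []
    pop_of = dict(zip(gm.samples, gm.populations))
    for s, segs in by_sample.items():
        sample_rows.append(
            RohSampleSummary(
                sample=s,
                population=pop_of[s],
                n_roh=len(segs),
                total_length_bp=sum(x.length_bp for x in segs),
                f_roh_1mb=f_roh(segs, l_auto_bp, 1_000_000),
                f_roh_5mb=f_roh(segs, l_auto_bp, 5_000_000),
                f_roh_10mb=f_roh(segs, l_auto_bp, 10_000_000),
            )
        )
    pop_rows = []
    for pop in gm.population_labels:
        rows = [r for r in sample_rows if r.population == pop]
        segs = [seg for r in rows for seg in by_sample[r.sample]]
        mean_f1 = float(np.mean([r.f_roh_1mb for r in rows]))
        mean_f10 = float(np.mean([r.f_roh_10mb for r in rows]))
        pop_rows.append(
            RohPopulationSummary(
                population=pop,
                n_samples=len(rows),
                mean_n_roh=float(np.mean([r.n_roh for r in rows])),
                mean_total_length_mb=float(np.mean([r.total_length_bp for r in rows])) / 1e6,
                mean_f_roh_1mb=mean_f1,
                mean_f_roh_5mb=float(np.mean([r.f_roh_5mb for r in rows])),
                mean_f_roh_10mb=mean_f10,
                class_frequencies=roh_class_frequencies(segs),
                recent_inbreeding_pct=(
                    recent_inbreeding_fraction(mean_f10, mean_f1) if mean_f1 > 0 else 0.0
                ),
            )
        )
    return sample_rows, pop_rows
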