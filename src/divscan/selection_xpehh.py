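"""Haplotype-based cross-population selection scan (EHH / iES / XPEHH).

Site-EHH at offset k from a core SNP is the probability that two random
haplotypes are identical over every SNP from the core out to offset k
(the core allele included); EHH at the core itself is 1 by definition.
iES integrates the bidirectional EHH curve over genetic distance
(trapezoid rule), truncating where EHH falls below a cutoff or at large
inter-SNP gaps. XPEHH is the genome-wide standardized ln(iES_A/iES_B),
and significance is expressed on the pXPEHH scale:

    pXPEHH = -log10(1 - |2 Phi(XPEHH) - 1|) = -log10(two-sided p)

so pXPEHH >= 5 corresponds to p <= 1e-5. Signals shared by every
pairwise comparison are chained into candidate regions of bounded span.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .genotype_io import HaplotypeSet, MarkerMap
from .selection_fst import SelectionRegion

logger = logging.getLogger(__name__)


@dataclass
class EhhCurve:
    core_index: int  # index within the chromosome's SNPs
    direction: int  # +1 downstream (increasing bp), -1 upstream
    offsets: np.ndarray  # SNP offsets from the core, 0, 1, 2, ...
    positions_bp: np.ndarray
    ehh: np.ndarray  # values in [0, 1], ehh[0] = 1


@dataclass
class XpehhScores:
    pop_a: str
    pop_b: str
    snp_id: np.ndarray
    raw: np.ndarray  # ln(iES_A / iES_B), NaN where skipped
    xpehh: np.ndarray  # genome-wide standardized
    pxpehh: np.ndarray
    map: MarkerMap
    degenerate: bool = False  # all-equal raw scores (no variance)


def _homozygosity(group_ids: np.ndarray) -> float:
    """Probability two distinct haplotypes share a group: sum C(n_g,2)/C(n,2)."""
    n = group_ids.size
    _, counts = np.unique(group_ids, return_counts=True)
    num = (counts * (counts - 1)).sum()
    return float(num / (n * (n - 1)))


def ehh(
    h: HaplotypeSet,
    core_index: int,
    direction: int,
    cutoff: float = 0.05,
    max_gap_bp: int = 250_000,
) -> EhhCurve:
    """Site-EHH decay from ``core_index`` in the given map direction.

    ``core_index`` addresses the full map; the curve stays on the core's
    chromosome. Truncates once EHH < ``cutoff`` or when the next
    inter-SNP gap exceeds ``max_gap_bp``.
    """
    if h.n_haplotypes < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    mm = h.map
    chrom = mm.chromosome[core_index]
    cidx = mm.chrom_index(chrom)
    local = int(np.searchsorted(cidx, core_index))
    haps = h.haplotypes[:, cidx]
    pos = mm.position_bp[cidx]
    m = cidx.size

    offsets = [0]
    positions = [int(pos[local])]
    values = [1.0]
    group = np.zeros(h.n_haplotypes, dtype=np.int64)
    k = 0
    while True:
        nxt = local + direction * (k + 1)
        if nxt < 0 or nxt >= m:
            break
        if abs(int(pos[nxt]) - positions[-1]) > max_gap_bp:
            break
        if k == 0:
            # first extension includes the core allele in the identity test
            group = group * 2 + haps[:, local]
        group = group * 2 + haps[:, nxt]
        # re-factor ids to keep them small
        _, group = np.unique(group, return_inverse=True)
        e = _homozygosity(group)
        k += 1
        offsets.append(k)
        positions.append(int(pos[nxt]))
        values.append(e)
        if e < cutoff:
            break
    return EhhCurve(
        core_index=core_index,
        direction=direction,
        offsets=np.array(offsets),
        positions_bp=np.array(positions),
        ehh=np.array(values),
    )


def ies(
    h: HaplotypeSet,
    core_index: int,
    rec_rate_cm_per_mb: float = 1.0,
    cutoff: float = 0.05,
    max_gap_bp: int = 250_000,
) -> float:
    """Trapezoidal integral of bidirectional site-EHH over genetic distance.

    Units are centimorgans at the given linear map rate. A curve that
    drops immediately on both sides still contributes a small positive
    value from the trapezoid between the core (EHH 1) and its
    neighbors.
    """
    rate_cm_per_bp = rec_rate_cm_per_mb / 1e6
    total = 0.0
    for direction in (+1, -1):
        curve = ehh(h, core_index, direction, cutoff, max_gap_bp)
        if curve.ehh.size < 2:
            continue
        x = np.abs(curve.positions_bp - curve.positions_bp[0]) * rate_cm_per_bp
        total += float(np.trapezoid(curve.ehh, x))
    return total


def _ies_all(h: HaplotypeSet, rate: float, cutoff: float, max_gap_bp: int) -> np.ndarray:
    """Per-SNP iES for every core, via the compiled per-chromosome kernel."""
    out = np.empty(h.map.n_snps)
    for chrom in h.map.chromosomes():
        cidx = h.map.chrom_index(chrom)
        haps = np.ascontiguousarray(h.haplotypes[:, cidx])
        pos = h.map.position_bp[cidx].astype(np.float64)
        out[cidx] = _ies_chromosome(haps, pos, rate / 1e6, cutoff, float(max_gap_bp))
    return out


def _ies_chromosome_py(
    haps: np.ndarray, pos_bp: np.ndarray, rate_cm_per_bp: float, cutoff: float, max_gap: float
) -> np.ndarray:
    """Bidirectional trapezoid iES for every core on one chromosome.

    Pure-numpy twin of the numba kernel below; kept as the fallback and
    as an independently readable statement of the algorithm.
    """
    n_hap, m = haps.shape
    pairs = n_hap * (n_hap - 1)
    out = np.zeros(m)
    for core in range(m):
        for direction in (1, -1):
            prev_ehh = 1.0
            prev_cm = pos_bp[core] * rate_cm_per_bp
            group = haps[:, core].astype(np.int64)
            k = 1
            while True:
                nxt = core + direction * k
                if nxt < 0 or nxt >= m:
                    break
                if abs(pos_bp[nxt] - pos_bp[core + direction * (k - 1)]) > max_gap:
                    break
                group = group * 2 + haps[:, nxt]
                _, group = np.unique(group, return_inverse=True)
                _, counts = np.unique(group, return_counts=True)
                e = float((counts * (counts - 1)).sum()) / pairs
                cm = pos_bp[nxt] * rate_cm_per_bp
                out[core] += 0.5 * (prev_ehh + e) * abs(cm - prev_cm)
                prev_ehh, prev_cm = e, cm
                if e < cutoff:
                    break
                k += 1
    return out


try:
    from numba import njit

    @njit(cache=False)
    def _ies_chromosome_nb(haps, pos_bp, rate_cm_per_bp, cutoff, max_gap):  # pragma: no cover
        n_hap, m = haps.shape
        pairs = n_hap * (n_hap - 1)
        out = np.zeros(m)
        group = np.empty(n_hap, dtype=np.int64)
        order = np.empty(n_hap, dtype=np.int64)
        for core in range(m):
            for direction in (1, -1):
                prev_ehh = 1.0
                prev_cm = pos_bp[core] * rate_cm_per_bp
                for i in range(n_hap):
                    group[i] = haps[i, core]
                k = 1
                while True:
                    nxt = core + direction * k
                    if nxt < 0 or nxt >= m:
                        break
                    if abs(pos_bp[nxt] - pos_bp[core + direction * (k - 1)]) > max_gap:
                        break
                    for i in range(n_hap):
                        group[i] = group[i] * 2 + haps[i, nxt]
                    # compress ids via argsort ranking (keeps values small)
                    order[:] = np.argsort(group, kind="mergesort")
                    rank = 0
                    num = 0
                    run = 1
                    prev = group[order[0]]
                    tmp_num = 0
                    for t in range(1, n_hap):
                        v = group[order[t]]
                        if v == prev:
                            run += 1
                        else:
                            tmp_num += run * (run - 1)
                            run = 1
                            prev = v
                    tmp_num += run * (run - 1)
                    # re-rank group ids
                    rank = 0
                    prev = group[order[0]]
                    newg = np.empty(n_hap, dtype=np.int64)
                    newg[order[0]] = 0
                    for t in range(1, n_hap):
                        v = group[order[t]]
                        if v != prev:
                            rank += 1
                            prev = v
                        newg[order[t]] = rank
                    for i in range(n_hap):
                        group[i] = newg[i]
                    num = tmp_num
                    e = num / pairs
                    cm = pos_bp[nxt] * rate_cm_per_bp
                    d = cm - prev_cm
                    if d < 0:
                        d = -d
                    out[core] += 0.5 * (prev_ehh + e) * d
                    prev_ehh = e
                    prev_cm = cm
                    if e < cutoff:
                        break
                    k += 1
        return out

    def _ies_chromosome(haps, pos_bp, rate, cutoff, max_gap):
        return _ies_chromosome_nb(
            np.ascontiguousarray(haps), pos_bp, float(rate), float(cutoff), float(max_gap)
        )

except ImportError:  # pragma: no cover
    _ies_chromosome = _ies_chromosome_py


def xpehh(
    h_a: HaplotypeSet,
    h_b: HaplotypeSet,
    rec_rate_cm_per_mb: float = 1.0,
    cutoff: float = 0.05,
    max_gap_bp: int = 250_000,
    ies_a: np.ndarray | None = None,
    ies_b: np.ndarray | None = None,
) -> XpehhScores:
    """Genome-wide standardized XPEHH between two phased populations.

    Pre-computed per-SNP iES vectors may be supplied to share work
    across comparisons. SNPs with zero iES in either population are
    skipped (logged).
    """
    if h_a.map.n_snps != h_b.map.n_snps or not np.array_equal(
        h_a.map.position_bp, h_b.map.position_bp
    ):
        raise ValueError("XPEHH requires identical marker maps")
    if ies_a is None:
        ies_a = _ies_all(h_a, rec_rate_cm_per_mb, cutoff, max_gap_bp)
    if ies_b is None:
        ies_b = _ies_all(h_b, rec_rate_cm_per_mb, cutoff, max_gap_bp)
    ok = (ies_a > 0) & (ies_b > 0)
    skipped = int((~ok).sum())
    if skipped:
        logger.info("xpehh: %d SNPs with zero iES skipped", skipped)
    raw = np.full(h_a.map.n_snps, np.nan)
    raw[ok] = np.log(ies_a[ok] / ies_b[ok])
    vals = raw[ok]
    degenerate = vals.size == 0 or float(vals.std()) == 0.0
    std = np.full_like(raw, np.nan)
    px = np.full_like(raw, np.nan)
    if degenerate:
        logger.warning("xpehh: raw scores have zero variance; standardization degenerate")
    else:
        std[ok] = (raw[ok] - vals.mean()) / vals.std(ddof=0)
        px[ok] = pxpehh_transform(std[ok])
    pop_a = h_a.populations[0] if h_a.n_samples else "A"
    pop_b = h_b.populations[0] if h_b.n_samples else "B"
    return XpehhScores(pop_a, pop_b, h_a.map.snp_id, raw, std, px, h_a.map, degenerate)


def pxpehh_transform(x: np.ndarray) -> np.ndarray:
    """-log10 two-sided Gaussian p of a standardized score.

    Even in x, zero at x = 0, strictly increasing in |x|; equals
    log10(1/P) for the two-sided tail probability P.
    """
    x = np.asarray(x, dtype=float)
    # 1 - |2 Phi(x) - 1| = 2 Phi(-|x|): use the survival function for precision
    p_two_sided = 2.0 * norm.sf(np.abs(x))
    with np.errstate(divide="ignore"):
        return -np.log10(p_two_sided)


def significant_snps(scores: XpehhScores, threshold: float = 5.0) -> np.ndarray:
    """Indices of SNPs with pXPEHH >= threshold (closed threshold)."""
    if scores.degenerate:
        raise ValueError("cannot threshold degenerate XPEHH scores")
    return np.flatnonzero(scores.pxpehh >= threshold)


def common_regions(
    significant_sets: list[np.ndarray],
    mm: MarkerMap,
    min_snps: int = 3,
    max_span_bp: int = 1_000_000,
) -> list[SelectionRegion]:
    """Cluster SNPs significant in every comparison into candidate regions.

    The intersection of the per-comparison significant-SNP index sets is
    chained per chromosome left to right; a region closes when adding
    the next SNP would stretch its span past ``max_span_bp`` or when the
    next SNP is itself more than ``max_span_bp`` away. Clusters with at
    least ``min_snps`` SNPs are emitted.
    """
    if len(significant_sets) < 2:
        raise ValueError("need >= 2 pairwise comparisons")
    common = set(significant_sets[0].tolist())
    for s in significant_sets[1:]:
        common &= set(s.tolist())
    idx = np.array(sorted(common), dtype=int)
    out: list[SelectionRegion] = []
    for chrom in mm.chromosomes():
        on_c = idx[mm.chromosome[idx] == chrom] if idx.size else idx
        if on_c.size == 0:
            continue
        pos = mm.position_bp[on_c]
        cluster: list[int] = []
        for j, bp in zip(on_c, pos):
            if cluster and (bp - mm.position_bp[cluster[0]]) > max_span_bp:
                _emit(out, int(chrom), cluster, mm, min_snps)
                cluster = []
            cluster.append(int(j))
        _emit(out, int(chrom), cluster, mm, min_snps)
    return out


def _emit(
    out: list[SelectionRegion], chrom: int, cluster: list[int], mm: MarkerMap, min_snps: int
) -> None:
    if len(cluster) >= min_snps:
        out.append(
            SelectionRegion(
                chromosome=chrom,
                start_bp=int(mm.position_bp[cluster[0]]),
                end_bp=int(mm.position_bp[cluster[-1]]),
                n_snps=len(cluster),
                source="xpehh_common",
            )
        )


def overlap_regions(
    di_regions: list[SelectionRegion], xpehh_regions: list[SelectionRegion]
) -> list[SelectionRegion]:
    """Interval intersections of the two scans' candidate regions."""
    out = []
    for a in di_regions:
        for b in xpehh_regions:
            if a.chromosome != b.chromosome:
                continue
            lo = max(a.start_bp, b.start_bp)
            hi = min(a.end_bp, b.end_bp)
            if lo <= hi:
                out.append(
                    SelectionRegion(
                        chromosome=a.chromosome,
                        start_bp=lo,
                        end_bp=hi,
                        n_snps=min(a.n_snps, b.n_snps),
                        source="overlap",
                    )
                )
    return out
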