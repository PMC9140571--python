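"""Per-SNP Weir–Cockerham FST, the d_i divergence statistic, window scan.

d_i standardizes the focal population's pairwise per-SNP FST against
each other population by the genome-wide pair mean and SD and sums over
pairs:

    d_i = sum_{j != i} (FST_ij - E[FST_ij]) / sd(FST_ij)

Per-SNP FST is the Weir & Cockerham (1984) two-population variance
component estimator theta = a / (a + b + c); negative estimates are
retained. d_i values are averaged over non-overlapping 1-Mb windows
anchored at position 1; windows with at least 5 SNPs are "informative"
and the top 1% (count by ceiling) are called as putative selection
regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)


@dataclass
class FstScanResult:
    focal: str
    others: list[str]
    snp_id: np.ndarray
    fst: dict[str, np.ndarray]  # other-pop label -> per-SNP FST (NaN undefined)
    pair_mean: dict[str, float]
    pair_sd: dict[str, float]
    d_i: np.ndarray  # per-SNP, NaN where undefined in any pair
    map: MarkerMap


@dataclass
class WindowScore:
    chromosome: int
    start_bp: int  # 1-based inclusive
    end_bp: int
    n_snps: int
    mean_d_i: float


@dataclass
class SelectionRegion:
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    source: str  # di | xpehh_pairwise | xpehh_common | overlap
    score: float = float("nan")


def wc_fst_per_snp(
    gm: GenotypeMatrix, pop_i: str, pop_j: str, estimator: str = "wc"
) -> np.ndarray:
    """Per-SNP two-population FST (NaN where undefined).

    ``estimator`` is "wc" (Weir–Cockerham 1984 theta, default) or
    "hudson" for sensitivity analysis. SNPs monomorphic across both
    populations, or with < 2 observed samples in either, are NaN.
    """
    stats_i = _pop_snp_stats(gm, pop_i)
    stats_j = _pop_snp_stats(gm, pop_j)
    if estimator == "wc":
        return _wc_theta(*stats_i, *stats_j)
    if estimator == "hudson":
        return _hudson_fst(*stats_i, *stats_j)
    raise ValueError(f"unknown estimator {estimator!r}")


def _pop_snp_stats(gm: GenotypeMatrix, pop: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n observed samples, allele_b freq, observed het fraction) per SNP."""
    sub = gm.calls[gm.pop_index(pop)]
    obs = sub != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, sub, 0).sum(axis=0) / (2.0 * n)
        h = ((sub == 1) & obs).sum(axis=0) / n
    return n, p, h


def _wc_theta(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> np.ndarray:
    r = 2.0
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(ok & (denom != 0), a / denom, np.nan)
    # monomorphic across both populations: undefined
    mono = (pbar <= 0.0) | (pbar >= 1.0)
    return np.where(mono, np.nan, theta)


def _hudson_fst(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> np.ndarray:
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = np.where(ok & (den > 0), num / den, np.nan)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    mono = (pbar <= 0.0) | (pbar >= 1.0)
    return np.where(mono, np.nan, fst)


def fst_scan(
    gm: GenotypeMatrix, focal: str, estimator: str = "wc", pooled: bool = False
) -> FstScanResult:
    """Pairwise FST of the focal population and the per-SNP d_i statistic.

    With ``pooled`` True all non-focal populations are merged into one
    comparison group (two-population mode); the default sums the
    standardized FST over the separate pairs.
    """
    others = [p for p in gm.population_labels if p != focal]
    if not others:
        raise ValueError("d_i needs at least one non-focal population")
    if pooled:
        pooled_gm = GenotypeMatrix(
            list(gm.samples),
            np.where(gm.populations == focal, focal, "OTHER"),
            gm.calls,
            gm.map,
        )
        others = ["OTHER"]
        gm = pooled_gm
    fst = {o: wc_fst_per_snp(gm, focal, o, estimator) for o in others}
    return di_statistic(gm.map, focal, fst)


def di_statistic(
    mm: MarkerMap, focal: str, fst: dict[str, np.ndarray]
) -> FstScanResult:
    """Standardize each pair's FST genome-wide and sum over pairs.

    A SNP undefined (NaN) in any pair gets d_i = NaN and is excluded
    from every pair's mean/SD. Pairs with zero SD are excluded with a
    warning.
    """
    others = list(fst)
    defined = np.ones(mm.n_snps, dtype=bool)
    for o in others:
        defined &= np.isfinite(fst[o])
    n_excl = int((~defined).sum())
    if n_excl:
        logger.info("d_i: %d SNPs undefined in >= 1 pair excluded", n_excl)
    pair_mean, pair_sd = {}, {}
    d = np.full(mm.n_snps, np.nan)
    acc = np.zeros(int(defined.sum()))
    used_pairs = 0
    for o in others:
        vals = fst[o][defined]
        mu = float(vals.mean())
        sd = float(vals.std(ddof=0))
        pair_mean[o], pair_sd[o] = mu, sd
        if sd == 0.0:
            logger.warning("pair %s has zero FST SD; excluded from d_i", o)
            continue
        acc += (vals - mu) / sd
        used_pairs += 1
    if used_pairs == 0:
        raise ValueError("no population pair with positive FST SD")
    d[defined] = acc
    return FstScanResult(
        focal=focal,
        others=others,
        snp_id=mm.snp_id,
        fst=fst,
        pair_mean=pair_mean,
        pair_sd=pair_sd,
        d_i=d,
        map=mm,
    )


def window_scores(
    d_i: np.ndarray, mm: MarkerMap, window_bp: int = 1_000_000, min_snps: int = 5
) -> list[WindowScore]:
    """Mean d_i over a fixed non-overlapping window grid per chromosome.

    The grid is anchored at position 1 ([1, window_bp], [window_bp + 1,
    2*window_bp], ...). Windows with fewer than ``min_snps`` scored SNPs
    are dropped from the informative set.
    """
    out = []
    for chrom in mm.chromosomes():
        cidx = mm.chrom_index(chrom)
        pos = mm.position_bp[cidx]
        vals = d_i[cidx]
        ok = np.isfinite(vals)
        if not ok.any():
            continue
        win = (pos - 1) // window_bp
        for w in np.unique(win[ok]):
            sel = ok & (win == w)
            n = int(sel.sum())
            if n < min_snps:
                continue
            out.append(
                WindowScore(
                    chromosome=int(chrom),
                    start_bp=int(w * window_bp + 1),
                    end_bp=int((w + 1) * window_bp),
                    n_snps=n,
                    mean_d_i=float(vals[sel].mean()),
                )
            )
    return out


def top_windows(windows: list[WindowScore], top_fraction: float = 0.01) -> list[SelectionRegion]:
    """Call the top-fraction windows (ceiling count) as selection regions.

    Ties at the cut are all included (logged).
    """
    if not windows:
        raise ValueError("no informative windows")
    k = math.ceil(top_fraction * len(windows))
    ranked = sorted(windows, key=lambda w: -w.mean_d_i)
    cut = ranked[k - 1].mean_d_i
    chosen = [w for w in ranked if w.mean_d_i >= cut]
    if len(chosen) > k:
        logger.warning("top_windows: %d extra tied windows included at the cut", len(chosen) - k)
    return [
        SelectionRegion(w.chromosome, w.start_bp, w.end_bp, w.n_snps, "di", w.mean_d_i)
        for w in chosen
    ]
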