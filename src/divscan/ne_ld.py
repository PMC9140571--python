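"""Effective population size from the decay of LD with genetic distance.

The estimator follows the Sved relationship E[r^2] = 1/(alpha + 4 N c)
with c the genetic distance in Morgans between a SNP pair: pairs are
binned on distance, the bin-mean r^2 is corrected for finite sample
size (subtracting 1/(2n) for unphased genotype r^2, 1/n for phased
haplotypes), and each bin c yields an estimate of the population size
roughly t = 1/(2c) generations ago:

    Ne(t) = (1 / (4 c)) * (1 / E[r^2'] - alpha)

alpha = 2 when mutation is ignored, 2.2 when the mutation-drift
correction is applied, 1 for the original phased formulation. The bp to
Morgan map is linear at ``rec_rate_cm_per_mb`` (default 1 cM/Mb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix
from .qc import pairwise_r2_matrix

logger = logging.getLogger(__name__)


def _default_bins() -> np.ndarray:
    return np.geomspace(50_000, 4_000_000, 21)


@dataclass
class NeParams:
    rec_rate_cm_per_mb: float = 1.0
    mutation_alpha: float = 2.2  # presets: 1, 2, 2.2
    sample_n: int | None = None  # diploid count; inferred when None
    distance_bins_bp: np.ndarray = field(default_factory=_default_bins)
    phased: bool = False

    def __post_init__(self) -> None:
        self.distance_bins_bp = np.asarray(self.distance_bins_bp, dtype=float)
        if np.any(np.diff(self.distance_bins_bp) <= 0):
            raise ValueError("distance bins must be strictly increasing")
        if self.mutation_alpha not in (1.0, 2.0, 2.2):
            raise ValueError("mutation_alpha presets are 1, 2 and 2.2")


@dataclass
class NeBin:
    c_morgans: float  # bin midpoint genetic distance
    t_generations: float  # ~ 1/(2c)
    mean_r2_adj: float
    n_pairs: int
    ne: float  # NaN when non-estimable
    estimable: bool


@dataclass
class NeTrajectory:
    population: str
    bins: list[NeBin]

    def spans(self, t: float) -> bool:
        ts = [b.t_generations for b in self.bins]
        return min(ts) <= t <= max(ts)


def binned_r2(gm: GenotypeMatrix, population: str, p: NeParams | None = None) -> list[NeBin]:
    """Bin-mean sample-size-adjusted r^2 over intra-chromosomal SNP pairs.

    Pair distance in Morgans is bp * rate; bins are taken on bp and
    converted. The adjustment subtracts 1/(2n) (unphased) or 1/n
    (phased) from each bin mean. Empty bins are flagged (estimable
    False) and excluded downstream.
    """
    p = p or NeParams()
    idx = gm.pop_index(population)
    if idx.size < 10:
        logger.warning("population %s has %d samples (< 10): Ne will be noisy", population, idx.size)
    sub = gm.calls[idx]
    n = p.sample_n or idx.size
    adj = 1.0 / n if p.phased else 1.0 / (2.0 * n)
    edges = p.distance_bins_bp
    nbins = edges.size - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    rate_m_per_bp = p.rec_rate_cm_per_mb / 1e8  # cM/Mb -> Morgans/bp
    for chrom in gm.map.chromosomes():
        cidx = gm.map.chrom_index(chrom)
        pos = gm.map.position_bp[cidx]
        r2m = pairwise_r2_matrix(sub[:, cidx])
        okm = np.isfinite(r2m)
        m = cidx.size
        for a in range(m):
            dist = pos[a + 1 :] - pos[a]
            lo = np.searchsorted(dist, edges[0], side="left")
            hi = np.searchsorted(dist, edges[-1], side="right")
            for boff in range(lo, hi):
                b = a + 1 + boff
                if not okm[a, b]:
                    continue
                k = int(np.searchsorted(edges, dist[boff], side="right")) - 1
                if 0 <= k < nbins:
                    sums[k] += r2m[a, b]
                    counts[k] += 1
    bins = []
    for k in range(nbins):
        mid_bp = np.sqrt(edges[k] * edges[k + 1])  # geometric midpoint
        c = mid_bp * rate_m_per_bp
        t = 1.0 / (2.0 * c)
        if counts[k] == 0:
            bins.append(NeBin(c, t, np.nan, 0, np.nan, False))
            continue
        mean_adj = sums[k] / counts[k] - adj
        bins.append(NeBin(c, t, mean_adj, int(counts[k]), np.nan, True))
    return bins


def estimate_ne(bins: list[NeBin], p: NeParams | None = None) -> list[NeBin]:
    """Invert the Sved relation per bin: Ne = (1/(4c)) (1/E[r^2'] - alpha).

    Bins with non-positive adjusted r^2 or negative Ne are flagged
    non-estimable.
    """
    p = p or NeParams()
    if not any(b.estimable for b in bins):
        raise ValueError("no non-empty distance bin to estimate from")
    out = []
    for b in bins:
        if not b.estimable or b.mean_r2_adj <= 0:
            out.append(NeBin(b.c_morgans, b.t_generations, b.mean_r2_adj, b.n_pairs, np.nan, False))
            continue
        ne = (1.0 / (4.0 * b.c_morgans)) * (1.0 / b.mean_r2_adj - p.mutation_alpha)
        est = ne >= 0
        out.append(
            NeBin(b.c_morgans, b.t_generations, b.mean_r2_adj, b.n_pairs, ne if est else np.nan, est)
        )
    return out


def ne_trajectory(
    gm: GenotypeMatrix, population: str, p: NeParams | None = None
) -> NeTrajectory:
    p = p or NeParams()
    return NeTrajectory(population, estimate_ne(binned_r2(gm, population, p), p))


def ne_at_generations(
    traj: NeTrajectory, targets: tuple[float, ...] = (5.0, 50.0)
) -> dict[float, tuple[float, bool]]:
    """Ne at each target generation count, from the nearest-t estimable bin.

    Returns {target: (Ne, extrapolated)}; ``extrapolated`` is True when
    the target lies outside the trajectory's t span (the nearest bin is
    still reported).
    """
    usable = [b for b in traj.bins if b.estimable and np.isfinite(b.ne)]
    if not usable:
        raise ValueError("trajectory has no estimable bins")
    out = {}
    for t in targets:
        best = min(usable, key=lambda b: abs(b.t_generations - t))
        extrapolated = not traj.spans(t)
        if extrapolated:
            logger.warning("target t=%g outside trajectory span; nearest bin t=%.3g used", t, best.t_generations)
        out[t] = (best.ne, extrapolated)
    return out
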