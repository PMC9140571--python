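"""Population structure: pairwise IBS distances and classical MDS.

The distance is 1 - IBS with IBS the mean shared-allele fraction per
jointly non-missing SNP (1, 0.5 or 0 per SNP). Embedding is classical
(Torgerson) multidimensional scaling on the double-centered squared
distance matrix; axis signs are canonicalized so the largest-magnitude
loading on each axis is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    samples: list[str]
    populations: np.ndarray
    ibs: np.ndarray  # mean IBS sharing in [0, 1]
    distance: np.ndarray  # 1 - ibs
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class MdsResult:
    samples: list[str]
    populations: np.ndarray
    coordinates: np.ndarray  # samples x k
    variance_explained: np.ndarray  # percentage per axis
    eigenvalues: np.ndarray  # all eigenvalues, descending


def ibs_matrix(gm: GenotypeMatrix, ld_pruned: bool = True) -> DistanceMatrix:
    """Pairwise IBS sharing and 1-IBS distances over jointly observed SNPs."""
    if not ld_pruned:
        logger.info("ibs_matrix on non-LD-pruned input; distances may be locally weighted")
    calls = gm.calls.astype(np.int16)
    n = gm.n_samples
    ibs = np.ones((n, n))
    flagged: list[tuple[str, str]] = []
    obs = calls != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = int(both.sum())
            if m == 0:
                flagged.append((gm.samples[i], gm.samples[j]))
                ibs[i, j] = ibs[j, i] = np.nan
                continue
            shared = 2.0 - np.abs(calls[i, both] - calls[j, both])
            ibs[i, j] = ibs[j, i] = shared.mean() / 2.0
    if flagged:
        logger.warning("%d sample pairs share no observed SNPs", len(flagged))
    return DistanceMatrix(list(gm.samples), gm.populations, ibs, 1.0 - ibs, flagged)


def mds(d: DistanceMatrix, k: int = 2) -> MdsResult:
    """Classical MDS of the distance matrix onto ``k`` axes.

    Negative eigenvalues (non-Euclidean distances) are reported but
    excluded from the variance-explained denominator.
    """
    n = len(d.samples)
    if k >= n:
        raise ValueError("k must be smaller than the sample count")
    dist = np.nan_to_num(d.distance, nan=0.0)
    d2 = dist**2
    j_c = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_c @ d2 @ j_c
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals[evals > 0].sum()
    coords = np.zeros((n, k))
    var = np.zeros(k)
    for a in range(k):
        lam = evals[a]
        if lam > 0:
            coords[:, a] = evecs[:, a] * np.sqrt(lam)
            var[a] = 100.0 * lam / pos if pos > 0 else 0.0
        # canonical sign: largest-magnitude loading positive
        imax = int(np.argmax(np.abs(coords[:, a])))
        if coords[imax, a] < 0:
            coords[:, a] = -coords[:, a]
    return MdsResult(list(d.samples), d.populations, coords, var, evals)
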