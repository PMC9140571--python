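"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle restates the operation's contract in the most literal way
possible (exhaustive enumeration, direct per-element recounting) and is
kept free of any code from the package's own implementation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# relatedness pruning: exhaustive minimal removal set
# ---------------------------------------------------------------------------


def minimal_removal_size(ibd: np.ndarray, ibd_max: float) -> int:
    """Size of the smallest sample subset whose removal clears all
    over-threshold pairs (exhaustive search, feasible for n <= 6)."""
    n = ibd.shape[0]
    over = [(i, j) for i in range(n) for j in range(i + 1, n) if ibd[i, j] > ibd_max]
    if not over:
        return 0
    for k in range(1, n + 1):
        for drop in itertools.combinations(range(n), k):
            ds = set(drop)
            if all(i in ds or j in ds for i, j in over):
                return k
    return n


# ---------------------------------------------------------------------------
# LD pruning: literal fixpoint with the same removal rule
# ---------------------------------------------------------------------------


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    both = (x != MISSING) & (y != MISSING)
    x, y = x[both].astype(float), y[both].astype(float)
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def ld_prune_fixpoint(calls: np.ndarray, maf: np.ndarray, window: int, step: int, r2_max: float):
    """Reference sliding-window prune on a single chromosome.

    Windows advance by ``step``; within a window the first over-threshold
    retained pair (map order) loses its lower-MAF member (tie: the later
    SNP), iterated to a fixpoint.
    """
    m = calls.shape[1]
    keep = np.ones(m, dtype=bool)
    start = 0
    while True:
        idx = [j for j in range(start, min(start + window, m))]
        changed = True
        while changed:
            changed = False
            live = [j for j in idx if keep[j]]
            for a in range(len(live)):
                for b in range(a + 1, len(live)):
                    r2 = _pair_r2(calls[:, live[a]], calls[:, live[b]])
                    if not math.isnan(r2) and r2 > r2_max:
                        sa, sb = live[a], live[b]
                        if maf[sa] < maf[sb]:
                            keep[sa] = False
                        elif maf[sb] < maf[sa]:
                            keep[sb] = False
                        else:
                            keep[max(sa, sb)] = False
                        changed = True
                        break
                if changed:
                    break
        if start + window >= m:
            break
        start += step
    return keep


# ---------------------------------------------------------------------------
# ROH: direct per-SNP recount scan
# ---------------------------------------------------------------------------


def roh_direct_scan(
    calls: np.ndarray,
    pos: np.ndarray,
    window: int,
    het_allowed: int,
    missing_allowed: int,
    hit_threshold: float,
    max_gap: int,
    min_density: float,
    min_length: int,
    min_snps: int,
) -> list[tuple[int, int, int]]:
    """All (start_bp, end_bp, n_snps) runs for one sample/chromosome,
    recomputed SNP by SNP without convolutions or cumulative sums."""
    m = calls.size
    w = min(window, m)
    passing = []
    for s in range(m - w + 1):
        seg = calls[s : s + w]
        passing.append(
            int((seg == 1).sum()) <= het_allowed and int((seg == MISSING).sum()) <= missing_allowed
        )
    flagged = []
    for j in range(m):
        covering = [s for s in range(len(passing)) if s <= j <= s + w - 1]
        rate = sum(passing[s] for s in covering) / len(covering)
        flagged.append(rate >= hit_threshold)
    # maximal flagged stretches
    stretches = []
    j = 0
    while j < m:
        if flagged[j]:
            s = j
            while j + 1 < m and flagged[j + 1]:
                j += 1
            stretches.append((s, j))
        j += 1
    # het allowance per run, left to right
    pieces = []
    for s, e in stretches:
        start, hets = s, 0
        for j in range(s, e + 1):
            if calls[j] == 1:
                hets += 1
                if hets > het_allowed:
                    if j > start:
                        pieces.append((start, j - 1))
                    start, hets = j + 1, 0
        if start <= e:
            pieces.append((start, e))
    # gap splitting
    final = []
    for s, e in pieces:
        start = s
        for j in range(s, e):
            if pos[j + 1] - pos[j] > max_gap:
                final.append((start, j))
                start = j + 1
        final.append((start, e))
    out = []
    for s, e in final:
        n = e - s + 1
        length = int(pos[e] - pos[s] + 1)
        if length >= min_length and n >= min_snps and length / n <= min_density:
            out.append((int(pos[s]), int(pos[e]), n))
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham two-population theta, scalar transliteration
# ---------------------------------------------------------------------------


def wc_theta_scalar(n1: float, p1: float, h1: float, n2: float, p2: float, h2: float) -> float:
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
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
    return a / (a + b + c)


def di_one_pass(fst_by_pair: dict[str, np.ndarray]) -> np.ndarray:
    """Literal per-SNP loop over the standardized-FST sum."""
    pairs = list(fst_by_pair)
    m = len(fst_by_pair[pairs[0]])
    defined = [all(np.isfinite(fst_by_pair[p][j]) for p in pairs) for j in range(m)]
    stats = {}
    for p in pairs:
        vals = [fst_by_pair[p][j] for j in range(m) if defined[j]]
        stats[p] = (float(np.mean(vals)), float(np.std(vals)))
    out = np.full(m, np.nan)
    for j in range(m):
        if not defined[j]:
            continue
        total = 0.0
        for p in pairs:
            mu, sd = stats[p]
            total += (fst_by_pair[p][j] - mu) / sd
        out[j] = total
    return out


# ---------------------------------------------------------------------------
# rarefaction: exhaustive enumeration of subsamples
# ---------------------------------------------------------------------------


def rarefied_alleles_enumerated(counts: list[int], g: int) -> float:
    """Expected distinct alleles in a g-copy draw, by enumerating every
    subset of the N gene copies."""
    pool = [a for a, c in enumerate(counts) for _ in range(c)]
    total = 0.0
    n_draws = 0
    for draw in itertools.combinations(range(len(pool)), g):
        total += len({pool[i] for i in draw})
        n_draws += 1
    return total / n_draws


def private_richness_enumerated(counts_by_pop: list[list[int]], g: int, focal: int) -> float:
    """Expected number of alleles private to ``focal`` across independent
    g-copy draws from every population (full enumeration)."""
    pools = [[a for a, c in enumerate(counts) for _ in range(c)] for counts in counts_by_pop]
    draws = [list(itertools.combinations(range(len(p)), g)) for p in pools]
    total = 0.0
    n_outcomes = 0
    for combo in itertools.product(*draws):
        present = [set(pools[k][i] for i in combo[k]) for k in range(len(pools))]
        others = set().union(*(present[k] for k in range(len(pools)) if k != focal))
        total += len(present[focal] - others)
        n_outcomes += 1
    return total / n_outcomes


# ---------------------------------------------------------------------------
# SNP clustering into bounded-span regions
# ---------------------------------------------------------------------------


def cluster_bounded(positions: list[int], min_snps: int, max_span: int) -> list[tuple[int, int, int]]:
    """Greedy left-to-right chaining closing a cluster when its span
    would exceed ``max_span``; returns (start, end, size) per cluster."""
    out = []
    cluster: list[int] = []
    for p in sorted(positions):
        if cluster and p - cluster[0] > max_span:
            if len(cluster) >= min_snps:
                out.append((cluster[0], cluster[-1], len(cluster)))
            cluster = []
        cluster.append(p)
    if len(cluster) >= min_snps:
        out.append((cluster[0], cluster[-1], len(cluster)))
    return out
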