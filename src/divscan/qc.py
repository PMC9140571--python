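"""Cohort quality control: SNP/sample filters, relatedness pruning, LD pruning.

The fixed filter order used by the pipeline is: sample missingness ->
SNP call rate -> MAF -> relatedness -> LD. Each step logs counts in/out
and returns a removal report alongside the filtered matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

R2_UNDEFINED = np.nan


@dataclass
class QcParams:
    """Thresholds for the marker/sample/relatedness filters.

    Defaults follow common SNP-chip practice for diversity studies:
    minor-allele frequency >= 5%, SNP call rate >= 95%, sample
    missingness <= 5%, and removal of one member of any pair with IBD
    proportion above 0.35.
    """

    maf_min: float = 0.05
    snp_call_rate_min: float = 0.95
    sample_missing_max: float = 0.05
    ibd_max: float = 0.35

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_call_rate_min", "sample_missing_max", "ibd_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class LdPruneParams:
    """Sliding-window pairwise LD pruning parameters (r^2 > 0.5, 50/5)."""

    r2_max: float = 0.5
    window_snps: int = 50
    step_snps: int = 5

    def __post_init__(self) -> None:
        if not (self.window_snps > self.step_snps >= 1):
            raise ValueError("need window_snps > step_snps >= 1")
        if not 0.0 < self.r2_max <= 1.0:
            raise ValueError("r2_max must be in (0, 1]")


@dataclass
class RemovalReport:
    """What a filter removed and why."""

    stage: str
    n_before: int
    n_after: int
    removed: list[str] = field(default_factory=list)
    by_criterion: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class KinshipMatrix:
    """Pairwise KING-robust kinship and the derived IBD proportions."""

    samples: list[str]
    kinship: np.ndarray  # symmetric, KING-robust phi-hat between pairs
    ibd: np.ndarray  # 2*phi clipped to [0, 1]
    estimator: str = "king-robust"
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)


def filter_snps(gm: GenotypeMatrix, p: QcParams) -> tuple[GenotypeMatrix, RemovalReport]:
    """Drop SNPs failing call rate then MAF (both computed on non-missing calls)."""
    n_obs = (~gm.missing_mask()).sum(axis=0)
    call_rate = n_obs / gm.n_samples if gm.n_samples else np.zeros(gm.n_snps)
    fail_cr = call_rate < p.snp_call_rate_min
    maf = gm.maf()
    fail_maf = ~fail_cr & (np.isnan(maf) | (maf < p.maf_min))
    keep = ~(fail_cr | fail_maf)
    report = RemovalReport(
        stage="snp_filter",
        n_before=gm.n_snps,
        n_after=int(keep.sum()),
        removed=list(gm.map.snp_id[~keep]),
        by_criterion={"call_rate": int(fail_cr.sum()), "maf": int(fail_maf.sum())},
    )
    if report.n_after == 0:
        report.warnings.append("all SNPs removed by QC filters")
        logger.warning("filter_snps removed every SNP")
    return gm.subset_snps(np.flatnonzero(keep)), report


def filter_samples(gm: GenotypeMatrix, p: QcParams) -> tuple[GenotypeMatrix, RemovalReport]:
    """Drop samples whose missing-call fraction exceeds the threshold."""
    miss_frac = gm.missing_mask().mean(axis=1) if gm.n_snps else np.zeros(gm.n_samples)
    keep = miss_frac <= p.sample_missing_max
    report = RemovalReport(
        stage="sample_filter",
        n_before=gm.n_samples,
        n_after=int(keep.sum()),
        removed=[s for s, k in zip(gm.samples, keep) if not k],
        by_criterion={"missingness": int((~keep).sum())},
    )
    if report.n_after == 0:
        report.warnings.append("all samples removed by missingness filter")
        logger.warning("filter_samples removed every sample")
    return gm.subset_samples(np.flatnonzero(keep)), report


def kinship_matrix(gm: GenotypeMatrix) -> KinshipMatrix:
    """KING-robust between-family kinship for every sample pair.

    phi-hat = (N_het,het - 2 N_opp-hom) / (N_het(i) + N_het(j)) over
    loci non-missing in both samples; IBD proportion = 2*phi clipped to
    [0, 1]. Pairs with no jointly observed loci (or no hets at all) are
    flagged and treated as unrelated.
    """
    if gm.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    calls = gm.calls
    n = gm.n_samples
    phi = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        gi = calls[i]
        for j in range(i + 1, n):
            gj = calls[j]
            both = (gi != MISSING) & (gj != MISSING)
            if not both.any():
                undefined.append((gm.samples[i], gm.samples[j]))
                continue
            a, b = gi[both], gj[both]
            het_i = int((a == 1).sum())
            het_j = int((b == 1).sum())
            het_het = int(((a == 1) & (b == 1)).sum())
            opp_hom = int((np.abs(a - b) == 2).sum())
            denom = het_i + het_j
            if denom == 0:
                if opp_hom == 0:
                    phi_ij = 0.0  # 0/0 convention: no information, unrelated
                else:
                    phi_ij = -1.0
            else:
                phi_ij = (het_het - 2.0 * opp_hom) / denom
            phi[i, j] = phi[j, i] = phi_ij
    np.fill_diagonal(phi, 0.5)
    ibd = np.clip(2.0 * phi, 0.0, 1.0)
    if undefined:
        logger.warning("%d sample pairs had no jointly observed loci", len(undefined))
    return KinshipMatrix(list(gm.samples), phi, ibd, undefined_pairs=undefined)


def prune_related(
    gm: GenotypeMatrix, k: KinshipMatrix, ibd_max: float = 0.35
) -> tuple[GenotypeMatrix, RemovalReport]:
    """Greedily drop samples until no pair's IBD proportion exceeds ``ibd_max``.

    At each step the sample in the most over-threshold pairs is removed;
    ties break toward higher missingness, then later sample order.
    """
    if k.samples != gm.samples:
        raise ValueError("kinship matrix was not computed on this cohort")
    n = gm.n_samples
    over = k.ibd > ibd_max
    np.fill_diagonal(over, False)
    miss_frac = gm.missing_mask().mean(axis=1) if gm.n_snps else np.zeros(n)
    active = np.ones(n, dtype=bool)
    removed_idx: list[int] = []
    while True:
        counts = (over & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        if counts.max(initial=0) == 0:
            break
        cmax = counts.max()
        cand = np.flatnonzero(counts == cmax)
        cand = cand[miss_frac[cand] == miss_frac[cand].max()]
        drop = int(cand.max())  # later sample order last tie-break
        active[drop] = False
        removed_idx.append(drop)
    report = RemovalReport(
        stage="relatedness",
        n_before=n,
        n_after=int(active.sum()),
        removed=[gm.samples[i] for i in removed_idx],
        by_criterion={"ibd": len(removed_idx)},
    )
    return gm.subset_samples(np.flatnonzero(active)), report


def r_squared(snp_i: np.ndarray, snp_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over jointly non-missing samples; returns NaN when either
    SNP is monomorphic in that subset or fewer than 2 samples remain.
    """
    x = np.asarray(snp_i, dtype=float)
    y = np.asarray(snp_j, dtype=float)
    both = (np.asarray(snp_i) != MISSING) & (np.asarray(snp_j) != MISSING)
    x, y = x[both], y[both]
    if x.size < 2:
        return R2_UNDEFINED
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return R2_UNDEFINED
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def pairwise_r2_matrix(calls: np.ndarray) -> np.ndarray:
    """All-pairs r^2 of dosage columns (samples x SNPs), NaN where undefined.

    Complete columns share one vectorized correlation; pairs involving
    missing data fall back to the per-pair estimator.
    """
    n, m = calls.shape
    out = np.full((m, m), np.nan)
    miss = calls == MISSING
    complete = ~miss.any(axis=0)
    full = np.flatnonzero(complete)
    if full.size >= 2:
        x = calls[:, full].astype(float)
        sd = x.std(axis=0)
        poly = np.flatnonzero(sd > 0)
        if poly.size >= 2:
            xs = x[:, poly]
            xc = (xs - xs.mean(axis=0)) / xs.std(axis=0)
            corr = (xc.T @ xc) / n
            sub = full[poly]
            out[np.ix_(sub, sub)] = corr**2
    partial = np.flatnonzero(~complete)
    for a in partial:
        for b in range(m):
            if b == a:
                continue
            out[a, b] = out[b, a] = r_squared(calls[:, a], calls[:, b])
    np.fill_diagonal(out, np.nan)
    return out


def ld_prune(gm: GenotypeMatrix, p: LdPruneParams) -> tuple[GenotypeMatrix, RemovalReport]:
    """Sliding-window pairwise LD pruning (``--indep-pairwise`` analog).

    Within each window of ``window_snps`` consecutive SNPs (advanced by
    ``step_snps`` per chromosome), while any retained pair has
    r^2 > r2_max, the member with the lower MAF is removed (tie: the
    later SNP in map order), iterated to a fixpoint. Undefined r^2
    (monomorphic after subsetting) never triggers removal.
    """
    maf = gm.maf()
    keep = np.ones(gm.n_snps, dtype=bool)
    for chrom in gm.map.chromosomes():
        cidx = gm.map.chrom_index(chrom)
        m = cidx.size
        start = 0
        while True:
            widx = cidx[start : start + p.window_snps]
            _prune_window(gm.calls, widx, maf, p.r2_max, keep)
            if start + p.window_snps >= m:
                break
            start += p.step_snps
    report = RemovalReport(
        stage="ld_prune",
        n_before=gm.n_snps,
        n_after=int(keep.sum()),
        removed=list(gm.map.snp_id[~keep]),
        by_criterion={"ld": int((~keep).sum())},
    )
    return gm.subset_snps(np.flatnonzero(keep)), report


def _prune_window(
    calls: np.ndarray, widx: np.ndarray, maf: np.ndarray, r2_max: float, keep: np.ndarray
) -> None:
    live_mask = keep[widx]
    if live_mask.sum() < 2:
        return
    r2 = pairwise_r2_matrix(calls[:, widx])
    while True:
        live = np.flatnonzero(live_mask)
        if live.size < 2:
            return
        sub = r2[np.ix_(live, live)]
        with np.errstate(invalid="ignore"):
            over = np.argwhere(np.triu(sub > r2_max, k=1))
        if over.size == 0:
            return
        a, b = over[0]  # first offending pair in map order
        sa, sb = widx[live[a]], widx[live[b]]
        if maf[sa] < maf[sb]:
            drop = sa
        elif maf[sb] < maf[sa]:
            drop = sb
        else:
            drop = max(sa, sb)  # tie -> later map order
        keep[drop] = False
        live_mask = keep[widx]


def run_qc(
    gm: GenotypeMatrix, p: QcParams | None = None
) -> tuple[GenotypeMatrix, list[RemovalReport]]:
    """Full QC pass in the pipeline's fixed order (no LD pruning)."""
    p = p or QcParams()
    reports = []
    gm, rep = filter_samples(gm, p)
    reports.append(rep)
    gm, rep = filter_snps(gm, p)
    reports.append(rep)
    if gm.n_samples >= 2:
        k = kinship_matrix(gm)
        gm, rep = prune_related(gm, k, p.ibd_max)
        reports.append(rep)
    for r in reports:
        logger.info("%s: %d -> %d", r.stage, r.n_before, r.n_after)
    return gm, reports
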