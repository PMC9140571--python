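"""Per-population diversity: heterozygosity, F_IS, rarefied allelic richness.

Rarefaction follows the hypergeometric (draw g gene copies without
replacement) construction: the expected number of distinct alleles at a
locus is sum_i [1 - C(N - N_i, g)/C(N, g)] with N the non-missing gene
copies and N_i the copies of allele i. Private allelic richness treats
the per-population g-copy draws as independent, so the probability that
an allele is private to population j is its capture probability in j
times the product of non-capture probabilities elsewhere. Missing data
are handled locus-wise (per-locus N), not by case-wise deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiversitySummary:
    population: str
    n: int
    h_obs: float
    h_exp: float
    f_is: float
    allelic_richness: float
    private_allelic_richness: float
    g: int


def _ln_choose(n: np.ndarray, k: float) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(n >= k, out, -np.inf)


def _capture_prob(n_total: np.ndarray, n_allele: np.ndarray, g: int) -> np.ndarray:
    """P(allele with n_allele copies out of n_total appears in a g-copy draw)."""
    with np.errstate(invalid="ignore"):
        miss = np.exp(_ln_choose(n_total - n_allele, g) - _ln_choose(n_total, g))
    miss = np.where(n_total - n_allele < g, 0.0, miss)
    return 1.0 - miss


def _pop_counts(gm: GenotypeMatrix, population: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (non-missing gene copies, allele_b copies) for one population."""
    sub = gm.calls[gm.pop_index(population)]
    obs = sub != MISSING
    n_copies = 2 * obs.sum(axis=0)
    b_copies = np.where(obs, sub, 0).sum(axis=0)
    return n_copies, b_copies


def het_summary(gm: GenotypeMatrix, population: str) -> tuple[float, float]:
    """Observed and expected heterozygosity, averaged over SNPs.

    Per SNP: Ho = heterozygote fraction among non-missing calls;
    He = 2p(1-p) from the non-missing allele frequency (plug-in
    estimator; see :func:`expected_het` for the small-sample flag).
    SNPs with no non-missing calls in the population are excluded.
    """
    idx = gm.pop_index(population)
    if idx.size < 2:
        raise ValueError(f"population {population!r} needs >= 2 samples")
    sub = gm.calls[idx]
    obs = sub != MISSING
    n_obs = obs.sum(axis=0)
    ok = n_obs > 0
    het = ((sub == 1) & obs).sum(axis=0)
    ho = het[ok] / n_obs[ok]
    p = np.where(obs, sub, 0).sum(axis=0)[ok] / (2.0 * n_obs[ok])
    he = 2.0 * p * (1.0 - p)
    return float(ho.mean()), float(he.mean())


def expected_het(gm: GenotypeMatrix, population: str, unbiased: bool = False) -> float:
    """Mean expected heterozygosity; ``unbiased`` applies 2n/(2n-1)."""
    idx = gm.pop_index(population)
    sub = gm.calls[idx]
    obs = sub != MISSING
    n_obs = obs.sum(axis=0)
    ok = n_obs > 0
    p = np.where(obs, sub, 0).sum(axis=0)[ok] / (2.0 * n_obs[ok])
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        he = he * (2.0 * n_obs[ok]) / (2.0 * n_obs[ok] - 1.0)
    return float(he.mean())


def f_is(h_obs: float, h_exp: float) -> float:
    """Wright's inbreeding coefficient (He - Ho) / He.

    Negative values indicate heterozygote excess. Undefined when
    He = 0 (monomorphic population).
    """
    if h_exp <= 0.0:
        raise ValueError("F_IS undefined for H_E = 0")
    return (h_exp - h_obs) / h_exp


def default_g(gm: GenotypeMatrix) -> int:
    """Standardized rarefaction size: 2 x smallest population (gene copies)."""
    sizes = [int((gm.populations == p).sum()) for p in gm.population_labels]
    return 2 * min(sizes)


def allelic_richness(gm: GenotypeMatrix, population: str, g: int) -> float:
    """Rarefied allelic richness at standardized size ``g`` gene copies.

    Loci with fewer than ``g`` non-missing gene copies in the population
    are excluded (logged). For biallelic data the per-locus value lies
    in [1, 2].
    """
    if g < 2:
        raise ValueError("g must be >= 2")
    n_copies, b_copies = _pop_counts(gm, population)
    usable = n_copies >= g
    if not usable.any():
        raise ValueError(f"no locus has >= {g} gene copies in {population!r}")
    dropped = int((~usable).sum())
    if dropped:
        logger.info("allelic_richness: %d loci with < g=%d copies excluded", dropped, g)
    n_tot = n_copies[usable]
    n_b = b_copies[usable]
    n_a = n_tot - n_b
    # an absent allele (0 copies) has capture probability 0 by construction
    per_locus = _capture_prob(n_tot, n_a, g) + _capture_prob(n_tot, n_b, g)
    return float(per_locus.mean())


def private_allelic_richness(gm: GenotypeMatrix, g: int) -> dict[str, float]:
    """Rarefied private allelic richness per population at size ``g``.

    Per locus and allele the private contribution to population j is
    Q_jg * prod_{k != j} (1 - Q_kg), where Q is the hypergeometric
    capture probability; contributions are summed over the two alleles
    and averaged over loci usable (>= g copies) in every population.
    """
    pops = gm.population_labels
    if len(pops) < 2:
        raise ValueError("private allelic richness needs >= 2 populations")
    counts = {p: _pop_counts(gm, p) for p in pops}
    usable = np.ones(gm.n_snps, dtype=bool)
    for n_copies, _ in counts.values():
        usable &= n_copies >= g
    if not usable.any():
        raise ValueError(f"no locus has >= {g} gene copies in every population")
    q = {}  # capture probabilities per pop: (allele_a, allele_b) arrays
    for p, (n_copies, b_copies) in counts.items():
        n_tot = n_copies[usable]
        n_b = b_copies[usable]
        q[p] = (_capture_prob(n_tot, n_tot - n_b, g), _capture_prob(n_tot, n_b, g))
    out = {}
    for p in pops:
        contrib = np.zeros(int(usable.sum()))
        for a in (0, 1):
            others = np.ones_like(contrib)
            for o in pops:
                if o != p:
                    others *= 1.0 - q[o][a]
            contrib += q[p][a] * others
        out[p] = float(contrib.mean())
    return out


def diversity_table(
    gm: GenotypeMatrix, g: int | None = None, unbiased_he: bool = False
) -> list[DiversitySummary]:
    """Per-population diversity summaries (the Table-1 analog)."""
    g = g if g is not None else default_g(gm)
    par = private_allelic_richness(gm, g) if len(gm.population_labels) > 1 else {}
    rows = []
    for p in gm.population_labels:
        ho, he = het_summary(gm, p)
        if unbiased_he:
            he = expected_het(gm, p, unbiased=True)
        rows.append(
            DiversitySummary(
                population=p,
                n=int((gm.populations == p).sum()),
                h_obs=ho,
                h_exp=he,
                f_is=f_is(ho, he) if he > 0 else float("nan"),
                allelic_richness=allelic_richness(gm, p, g),
                private_allelic_richness=par.get(p, float("nan")),
                g=g,
            )
        )
    return rows
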