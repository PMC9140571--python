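"""Forward Wright–Fisher simulator for multi-population SNP cohorts.

The generator emulates a small-ruminant SNP-chip study: a handful of
related populations genotyped at a common autosomal marker panel, one
partially inbred focal population, and optional localized selective
sweeps. Discrete generations; haplotype
transmission with Poisson crossovers on a linear genetic map; additive
fitness 1 + s per sweep-allele copy; partial selfing inflates
inbreeding. The truth record carries the sweep trajectory and per-
population realized parameters so every analysis stage can be tested
against known ground truth.

All randomness flows from one integer seed through numpy's
``SeedSequence`` spawning; runs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import (
    GenotypeMatrix,
    HaplotypeSet,
    MarkerMap,
    write_haps,
    write_phased_vcf,
    write_plink_bed,
    write_plink_text,
)

logger = logging.getLogger(__name__)


@dataclass
class SweepSpec:
    population: str
    chromosome: int
    position_bp: int  # the swept SNP is the closest marker to this bp
    s: float = 1.0  # additive selection coefficient per allele copy
    start_generation: int = 0  # generations after the split
    init_copies: int = 1  # hard sweep: single-origin haplotype
    reinject: bool = True  # re-seed the allele if drift loses it early

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("selection coefficient must be in [0, 1]")


def _default_sizes() -> dict[str, int]:
    return {"BAL": 45, "BAR": 29, "IST": 23, "RUD": 16}


def _default_ne() -> dict[str, int]:
    return {"BAL": 300, "BAR": 300, "IST": 300, "RUD": 300}


def _default_selfing() -> dict[str, float]:
    return {"BAL": 0.03, "BAR": 0.0, "IST": 0.0, "RUD": 0.0}


@dataclass
class SimulationConfig:
    """Desk-scale emulation of a four-breed 50K-chip cohort.

    Pre-QC sample sizes mirror the field collection (45/29/23/16); the
    six 40-Mb chromosomes at ~1 SNP/50 kb approximate chip density. The
    3 cM/Mb map rate compresses sweep footprints so the scaled-down
    window scan resolves a sweep the way the full 26-autosome study
    does. The focal population carries partial selfing (its inbreeding
    signal); sweeps are hard (single-origin) by default."""

    sample_sizes: dict[str, int] = field(default_factory=_default_sizes)
    ne: dict[str, int] = field(default_factory=_default_ne)
    selfing: dict[str, float] = field(default_factory=_default_selfing)
    ancestral_ne: int = 200
    burnin_generations: int = 40
    split_generations: int = 20  # generations from split to sampling
    bottleneck: dict[str, tuple[int, int]] = field(default_factory=dict)
    # population -> (generation-before-present, Ne during/after)
    n_chromosomes: int = 6
    snps_per_chromosome: int = 800
    chromosome_bp: int = 40_000_000
    rec_rate_cm_per_mb: float = 3.0
    maf_min_init: float = 0.05
    sweeps: list[SweepSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.ne) != set(self.sample_sizes) or set(self.selfing) != set(self.sample_sizes):
            raise ValueError("sample_sizes, ne and selfing must share population labels")
        for pop, n in self.sample_sizes.items():
            if n < 2:
                raise ValueError(f"population {pop} needs >= 2 samples")
            if n > self.ne[pop]:
                raise ValueError(f"cannot sample {n} diploids from Ne={self.ne[pop]} ({pop})")
        if self.n_chromosomes < 1 or self.n_chromosomes > 26:
            raise ValueError("1-26 autosomes supported")


@dataclass
class SimulationTruth:
    config_seed: int
    sweep_outcomes: list[dict]
    final_sweep_freq: dict[str, float] = field(default_factory=dict)
    mean_pedigree_f: dict[str, float] = field(default_factory=dict)


def _make_map(cfg: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    chroms, bps, ids, aa, ab, cms = [], [], [], [], [], []
    for c in range(1, cfg.n_chromosomes + 1):
        pos = np.sort(
            rng.choice(
                np.arange(1, cfg.chromosome_bp + 1), size=cfg.snps_per_chromosome, replace=False
            )
        )
        for j, bp in enumerate(pos):
            chroms.append(c)
            bps.append(int(bp))
            ids.append(f"snp_{c}_{j}")
            pair = rng.choice(len(_ALLELE_PAIRS))
            aa.append(_ALLELE_PAIRS[pair][0])
            ab.append(_ALLELE_PAIRS[pair][1])
            cms.append(bp * cfg.rec_rate_cm_per_mb / 1e6)
    return MarkerMap(chroms, bps, ids, aa, ab, cms)


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


class _Population:
    """Haplotype pool of one population: array (2*N, n_snps) per chromosome."""

    def __init__(self, haps: list[np.ndarray], pedigree_f: np.ndarray):
        self.haps = haps  # per-chromosome arrays, rows 2i/2i+1 = individual i
        self.pedigree_f = pedigree_f  # per-individual pedigree inbreeding

    @property
    def n(self) -> int:
        return self.haps[0].shape[0] // 2


def _meiosis(
    parent: np.ndarray, ind: int, cm_pos: list[np.ndarray], rng: np.random.Generator
) -> list[np.ndarray]:
    """One gamete per chromosome from diploid ``ind`` of haplotype pool."""
    out = []
    for c, cm in enumerate(cm_pos):
        h0 = parent[c][2 * ind]
        h1 = parent[c][2 * ind + 1]
        length_m = (cm[-1] - cm[0]) / 100.0 if cm.size > 1 else 0.0
        n_x = rng.poisson(length_m)
        start = rng.integers(2)
        if n_x == 0:
            out.append(h0.copy() if start == 0 else h1.copy())
            continue
        x_cm = np.sort(rng.uniform(cm[0], cm[-1], size=n_x))
        phase = (start + np.searchsorted(x_cm, cm, side="right")) % 2
        out.append(np.where(phase == 0, h0, h1))
    return out


def _next_generation(
    pop: _Population,
    n_next: int,
    selfing: float,
    fitness: np.ndarray,
    cm_pos: list[np.ndarray],
    rng: np.random.Generator,
) -> _Population:
    n = pop.n
    w = fitness / fitness.sum()
    haps = [np.empty((2 * n_next, arr.shape[1]), dtype=arr.dtype) for arr in pop.haps]
    ped_f = np.zeros(n_next)
    for k in range(n_next):
        p1 = int(rng.choice(n, p=w))
        if rng.random() < selfing:
            p2 = p1
        else:
            p2 = int(rng.choice(n, p=w))
        g1 = _meiosis(pop.haps, p1, cm_pos, rng)
        g2 = _meiosis(pop.haps, p2, cm_pos, rng)
        for c in range(len(haps)):
            haps[c][2 * k] = g1[c]
            haps[c][2 * k + 1] = g2[c]
        # coarse pedigree inbreeding: selfed offspring of parent with
        # pedigree F get F' = (1 + F)/2
        ped_f[k] = (1.0 + pop.pedigree_f[p1]) / 2.0 if p2 == p1 else 0.0
    return _Population(haps, ped_f)


def simulate(cfg: SimulationConfig) -> tuple[HaplotypeSet, GenotypeMatrix, SimulationTruth]:
    """Run the forward simulation and sample the final generation."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_map, rng_init, rng_evo, rng_sample = [np.random.default_rng(s) for s in ss.spawn(4)]
    mm = _make_map(cfg, rng_map)
    cidx = [mm.chrom_index(c) for c in range(1, cfg.n_chromosomes + 1)]
    cm_pos = [mm.position_cm[ix] for ix in cidx]

    # ancestral pool at linkage equilibrium, then burn-in to build LD
    n_anc = cfg.ancestral_ne
    anc_haps = []
    for ix in cidx:
        freqs = rng_init.uniform(cfg.maf_min_init, 0.5, size=ix.size)
        anc_haps.append((rng_init.random((2 * n_anc, ix.size)) < freqs).astype(np.uint8))
    anc = _Population(anc_haps, np.zeros(n_anc))
    for _ in range(cfg.burnin_generations):
        anc = _next_generation(anc, n_anc, 0.0, np.ones(anc.n), cm_pos, rng_evo)

    pops_order = list(cfg.sample_sizes)
    pops: dict[str, _Population] = {}
    for p in pops_order:
        ne = cfg.ne[p]
        founders = rng_evo.choice(n_anc, size=ne, replace=True)
        haps = []
        for c in range(cfg.n_chromosomes):
            rows = np.repeat(2 * founders, 2) + np.tile([0, 1], ne)
            haps.append(anc.haps[c][rows].copy())
        pops[p] = _Population(haps, np.zeros(ne))

    sweep_site: dict[int, tuple[int, int]] = {}  # sweep idx -> (chrom-1, local snp)
    sweep_log: list[dict] = []
    for k, sw in enumerate(cfg.sweeps):
        ci = sw.chromosome - 1
        local = int(np.argmin(np.abs(mm.position_bp[cidx[ci]] - sw.position_bp)))
        sweep_site[k] = (ci, local)
        sweep_log.append(
            {
                "population": sw.population,
                "chromosome": sw.chromosome,
                "target_bp": int(mm.position_bp[cidx[ci]][local]),
                "snp_id": str(mm.snp_id[cidx[ci]][local]),
                "s": sw.s,
                "fixed": False,
                "lost": False,
            }
        )

    for gen in range(cfg.split_generations):
        t_before_present = cfg.split_generations - gen
        for p in pops_order:
            pop = pops[p]
            ne = cfg.ne[p]
            if p in cfg.bottleneck and t_before_present <= cfg.bottleneck[p][0]:
                ne = cfg.bottleneck[p][1]
            fitness = np.ones(pop.n)
            for k, sw in enumerate(cfg.sweeps):
                if sw.population != p or gen < sw.start_generation:
                    continue
                ci, local = sweep_site[k]
                dose = pop.haps[ci][0::2, local] + pop.haps[ci][1::2, local]
                if gen == sw.start_generation or (sw.reinject and dose.sum() == 0):
                    _inject_allele(pop.haps[ci], local, sw.init_copies, rng_evo)
                    dose = pop.haps[ci][0::2, local] + pop.haps[ci][1::2, local]
                fitness = fitness * (1.0 + sw.s) ** dose
            pops[p] = _next_generation(pop, ne, cfg.selfing[p], fitness, cm_pos, rng_evo)

    truth = SimulationTruth(cfg.seed, sweep_log)
    for k, sw in enumerate(cfg.sweeps):
        ci, local = sweep_site[k]
        pool = pops[sw.population].haps[ci][:, local]
        freq = float(pool.mean())
        truth.final_sweep_freq[f"sweep_{k}"] = freq
        sweep_log[k]["final_freq"] = freq
        sweep_log[k]["fixed"] = freq == 1.0
        sweep_log[k]["lost"] = freq == 0.0
        if freq == 0.0:
            logger.warning("sweep %d allele lost in %s", k, sw.population)

    samples, labels, rows = [], [], []
    for p in pops_order:
        pop = pops[p]
        pick = rng_sample.choice(pop.n, size=cfg.sample_sizes[p], replace=False)
        truth.mean_pedigree_f[p] = float(pop.pedigree_f[pick].mean())
        for q, ind in enumerate(pick):
            samples.append(f"{p}_{q:03d}")
            labels.append(p)
            rows.append(
                np.concatenate([pop.haps[c][[2 * ind, 2 * ind + 1]] for c in range(cfg.n_chromosomes)], axis=1)
            )
    hap_matrix = np.concatenate(rows, axis=0)
    hs = HaplotypeSet(samples, np.array(labels, dtype=object), hap_matrix, mm)
    return hs, hs.to_genotypes(), truth


def _inject_allele(
    haps: np.ndarray, local: int, copies: int, rng: np.random.Generator
) -> None:
    """Seed the sweep allele on ``copies`` haplotypes (hard sweep when 1).

    The column is overwritten so the derived allele has a single marker
    state; hitchhiking then traces the carrier haplotype(s).
    """
    n_hap = haps.shape[0]
    col = np.zeros(n_hap, dtype=np.uint8)
    col[rng.choice(n_hap, size=min(copies, n_hap), replace=False)] = 1
    haps[:, local] = col


def default_sweep_config(seed: int = 0) -> SimulationConfig:
    """The canonical sweep scenario: one hard sweep in the focal
    population on chromosome 1 at 20.5 Mb (mid-window on the 1-Mb
    scan grid)."""
    return SimulationConfig(
        sweeps=[SweepSpec(population="BAL", chromosome=1, position_bp=20_500_000)], seed=seed
    )


def neutral_config(seed: int = 0) -> SimulationConfig:
    """Generator defaults with no sweep (null scenario for scan tests)."""
    return SimulationConfig(seed=seed)


def write_fixture_suite(out_dir: str | Path, seed: int = 20_220_866) -> dict[str, Path]:
    """Write the canonical small test cohort in every supported format.

    Deterministic from the embedded default seed: PED/MAP, BED/BIM/FAM,
    HAPS (+samples), phased VCF, population TSV and a truth JSON. The
    cohort is compacted to 3 chromosomes (~2,400 SNPs) so the emitted
    text files stay small.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(default_sweep_config(seed=seed), n_chromosomes=3)
    hs, gm, truth = simulate(cfg)
    paths = {
        "ped": out / "cohort.ped",
        "map": out / "cohort.map",
        "bed": out / "cohort.bed",
        "bim": out / "cohort.bim",
        "fam": out / "cohort.fam",
        "haps": out / "cohort.haps",
        "vcf": out / "cohort.vcf",
        "pops": out / "cohort.pops.tsv",
        "truth": out / "cohort.truth.json",
    }
    write_plink_text(gm, paths["ped"], paths["map"])
    write_plink_bed(gm, paths["bed"], paths["bim"], paths["fam"])
    write_haps(hs, paths["haps"])
    write_phased_vcf(hs, paths["vcf"])
    with open(paths["pops"], "w") as fh:
        for s, p in zip(gm.samples, gm.populations):
            fh.write(f"{s}\t{p}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": truth.config_seed,
                "sweeps": truth.sweep_outcomes,
                "final_sweep_freq": truth.final_sweep_freq,
                "mean_pedigree_f": truth.mean_pedigree_f,
                "chromosome_bp": cfg.chromosome_bp,
                "n_chromosomes": cfg.n_chromosomes,
            },
            fh,
            indent=2,
        )
    return paths
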