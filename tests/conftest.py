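"""Shared fixtures: small deterministic cohorts and the simulated
fixture sets used by the scan power tests (built once per session)."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from divscan import qc
from divscan.genotype_io import (
    MISSING,
    GenotypeMatrix,
    HaplotypeSet,
    MarkerMap,
    match_haplotypes,
)
from divscan import synthetic_data as sd

N_POWER_SEEDS = 10


def make_map(n_snps: int, chrom: int = 1, spacing: int = 50_000, rate: float = 1.0) -> MarkerMap:
    pos = np.arange(1, n_snps + 1) * spacing
    return MarkerMap(
        chromosome=[chrom] * n_snps,
        position_bp=pos,
        snp_id=[f"c{chrom}s{j}" for j in range(n_snps)],
        allele_a=["A"] * n_snps,
        allele_b=["G"] * n_snps,
        position_cm=pos * rate / 1e6,
    )


def random_gm(
    n_samples: int = 10,
    n_snps: int = 50,
    missing_frac: float = 0.0,
    seed: int = 0,
    n_pops: int = 1,
) -> GenotypeMatrix:
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.9, size=n_snps)
    calls = rng.binomial(2, freqs, size=(n_samples, n_snps)).astype(np.int8)
    if missing_frac > 0:
        calls[rng.random((n_samples, n_snps)) < missing_frac] = MISSING
    pops = [f"P{i % n_pops + 1}" for i in range(n_samples)]
    return GenotypeMatrix(
        [f"s{i}" for i in range(n_samples)], np.array(pops, dtype=object), calls, make_map(n_snps)
    )


@pytest.fixture(scope="session")
def fixture_cohort():
    """One default sweep cohort: raw haplotypes, QC'd genotypes, truth."""
    hs, gm, truth = sd.simulate(sd.default_sweep_config(seed=1))
    gm_qc, _ = qc.run_qc(gm)
    hs_qc = match_haplotypes(hs, gm_qc)
    return hs_qc, gm_qc, truth


def _prepare(cfg: sd.SimulationConfig):
    hs, gm, truth = sd.simulate(cfg)
    gm_qc, _ = qc.run_qc(gm)
    return match_haplotypes(hs, gm_qc), gm_qc, truth


@pytest.fixture(scope="session")
def sweep_cohorts():
    """Default-config sweep cohorts over the fixed power-test seeds."""
    return [_prepare(sd.default_sweep_config(seed=s)) for s in range(N_POWER_SEEDS)]


@pytest.fixture(scope="session")
def neutral_cohorts():
    """Null (no-sweep) cohorts over a disjoint block of fixed seeds."""
    return [
        _prepare(sd.neutral_config(seed=s))
        for s in range(N_POWER_SEEDS, 2 * N_POWER_SEEDS)
    ]
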