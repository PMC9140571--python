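"""Genotype and haplotype containers plus PLINK / HAPS / phased-VCF I/O.

Conventions used throughout the package:

* coordinates are 1-based inclusive base pairs (PLINK convention);
* genotype calls are stored as alt-allele dosage of ``allele_b``
  (the PLINK A2 analog) in ``{0, 1, 2}`` with ``-1`` as the missing
  sentinel — missing is never conflated with dosage 0;
* only autosomes (labels 1..26 for sheep) are analyzed; non-autosomal
  records are dropped at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MISSING: int = -1
N_AUTOSOMES: int = 26

_VALID_ALLELES = set("ACGT0")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class MarkerMap:
    """Per-SNP map: chromosome, bp position, id, and the two allele codes.

    Positions are 1-based; within each chromosome positions must be
    strictly increasing once the map is sorted. ``position_cm`` is
    optional genetic-map information (centimorgans).
    """

    chromosome: np.ndarray  # int per SNP
    position_bp: np.ndarray  # int64, >= 1
    snp_id: np.ndarray  # str
    allele_a: np.ndarray  # str (the non-counted allele, PLINK A1 analog)
    allele_b: np.ndarray  # str (the counted allele, PLINK A2 analog)
    position_cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        if self.position_cm is not None:
            self.position_cm = np.asarray(self.position_cm, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.snp_id)
        for arr in (self.chromosome, self.position_bp, self.allele_a, self.allele_b):
            if len(arr) != n:
                raise ValueError("marker map field lengths differ")
        if n and self.position_bp.min() < 1:
            raise ValueError("positions must be >= 1 (1-based)")
        if len(set(self.snp_id)) != n:
            raise ValueError("duplicate snp_id in marker map")
        for c in np.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            self.chromosome[idx],
            self.position_bp[idx],
            self.snp_id[idx],
            self.allele_a[idx],
            self.allele_b[idx],
            None if self.position_cm is None else self.position_cm[idx],
        )

    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chrom_index(self, chrom: int) -> np.ndarray:
        """Indices of the SNPs on ``chrom`` in map order."""
        return np.flatnonzero(self.chromosome == chrom)


@dataclass
class GenotypeMatrix:
    """Diploid calls (samples x SNPs) bound to a marker map and labels."""

    samples: list[str]
    populations: np.ndarray  # str label per sample
    calls: np.ndarray  # int8, dosage of allele_b, MISSING = -1
    map: MarkerMap

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), self.map.n_snps):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {self.map.n_snps} SNPs"
            )
        if len(self.populations) != len(self.samples):
            raise ValueError("one population label per sample required")
        ok = (self.calls >= 0) & (self.calls <= 2)
        if not np.all(ok | (self.calls == MISSING)):
            raise ValueError("calls must be 0/1/2 or the missing sentinel")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.map.n_snps

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_index(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.populations == population)
        if idx.size == 0:
            raise KeyError(f"population {population!r} not present")
        return idx

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.populations[idx],
            self.calls[idx],
            self.map,
        )

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.samples), self.populations, self.calls[:, idx], self.map.subset(idx)
        )

    def restrict_population(self, population: str) -> "GenotypeMatrix":
        return self.subset_samples(self.pop_index(population))

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele_b_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele over non-missing calls.

        SNPs with no non-missing calls get NaN.
        """
        miss = self.missing_mask()
        n_obs = (~miss).sum(axis=0)
        dose = np.where(miss, 0, self.calls).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, dose / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_b_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes, two rows per sample, on a marker map.

    Entry ``h[2*i + k, j]`` is 1 when haplotype ``k`` of sample ``i``
    carries ``allele_b`` at SNP ``j``. Phased input may not contain
    missing calls.
    """

    samples: list[str]
    populations: np.ndarray
    haplotypes: np.ndarray  # uint8 (2*n_samples, n_snps), entries 0/1
    map: MarkerMap

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (2 * len(self.samples), self.map.n_snps):
            raise ValueError("haplotype matrix must be (2*samples) x SNPs")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.samples)

    def sample_of_haplotype(self, row: int) -> str:
        return self.samples[row // 2]

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse haplotype pairs to a dosage GenotypeMatrix."""
        dose = (
            self.haplotypes[0::2].astype(np.int8) + self.haplotypes[1::2].astype(np.int8)
        )
        return GenotypeMatrix(list(self.samples), self.populations, dose, self.map)

    def restrict_population(self, population: str) -> "HaplotypeSet":
        idx = np.flatnonzero(self.populations == population)
        if idx.size == 0:
            raise KeyError(f"population {population!r} not present")
        rows = np.repeat(2 * idx, 2) + np.tile([0, 1], idx.size)
        return HaplotypeSet(
            [self.samples[i] for i in idx],
            self.populations[idx],
            self.haplotypes[rows],
            self.map,
        )

    def subset_snps(self, idx: np.ndarray) -> "HaplotypeSet":
        idx = np.asarray(idx)
        return HaplotypeSet(
            list(self.samples), self.populations, self.haplotypes[:, idx], self.map.subset(idx)
        )


# ---------------------------------------------------------------------------
# marker-map helpers
# ---------------------------------------------------------------------------


def _autosome_filter(mm: MarkerMap) -> np.ndarray:
    keep = (mm.chromosome >= 1) & (mm.chromosome <= N_AUTOSOMES)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d non-autosomal records at read time", dropped)
    return np.flatnonzero(keep)


def _parse_chrom(tok: str) -> int:
    try:
        return int(tok)
    except ValueError:
        # X/Y/MT and friends map outside the autosome range and get dropped
        return 0


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK PED/MAP pair into a :class:`GenotypeMatrix`.

    The PED family-id column supplies the population label. ``0 0``
    allele pairs become missing. Dosage counts ``allele_b``, taken per
    SNP as the lexically larger of the two observed alleles unless the
    MAP file carries explicit allele columns (a ``divscan`` extension).
    """
    map_rows = _read_tokens(map_path)
    chroms, ids, cms, bps = [], [], [], []
    map_alleles: list[tuple[str, str]] | None = [] if map_rows and len(map_rows[0]) >= 6 else None
    for row in map_rows:
        if len(row) < 4:
            raise FormatError(f"MAP row with {len(row)} columns (need 4): {row}")
        chroms.append(_parse_chrom(row[0]))
        ids.append(row[1])
        cms.append(float(row[2]))
        bps.append(int(row[3]))
        if map_alleles is not None:
            map_alleles.append((row[4], row[5]))
    n_snps = len(ids)

    samples: list[str] = []
    pops: list[str] = []
    allele_rows: list[list[str]] = []
    for r, row in enumerate(_read_tokens(ped_path)):
        if len(row) != 6 + 2 * n_snps:
            raise FormatError(
                f"PED row {r + 1} has {len(row)} columns, expected {6 + 2 * n_snps} "
                f"for {n_snps} MAP SNPs"
            )
        pops.append(row[0])
        samples.append(row[1])
        alleles = row[6:]
        for a in alleles:
            if a not in _VALID_ALLELES:
                raise FormatError(f"PED row {r + 1}: allele code {a!r} not in ACGT0")
        allele_rows.append(alleles)

    n = len(samples)
    a1 = np.empty((n, n_snps), dtype=object)
    a2 = np.empty((n, n_snps), dtype=object)
    for i, row_alleles in enumerate(allele_rows):
        a1[i] = row_alleles[0::2]
        a2[i] = row_alleles[1::2]

    allele_a_col, allele_b_col, calls = _encode_allele_calls(a1, a2, map_alleles)
    mm = MarkerMap(chroms, bps, ids, allele_a_col, allele_b_col, cms)
    keep = _autosome_filter(mm)
    gm = GenotypeMatrix(samples, pops, calls, mm)
    if keep.size != mm.n_snps:
        gm = gm.subset_snps(keep)
    return gm


def _encode_allele_calls(
    a1: np.ndarray, a2: np.ndarray, map_alleles: list[tuple[str, str]] | None
) -> tuple[list[str], list[str], np.ndarray]:
    n, m = a1.shape
    calls = np.full((n, m), MISSING, dtype=np.int8)
    out_a, out_b = [], []
    for j in range(m):
        col1, col2 = a1[:, j], a2[:, j]
        obs = sorted({x for x in np.concatenate([col1, col2]) if x != "0"})
        if len(obs) > 2:
            raise FormatError(f"SNP column {j} has >2 alleles: {obs}")
        if map_alleles is not None:
            aa, ab = map_alleles[j]
            extra = [x for x in obs if x not in (aa, ab)]
            if extra:
                raise FormatError(
                    f"SNP column {j}: allele {extra[0]!r} conflicts with map alleles {aa}/{ab}"
                )
        else:
            # allele_b = lexically larger observed allele; monomorphic ->
            # the observed allele is allele_b with a placeholder allele_a
            if len(obs) == 2:
                aa, ab = obs[0], obs[1]
            elif len(obs) == 1:
                aa, ab = "0", obs[0]
            else:
                aa, ab = "0", "0"
        out_a.append(aa)
        out_b.append(ab)
        missing = (col1 == "0") | (col2 == "0")
        dose = (col1 == ab).astype(np.int8) + (col2 == ab).astype(np.int8)
        calls[:, j] = np.where(missing, MISSING, dose)
    return out_a, out_b, calls


def write_plink_text(gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PED/MAP; exact round-trip with :func:`read_plink_text`.

    The MAP file carries two extra allele columns (allele_a, allele_b)
    so the counted allele survives the round trip even for monomorphic
    or all-missing SNPs.
    """
    mm = gm.map
    with open(map_path, "w") as fh:
        cms = mm.position_cm if mm.position_cm is not None else np.zeros(mm.n_snps)
        for j in range(mm.n_snps):
            fh.write(
                f"{mm.chromosome[j]}\t{mm.snp_id[j]}\t{cms[j]:g}\t{mm.position_bp[j]}"
                f"\t{mm.allele_a[j]}\t{mm.allele_b[j]}\n"
            )
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.samples):
            fields = [str(gm.populations[i]), sid, "0", "0", "0", "-9"]
            row = gm.calls[i]
            for j in range(mm.n_snps):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [mm.allele_a[j], mm.allele_a[j]]
                elif d == 1:
                    fields += [mm.allele_a[j], mm.allele_b[j]]
                else:
                    fields += [mm.allele_b[j], mm.allele_b[j]]
            fh.write(" ".join(fields) + "\n")


def _read_tokens(path: str | Path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(line.split())
    return rows


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM), 1.9 dialect, SNP-major
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B])
# 2-bit code -> dosage of allele_b (A2): 00 hom-A1, 01 missing, 10 het, 11 hom-A2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_plink_bed(
    bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> GenotypeMatrix:
    """Read a PLINK 1.9 binary fileset (SNP-major)."""
    fam = _read_tokens(fam_path)
    samples = [r[1] for r in fam]
    pops = [r[0] for r in fam]
    n = len(samples)

    chroms, ids, cms, bps, aas, abs_ = [], [], [], [], [], []
    for row in _read_tokens(bim_path):
        if len(row) < 6:
            raise FormatError(f"BIM row with {len(row)} columns (need 6): {row}")
        chroms.append(_parse_chrom(row[0]))
        ids.append(row[1])
        cms.append(float(row[2]))
        bps.append(int(row[3]))
        aas.append(row[4])
        abs_.append(row[5])
    m = len(ids)

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError("not a PLINK BED file (bad magic bytes)")
    if raw[2:3] != b"\x01":
        raise FormatError("only SNP-major BED files are supported (mode byte != 0x01)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * bytes_per_snp:
        raise FormatError(
            f"BED body has {body.size} bytes, expected {m * bytes_per_snp} "
            f"({m} SNPs x {bytes_per_snp} bytes)"
        )
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]  # drop pad genotypes
    calls = _BED_DECODE[codes].T.copy()  # samples x SNPs

    mm = MarkerMap(chroms, bps, ids, aas, abs_, cms)
    gm = GenotypeMatrix(samples, pops, calls, mm)
    keep = _autosome_filter(mm)
    if keep.size != mm.n_snps:
        gm = gm.subset_snps(keep)
    return gm


def write_plink_bed(
    gm: GenotypeMatrix, bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> None:
    """Write a PLINK 1.9 SNP-major binary fileset."""
    mm = gm.map
    with open(fam_path, "w") as fh:
        for i, sid in enumerate(gm.samples):
            fh.write(f"{gm.populations[i]} {sid} 0 0 0 -9\n")
    with open(bim_path, "w") as fh:
        cms = mm.position_cm if mm.position_cm is not None else np.zeros(mm.n_snps)
        for j in range(mm.n_snps):
            fh.write(
                f"{mm.chromosome[j]}\t{mm.snp_id[j]}\t{cms[j]:g}\t{mm.position_bp[j]}"
                f"\t{mm.allele_a[j]}\t{mm.allele_b[j]}\n"
            )
    n = gm.n_samples
    bytes_per_snp = (n + 3) // 4
    lut = np.array([_BED_ENCODE[0], _BED_ENCODE[1], _BED_ENCODE[2]], dtype=np.uint8)
    out = bytearray(_BED_MAGIC + b"\x01")
    for j in range(gm.n_snps):
        col = gm.calls[:, j]
        codes = np.where(col == MISSING, _BED_ENCODE[MISSING], lut[np.maximum(col, 0)])
        padded = np.zeros(bytes_per_snp * 4, dtype=np.uint8)
        padded[:n] = codes
        packed = (
            padded[0::4] | (padded[1::4] << 2) | (padded[2::4] << 4) | (padded[3::4] << 6)
        )
        out += packed.tobytes()
    Path(bed_path).write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# phased haplotypes: HAPS-like table and phased VCF
# ---------------------------------------------------------------------------


def read_haplotypes(
    path: str | Path,
    format: str = "haps",
    samples: list[str] | None = None,
    populations: dict[str, str] | None = None,
) -> HaplotypeSet:
    """Read phased haplotypes from a HAPS-like table or a phased VCF.

    HAPS layout per row: snp_id, chromosome, bp, allele_a, allele_b,
    then one 0/1 column per haplotype (two consecutive columns per
    sample). ``samples`` names the samples for the HAPS format (a
    sidecar ``.samples`` file next to ``path`` is used when omitted).
    ``populations`` maps sample id to population label; unmapped samples
    get the label ``"NA"``.
    """
    if format in ("haps", "haps-like"):
        return _read_haps(path, samples, populations)
    if format in ("vcf", "phased-vcf"):
        return _read_phased_vcf(path, populations)
    raise ValueError(f"unknown haplotype format {format!r}")


def _pop_labels(samples: list[str], populations: dict[str, str] | None) -> np.ndarray:
    if populations is None:
        return np.array(["NA"] * len(samples), dtype=object)
    return np.array([populations.get(s, "NA") for s in samples], dtype=object)


def _read_haps(
    path: str | Path, samples: list[str] | None, populations: dict[str, str] | None
) -> HaplotypeSet:
    rows = _read_tokens(path)
    if not rows:
        raise FormatError("empty HAPS file")
    n_hap = len(rows[0]) - 5
    if n_hap < 2 or n_hap % 2:
        raise FormatError("HAPS rows need 5 site columns plus an even haplotype count")
    if samples is None:
        sample_path = Path(str(path) + ".samples")
        if not sample_path.exists():
            raise FormatError(f"no sample list given and {sample_path} not found")
        samples = [r[0] for r in _read_tokens(sample_path)]
    if 2 * len(samples) != n_hap:
        raise FormatError(f"{len(samples)} samples inconsistent with {n_hap} haplotype columns")

    ids, chroms, bps, aas, abs_ = [], [], [], [], []
    cols = np.empty((len(rows), n_hap), dtype=np.uint8)
    for r, row in enumerate(rows):
        if len(row) != 5 + n_hap:
            raise FormatError(f"HAPS row {r + 1} has {len(row)} columns, expected {5 + n_hap}")
        ids.append(row[0])
        chroms.append(_parse_chrom(row[1]))
        bps.append(int(row[2]))
        aas.append(row[3])
        abs_.append(row[4])
        for h, tok in enumerate(row[5:]):
            if tok not in ("0", "1"):
                raise FormatError(f"HAPS row {r + 1}: allele code {tok!r} not 0/1")
            cols[r, h] = int(tok)
    mm = MarkerMap(chroms, bps, ids, aas, abs_)
    hs = HaplotypeSet(samples, _pop_labels(samples, populations), cols.T.copy(), mm)
    keep = _autosome_filter(mm)
    if keep.size != mm.n_snps:
        hs = hs.subset_snps(keep)
    return hs


def write_haps(hs: HaplotypeSet, path: str | Path) -> None:
    """Write the HAPS-like table plus a sidecar ``.samples`` list."""
    mm = hs.map
    with open(path, "w") as fh:
        for j in range(mm.n_snps):
            alleles = " ".join(str(x) for x in hs.haplotypes[:, j])
            fh.write(
                f"{mm.snp_id[j]} {mm.chromosome[j]} {mm.position_bp[j]} "
                f"{mm.allele_a[j]} {mm.allele_b[j]} {alleles}\n"
            )
    with open(str(path) + ".samples", "w") as fh:
        for s, p in zip(hs.samples, hs.populations):
            fh.write(f"{s}\t{p}\n")


def _read_phased_vcf(path: str | Path, populations: dict[str, str] | None) -> HaplotypeSet:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, bps, aas, abs_, cols = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(f"site {var.ID or var.POS}: biallelic sites only")
        phases = var.genotypes  # [a0, a1, phased] per sample
        row = np.empty(2 * len(samples), dtype=np.uint8)
        for i, g in enumerate(phases):
            if not g[2]:
                raise FormatError(
                    f"unphased genotype at site {var.ID or var.POS}, sample {samples[i]}"
                )
            if g[0] not in (0, 1) or g[1] not in (0, 1):
                raise FormatError(
                    f"allele code other than 0/1 at site {var.ID or var.POS}, "
                    f"sample {samples[i]}"
                )
            row[2 * i], row[2 * i + 1] = g[0], g[1]
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(_parse_chrom(var.CHROM))
        bps.append(var.POS)
        aas.append(var.REF)
        abs_.append(var.ALT[0])
        cols.append(row)
    mm = MarkerMap(chroms, bps, ids, aas, abs_)
    hs = HaplotypeSet(
        samples, _pop_labels(samples, populations), np.array(cols, dtype=np.uint8).T.copy(), mm
    )
    keep = _autosome_filter(mm)
    if keep.size != mm.n_snps:
        hs = hs.subset_snps(keep)
    return hs


def write_phased_vcf(hs: HaplotypeSet, path: str | Path) -> None:
    """Write haplotypes as a minimal phased VCF (uncompressed text)."""
    mm = hs.map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divscan\n")
        for c in mm.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(hs.samples) + "\n")
        for j in range(mm.n_snps):
            ref = mm.allele_a[j] if mm.allele_a[j] != "0" else "N"
            alt = mm.allele_b[j]
            gts = "\t".join(
                f"{hs.haplotypes[2 * i, j]}|{hs.haplotypes[2 * i + 1, j]}"
                for i in range(hs.n_samples)
            )
            fh.write(
                f"{mm.chromosome[j]}\t{mm.position_bp[j]}\t{mm.snp_id[j]}\t{ref}\t{alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# sample -> population sidecar
# ---------------------------------------------------------------------------


def match_haplotypes(hs: HaplotypeSet, gm: GenotypeMatrix) -> HaplotypeSet:
    """Restrict a haplotype set to the samples and SNPs of a genotype
    matrix (e.g. after QC), preserving the matrix's SNP order."""
    snp_pos = {s: k for k, s in enumerate(hs.map.snp_id)}
    snp_idx = np.array([snp_pos[s] for s in gm.map.snp_id if s in snp_pos], dtype=int)
    samp_pos = {s: k for k, s in enumerate(hs.samples)}
    samp_idx = np.array([samp_pos[s] for s in gm.samples], dtype=int)
    rows = np.repeat(2 * samp_idx, 2) + np.tile([0, 1], samp_idx.size)
    return HaplotypeSet(
        [hs.samples[i] for i in samp_idx],
        hs.populations[samp_idx],
        hs.haplotypes[np.ix_(rows, snp_idx)],
        hs.map.subset(snp_idx),
    )


def read_population_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, population) TSV into a dict."""
    mapping: dict[str, str] = {}
    for row in _read_tokens(path):
        if len(row) < 2:
            raise FormatError(f"population TSV row needs 2 columns: {row}")
        mapping[row[0]] = row[1]
    return mapping


def apply_population_labels(gm: GenotypeMatrix, mapping: dict[str, str]) -> GenotypeMatrix:
    """Override population labels from a sample->population mapping."""
    pops = np.array([mapping.get(s, p) for s, p in zip(gm.samples, gm.populations)], dtype=object)
    return replace(gm, populations=pops)
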