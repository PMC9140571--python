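"""Container invariants and exact round-trips for every I/O format."""

import numpy as np
import pytest

from divscan.genotype_io import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    HaplotypeSet,
    MarkerMap,
    apply_population_labels,
    match_haplotypes,
    read_haplotypes,
    read_plink_bed,
    read_plink_text,
    read_population_tsv,
    write_haps,
    write_phased_vcf,
    write_plink_bed,
    write_plink_text,
)

from conftest import make_map, random_gm


class TestMarkerMap:
    def test_rejects_unsorted_positions(self):
        with pytest.raises(ValueError, match="increasing"):
            MarkerMap([1, 1], [200, 100], ["a", "b"], ["A", "A"], ["G", "G"])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            MarkerMap([1, 1], [100, 200], ["a", "a"], ["A", "A"], ["G", "G"])

    def test_rejects_zero_position(self):
        with pytest.raises(ValueError, match=">= 1"):
            MarkerMap([1], [0], ["a"], ["A"], ["G"])


class TestPlinkText:
    def test_direct_encoding(self, tmp_path):
        (tmp_path / "c.map").write_text("1 s1 0 100 A G\n1 s2 0 200 A G\n")
        (tmp_path / "c.ped").write_text("POP1 ind1 0 0 0 -9 A A A G\n")
        gm = read_plink_text(tmp_path / "c.ped", tmp_path / "c.map")
        assert gm.calls.tolist() == [[0, 1]]
        assert gm.populations[0] == "POP1"

    def test_zero_allele_pair_is_missing(self, tmp_path):
        (tmp_path / "c.map").write_text("1 s1 0 100 A G\n")
        (tmp_path / "c.ped").write_text("P i1 0 0 0 -9 0 0\n")
        gm = read_plink_text(tmp_path / "c.ped", tmp_path / "c.map")
        assert gm.calls[0, 0] == MISSING

    def test_column_count_mismatch_names_row(self, tmp_path):
        (tmp_path / "c.map").write_text("1 s1 0 100 A G\n1 s2 0 200 A G\n")
        (tmp_path / "c.ped").write_text("P i1 0 0 0 -9 A A\n")
        with pytest.raises(FormatError, match="row 1"):
            read_plink_text(tmp_path / "c.ped", tmp_path / "c.map")

    def test_bad_allele_code(self, tmp_path):
        (tmp_path / "c.map").write_text("1 s1 0 100 A G\n")
        (tmp_path / "c.ped").write_text("P i1 0 0 0 -9 A X\n")
        with pytest.raises(FormatError, match="ACGT0"):
            read_plink_text(tmp_path / "c.ped", tmp_path / "c.map")

    @pytest.mark.parametrize("n,m,miss", [(10, 50, 0.0), (20, 100, 0.05), (1, 1, 0.0)])
    def test_round_trip_exact(self, tmp_path, n, m, miss):
        gm = random_gm(n, m, missing_frac=miss, seed=7)
        write_plink_text(gm, tmp_path / "o.ped", tmp_path / "o.map")
        back = read_plink_text(tmp_path / "o.ped", tmp_path / "o.map")
        assert back.samples == gm.samples
        np.testing.assert_array_equal(back.calls, gm.calls)
        np.testing.assert_array_equal(back.map.position_bp, gm.map.position_bp)

    def test_empty_cohort_round_trips(self, tmp_path):
        gm = GenotypeMatrix([], np.array([], dtype=object), np.zeros((0, 3), np.int8), make_map(3))
        write_plink_text(gm, tmp_path / "e.ped", tmp_path / "e.map")
        back = read_plink_text(tmp_path / "e.ped", tmp_path / "e.map")
        assert back.n_samples == 0 and back.n_snps == 3

    def test_non_autosomes_dropped(self, tmp_path):
        (tmp_path / "c.map").write_text("1 s1 0 100 A G\nX s2 0 200 A G\n27 s3 0 300 A G\n")
        (tmp_path / "c.ped").write_text("P i1 0 0 0 -9 A A A G G G\n")
        gm = read_plink_text(tmp_path / "c.ped", tmp_path / "c.map")
        assert gm.n_snps == 1


class TestPlinkBed:
    def test_round_trip_known_matrix(self, tmp_path):
        calls = np.array([[0, 1, 2, MISSING], [2, 2, 0, 1], [1, 0, MISSING, 0]], dtype=np.int8)
        gm = GenotypeMatrix(
            ["a", "b", "c"], np.array(["P"] * 3, dtype=object), calls, make_map(4)
        )
        write_plink_bed(gm, tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
        back = read_plink_bed(tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
        np.testing.assert_array_equal(back.calls, calls)

    def test_padded_final_byte_with_five_samples(self, tmp_path):
        gm = random_gm(5, 7, missing_frac=0.1, seed=3)
        write_plink_bed(gm, tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
        back = read_plink_bed(tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
        np.testing.assert_array_equal(back.calls, gm.calls)

    def test_all_missing_snp(self, tmp_path):
        calls = np.full((3, 2), MISSING, dtype=np.int8)
        gm = GenotypeMatrix(["a", "b", "c"], np.array(["P"] * 3, dtype=object), calls, make_map(2))
        write_plink_bed(gm, tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
        back = read_plink_bed(tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
        assert (back.calls == MISSING).all()

    def test_bad_magic_rejected(self, tmp_path):
        gm = random_gm(3, 2)
        write_plink_bed(gm, tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
        raw = (tmp_path / "x.bed").read_bytes()
        (tmp_path / "x.bed").write_bytes(b"\x00\x00" + raw[2:])
        with pytest.raises(FormatError, match="magic"):
            read_plink_bed(tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")

    def test_truncated_body_rejected(self, tmp_path):
        gm = random_gm(3, 4)
        write_plink_bed(gm, tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
        raw = (tmp_path / "x.bed").read_bytes()
        (tmp_path / "x.bed").write_bytes(raw[:-1])
        with pytest.raises(FormatError, match="bytes"):
            read_plink_bed(tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")

    def test_agrees_with_text_reader(self, tmp_path):
        gm = random_gm(13, 40, missing_frac=0.07, seed=11, n_pops=2)
        write_plink_text(gm, tmp_path / "t.ped", tmp_path / "t.map")
        write_plink_bed(gm, tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam")
        g1 = read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")
        g2 = read_plink_bed(tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam")
        np.testing.assert_array_equal(g1.calls, g2.calls)
        assert g1.samples == g2.samples


def _random_hs(n=4, m=30, seed=5) -> HaplotypeSet:
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, size=(2 * n, m)).astype(np.uint8)
    return HaplotypeSet(
        [f"s{i}" for i in range(n)],
        np.array(["P1", "P1", "P2", "P2"][:n], dtype=object),
        haps,
        make_map(m),
    )


class TestHaplotypes:
    def test_haps_round_trip(self, tmp_path):
        hs = _random_hs()
        write_haps(hs, tmp_path / "h.haps")
        back = read_haplotypes(tmp_path / "h.haps", "haps")
        np.testing.assert_array_equal(back.haplotypes, hs.haplotypes)
        assert back.samples == hs.samples

    def test_phased_vcf_round_trip(self, tmp_path):
        hs = _random_hs()
        write_phased_vcf(hs, tmp_path / "h.vcf")
        back = read_haplotypes(tmp_path / "h.vcf", "phased-vcf")
        np.testing.assert_array_equal(back.haplotypes, hs.haplotypes)
        assert back.samples == hs.samples

    def test_vcf_direct_encoding(self, tmp_path):
        (tmp_path / "t.vcf").write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "1\t100\ts1\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\n"
        )
        hs = read_haplotypes(tmp_path / "t.vcf", "phased-vcf")
        assert hs.haplotypes[:, 0].tolist() == [0, 1, 1, 1]

    def test_unphased_vcf_rejected(self, tmp_path):
        (tmp_path / "t.vcf").write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "1\t100\ts1\tA\tG\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(FormatError, match="unphased"):
            read_haplotypes(tmp_path / "t.vcf", "phased-vcf")

    def test_collapse_matches_genotypes(self):
        hs = _random_hs()
        gm = hs.to_genotypes()
        np.testing.assert_array_equal(
            gm.calls, hs.haplotypes[0::2].astype(np.int8) + hs.haplotypes[1::2]
        )

    def test_match_haplotypes_after_subsetting(self):
        hs = _random_hs()
        gm = hs.to_genotypes().subset_samples([2, 0]).subset_snps(np.arange(5, 20))
        sub = match_haplotypes(hs, gm)
        np.testing.assert_array_equal(sub.to_genotypes().calls, gm.calls)
        assert sub.samples == gm.samples


def test_population_tsv_override(tmp_path):
    gm = random_gm(3, 5)
    (tmp_path / "p.tsv").write_text("s0\tBAL\ns2\tRUD\n")
    out = apply_population_labels(gm, read_population_tsv(tmp_path / "p.tsv"))
    assert out.populations.tolist() == ["BAL", "P1", "RUD"]
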