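"""EHH decay, iES integration, XPEHH standardization, region calling."""

import numpy as np
import pytest
from scipy.stats import norm

from divscan.genotype_io import HaplotypeSet
from divscan.selection_fst import SelectionRegion
from divscan.selection_xpehh import (
    _ies_chromosome,
    _ies_chromosome_py,
    common_regions,
    ehh,
    ies,
    overlap_regions,
    pxpehh_transform,
    significant_snps,
    xpehh,
)

from conftest import make_map


def hs_from_rows(rows, spacing=50_000, rate=1.0):
    rows = np.asarray(rows, dtype=np.uint8)
    n = rows.shape[0] // 2
    return HaplotypeSet(
        [f"s{i}" for i in range(n)],
        np.array(["P"] * n, dtype=object),
        rows,
        make_map(rows.shape[1], spacing=spacing, rate=rate),
    )


class TestEhh:
    def test_identical_haplotypes_stay_at_one(self):
        hs = hs_from_rows(np.tile([0, 1, 0, 1, 1], (4, 1)))
        curve = ehh(hs, core_index=0, direction=+1)
        assert (curve.ehh == 1.0).all()
        assert curve.offsets[-1] == 4  # runs to the chromosome end

    def test_all_distinct_at_adjacent_snp_drops_to_zero(self):
        rows = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        hs = hs_from_rows(rows)
        curve = ehh(hs, core_index=0, direction=+1)
        assert curve.ehh[1] == 0.0

    def test_four_haplotype_worked_case(self):
        # from the core out: AB, AB, Ab, aB -> one identical pair of six
        rows = np.array([[0, 0], [0, 0], [0, 1], [1, 0]], dtype=np.uint8)
        hs = hs_from_rows(rows)
        curve = ehh(hs, core_index=0, direction=+1)
        assert curve.ehh[1] == pytest.approx(1 / 6)

    def test_core_value_is_one_and_curve_monotone(self):
        rng = np.random.default_rng(0)
        hs = hs_from_rows(rng.integers(0, 2, size=(12, 40)))
        for core in (0, 20, 39):
            for direction in (+1, -1):
                c = ehh(hs, core, direction)
                assert c.ehh[0] == 1.0
                assert (np.diff(c.ehh) <= 1e-12).all()
                assert ((c.ehh >= 0) & (c.ehh <= 1)).all()

    def test_gap_truncation(self):
        rows = np.tile([0, 1, 0], (4, 1))
        hs = hs_from_rows(rows, spacing=300_000)  # gaps above 250 kb
        curve = ehh(hs, 0, +1, max_gap_bp=250_000)
        assert curve.offsets.tolist() == [0]


class TestIes:
    def test_identical_haplotypes_integrate_interval_length(self):
        # 21 SNPs spanning 1 Mb at 1 cM/Mb -> 1 cM per direction from an end
        hs = hs_from_rows(np.tile([1] * 21, (4, 1)))
        v = ies(hs, core_index=0, rec_rate_cm_per_mb=1.0)
        assert v == pytest.approx(1.0)

    def test_hand_quadrature_of_step_curve(self):
        # EHH from core: 1 at 0 cM, 1/6 at 0.05 cM, then 1/6 at 0.1 cM
        rows = np.array([[0, 0, 0], [0, 0, 0], [0, 1, 1], [1, 0, 0]], dtype=np.uint8)
        hs = hs_from_rows(rows)
        v = ies(hs, 0, 1.0)
        expected = 0.5 * (1 + 1 / 6) * 0.05 + 0.5 * (1 / 6 + 1 / 6) * 0.05
        assert v == pytest.approx(expected)

    def test_map_rate_linearity(self):
        rng = np.random.default_rng(1)
        hs = hs_from_rows(rng.integers(0, 2, size=(10, 30)))
        assert ies(hs, 15, 2.0) == pytest.approx(2 * ies(hs, 15, 1.0))

    def test_fast_kernel_equals_reference(self):
        rng = np.random.default_rng(7)
        haps = rng.integers(0, 2, size=(20, 80)).astype(np.uint8)
        pos = np.sort(rng.choice(np.arange(1, 4_000_000), 80, replace=False)).astype(float)
        ref = _ies_chromosome_py(haps, pos, 1e-6, 0.05, 250_000.0)
        fast = _ies_chromosome(haps, pos, 1e-6, 0.05, 250_000.0)
        np.testing.assert_allclose(fast, ref, rtol=1e-12)


class TestXpehh:
    def _pair(self, seed=0, m=60):
        rng = np.random.default_rng(seed)
        a = hs_from_rows(rng.integers(0, 2, size=(16, m)))
        b = hs_from_rows(rng.integers(0, 2, size=(12, m)))
        return a, b

    def test_identical_sets_degenerate(self):
        a, _ = self._pair()
        scores = xpehh(a, a)
        assert scores.degenerate
        with pytest.raises(ValueError):
            significant_snps(scores)

    def test_sign_symmetry_on_swap(self):
        a, b = self._pair(3)
        ab = xpehh(a, b)
        ba = xpehh(b, a)
        np.testing.assert_allclose(ab.raw, -ba.raw, rtol=1e-12, equal_nan=True)

    def test_pxpehh_identities(self):
        assert pxpehh_transform(np.array([0.0]))[0] == 0.0
        z_05 = norm.isf(0.025)  # two-sided p = 0.05
        assert pxpehh_transform(np.array([z_05]))[0] == pytest.approx(1.301, abs=1e-3)

    def test_pxpehh_even_and_increasing(self):
        grid = np.linspace(0.0, 6.0, 61)
        up = pxpehh_transform(grid)
        down = pxpehh_transform(-grid)
        np.testing.assert_allclose(up, down, rtol=1e-12)
        assert (np.diff(up) > 0).all()

    def test_threshold_is_closed(self):
        a, b = self._pair(5)
        scores = xpehh(a, b)
        scores.pxpehh[:] = 0.0
        scores.pxpehh[3] = 5.0
        scores.pxpehh[4] = 4.999
        assert significant_snps(scores, 5.0).tolist() == [3]

    def test_threshold_five_is_p_1e5(self):
        z = norm.isf(5e-6)  # two-sided p = 1e-5
        assert pxpehh_transform(np.array([z]))[0] == pytest.approx(5.0, abs=1e-9)


class TestCommonRegions:
    def _map(self, m=40, spacing=100_000):
        return make_map(m, spacing=spacing)

    def test_disjoint_sets_empty(self):
        mm = self._map()
        assert common_regions([np.array([1, 2, 3]), np.array([10, 11, 12])], mm) == []

    def test_identical_clustered_sets(self):
        mm = self._map()
        sets = [np.array([5, 6, 7])] * 3
        regions = common_regions(sets, mm)
        assert len(regions) == 1
        assert regions[0].n_snps == 3
        assert regions[0].start_bp == mm.position_bp[5]
        assert regions[0].end_bp == mm.position_bp[7]

    def test_planted_cluster_with_scattered_singletons(self):
        from oracles import cluster_bounded

        mm = self._map(60)
        shared = np.array([20, 21, 22, 23, 24, 40, 3])
        sets = [shared, np.concatenate([shared, [50]]), np.concatenate([shared, [55]])]
        regions = common_regions(sets, mm, min_snps=3, max_span_bp=1_000_000)
        expected = cluster_bounded(
            [int(mm.position_bp[j]) for j in shared], 3, 1_000_000
        )
        assert [(r.start_bp, r.end_bp, r.n_snps) for r in regions] == expected
        assert len(regions) == 1  # the 5-SNP cluster only

    def test_span_bound_respected(self):
        mm = self._map(60, spacing=300_000)
        sets = [np.arange(0, 10)] * 2
        for r in common_regions(sets, mm, min_snps=3, max_span_bp=1_000_000):
            assert r.end_bp - r.start_bp <= 1_000_000


class TestOverlapRegions:
    def r(self, chrom, a, b, src="di"):
        return SelectionRegion(chrom, a, b, 5, src)

    def test_no_shared_chromosome(self):
        assert overlap_regions([self.r(1, 1, 10)], [self.r(2, 1, 10)]) == []

    def test_identical_lists(self):
        out = overlap_regions([self.r(1, 5, 9)], [self.r(1, 5, 9)])
        assert [(o.start_bp, o.end_bp) for o in out] == [(5, 9)]
        assert out[0].source == "overlap"

    def test_partial_overlap(self):
        out = overlap_regions([self.r(1, 1, 10)], [self.r(1, 5, 20)])
        assert (out[0].start_bp, out[0].end_bp) == (5, 10)


def test_sweep_core_has_elevated_ehh_against_neutral(sweep_cohorts, neutral_cohorts):
    """Paired over seeds: iES at the sweep core in the sweep population
    exceeds iES at the same map position in a neutral cohort."""
    wins = 0
    for (hs_s, gm_s, truth), (hs_n, _, _) in zip(sweep_cohorts[:3], neutral_cohorts[:3]):
        bp = truth.sweep_outcomes[0]["target_bp"]
        bal_s = hs_s.restrict_population("BAL")
        bal_n = hs_n.restrict_population("BAL")
        core_s = int(np.argmin(np.abs(bal_s.map.position_bp * (bal_s.map.chromosome == 1) - bp)))
        core_n = int(np.argmin(np.abs(bal_n.map.position_bp * (bal_n.map.chromosome == 1) - bp)))
        v_s = ies(bal_s, core_s, 3.0)
        v_n = ies(bal_n, core_n, 3.0)
        wins += v_s > v_n
    assert wins == 3
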