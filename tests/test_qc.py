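"""SNP/sample filters, KING-robust kinship, relatedness and LD pruning."""

import numpy as np
import pytest

from divscan.genotype_io import MISSING, GenotypeMatrix
from divscan.qc import (
    KinshipMatrix,
    LdPruneParams,
    QcParams,
    filter_samples,
    filter_snps,
    kinship_matrix,
    ld_prune,
    prune_related,
    r_squared,
)

from conftest import make_map, random_gm
from oracles import ld_prune_fixpoint, minimal_removal_size


def gm_from_calls(calls, pops=None, spacing=50_000):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    pops = pops or ["P"] * n
    return GenotypeMatrix(
        [f"s{i}" for i in range(n)], np.array(pops, dtype=object), calls, make_map(m, spacing=spacing)
    )


class TestSnpFilter:
    def test_boundaries(self):
        # SNP0: alt freq 0.04 (below MAF 0.05); SNP1: freq 0.5 but 96% call rate
        n = 50
        calls = np.zeros((n, 2), dtype=np.int8)
        calls[:4, 0] = 1  # freq 4/100 = 0.04
        calls[: n // 2, 1] = 2
        calls[n - 2, 1] = MISSING  # call rate 48/50 = 0.96
        gm = gm_from_calls(calls)
        out, rep = filter_snps(gm, QcParams())
        assert list(out.map.snp_id) == ["c1s1"]
        assert rep.by_criterion["maf"] == 1

    def test_hand_counted_toy(self):
        # 10 SNPs x 20 samples: 3 fail MAF only, 2 fail call rate only,
        # 1 fails both, 4 pass
        rng = np.random.default_rng(0)
        calls = rng.binomial(2, 0.5, size=(20, 10)).astype(np.int8)
        for j in (0, 1, 2):  # MAF failures: monomorphic
            calls[:, j] = 0
        for j in (3, 4):  # call-rate failures: 3 missing of 20 (85%)
            calls[0:3, j] = MISSING
        calls[:, 5] = 0  # fails both
        calls[0:3, 5] = MISSING
        gm = gm_from_calls(calls)
        out, rep = filter_snps(gm, QcParams(maf_min=0.05, snp_call_rate_min=0.95))
        assert out.n_snps == 4
        assert rep.by_criterion == {"call_rate": 3, "maf": 3}

    def test_idempotent(self):
        gm = random_gm(30, 60, missing_frac=0.1, seed=2)
        once, _ = filter_snps(gm, QcParams())
        twice, rep = filter_snps(once, QcParams())
        assert twice.n_snps == once.n_snps and not rep.removed

    def test_all_removed_warns_not_raises(self):
        gm = gm_from_calls(np.zeros((10, 3)))
        out, rep = filter_snps(gm, QcParams())
        assert out.n_snps == 0 and rep.warnings


class TestSampleFilter:
    def test_exact_retained_set(self):
        calls = np.ones((5, 100), dtype=np.int8)
        calls[1, :6] = MISSING  # 6% missing -> removed
        calls[2, :5] = MISSING  # exactly 5% -> retained (threshold is >)
        calls[4, :50] = MISSING
        gm = gm_from_calls(calls)
        out, rep = filter_samples(gm, QcParams())
        assert out.samples == ["s0", "s2", "s3"]
        assert rep.removed == ["s1", "s4"]


class TestKinship:
    def test_duplicate_pair_is_full_ibd(self):
        row = np.array([0, 1, 2, 1, 0, 1, 2, 2], dtype=np.int8)
        gm = gm_from_calls([row, row])
        k = kinship_matrix(gm)
        assert k.kinship[0, 1] == pytest.approx(0.5)
        assert k.ibd[0, 1] == pytest.approx(1.0)

    def test_monomorphic_zero_over_zero_guard(self):
        gm = gm_from_calls([[0, 0, 0], [0, 0, 0]])
        k = kinship_matrix(gm)
        assert k.kinship[0, 1] == 0.0

    def test_four_sample_hand_evaluation(self):
        calls = np.array(
            [
                [0, 1, 2, 1, 0],
                [1, 1, 0, 2, 0],
                [2, 0, 0, 1, 1],
                [0, 1, 2, 1, MISSING],
            ],
            dtype=np.int8,
        )
        gm = gm_from_calls(calls)
        k = kinship_matrix(gm)
        # pair (0,1): one het-het (snp 1), one opposite hom (snp 2),
        # two hets each (s0: snps 1,3; s1: snps 0,1)
        assert k.kinship[0, 1] == pytest.approx((1 - 2 * 1) / (2 + 2))
        # pair (0,3): identical over the 4 jointly observed loci
        assert k.kinship[0, 3] == pytest.approx((2 - 0) / (2 + 2))

    def test_no_shared_loci_flagged_unrelated(self):
        calls = np.array([[1, MISSING], [MISSING, 1]], dtype=np.int8)
        gm = gm_from_calls(calls)
        k = kinship_matrix(gm)
        assert k.kinship[0, 1] == 0.0 and k.undefined_pairs == [("s0", "s1")]


class TestPruneRelated:
    def test_no_pair_over_threshold_is_identity(self):
        gm = random_gm(6, 200, seed=4)
        k = kinship_matrix(gm)
        out, rep = prune_related(gm, k, ibd_max=1.1)
        assert out.samples == gm.samples and not rep.removed

    def test_duplicate_pair_drops_exactly_one(self):
        row = np.array([0, 1, 2, 1, 1, 0], dtype=np.int8)
        other = np.array([2, 1, 0, 1, 1, 2], dtype=np.int8)
        gm = gm_from_calls([row, row.copy(), other])
        out, rep = prune_related(gm, kinship_matrix(gm), 0.35)
        assert len(rep.removed) == 1 and rep.removed[0] in ("s0", "s1")

    def test_triangle_matches_minimal_removal(self):
        row = np.array([0, 1, 2, 1, 1, 0, 2, 1], dtype=np.int8)
        gm = gm_from_calls([row, row.copy(), row.copy(), 2 - row])
        k = kinship_matrix(gm)
        out, rep = prune_related(gm, k, 0.35)
        assert len(rep.removed) == minimal_removal_size(k.ibd, 0.35) == 2
        k2 = kinship_matrix(out)
        off = k2.ibd[~np.eye(out.n_samples, dtype=bool)]
        assert (off <= 0.35).all()

    def test_output_never_contains_over_threshold_pair(self):
        gm = random_gm(12, 80, seed=9)
        # plant two duplicate pairs
        gm.calls[1] = gm.calls[0]
        gm.calls[7] = gm.calls[6]
        out, _ = prune_related(gm, kinship_matrix(gm), 0.35)
        k = kinship_matrix(out)
        off = k.ibd[~np.eye(out.n_samples, dtype=bool)]
        assert (off <= 0.35).all()
        assert not ({"s0", "s1"} <= set(out.samples))
        assert not ({"s6", "s7"} <= set(out.samples))


class TestRSquared:
    def test_identical_and_opposite(self):
        x = np.array([0, 0, 1, 1, 2, 2])
        assert r_squared(x, x) == pytest.approx(1.0)
        assert r_squared(np.array([0, 0, 1, 1]), np.array([1, 1, 0, 0])) == pytest.approx(1.0)

    def test_matches_textbook_pearson(self):
        x = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        y = np.array([1, 1, 2, 0, 0, 2], dtype=float)
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert r_squared(x.astype(np.int8), y.astype(np.int8)) == pytest.approx(expected)

    def test_monomorphic_subset_undefined(self):
        x = np.array([1, 1, 1, 1], dtype=np.int8)
        y = np.array([0, 1, 2, 0], dtype=np.int8)
        assert np.isnan(r_squared(x, y))

    def test_missing_excluded(self):
        x = np.array([0, 1, 2, MISSING], dtype=np.int8)
        y = np.array([0, 1, 2, 0], dtype=np.int8)
        assert r_squared(x, y) == pytest.approx(1.0)


class TestLdPrune:
    def test_independent_snps_identity(self):
        gm = random_gm(200, 30, seed=13)
        out, _ = ld_prune(gm, LdPruneParams(window_snps=10, step_snps=3))
        assert out.n_snps == 30

    def test_duplicate_snps_keep_one(self):
        rng = np.random.default_rng(3)
        col = rng.binomial(2, 0.5, 40).astype(np.int8)
        calls = np.column_stack([col, col, rng.binomial(2, 0.5, 40)]).astype(np.int8)
        gm = gm_from_calls(calls)
        out, _ = ld_prune(gm, LdPruneParams(window_snps=3, step_snps=1))
        assert out.n_snps == 2

    def test_block_matches_bruteforce_fixpoint(self):
        rng = np.random.default_rng(21)
        base = rng.binomial(2, 0.5, 60).astype(np.int8)
        cols = [base]
        for _ in range(7):  # correlated block with occasional flips
            c = base.copy()
            flip = rng.random(60) < rng.uniform(0.05, 0.5)
            c[flip] = rng.binomial(2, 0.5, flip.sum())
            cols.append(c.astype(np.int8))
        gm = gm_from_calls(np.column_stack(cols))
        p = LdPruneParams(r2_max=0.5, window_snps=5, step_snps=2)
        out, _ = ld_prune(gm, p)
        keep = ld_prune_fixpoint(gm.calls, gm.maf(), p.window_snps, p.step_snps, p.r2_max)
        assert list(out.map.snp_id) == list(gm.map.snp_id[keep])

    def test_no_remaining_window_pair_above_threshold(self):
        gm = random_gm(60, 40, seed=17)
        gm.calls[:, 5] = gm.calls[:, 4]  # plant one duplicate
        p = LdPruneParams(r2_max=0.5, window_snps=8, step_snps=2)
        out, _ = ld_prune(gm, p)
        for a in range(out.n_snps):
            for b in range(a + 1, min(a + p.window_snps, out.n_snps)):
                r2 = r_squared(out.calls[:, a], out.calls[:, b])
                assert np.isnan(r2) or r2 <= p.r2_max

    def test_idempotent(self):
        gm = random_gm(50, 35, seed=29)
        p = LdPruneParams(window_snps=10, step_snps=4)
        once, _ = ld_prune(gm, p)
        twice, rep = ld_prune(once, p)
        assert twice.n_snps == once.n_snps and not rep.removed


def test_param_validation():
    with pytest.raises(ValueError):
        QcParams(maf_min=1.5)
    with pytest.raises(ValueError):
        LdPruneParams(window_snps=5, step_snps=5)
    with pytest.raises(ValueError):
        LdPruneParams(r2_max=0.0)
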