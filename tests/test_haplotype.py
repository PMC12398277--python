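"""EHH/iHH/iHS and SL/nSL statistics and their standardization."""

import math

import numpy as np
import pytest

from conftest import random_matrix
from oracles import brute_ehh_curve, brute_sl
from panscan.haplotype import (
    HaplotypeMatrix,
    ScanConfig,
    SiteScore,
    ehh_curve,
    ihh,
    ihs_unstandardized,
    nsl_unstandardized,
    sl_statistic,
    standardize,
)


def matrix_from_rows(rows, positions=None):
    rows = np.array(rows, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, rows.shape[1] + 1)
    return HaplotypeMatrix(alleles=rows, positions=np.asarray(positions))


class TestEhhCurve:
    def test_identical_carriers_keep_ehh_one(self):
        m = matrix_from_rows([[1] * 6, [1] * 6, [1] * 6, [0] * 6])
        curve = ehh_curve(m, 2, 1)
        assert (curve.right[:, 1] == 1.0).all()
        assert (curve.left[:, 1] == 1.0).all()
        assert curve.reached_edge  # EHH never decayed below the cutoff

    def test_two_carriers_differing_next_site(self):
        m = matrix_from_rows([[1, 0, 0], [1, 1, 0], [0, 0, 0], [0, 1, 1]])
        curve = ehh_curve(m, 0, 1)
        # C(1,2) = 0 shared pairs at the first extension
        assert curve.right[1, 1] == 0.0

    def test_four_carriers_splitting_two_two(self):
        m = matrix_from_rows(
            [[1, 0], [1, 0], [1, 1], [1, 1], [0, 0], [0, 1]]
        )
        curve = ehh_curve(m, 0, 1)
        assert curve.right[1, 1] == pytest.approx(1 / 3)  # (1+1)/C(4,2)

    def test_fewer_than_two_carriers_rejected(self):
        m = matrix_from_rows([[1, 0], [0, 0], [0, 0], [0, 1]])
        with pytest.raises(ValueError):
            ehh_curve(m, 0, 1)

    def test_ehh_non_increasing(self, rng):
        for _ in range(50):
            m = random_matrix(rng, 8, 12)
            for allele in (0, 1):
                if (m.alleles[:, 5] == allele).sum() < 2:
                    continue
                c = ehh_curve(m, 5, allele)
                for arm in (c.left, c.right):
                    assert (np.diff(arm[:, 1]) <= 1e-15).all()

    def test_matches_pair_enumeration_oracle_exactly(self, rng):
        for _ in range(100):
            m = random_matrix(rng, int(rng.integers(4, 7)), int(rng.integers(2, 11)))
            core = int(rng.integers(m.n_site))
            for allele in (0, 1):
                if (m.alleles[:, core] == allele).sum() < 2:
                    continue
                (bl, bel), (br, ber) = brute_ehh_curve(m, core, allele, 0.05)
                c = ehh_curve(m, core, allele, 0.05)
                assert np.array_equal(bl, c.left)
                assert np.array_equal(br, c.right)
                assert (bel, ber) == (c.edge_left, c.edge_right)


class TestIhh:
    def test_trapezoid_single_segment(self):
        # EHH 1.0 at 0 bp, 0.5 at 100 bp, then truncated: area 75
        m = matrix_from_rows(
            [[1, 0], [1, 0], [1, 0], [1, 1], [0, 0], [0, 0]],
            positions=[1, 101],
        )
        curve = ehh_curve(m, 0, 1, ehh_cutoff=0.6)  # 0.5 is the below-cutoff point
        assert curve.right[1, 1] == 0.5
        arm_area = np.trapezoid(curve.right[:, 1], curve.right[:, 0])
        assert arm_area == 75.0

    def test_flat_curve_integrates_to_span(self):
        m = matrix_from_rows(
            [[1] * 3, [1] * 3, [0] * 3, [0] * 3], positions=[1, 500, 1001]
        )
        curve = ehh_curve(m, 0, 1)
        assert ihh(curve) == 1000.0

    def test_immediately_truncated_curve_is_zero(self):
        m = matrix_from_rows([[1, 0], [1, 1], [0, 0], [0, 1]], positions=[1, 2])
        curve = ehh_curve(m, 1, 0)
        # single extension point with EHH 0 on the left arm; right arm empty
        assert ihh(curve) == pytest.approx(0.5)  # trapezoid over 1 bp to EHH 0


class TestIhs:
    def test_symmetric_configuration_gives_zero(self):
        # relabeling 0<->1 maps carriers onto each other exactly
        rows = [[1, 1, 0, 1], [1, 1, 1, 0], [0, 0, 1, 0], [0, 0, 0, 1]]
        m = matrix_from_rows(rows)
        cfg = ScanConfig(truncation_policy="clip", maf_floor=0.0)
        s = ihs_unstandardized(m, 1, cfg)
        assert s.valid and s.raw == pytest.approx(0.0)

    def test_sweep_gives_negative_raw_at_core(self):
        from panscan.simulate import PanelConfig, SweepConfig, \
            generate_neutral_panel, implant_sweep

        panel = generate_neutral_panel(PanelConfig(n_haplotypes=60, n_sites=600,
                                                   seed=42))
        swept = implant_sweep(
            panel, SweepConfig(core_index=300, halfwidth_sites=80,
                               template_noise=0.0, seed=43)
        )
        s = ihs_unstandardized(swept, 300)
        assert s.valid and s.raw < 0

    def test_maf_floor_skips_rare_core(self):
        m = matrix_from_rows([[1] + [0] * 5] + [[0] * 6] * 49)
        s = ihs_unstandardized(m, 0, ScanConfig(maf_floor=0.05))
        assert not s.valid

    def test_relabeling_negates_raw(self, rng):
        cfg = ScanConfig(truncation_policy="clip", maf_floor=0.0)
        done = 0
        for _ in range(50):
            m = random_matrix(rng, 8, 10)
            core = 5
            counts = m.alleles[:, core].sum()
            if counts < 2 or counts > 6:
                continue
            s = ihs_unstandardized(m, core, cfg)
            flipped = HaplotypeMatrix(1 - m.alleles, m.positions)
            sf = ihs_unstandardized(flipped, core, cfg)
            if s.valid and sf.valid:
                assert sf.raw == pytest.approx(-s.raw)
                done += 1
        assert done > 10


class TestSl:
    def test_identical_pair_spans_chromosome(self):
        m = matrix_from_rows([[1, 0, 1, 1, 0]] * 2 + [[0, 1, 0, 0, 1]] * 2)
        assert sl_statistic(m, 2, 1) == 5.0

    def test_pair_identical_only_at_core(self):
        m = matrix_from_rows([[0, 1, 0], [1, 1, 1], [0, 0, 1], [1, 0, 0]])
        assert sl_statistic(m, 1, 1) == 1.0

    def test_three_carriers_mean_of_pairwise(self):
        rows = [
            [1, 1, 0, 0, 0],
            [1, 1, 0, 1, 0],
            [0, 1, 1, 1, 0],
            [0, 0, 0, 0, 1],
        ]
        m = matrix_from_rows(rows)
        # around core site 1: pair (0,1) shares sites 0-2 (L=3); pairs (0,2)
        # and (1,2) mismatch immediately on both arms (L=1)
        assert sl_statistic(m, 1, 1) == pytest.approx((3 + 1 + 1) / 3)

    def test_matches_pair_scan_oracle_exactly(self, rng):
        for _ in range(100):
            m = random_matrix(rng, int(rng.integers(4, 7)), int(rng.integers(2, 11)))
            core = int(rng.integers(m.n_site))
            for allele in (0, 1):
                if (m.alleles[:, core] == allele).sum() < 2:
                    continue
                assert brute_sl(m, core, allele) == sl_statistic(m, core, allele)

    def test_nsl_single_ancestral_carrier_invalid(self):
        m = matrix_from_rows([[0, 1, 1], [1, 1, 0], [1, 0, 1], [1, 1, 1]])
        s = nsl_unstandardized(m, 0, ScanConfig(maf_floor=0.0))
        assert not s.valid

    def test_nsl_symmetric_configuration_zero(self):
        rows = [[1, 1, 0, 1], [1, 1, 1, 0], [0, 0, 1, 0], [0, 0, 0, 1]]
        m = matrix_from_rows(rows)
        s = nsl_unstandardized(m, 1, ScanConfig(maf_floor=0.0))
        assert s.valid and s.raw == pytest.approx(0.0)


def make_scores(raws, dafs):
    return [
        SiteScore(i, 10 * (i + 1), d, r, "ihs", True)
        for i, (r, d) in enumerate(zip(raws, dafs))
    ]


class TestStandardize:
    def test_single_bin_two_scores(self):
        out = standardize(make_scores([1.0, 3.0], [0.5, 0.5]),
                          n_daf_bins=1, min_bin_count=1)
        assert [s.z for s in out] == [-1.0, 1.0]

    def test_constant_raws_give_zero_z(self):
        out = standardize(make_scores([2.0] * 5, [0.3] * 5),
                          n_daf_bins=1, min_bin_count=1)
        assert all(s.z == 0.0 for s in out)

    def test_moments_within_every_bin(self, rng):
        dafs = rng.uniform(0.05, 0.95, size=500)
        raws = rng.normal(size=500) + 2 * dafs
        out = standardize(make_scores(raws, dafs), n_daf_bins=20, min_bin_count=15)
        zs = {}
        for s in out:
            zs.setdefault(s.bin_index, []).append(s.z)
        for bin_z in zs.values():
            arr = np.array(bin_z)
            if arr.std() > 0:
                assert abs(arr.mean()) < 1e-9
                assert abs(arr.std() - 1) < 1e-9

    def test_small_bins_merged_to_floor(self, rng):
        dafs = np.concatenate([rng.uniform(0.4, 0.6, 300), [0.02, 0.98]])
        raws = rng.normal(size=302)
        out = standardize(make_scores(raws, dafs), n_daf_bins=50, min_bin_count=20)
        from collections import Counter

        counts = Counter(s.bin_index for s in out if s.valid)
        assert all(c >= 20 or len(counts) == 1 for c in counts.values())

    def test_invalid_scores_pass_through(self):
        scores = make_scores([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        scores.append(SiteScore(3, 40, 0.5, math.nan, "ihs", False))
        out = standardize(scores, n_daf_bins=1, min_bin_count=1)
        assert not out[-1].valid and math.isnan(out[-1].z)
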