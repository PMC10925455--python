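import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zonescore import (
    CellGeometry, INTRA_NEG, INTRA_POS, NoTumorError, PERI_NEG, PERI_POS,
    ZonePartition, classify_zones, digital_k17_score, estimate_cell_count,
    scores_to_frame, zone_scores,
)

from conftest import BG, TP, TN, CD8, CD16, make_mask, random_tumor_mask


class TestEstimateCellCount:
    def test_zero_pixels(self):
        assert estimate_cell_count(0, "lymphocyte", 0.346) == 0.0

    def test_lymphocyte_hand_value(self):
        # 420 px * 0.346^2 um^2/px / (pi * 4^2 um^2) = 1.0003 cells
        got = estimate_cell_count(420, "lymphocyte", 0.346)
        expected = 420 * 0.346 ** 2 / (math.pi * 4.0 ** 2)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.0003, abs=5e-4)

    def test_macrophage_hand_value_and_area_ratio(self):
        got = estimate_cell_count(1680, "macrophage", 0.346)
        assert got == pytest.approx(1.0003, abs=5e-4)
        # a 16 um disk covers exactly 4x the area of an 8 um disk
        assert estimate_cell_count(400, "lymphocyte", 1.0) == pytest.approx(
            4 * estimate_cell_count(400, "macrophage", 1.0), rel=1e-12
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        px=st.integers(min_value=0, max_value=10 ** 6),
        k=st.integers(min_value=1, max_value=20),
        res=st.floats(min_value=0.05, max_value=10.0),
    )
    def test_linear_in_pixels_quadratic_in_resolution(self, px, k, res):
        one = estimate_cell_count(px, "lymphocyte", res)
        assert estimate_cell_count(k * px, "lymphocyte", res) == pytest.approx(
            k * one, rel=1e-12
        )
        assert estimate_cell_count(px, "lymphocyte", 2 * res) == pytest.approx(
            4 * one, rel=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_cell_count(-1, "lymphocyte", 1.0)
        with pytest.raises(ValueError):
            estimate_cell_count(1, "dendritic", 1.0)
        with pytest.raises(ValueError):
            CellGeometry(lymphocyte_diameter_um=0.0)


def _manual_partition(zone, resolution=1.0, band=25.0):
    zone = np.asarray(zone, dtype=np.uint8)
    inf = np.full(zone.shape, np.inf)
    return ZonePartition(zone=zone, band_depth_um=band, dist_pos_um=inf,
                         dist_neg_um=inf, resolution_um_per_px=resolution)


class TestZoneScores:
    def test_no_immune_pixels_gives_zero_scores(self, rng):
        m = random_tumor_mask(rng, shape=(40, 40), p_immune=0.0)
        p = classify_zones(m, band_depth_um=5.0)
        scores = [s for s in zone_scores(m, p)]
        assert len(scores) == 8  # 4 markers x 2 compartments
        for s in scores:
            assert s.cell_count_pos == 0.0 and s.cell_count_neg == 0.0
            if s.zone_area_pos_um2 > 0:
                assert s.zs_pos == 0.0

    def test_constructed_two_to_one_ratio(self):
        # 100 px in each peritumoral zone; 40 CD8 px in NEG vs 20 in POS
        zone = np.full((20, 10), 0, dtype=np.uint8)
        zone[0:10, :] = PERI_POS
        zone[10:20, :] = PERI_NEG
        pix = np.full((20, 10), BG)
        pix[0, 0:10] = CD8
        pix[1, 0:10] = CD8
        pix[10:14, 0:10] = CD8
        part = _manual_partition(zone)
        m = make_mask(pix)
        s = next(x for x in zone_scores(m, part)
                 if x.marker == "cd8" and x.compartment == "peritumoral")
        assert s.ratio_neg_over_pos == pytest.approx(2.0, rel=1e-12)
        assert s.ratio_defined

    def test_uniform_density_gives_unit_ratio(self, rng):
        m = random_tumor_mask(rng, shape=(80, 80), p_immune=0.0)
        p = classify_zones(m, band_depth_um=8.0)
        pix = m.pixels.copy()
        pix[(p.zone == PERI_POS) | (p.zone == PERI_NEG)] = CD8
        m2 = make_mask(pix)
        s = next(x for x in zone_scores(m2, p)
                 if x.marker == "cd8" and x.compartment == "peritumoral")
        assert s.ratio_neg_over_pos == pytest.approx(1.0, rel=1e-12)

    def test_counts_sum_to_total_in_band_estimate(self, rng):
        m = random_tumor_mask(rng, shape=(60, 60))
        p = classify_zones(m, band_depth_um=6.0)
        for s in zone_scores(m, p):
            kind = m.scheme.marker_kind[s.marker]
            total = estimate_cell_count(
                s.pixel_count_pos + s.pixel_count_neg, kind, 1.0
            )
            assert s.cell_count_pos + s.cell_count_neg == pytest.approx(
                total, rel=1e-12
            )

    def test_doubling_zone_area_halves_density(self):
        zone_small = np.full((1, 30), 0, dtype=np.uint8)
        zone_small[0, :10] = PERI_POS
        zone_big = np.full((1, 30), 0, dtype=np.uint8)
        zone_big[0, :20] = PERI_POS
        pix = np.full((1, 30), BG)
        pix[0, :5] = CD8
        m = make_mask(pix)
        s_small = next(x for x in zone_scores(m, _manual_partition(zone_small))
                       if x.marker == "cd8" and x.compartment == "peritumoral")
        s_big = next(x for x in zone_scores(m, _manual_partition(zone_big))
                     if x.marker == "cd8" and x.compartment == "peritumoral")
        assert s_big.zs_pos == pytest.approx(s_small.zs_pos / 2, rel=1e-12)

    def test_empty_zone_yields_sentinel(self):
        zone = np.full((5, 5), 0, dtype=np.uint8)
        zone[0] = PERI_POS  # no PERI_NEG anywhere
        pix = np.full((5, 5), BG)
        pix[0, 0] = CD8
        s = next(x for x in zone_scores(make_mask(pix), _manual_partition(zone))
                 if x.marker == "cd8" and x.compartment == "peritumoral")
        assert not s.ratio_defined
        assert np.isnan(s.ratio_neg_over_pos)
        assert np.isnan(s.zs_neg)

    def test_shape_mismatch_rejected(self, rng):
        m = random_tumor_mask(rng, shape=(20, 20))
        p = classify_zones(m, band_depth_um=4.0)
        m2 = random_tumor_mask(rng, shape=(10, 10))
        with pytest.raises(ValueError, match="shape"):
            zone_scores(m2, p)

    def test_label_swap_reciprocal_ratio(self, rng):
        m = random_tumor_mask(rng, shape=(60, 60), p_immune=0.08)
        p = classify_zones(m, band_depth_um=8.0, tie_break="pos")
        swapped = m.pixels.copy()
        swapped[m.pixels == TP] = TN
        swapped[m.pixels == TN] = TP
        m2 = make_mask(swapped)
        q = classify_zones(m2, band_depth_um=8.0, tie_break="neg")
        ref = {(s.marker, s.compartment): s for s in zone_scores(m, p)}
        for s in zone_scores(m2, q):
            r = ref[(s.marker, s.compartment)]
            if s.ratio_defined and r.ratio_defined:
                assert s.ratio_neg_over_pos == pytest.approx(
                    1.0 / r.ratio_neg_over_pos, rel=1e-12
                )

    def test_long_format_frame(self, rng):
        m = random_tumor_mask(rng, shape=(30, 30))
        p = classify_zones(m, band_depth_um=5.0)
        df = scores_to_frame(zone_scores(m, p))
        assert len(df) == 8
        assert {"case_id", "marker", "compartment", "depth_um",
                "zs_pos", "zs_neg", "ratio_neg_over_pos",
                "ratio_defined"} <= set(df.columns)


class TestDigitalK17:
    def test_pure_masks(self):
        assert digital_k17_score(make_mask(np.full((4, 4), TP))) == 1.0
        assert digital_k17_score(make_mask(np.full((4, 4), TN))) == 0.0

    def test_area_fraction(self):
        pix = np.full((40, 25), BG)
        flat = pix.ravel()
        flat[:600] = TP
        flat[600:1000] = TN
        assert digital_k17_score(make_mask(flat.reshape(40, 25))) == 0.6

    def test_no_tumor_raises(self):
        with pytest.raises(NoTumorError):
            digital_k17_score(make_mask(np.full((4, 4), BG)))
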