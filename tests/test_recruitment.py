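"""Vertical ROI partitions, tidal recruitment, intratidal changes, and
regional profiles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from lungstrain import aeration, phantom, recruitment as rec
from lungstrain.aeration import AerationCategoryMasses
from lungstrain.core_io import AerationMap, LungMask, StrainMap


def _box_mask(shape=(10, 40, 8), spacing=(1.0, 1.0, 2.5)):
    return LungMask(data=np.ones(shape), spacing=spacing)


class TestVerticalRois:
    def test_returns_n_regions(self):
        part = rec.vertical_rois(_box_mask(), 10)
        assert part.n == 10

    def test_exact_division(self):
        """40 rows split into 10 ROIs: every slab spans 4 rows."""
        part = rec.vertical_rois(_box_mask((10, 40, 8)), 10)
        heights = [hi - lo for lo, hi in part.row_bounds]
        assert heights == [4] * 10

    def test_remainder_assigned_dorsal_first(self):
        """43 rows into 10 ROIs: heights 5,5,5,4,... from the dorsal end."""
        part = rec.vertical_rois(_box_mask((6, 43, 6)), 10)
        heights = [hi - lo for lo, hi in part.row_bounds]
        assert heights == [5, 5, 5, 4, 4, 4, 4, 4, 4, 4]

    def test_partition_is_disjoint_and_exhaustive(self, noiseless_case):
        part = rec.vertical_rois(noiseless_case.ee_mask, 10)
        union = np.zeros_like(noiseless_case.ee_mask.data, dtype=int)
        for roi in part.masks:
            union += roi.astype(int)
        assert union.max() == 1
        np.testing.assert_array_equal(union > 0, noiseless_case.ee_mask.data)

    @given(n=st.integers(1, 12), extent=st.integers(12, 40))
    def test_heights_differ_by_at_most_one(self, n, extent):
        mask = _box_mask((4, extent, 4))
        part = rec.vertical_rois(mask, n)
        heights = [hi - lo for lo, hi in part.row_bounds]
        assert sum(heights) == extent
        assert max(heights) - min(heights) <= 1

    def test_numbering_runs_dorsal_to_ventral(self):
        part = rec.vertical_rois(_box_mask((4, 20, 4)), 4)
        # ROI 1 (index 0) occupies the highest y rows (dorsal)
        assert part.row_bounds[0][1] == 20
        assert part.row_bounds[-1][0] == 0

    def test_n_exceeding_extent_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            rec.vertical_rois(_box_mask((4, 6, 4)), 10)


def _masses(non, poor=0.0, normal=0.0, hyper=0.0):
    mass = {"non": non, "poor": poor, "normal": normal, "hyper": hyper}
    total = sum(mass.values())
    return AerationCategoryMasses(
        mass_g=mass,
        percent={k: 100 * v / total for k, v in mass.items()},
        total_mass_g=total,
        gas_volume_ml=0.0,
    )


class TestTidalRecruitment:
    def test_direct_arithmetic(self):
        """Non-aerated 10 g at EE, 7 g at EI, 100 g lung: TR = 3 %."""
        ee = _masses(non=10.0, poor=40.0, normal=50.0)
        ei = _masses(non=7.0, poor=40.0, normal=53.0)
        assert rec.tidal_recruitment(ee, ei) == pytest.approx(0.03)

    def test_identical_summaries_give_zero(self):
        m = _masses(non=5.0, poor=20.0, normal=30.0)
        assert rec.tidal_recruitment(m, m) == 0.0

    def test_mean_denominator_option(self):
        ee = _masses(non=10.0, normal=90.0)
        ei = _masses(non=6.0, normal=114.0)  # total 120
        assert rec.tidal_recruitment(ee, ei, denominator="mean") == pytest.approx(
            4.0 / 110.0
        )

    @pytest.mark.parametrize("target", [0.0, 0.02, 0.05])
    def test_pipeline_recovery_on_phantoms(self, target):
        """Full aeration pipeline recovers the phantom's recruited mass
        fraction within +-0.01 under the default noise conditions."""
        case = phantom.generate(phantom.PhantomSpec(recruit_mass_fraction=target))
        fe = aeration.hu_to_fgas(case.ee, case.ee_mask)
        fi = aeration.hu_to_fgas(case.ei, case.ei_mask)
        tr = rec.tidal_recruitment(
            aeration.mass_summary(fe), aeration.mass_summary(fi)
        )
        assert tr == pytest.approx(case.truth.recruited_mass_fraction, abs=0.01)


class TestRegionalRecruitment:
    def _case_maps(self, target):
        case = phantom.generate(
            phantom.PhantomSpec(hu_noise_sd=0.0, recruit_mass_fraction=target)
        )
        fe = aeration.hu_to_fgas(case.ee, case.ee_mask)
        fi = aeration.hu_to_fgas(case.ei, case.ei_mask)
        return case, fe, fi

    def test_recruitment_confined_to_block_rois(self):
        case, fe, fi = self._case_maps(0.05)
        part_ee = rec.vertical_rois(case.ee_mask, 10)
        part_ei = rec.vertical_rois(case.ei_mask, 10)
        regional = rec.regional_recruitment(fe, fi, part_ee, part_ei)
        block_rows = np.where(case.truth.recruitment_block.any(axis=(0, 2)))[0]
        block_rois = {
            k for k, (lo, hi) in enumerate(part_ee.row_bounds)
            if np.any((block_rows >= lo) & (block_rows < hi))
        }
        for k, value in enumerate(regional):
            if k in block_rois:
                continue
            assert abs(value) < 0.02

    def test_null_case_near_zero(self):
        case, fe, fi = self._case_maps(0.0)
        part_ee = rec.vertical_rois(case.ee_mask, 10)
        part_ei = rec.vertical_rois(case.ei_mask, 10)
        regional = rec.regional_recruitment(fe, fi, part_ee, part_ei)
        assert np.all(np.abs(regional) < 0.02)

    def test_mass_weighted_average_recovers_whole_lung_tr(self):
        """With a common partition basis, the ROI-mass-weighted mean of
        regional recruitment equals the whole-lung value to 1e-9."""
        case, fe, fi = self._case_maps(0.05)
        part = rec.vertical_rois(case.ee_mask, 10)
        # same partition for both phases -> exact algebraic identity
        regional = rec.regional_recruitment(fe, fi, part, part)
        weights = np.array(
            [
                aeration.mass_summary(
                    AerationMap(data=fe.data, spacing=fe.spacing, mask=roi)
                ).total_mass_g
                for roi in part.masks
            ]
        )
        combined = float((regional * weights).sum() / weights.sum())
        fi_on_ee = AerationMap(data=fi.data, spacing=fi.spacing, mask=case.ee_mask.data)
        whole = rec.tidal_recruitment(
            aeration.mass_summary(fe), aeration.mass_summary(fi_on_ee)
        )
        assert combined == pytest.approx(whole, abs=1e-9)


class TestIntratidalChange:
    def test_identical_summaries_zero_change(self):
        m = _masses(non=5.0, poor=20.0, normal=30.0)
        table = rec.intratidal_change(m, m)
        assert np.all(table["delta_g"] == 0.0)

    def test_delta_sums_to_total_mass_change(self):
        ee = _masses(non=10.0, poor=40.0, normal=50.0)
        ei = _masses(non=6.0, poor=35.0, normal=57.0, hyper=1.0)
        table = rec.intratidal_change(ee, ei)
        assert table["delta_g"].sum() == pytest.approx(
            ei.total_mass_g - ee.total_mass_g
        )

    def test_default_phantom_pattern(self, noiseless_case):
        """Expansion without recruitment moves mass out of the poorly- and
        into the normally-aerated compartment."""
        fe = aeration.hu_to_fgas(noiseless_case.ee, noiseless_case.ee_mask)
        fi = aeration.hu_to_fgas(noiseless_case.ei, noiseless_case.ei_mask)
        table = rec.intratidal_change(
            aeration.mass_summary(fe), aeration.mass_summary(fi)
        )
        assert table.loc["normal", "delta_g"] > 0
        assert table.loc["poor", "delta_g"] < 0


class TestRoiProfile:
    def test_uniform_aeration_equal_means(self):
        mask = _box_mask((6, 30, 6))
        amap = AerationMap(
            data=np.full((6, 30, 6), 0.42), spacing=mask.spacing, mask=mask.data
        )
        prof = rec.roi_profile(rec.vertical_rois(mask, 5), amap)
        assert np.allclose(prof["mean_fgas"], 0.42)

    def test_gradient_gives_monotone_profile(self, noiseless_case):
        """With the ventral-to-dorsal aeration gradient, ROI mean aeration
        decreases strictly from ROI 10 (ventral) to ROI 1 (dorsal)."""
        fe = aeration.hu_to_fgas(noiseless_case.ee, noiseless_case.ee_mask)
        prof = rec.roi_profile(rec.vertical_rois(noiseless_case.ee_mask, 10), fe)
        means = prof["mean_fgas"].to_numpy()  # index 0 = ROI 1 (dorsal)
        assert np.all(np.diff(means) > 0)

    def test_stretch_peak_strain_in_dorsal_half(self, noiseless_case):
        """Median strain peaks in the dorsal half of the lung where the
        stretch is applied."""
        em = ndimage.binary_erosion(noiseless_case.ee_mask.data)
        smap = StrainMap(
            data=noiseless_case.truth.jacobian - 1.0,
            spacing=noiseless_case.ee.spacing, mask=em,
        )
        fe = aeration.hu_to_fgas(noiseless_case.ee, noiseless_case.ee_mask)
        prof = rec.roi_profile(
            rec.vertical_rois(noiseless_case.ee_mask, 10), fe, smap
        )
        peak_roi = prof["median_strain"].idxmax()  # ROI numbering, 1 = dorsal
        assert peak_roi <= 6
        assert prof.loc[peak_roi, "median_strain"] > prof.loc[10, "median_strain"]
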