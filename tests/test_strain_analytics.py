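"""Strain summaries, EI-aeration pull-back, strain-aeration joint
structure, and parametric response maps."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from lungstrain import aeration, phantom, strain_analytics as sa
from lungstrain.core_io import AerationMap, DisplacementField, StrainMap


def _uniform_strain(value, shape=(8, 8, 4), spacing=(1, 1, 2.5)):
    return StrainMap(
        data=np.full(shape, float(value)), spacing=spacing,
        mask=np.ones(shape, dtype=bool),
    )


class TestStrainSummary:
    def test_uniform(self):
        s = sa.strain_summary(_uniform_strain(0.2))
        assert (s.mean, s.p95, s.cov) == pytest.approx((0.2, 0.2, 0.0))

    def test_zero_mean_flagged(self):
        smap = _uniform_strain(0.0)
        smap.data[:4] = 0.3
        smap.data[4:] = -0.3
        with pytest.raises(ValueError, match="zero"):
            sa.strain_summary(smap)

    def test_phantom_mean_matches_truth(self, noiseless_case):
        """The mean of the analytic strain map equals the volume-weighted
        true mean by construction (sanity anchor for downstream use)."""
        em = ndimage.binary_erosion(noiseless_case.ee_mask.data)
        smap = StrainMap(
            data=noiseless_case.truth.jacobian - 1.0,
            spacing=noiseless_case.ee.spacing, mask=em,
        )
        s = sa.strain_summary(smap)
        true_mean = (noiseless_case.truth.jacobian - 1.0)[em].mean()
        assert s.mean == pytest.approx(true_mean, abs=1e-12)


class TestRegionalStrain:
    def test_median_robustness(self):
        smap = _uniform_strain(0.0, shape=(3, 2, 2))
        smap.data[:, 0, 0] = [0.1, 0.2, 0.9]
        region = np.zeros((3, 2, 2), dtype=bool)
        region[:, 0, 0] = True
        assert sa.regional_strain(smap, region) == pytest.approx(0.2)

    def test_whole_mask_consistency(self):
        rng = np.random.default_rng(2)
        smap = _uniform_strain(0.0)
        smap.data = rng.uniform(-0.1, 0.5, smap.data.shape)
        assert sa.regional_strain(smap, smap.mask) == pytest.approx(
            np.median(smap.in_mask())
        )

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sa.regional_strain(_uniform_strain(0.1), np.zeros((8, 8, 4), dtype=bool))

    def test_dorsal_stretch_region_has_higher_median(self, noiseless_case):
        """The stretched (dorsal-of-center) half of the phantom carries
        more strain than the unstretched ventral half."""
        em = ndimage.binary_erosion(noiseless_case.ee_mask.data)
        smap = StrainMap(
            data=noiseless_case.truth.jacobian - 1.0,
            spacing=noiseless_case.ee.spacing, mask=em,
        )
        ny = noiseless_case.ee.shape[1]
        dorsal = np.zeros_like(em)
        dorsal[:, ny // 2:, :] = True
        ventral = ~dorsal
        assert sa.regional_strain(smap, dorsal & em) > sa.regional_strain(
            smap, ventral & em
        )


class TestPullBack:
    def _amap(self, data, spacing=(1, 1, 1)):
        return AerationMap(
            data=data, spacing=spacing, mask=np.ones(data.shape, dtype=bool)
        )

    def test_identity_field(self):
        rng = np.random.default_rng(0)
        amap = self._amap(rng.uniform(0, 1, (10, 10, 6)))
        fld = DisplacementField(data=np.zeros((10, 10, 6, 3)), spacing=(1, 1, 1))
        pulled, n_out = sa.ei_aeration_on_ee_grid(amap, fld, amap.mask)
        np.testing.assert_allclose(pulled.data, amap.data, atol=1e-12)
        assert n_out == 0

    def test_shift_equivariance(self):
        """A uniform one-voxel translation shifts the map accordingly."""
        rng = np.random.default_rng(1)
        data = rng.uniform(0, 1, (12, 10, 6))
        amap = self._amap(data)
        u = np.zeros((12, 10, 6, 3))
        u[..., 0] = 1.0  # +1 voxel along x (1 mm spacing)
        fld = DisplacementField(data=u, spacing=(1, 1, 1))
        pulled, _ = sa.ei_aeration_on_ee_grid(amap, fld, amap.mask)
        np.testing.assert_allclose(pulled.data[:-1], data[1:], atol=1e-12)

    def test_phantom_transport_oracle(self, noiseless_case):
        """Pulling EI aeration back through the true field reproduces the
        analytic mass-transport prediction to MAE < 0.02."""
        fi = aeration.hu_to_fgas(noiseless_case.ei, noiseless_case.ei_mask)
        pulled, _ = sa.ei_aeration_on_ee_grid(
            fi, noiseless_case.truth.field, noiseless_case.ee_mask.data
        )
        fe = aeration.hu_to_fgas(noiseless_case.ee, noiseless_case.ee_mask)
        predicted = 1.0 - (1.0 - fe.data) / noiseless_case.truth.jacobian
        interior = ndimage.binary_erosion(noiseless_case.ee_mask.data, iterations=2)
        mae = np.abs(pulled.data - predicted)[interior].mean()
        assert mae < 0.02


class TestStrainVsAeration:
    def _pair(self, strain_vals, fgas_vals):
        n = len(strain_vals)
        shape = (n, 2, 2)
        mask = np.zeros(shape, dtype=bool)
        mask[:, 0, 0] = True
        sdata = np.zeros(shape)
        sdata[:, 0, 0] = strain_vals
        gdata = np.zeros(shape)
        gdata[:, 0, 0] = fgas_vals
        return (
            StrainMap(data=sdata, spacing=(1, 1, 1), mask=mask),
            AerationMap(data=gdata, spacing=(1, 1, 1), mask=mask),
        )

    def test_constant_strain(self):
        smap, amap = self._pair([0.1] * 40, np.linspace(0.15, 0.95, 40))
        joint = sa.strain_vs_aeration(smap, amap)
        for interval in joint.intervals:
            if interval.count:
                assert interval.median == pytest.approx(0.1)
                assert interval.iqr[1] - interval.iqr[0] == pytest.approx(0.0)

    def test_constructed_inverted_u(self):
        """Strain peaked at aeration 0.6 reproduces the inverted-U
        ordering of interval medians."""
        g = np.linspace(0.12, 0.99, 300)
        s = 0.4 * np.exp(-((g - 0.6) ** 2) / 0.05)
        smap, amap = self._pair(s, g)
        joint = sa.strain_vs_aeration(smap, amap)
        medians = [i.median for i in joint.intervals if i.median is not None]
        peak = np.argmax(medians)
        assert 0 < peak < len(medians) - 1  # interior maximum
        assert medians[0] < medians[peak] > medians[-1]

    def test_counts_partition_aerated_voxels(self):
        rng = np.random.default_rng(4)
        g = rng.uniform(0, 1, 200)
        s = rng.uniform(0, 0.4, 200)
        smap, amap = self._pair(s, g)
        joint = sa.strain_vs_aeration(smap, amap)
        assert sum(i.count for i in joint.intervals) == joint.n_aerated
        assert joint.n_aerated == int((g > 0.1).sum())

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        g = rng.uniform(0.1, 1, 100)
        s = rng.uniform(0, 0.4, 100)
        perm = rng.permutation(100)
        j1 = sa.strain_vs_aeration(*self._pair(s, g))
        j2 = sa.strain_vs_aeration(*self._pair(s[perm], g[perm]))
        for a, b in zip(j1.intervals, j2.intervals):
            assert a.median == b.median and a.count == b.count


class TestPrm:
    def _maps(self, ge, gi, s):
        n = len(ge)
        shape = (n, 2, 2)
        mask = np.zeros(shape, dtype=bool)
        mask[:, 0, 0] = True

        def build(vals, cls, **kw):
            data = np.zeros(shape)
            data[:, 0, 0] = vals
            return cls(data=data, spacing=(1, 1, 1), mask=mask, **kw)

        return (
            build(ge, AerationMap),
            build(gi, AerationMap),
            build(s, StrainMap),
        )

    def test_identity_pair_is_diagonal(self):
        g = np.linspace(0.0, 1.0, 150)
        maps = self._maps(g, g, np.zeros_like(g) + 0.1)
        result = sa.prm(*maps)
        ee_bins, ei_bins = np.nonzero(result.volume_fraction)
        assert np.all(ee_bins == ei_bins)

    def test_fgas_one_falls_in_last_bin(self):
        maps = self._maps([1.0, 0.5], [1.0, 0.5], [0.1, 0.1])
        result = sa.prm(*maps)
        assert result.volume_fraction[99, 99] > 0
        assert result.volume_fraction.shape == (100, 100)

    def test_reported_bins_meet_threshold(self, noiseless_case):
        fe = aeration.hu_to_fgas(noiseless_case.ee, noiseless_case.ee_mask)
        fi = aeration.hu_to_fgas(noiseless_case.ei, noiseless_case.ei_mask)
        pulled, _ = sa.ei_aeration_on_ee_grid(
            fi, noiseless_case.truth.field, noiseless_case.ee_mask.data
        )
        em = ndimage.binary_erosion(noiseless_case.ee_mask.data)
        smap = StrainMap(
            data=noiseless_case.truth.jacobian - 1.0,
            spacing=noiseless_case.ee.spacing, mask=em,
        )
        result = sa.prm(fe, pulled, smap)
        assert np.all(result.volume_fraction[result.reported] >= 0.0005)
        assert result.volume_fraction.sum() == pytest.approx(1.0)

    def test_mean_strain_per_bin(self):
        ge = [0.205, 0.205, 0.805]
        gi = [0.305, 0.305, 0.905]
        s = [0.1, 0.3, 0.5]
        result = sa.prm(*self._maps(ge, gi, s))
        assert result.mean_strain[20, 30] == pytest.approx(0.2)
        assert result.mean_strain[80, 90] == pytest.approx(0.5)


class TestDeltaAeration:
    def test_reference_arithmetic(self):
        assert sa.delta_aeration(0.514, 0.456) == pytest.approx(0.058)

    def test_equal_means(self):
        assert sa.delta_aeration(0.4, 0.4) == 0.0

    def test_antisymmetry(self):
        assert sa.delta_aeration(0.5, 0.3) == -sa.delta_aeration(0.3, 0.5)
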