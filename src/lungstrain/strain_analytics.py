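"""Whole-lung and conditional strain statistics, strain-aeration joint
structure, and strain-colored parametric response maps.

Strain lives on the end-expiratory (EE) grid; end-inspiratory (EI)
aeration is pulled back onto the EE grid through the registration
transform so voxel-level strain and EI aeration can be compared at
corresponding tissue. The parametric response map (PRM) bins paired
EE/EI gas fractions on a 100 x 100 grid over [0, 1] and reports, per
occupied bin, the fraction of lung volume and the mean strain; bins
holding less than 0.05 % of the lung volume are suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .aeration import percentile95
from .core_io import AerationMap, DisplacementField, StrainMap, require_same_geometry

__all__ = [
    "AERATION_INTERVALS",
    "StrainSummary",
    "StrainAerationJoint",
    "ParametricResponseMap",
    "strain_summary",
    "regional_strain",
    "ei_aeration_on_ee_grid",
    "strain_vs_aeration",
    "prm",
    "delta_aeration",
]

#: end-inspiratory aeration intervals used for conditional strain
#: summaries; (low, high] ... the last interval is open-ended above 0.9
AERATION_INTERVALS = ((0.1, 0.3), (0.3, 0.5), (0.5, 0.7), (0.7, 0.9), (0.9, np.inf))


@dataclass
class StrainSummary:
    mean: float
    p95: float
    cov: float  # SD normalized by the global (mean) strain


@dataclass
class IntervalSummary:
    interval: tuple[float, float]
    median: float | None
    iqr: tuple[float, float] | None
    count: int


@dataclass
class StrainAerationJoint:
    """Per-aeration-interval strain summaries plus a 2-D histogram of
    (strain, EI aeration) over voxels between the 5th and 95th strain
    percentiles."""

    intervals: list[IntervalSummary]
    hist: np.ndarray  # (n_strain_bins, n_aeration_bins) volume fractions
    strain_edges: np.ndarray
    aeration_edges: np.ndarray
    n_aerated: int  # voxels with F_gas > 0.1 considered


@dataclass
class ParametricResponseMap:
    volume_fraction: np.ndarray  # (100, 100): EE bins x EI bins
    mean_strain: np.ndarray  # NaN where empty
    occupancy_threshold: float
    reported: np.ndarray  # boolean: occupied at/above threshold

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.volume_fraction.shape[0] + 1)


def strain_summary(strain: StrainMap) -> StrainSummary:
    """Mean, 95th percentile, and coefficient of variation of in-mask strain.

    The CoV is normalized by the global strain, taken as the mean of all
    in-mask voxels; it is undefined (error) for zero mean strain.
    """
    values = strain.in_mask()
    if values.size == 0:
        raise ValueError("empty mask")
    mean = float(values.mean())
    p95 = percentile95(strain)
    if mean == 0.0:
        raise ValueError("mean strain is zero; coefficient of variation undefined")
    cov = float(values.std(ddof=0) / mean)
    return StrainSummary(mean=mean, p95=p95, cov=cov)


def regional_strain(strain: StrainMap, region_mask: np.ndarray) -> float:
    """Median volumetric strain of the voxels within a regional mask."""
    region = np.asarray(region_mask) > 0
    sel = strain.data[region & strain.mask]
    if sel.size == 0:
        raise ValueError("empty region")
    return float(np.median(sel))


def ei_aeration_on_ee_grid(
    fgas_ei: AerationMap, fld: DisplacementField, ee_mask: np.ndarray
) -> tuple[AerationMap, int]:
    """Pull end-inspiratory aeration back to the EE grid: value at EE voxel
    x is the linear interpolation of the EI map at T(x) = x + u(x).

    Returns the pulled-back map (masked by ``ee_mask``) and the number of
    EE voxels whose target fell outside the EI grid (clamped to the
    nearest edge value).
    """
    require_same_geometry(fgas_ei, fld, "EI aeration map and field")
    spacing = np.asarray(fgas_ei.spacing)
    shape = fgas_ei.shape
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    coords = [idx[k] + fld.data[..., k] / spacing[k] for k in range(3)]
    out_of_grid = np.zeros(shape, dtype=bool)
    for k in range(3):
        out_of_grid |= (coords[k] < 0) | (coords[k] > shape[k] - 1)
    pulled = ndimage.map_coordinates(fgas_ei.data, coords, order=1, mode="nearest")
    n_outside = int((out_of_grid & np.asarray(ee_mask, dtype=bool)).sum())
    return (
        AerationMap(data=np.clip(pulled, 0.0, 1.0), spacing=fgas_ei.spacing, mask=ee_mask),
        n_outside,
    )


def strain_vs_aeration(
    strain: StrainMap,
    fgas_ei_on_ee: AerationMap,
    n_strain_bins: int = 50,
) -> StrainAerationJoint:
    """Conditional strain structure over aerated lung (F_gas > 0.1).

    Per EI-aeration interval: median strain, interquartile range and voxel
    count. The joint 2-D histogram covers voxels between the 5th and 95th
    strain percentiles, normalized to fractions of the aerated volume
    considered.
    """
    require_same_geometry(strain, fgas_ei_on_ee, "strain and aeration maps")
    mask = strain.mask & fgas_ei_on_ee.mask
    s = strain.data[mask]
    g = fgas_ei_on_ee.data[mask]
    aerated = g > 0.1
    s, g = s[aerated], g[aerated]
    intervals: list[IntervalSummary] = []
    for low, high in AERATION_INTERVALS:
        sel = (g > low) & (g <= high)
        vals = s[sel]
        if vals.size == 0:
            intervals.append(
                IntervalSummary(interval=(low, high), median=None, iqr=None, count=0)
            )
        else:
            intervals.append(
                IntervalSummary(
                    interval=(low, high),
                    median=float(np.median(vals)),
                    iqr=(
                        float(np.percentile(vals, 25)),
                        float(np.percentile(vals, 75)),
                    ),
                    count=int(vals.size),
                )
            )
    if s.size:
        s5, s95 = np.percentile(s, [5, 95])
        window = (s >= s5) & (s <= s95)
        strain_edges = np.linspace(s5, s95, n_strain_bins + 1)
    else:
        window = s.astype(bool)
        strain_edges = np.linspace(0.0, 1.0, n_strain_bins + 1)
    aeration_edges = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
    hist, _, _ = np.histogram2d(
        s[window], np.clip(g[window], None, 1.0), bins=(strain_edges, aeration_edges)
    )
    total = max(s.size, 1)
    return StrainAerationJoint(
        intervals=intervals,
        hist=hist / total,
        strain_edges=strain_edges,
        aeration_edges=aeration_edges,
        n_aerated=int(s.size),
    )


def prm(
    fgas_ee: AerationMap,
    fgas_ei_on_ee: AerationMap,
    strain: StrainMap,
    n_bins: int = 100,
    occupancy_threshold: float = 0.0005,
) -> ParametricResponseMap:
    """Parametric response map of paired EE/EI voxel aeration.

    Voxels are binned on an ``n_bins`` x ``n_bins`` grid over [0, 1] with
    half-open bins (the last bin closed at 1). Per bin: fraction of lung
    volume and mean strain. Bins holding less than ``occupancy_threshold``
    of the lung volume are left out of the reported map.
    """
    require_same_geometry(fgas_ee, fgas_ei_on_ee, "EE and pulled-back EI maps")
    require_same_geometry(fgas_ee, strain, "aeration and strain maps")
    mask = fgas_ee.mask & fgas_ei_on_ee.mask & strain.mask
    if not mask.any():
        raise ValueError("empty common mask")
    ge = fgas_ee.data[mask]
    gi = fgas_ei_on_ee.data[mask]
    s = strain.data[mask]
    # half-open bins [k/n, (k+1)/n); F_gas = 1 falls in the last bin
    ie = np.minimum((ge * n_bins).astype(int), n_bins - 1)
    ii = np.minimum((gi * n_bins).astype(int), n_bins - 1)
    flat = ie * n_bins + ii
    counts = np.bincount(flat, minlength=n_bins * n_bins).astype(float)
    ssum = np.bincount(flat, weights=s, minlength=n_bins * n_bins)
    volume_fraction = (counts / mask.sum()).reshape(n_bins, n_bins)
    with np.errstate(invalid="ignore"):
        mean_strain = np.where(counts > 0, ssum / np.maximum(counts, 1), np.nan)
    mean_strain = mean_strain.reshape(n_bins, n_bins)
    reported = volume_fraction >= occupancy_threshold
    return ParametricResponseMap(
        volume_fraction=volume_fraction,
        mean_strain=mean_strain,
        occupancy_threshold=occupancy_threshold,
        reported=reported,
    )


def delta_aeration(mean_ei: float, mean_ee: float) -> float:
    """Delta aeration: mean aeration at end-inspiration minus mean aeration
    at end-expiration."""
    return float(mean_ei) - float(mean_ee)
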