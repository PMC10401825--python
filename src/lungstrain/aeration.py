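"""Quantitative CT densitometry: gas fraction, aeration categories, mass,
end-expiratory lung volume, percentiles, and spatial heterogeneity.

Aeration is quantified as the voxel gas fraction F_gas = HU / -1000
(air = -1000 HU -> F_gas = 1; tissue = 0 HU -> F_gas = 0) and classified
into non- (F_gas < 0.1), poorly- (0.1 <= F_gas < 0.5), normally-
(0.5 <= F_gas < 0.9) and hyper-aerated (F_gas >= 0.9) compartments whose
tissue masses are expressed as percentages of total lung mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import AerationMap, CTVolume, LungMask, StrainMap, require_same_geometry

__all__ = [
    "CATEGORIES",
    "CATEGORY_BOUNDS",
    "hu_to_fgas",
    "classify",
    "mass_summary",
    "heterogeneity",
    "percentile95",
    "AerationCategoryMasses",
    "HeterogeneityResult",
]

#: aeration compartments in order of increasing gas fraction
CATEGORIES = ("non", "poor", "normal", "hyper")

#: half-open F_gas bounds [low, high); the last bin is closed at 1
CATEGORY_BOUNDS = {
    "non": (0.0, 0.1),
    "poor": (0.1, 0.5),
    "normal": (0.5, 0.9),
    "hyper": (0.9, 1.0),
}

#: tissue is assumed water-equivalent: 1 g per ml of tissue volume
TISSUE_DENSITY_G_PER_ML = 1.0


@dataclass
class AerationCategoryMasses:
    """Per-compartment tissue mass and its percentage of total lung mass."""

    mass_g: dict[str, float]
    percent: dict[str, float]
    total_mass_g: float
    gas_volume_ml: float  # EELV when computed on the end-expiratory image

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.mass_g.values()):
            raise ValueError("category masses must be non-negative")


@dataclass
class HeterogeneityResult:
    """Coefficient of variation of a map after in-plane resolution matching."""

    cov: float
    mean: float
    filter_fwhm_mm: float


def hu_to_fgas(vol: CTVolume, mask: LungMask) -> AerationMap:
    """Convert Hounsfield units to gas fraction, F_gas = HU / -1000.

    HU are clamped to [-1000, 0] first so residual dense material (vessel
    fragments, debris) inside the mask cannot yield gas fractions outside
    [0, 1]. Values outside the mask are set to 0 and are undefined.
    """
    require_same_geometry(vol, mask, "CT volume and lung mask")
    hu = np.clip(vol.data, -1000.0, 0.0)
    fgas = hu / -1000.0
    fgas[~mask.data] = 0.0
    return AerationMap(data=fgas, spacing=vol.spacing, mask=mask.data)


def classify(fgas: AerationMap) -> np.ndarray:
    """Assign each in-mask voxel to one aeration compartment.

    Returns an integer grid: -1 outside the mask, otherwise the index into
    :data:`CATEGORIES`. Bounds are half-open with the boundary value
    belonging to the upper compartment (F_gas = 0.1 is poorly aerated,
    F_gas = 0.9 is hyper-aerated).
    """
    edges = [CATEGORY_BOUNDS[c][0] for c in CATEGORIES[1:]]
    cat = np.digitize(fgas.data, edges, right=False)
    cat[~fgas.mask] = -1
    return cat


def mass_summary(fgas: AerationMap) -> AerationCategoryMasses:
    """Tissue mass per aeration compartment and total gas volume.

    Voxel tissue mass is (1 - F_gas) * voxel volume * 1 g/ml; the gas
    volume is sum(F_gas) * voxel volume, i.e. the end-expiratory lung
    volume when applied to the end-expiratory image.
    """
    if not fgas.mask.any():
        raise ValueError("empty mask")
    vvol = fgas.voxel_volume_ml
    values = fgas.in_mask()
    cat = classify(fgas)[fgas.mask]
    tissue = (1.0 - values) * vvol * TISSUE_DENSITY_G_PER_ML
    mass = {
        name: float(tissue[cat == i].sum()) for i, name in enumerate(CATEGORIES)
    }
    total = float(tissue.sum())
    if total <= 0:
        raise ValueError("total lung mass is zero")
    percent = {name: 100.0 * m / total for name, m in mass.items()}
    gas_volume = float(values.sum() * vvol)
    return AerationCategoryMasses(
        mass_g=mass, percent=percent, total_mass_g=total, gas_volume_ml=gas_volume
    )


def _masked_inplane_gaussian(
    data: np.ndarray, mask: np.ndarray, sigma_vox: tuple[float, float]
) -> np.ndarray:
    """In-plane Gaussian smoothing renormalised to the mask support."""
    if max(sigma_vox) <= 0:
        return data
    sigma = (sigma_vox[0], sigma_vox[1], 0.0)
    num = ndimage.gaussian_filter(np.where(mask, data, 0.0), sigma)
    den = ndimage.gaussian_filter(mask.astype(np.float64), sigma)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 1e-12)
    return out


def heterogeneity(
    vmap: AerationMap | StrainMap, target_fwhm_mm: float = 2.5
) -> HeterogeneityResult:
    """Spatial heterogeneity as the coefficient of variation.

    The map is first smoothed in-plane with a Gaussian so its effective
    in-plane resolution matches the slice thickness (default 2.5 mm); the
    added FWHM is sqrt(target^2 - d^2) for native in-plane spacing d (FWHM
    adds in quadrature; no smoothing along z). Heterogeneity is then the
    normalised variance of the filtered map, SD / mean over the mask,
    with the mean of all in-mask voxels as the normaliser.
    """
    mask = vmap.mask
    sigma_vox = []
    for d in vmap.spacing[:2]:
        add_fwhm = np.sqrt(max(target_fwhm_mm**2 - d**2, 0.0))
        sigma_vox.append(add_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / d)
    filtered = _masked_inplane_gaussian(vmap.data, mask, tuple(sigma_vox))
    inside = filtered[mask]
    mean = float(inside.mean())
    if mean == 0.0:
        raise ValueError("in-mask mean is zero; coefficient of variation undefined")
    cov = float(inside.std(ddof=0) / mean)
    return HeterogeneityResult(cov=cov, mean=mean, filter_fwhm_mm=target_fwhm_mm)


def percentile95(vmap: AerationMap | StrainMap) -> float:
    """95th percentile of in-mask values (linear interpolation between ranks)."""
    inside = vmap.in_mask()
    if inside.size == 0:
        raise ValueError("empty mask")
    return float(np.percentile(inside, 95.0, method="linear"))
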