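"""Tidal recruitment, intratidal aeration-category mass changes, and
vertical (iso-gravitational) ROI profiles.

Tidal recruitment is the fraction of whole-lung mass leaving the
non-aerated compartment from end-expiration to end-inspiration:

    TR = (M_non_EE - M_non_EI) / M_total_EE,

with the end-expiratory total mass as denominator (tissue mass is
phase-invariant and EE is the reference frame; a config switch selects
the EE/EI mean instead). Vertical analysis splits the lung into ten
contiguous slabs of equal height along the ventral-dorsal (gravity)
axis, numbered 1 (most dorsal) to 10 (most ventral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aeration import AerationCategoryMasses, mass_summary
from .core_io import AerationMap, LungMask, StrainMap

__all__ = [
    "ROIPartition",
    "vertical_rois",
    "tidal_recruitment",
    "regional_recruitment",
    "intratidal_change",
    "roi_profile",
]


@dataclass
class ROIPartition:
    """Equal-height dorsoventral slabs of a lung mask.

    ``masks[k]`` is ROI k+1; index 0 is the most dorsal region. Slab
    boundaries are voxel rows along y (half-open [low, high)).
    """

    masks: list[np.ndarray]
    row_bounds: list[tuple[int, int]]
    spacing: tuple[float, float, float]

    @property
    def n(self) -> int:
        return len(self.masks)


def vertical_rois(mask: LungMask, n: int = 10) -> ROIPartition:
    """Split the mask's dorsoventral extent into ``n`` equal-height slabs.

    The y-extent of the mask is divided into contiguous slabs whose
    heights differ by at most one voxel row; remainder rows are assigned
    one per slab starting from the dorsal side. ROI 1 is the most dorsal
    slab, ROI ``n`` the most ventral.
    """
    if n < 1:
        raise ValueError("need n >= 1 regions")
    ys = np.where(mask.data.any(axis=(0, 2)))[0]
    y_lo, y_hi = int(ys.min()), int(ys.max()) + 1
    extent = y_hi - y_lo
    if n > extent:
        raise ValueError(f"n = {n} exceeds the mask's y-extent of {extent} rows")
    base, rem = divmod(extent, n)
    # dorsal-first heights: the first `rem` slabs from the dorsal side get
    # the extra row
    heights_dorsal_first = [base + (1 if k < rem else 0) for k in range(n)]
    masks, bounds = [], []
    hi = y_hi
    for h in heights_dorsal_first:
        lo = hi - h
        roi = np.zeros_like(mask.data)
        roi[:, lo:hi, :] = mask.data[:, lo:hi, :]
        masks.append(roi)
        bounds.append((lo, hi))
        hi = lo
    return ROIPartition(masks=masks, row_bounds=bounds, spacing=mask.spacing)


def tidal_recruitment(
    masses_ee: AerationCategoryMasses,
    masses_ei: AerationCategoryMasses,
    denominator: str = "ee",
) -> float:
    """Whole-lung tidal recruitment as a fraction of lung mass.

    (end-expiratory non-aerated mass - end-inspiratory non-aerated mass)
    divided by the whole-lung mass (end-expiratory by default).
    """
    if denominator == "ee":
        total = masses_ee.total_mass_g
    elif denominator == "mean":
        total = 0.5 * (masses_ee.total_mass_g + masses_ei.total_mass_g)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if total <= 0:
        raise ValueError("zero total lung mass")
    return (masses_ee.mass_g["non"] - masses_ei.mass_g["non"]) / total


def regional_recruitment(
    fgas_ee: AerationMap,
    fgas_ei: AerationMap,
    partition_ee: ROIPartition,
    partition_ei: ROIPartition,
    normalizer: str = "roi",
    align: str = "reference",
) -> np.ndarray:
    """Per-ROI tidal recruitment fractions (index 0 = most dorsal ROI).

    With ``align="reference"`` (default) the end-expiratory slab
    boundaries are applied to both phases, the outermost slabs extended to
    cover any extra end-inspiratory rows: recruitment then compares the
    same anatomical heights, so a phase-varying lung extent does not
    masquerade as (de)recruitment. ``align="independent"`` uses each
    image's own equal-height partition instead. Per ROI the non-aerated
    mass change is normalized by the ROI's end-expiratory mass
    (``normalizer="roi"``) or by the whole-lung end-expiratory mass
    (``"lung"``).
    """
    if partition_ee.n != partition_ei.n:
        raise ValueError("partitions must have the same number of ROIs")
    if align == "reference":
        ei_bounds = list(partition_ee.row_bounds)
        ny = fgas_ei.shape[1]
        lo0, _hi0 = ei_bounds[0]
        ei_bounds[0] = (lo0, ny)  # dorsal-most slab open to the grid edge
        lo_last, hi_last = ei_bounds[-1]
        ei_bounds[-1] = (0, hi_last)  # ventral-most slab open downward
        ei_masks = []
        ei_support = np.zeros_like(fgas_ei.mask)
        for roi in partition_ei.masks:
            ei_support |= roi
        for lo, hi in ei_bounds:
            roi = np.zeros_like(ei_support)
            roi[:, lo:hi, :] = ei_support[:, lo:hi, :]
            ei_masks.append(roi)
    elif align == "independent":
        ei_masks = partition_ei.masks
    else:
        raise ValueError(f"unknown align mode {align!r}")
    lung_total = None
    if normalizer == "lung":
        lung_total = mass_summary(fgas_ee).total_mass_g
    elif normalizer != "roi":
        raise ValueError(f"unknown normalizer {normalizer!r}")
    out = np.empty(partition_ee.n)
    for k, (roi_ee, roi_ei) in enumerate(zip(partition_ee.masks, ei_masks)):
        if not roi_ee.any() or not roi_ei.any():
            raise ValueError(f"empty ROI {k + 1}")
        m_ee = mass_summary(
            AerationMap(data=fgas_ee.data, spacing=fgas_ee.spacing, mask=roi_ee)
        )
        m_ei = mass_summary(
            AerationMap(data=fgas_ei.data, spacing=fgas_ei.spacing, mask=roi_ei)
        )
        denom = m_ee.total_mass_g if normalizer == "roi" else lung_total
        out[k] = (m_ee.mass_g["non"] - m_ei.mass_g["non"]) / denom
    return out


def intratidal_change(
    masses_ee: AerationCategoryMasses, masses_ei: AerationCategoryMasses
) -> pd.DataFrame:
    """Expiratory-to-inspiratory change of lung mass per aeration category.

    Returns one row per category with the EE mass, EI mass, and the change
    EI - EE in grams and as a percentage of the EE total lung mass.
    """
    rows = []
    for cat in masses_ee.mass_g:
        ee_g = masses_ee.mass_g[cat]
        ei_g = masses_ei.mass_g[cat]
        rows.append(
            {
                "category": cat,
                "mass_ee_g": ee_g,
                "mass_ei_g": ei_g,
                "delta_g": ei_g - ee_g,
                "delta_percent_of_ee_mass": 100.0 * (ei_g - ee_g) / masses_ee.total_mass_g,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def roi_profile(
    partition: ROIPartition,
    fgas: AerationMap,
    strain: StrainMap | None = None,
) -> pd.DataFrame:
    """Per-ROI vertical profile: mean and 95th-percentile aeration, and —
    when a strain map is given — mean, median and 95th-percentile strain.

    ROI numbering runs 1 (most dorsal) to n (most ventral). ROIs whose
    intersection with the relevant map mask is empty are reported as NaN
    and flagged in the ``empty`` column.
    """
    rows = []
    for k, roi in enumerate(partition.masks):
        row: dict = {"roi": k + 1, "empty": False}
        sel = roi & fgas.mask
        if sel.any():
            vals = fgas.data[sel]
            row["mean_fgas"] = float(vals.mean())
            row["p95_fgas"] = float(np.percentile(vals, 95))
            row["n_voxels"] = int(sel.sum())
        else:
            row.update(mean_fgas=np.nan, p95_fgas=np.nan, n_voxels=0, empty=True)
        if strain is not None:
            ssel = roi & strain.mask
            if ssel.any():
                svals = strain.data[ssel]
                row["mean_strain"] = float(svals.mean())
                row["median_strain"] = float(np.median(svals))
                row["p95_strain"] = float(np.percentile(svals, 95))
            else:
                row.update(
                    mean_strain=np.nan, median_strain=np.nan, p95_strain=np.nan,
                    empty=True,
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("roi")
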