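"""Synthetic deformable lung phantom with analytic ground truth.

The phantom emulates a supine, surfactant-depleted, partly atelectatic
lung: an ellipsoidal parenchymal region with a ventral-to-dorsal aeration
gradient, a dorsal non-aerated slab, a smooth diffeomorphic end-expiratory
to end-inspiratory warp with mass-consistent density transport, optional
tidal recruitment of a dorsal block, and additive Hounsfield-unit noise.

The warp family is the composition of (i) anisotropic scaling about the
lung center and (ii) a dorsally anchored axial stretch

    y -> y - alpha * (1 - exp(-(y0 - y) / lam))   for y <= y0,

chosen because it has a closed-form inverse and closed-form Jacobian

    J(x) = s_x * s_y * s_z * (1 + (alpha/lam) * exp(-(y0 - y')/lam))

on the stretched region, so every downstream stage (registration, strain,
recruitment) can be validated against exact ground truth. The stretch is
anchored on the dorsal side — the dependent lung rests against the spine
and chest wall, so the dorsal boundary and the atelectatic slab stay
fixed while inspiratory expansion displaces tissue ventrally. Volumetric
strain peaks on the y = y0 plane (by default the ventral boundary of the
atelectasis slab, i.e. the mid-dorsal lung) at
s_x*s_y*s_z*(1 + alpha/lam) - 1 and decays ventrally with length lam.

Tissue is transported with local mass conservation,

    (1 - F_gas_EI)(T(x)) = (1 - F_gas_EE)(x) / J(x),

evaluated from the continuous phantom fields at exactly inverted warp
locations, so whole-lung tissue mass is conserved up to voxelisation of
the lung boundary. Tidal recruitment is modeled as an end-inspiratory
aeration overwrite of a tracked dorsal block (non-aerated at EE, aerated
at EI), mirroring how recruitment appears in images without implying a
specific micromechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import CTVolume, DisplacementField, LungMask

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomCase",
    "AnalyticWarp",
    "make_reference",
    "analytic_warp",
    "make_inspiratory",
    "generate",
]

HU_CLIP = (-1024.0, 100.0)


@dataclass
class PhantomSpec:
    """Generator parameters for one synthetic case (all lengths in mm)."""

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    center_mm: tuple[float, float, float] | None = None  # default: grid center
    semi_axes_mm: tuple[float, float, float] = (36.0, 34.0, 48.0)
    #: F_gas at the ventral and dorsal lung boundary (linear in between)
    fgas_ventral: float = 0.75
    fgas_dorsal: float = 0.15
    #: dorsal slab, as a fraction of the lung's dorsoventral extent,
    #: overwritten to a non-aerated gas fraction
    atelectasis_fraction: float = 0.25
    atelectasis_fgas: float = 0.03
    #: warp: scaling factors about the lung center + dorsal stretch
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    stretch_alpha_mm: float = 3.6
    stretch_lambda_mm: float = 12.0
    #: stretch anchor plane; default: ventral boundary of the atelectasis
    #: slab, where inspiratory strain peaks
    stretch_y0_mm: float | None = None
    #: tidal recruitment: target recruited fraction of whole-lung mass and
    #: the gas fraction the recruited block takes at end-inspiration
    recruit_mass_fraction: float = 0.0
    recruit_fgas_ei: float = 0.3
    #: smooth parenchymal density texture (band-limited random field added
    #: to F_gas, tapered by 4*F*(1-F) so category structure is preserved);
    #: transported with the tissue, like the vascular texture of real lungs
    texture_amplitude: float = 0.05
    texture_wavelengths_mm: tuple[float, float] = (6.0, 18.0)
    texture_modes: int = 48
    hu_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.center_mm is None:
            self.center_mm = tuple(
                (n - 1) * s / 2.0 for n, s in zip(self.shape, self.spacing)
            )
        if self.stretch_y0_mm is None:
            cy, by = self.center_mm[1], self.semi_axes_mm[1]
            self.stretch_y0_mm = float(cy + by - self.atelectasis_fraction * 2.0 * by)
        extent = tuple(n * s for n, s in zip(self.shape, self.spacing))
        for c, a, e in zip(self.center_mm, self.semi_axes_mm, extent):
            if a <= 0:
                raise ValueError("degenerate ellipsoid: non-positive semi-axis")
            if c - a < 0 or c + a > e:
                raise ValueError("lung ellipsoid does not fit inside the grid")
        for g in (self.fgas_ventral, self.fgas_dorsal, self.atelectasis_fgas):
            if not 0.0 <= g <= 1.0:
                raise ValueError("gas-fraction endpoints must lie in [0, 1]")
        if any(s <= 0 for s in self.scale):
            raise ValueError("scale factors must be positive")
        if self.stretch_lambda_mm <= 0:
            raise ValueError("stretch decay length must be positive")
        # analytic positivity of the Jacobian: its minimum over the grid is
        # prod(scale) * min(1, 1 + alpha/lam)
        if 1.0 + self.stretch_alpha_mm / self.stretch_lambda_mm <= 0:
            raise ValueError("warp parameters yield a non-positive Jacobian")
        if not 0.0 <= self.recruit_mass_fraction < 1.0:
            raise ValueError("recruited mass fraction must lie in [0, 1)")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic case."""

    field: DisplacementField  # EE -> EI displacement on the EE grid, mm
    jacobian: np.ndarray  # closed-form J at EE voxel centers
    recruited_mass_fraction: float  # achieved fraction of EE lung mass
    recruitment_block: np.ndarray  # boolean EE grid of recruited voxels
    spec: PhantomSpec


@dataclass
class PhantomCase:
    """A complete generated case: paired volumes, masks, and truth."""

    ee: CTVolume
    ee_mask: LungMask
    ei: CTVolume
    ei_mask: LungMask
    truth: PhantomTruth


class AnalyticWarp:
    """The EE -> EI coordinate map T with closed-form inverse and Jacobian."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.center = np.asarray(spec.center_mm, dtype=float)
        self.scale = np.asarray(spec.scale, dtype=float)
        self.alpha = float(spec.stretch_alpha_mm)
        self.lam = float(spec.stretch_lambda_mm)
        self.y0 = float(spec.stretch_y0_mm)

    # -- forward ---------------------------------------------------------
    def _stretch(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        d = self.y0 - y  # distance ventral of the dorsal anchor plane
        return np.where(d > 0, y - self.alpha * (1.0 - np.exp(-d / self.lam)), y)

    def _stretch_deriv(self, y: np.ndarray) -> np.ndarray:
        d = self.y0 - np.asarray(y, dtype=float)
        return np.where(d > 0, 1.0 + (self.alpha / self.lam) * np.exp(-d / self.lam), 1.0)

    @property
    def is_identity(self) -> bool:
        return self.alpha == 0.0 and np.all(self.scale == 1.0)

    def forward(self, pts: np.ndarray) -> np.ndarray:
        """T(x) for points of shape (..., 3) in mm."""
        pts = np.asarray(pts, dtype=float)
        out = self.center + self.scale * (pts - self.center)
        out = out.copy()
        out[..., 1] = self._stretch(out[..., 1])
        return out

    # -- inverse ---------------------------------------------------------
    def _stretch_inverse(self, y2: np.ndarray) -> np.ndarray:
        """Invert the monotone 1-D stretch by Newton iteration."""
        y2 = np.asarray(y2, dtype=float)
        y = y2 + np.where(y2 < self.y0, self.alpha * 0.5, 0.0)
        y = np.minimum(y, np.maximum(y2, self.y0))
        for _ in range(60):
            f = self._stretch(y) - y2
            y = y - f / self._stretch_deriv(y)
        if np.max(np.abs(self._stretch(y) - y2)) > 1e-8:
            raise RuntimeError("stretch inversion did not converge")
        return np.where(y2 >= self.y0, y2, y)

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        """T^-1(p) for points of shape (..., 3) in mm."""
        pts = np.asarray(pts, dtype=float).copy()
        pts[..., 1] = self._stretch_inverse(pts[..., 1])
        return self.center + (pts - self.center) / self.scale

    # -- Jacobian --------------------------------------------------------
    def jacobian(self, pts: np.ndarray) -> np.ndarray:
        """Closed-form det(grad T) at EE points of shape (..., 3)."""
        pts = np.asarray(pts, dtype=float)
        y_scaled = self.center[1] + self.scale[1] * (pts[..., 1] - self.center[1])
        return float(np.prod(self.scale)) * self._stretch_deriv(y_scaled)


def _grid_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(
        np.arange(n, dtype=float) * s for n, s in zip(spec.shape, spec.spacing)
    )


def _grid_points(spec: PhantomSpec) -> np.ndarray:
    cx, cy, cz = _grid_coords(spec)
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    return np.stack([X, Y, Z], axis=-1)


def _ellipsoid_indicator(pts: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    c = np.asarray(spec.center_mm)
    a = np.asarray(spec.semi_axes_mm)
    r2 = (((pts - c) / a) ** 2).sum(axis=-1)
    return r2 <= 1.0


def _texture(pts: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Smooth unit-variance random field: a seeded sum of plane-wave cosines.

    Being a closed-form function of position it can be evaluated at warped
    locations exactly, so the texture is transported with the tissue.
    """
    if spec.texture_amplitude == 0 or spec.texture_modes == 0:
        return np.zeros(pts.shape[:-1])
    rng = np.random.default_rng([int(spec.seed), 0x7E57])
    m = spec.texture_modes
    dirs = rng.normal(size=(m, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    wl = rng.uniform(*spec.texture_wavelengths_mm, size=m)
    k = 2.0 * np.pi * dirs / wl[:, None]
    phase = rng.uniform(0.0, 2.0 * np.pi, size=m)
    flat = pts.reshape(-1, 3)
    acc = np.zeros(flat.shape[0])
    for km, ph in zip(k, phase):
        acc += np.cos(flat @ km + ph)
    return (acc * np.sqrt(2.0 / m)).reshape(pts.shape[:-1])


def _fgas_continuous(pts: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """The phantom's continuous EE gas-fraction field (undefined outside)."""
    cy, by = spec.center_mm[1], spec.semi_axes_mm[1]
    t = (pts[..., 1] - (cy - by)) / (2.0 * by)
    fgas = spec.fgas_ventral + (spec.fgas_dorsal - spec.fgas_ventral) * np.clip(t, 0, 1)
    y_slab = cy + by - spec.atelectasis_fraction * 2.0 * by
    if spec.atelectasis_fraction > 0:
        fgas = np.where(pts[..., 1] >= y_slab, spec.atelectasis_fgas, fgas)
    if spec.texture_amplitude > 0:
        taper = 4.0 * fgas * (1.0 - fgas)
        fgas = fgas + spec.texture_amplitude * taper * _texture(pts, spec)
    return np.clip(fgas, 0.0, 1.0)


def make_reference(spec: PhantomSpec) -> tuple[CTVolume, LungMask]:
    """Noise-free end-expiratory CT volume and lung mask.

    Inside the ellipsoid F_gas varies linearly from the ventral to the
    dorsal endpoint along y, the dorsal atelectasis slab is overwritten to
    its (non-aerated) gas fraction, and HU = -1000 * F_gas. Outside the
    lung HU = 0 (soft tissue).
    """
    pts = _grid_points(spec)
    inside = _ellipsoid_indicator(pts, spec)
    if not inside.any():
        raise ValueError("degenerate ellipsoid: empty lung mask")
    fgas = _fgas_continuous(pts, spec)
    hu = np.where(inside, -1000.0 * fgas, 0.0)
    return (
        CTVolume(data=hu, spacing=spec.spacing),
        LungMask(data=inside, spacing=spec.spacing),
    )


def analytic_warp(spec: PhantomSpec) -> AnalyticWarp:
    """The spec's EE -> EI warp; rejects parameters with J <= 0."""
    return AnalyticWarp(spec)


def _select_recruitment_block(
    spec: PhantomSpec, fgas_ee: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, float]:
    """Choose dorsal-most non-aerated voxels until the target mass is reached.

    Returns the block indicator on the EE grid and the achieved recruited
    mass fraction (exact voxel arithmetic on the noise-free EE image).
    """
    vvol = spec.voxel_volume_ml
    tissue = np.where(mask, (1.0 - fgas_ee) * vvol, 0.0)
    total = tissue.sum()
    target = spec.recruit_mass_fraction * total
    block = np.zeros(spec.shape, dtype=bool)
    if target <= 0:
        return block, 0.0
    candidate = mask & (fgas_ee < 0.1)
    acc = 0.0
    for j in range(spec.shape[1] - 1, -1, -1):  # dorsal-most rows first
        row = candidate[:, j, :]
        if not row.any():
            continue
        row_mass = tissue[:, j, :][row].sum()
        if acc + row_mass <= target:
            block[:, j, :] = row
            acc += row_mass
        else:
            # take a partial row, deterministic voxel order
            idx = np.argwhere(row)
            masses = tissue[:, j, :][row]
            for (i, k), m in zip(idx, masses):
                if acc + m > target and acc > 0:
                    break
                block[i, j, k] = True
                acc += m
            break
        if acc >= target:
            break
    if acc == 0.0:
        raise ValueError("recruitment block is empty (no non-aerated voxels)")
    return block, float(acc / total)


def make_inspiratory(
    ee: CTVolume, ee_mask: LungMask, warp: AnalyticWarp, spec: PhantomSpec
) -> tuple[CTVolume, LungMask, PhantomTruth]:
    """Warp the reference to end-inspiration with mass-consistent transport.

    The EI image on the common grid is built by exact pull-back: for each
    voxel center p, x = T^-1(p); p is lung iff x lies in the ellipsoid, and
    its tissue fraction is (1 - F_gas_EE(x)) / J(x). The recruitment block
    (if any) is overwritten at EI to its target gas fraction and its EE
    tissue mass recorded as the recruited mass fraction. Gaussian HU noise
    of the spec's SD is added to the EI volume (:func:`generate` noises the
    EE volume from the same seeded stream; pass hu_noise_sd=0 for
    noise-free output).
    """
    pts = _grid_points(spec)
    fgas_ee_grid = np.where(ee_mask.data, _fgas_continuous(pts, spec), 0.0)
    block, achieved = _select_recruitment_block(spec, fgas_ee_grid, ee_mask.data)

    if warp.is_identity:
        x = pts
        in_ei = _ellipsoid_indicator(pts, spec)
        fgas_ei = np.where(in_ei, _fgas_continuous(pts, spec), 0.0)
    else:
        x = warp.inverse(pts)
        in_ei = _ellipsoid_indicator(x, spec)
        jac_at_x = warp.jacobian(x)
        ftis_ee_at_x = 1.0 - _fgas_continuous(x, spec)
        fgas_ei = np.where(in_ei, 1.0 - ftis_ee_at_x / jac_at_x, 0.0)

    if block.any():
        # EI voxels whose pre-image lies in the recruitment block
        idx = np.round(x / np.asarray(spec.spacing)).astype(int)
        np.clip(idx, 0, np.asarray(spec.shape) - 1, out=idx)
        from_block = block[idx[..., 0], idx[..., 1], idx[..., 2]] & in_ei
        fgas_ei = np.where(from_block, spec.recruit_fgas_ei, fgas_ei)

    hu_ei = np.where(in_ei, -1000.0 * np.clip(fgas_ei, 0.0, 1.0), 0.0)

    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        rng.normal(0.0, spec.hu_noise_sd, size=spec.shape)  # EE draw (see generate)
        hu_ei = np.clip(
            hu_ei + rng.normal(0.0, spec.hu_noise_sd, size=spec.shape), *HU_CLIP
        )

    u = warp.forward(pts) - pts
    truth = PhantomTruth(
        field=DisplacementField(data=u, spacing=spec.spacing),
        jacobian=warp.jacobian(pts),
        recruited_mass_fraction=achieved,
        recruitment_block=block,
        spec=replace(spec),
    )
    ei = CTVolume(data=hu_ei, spacing=spec.spacing)
    ei_mask = LungMask(data=in_ei, spacing=spec.spacing)
    return ei, ei_mask, truth


def generate(spec: PhantomSpec | None = None, **overrides) -> PhantomCase:
    """Generate one complete phantom case (EE/EI volumes, masks, truth)."""
    if spec is None:
        spec = PhantomSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    ee, ee_mask = make_reference(spec)
    warp = analytic_warp(spec)
    ei, ei_mask, truth = make_inspiratory(ee, ee_mask, warp, spec)
    if spec.hu_noise_sd > 0:
        # first draw of the seeded stream is the EE noise (the second, used
        # inside make_inspiratory, is the EI noise)
        rng = np.random.default_rng(spec.seed)
        noisy = np.clip(
            ee.data + rng.normal(0.0, spec.hu_noise_sd, size=spec.shape), *HU_CLIP
        )
        ee = CTVolume(data=noisy, spacing=spec.spacing)
    return PhantomCase(ee=ee, ee_mask=ee_mask, ei=ei, ei_mask=ei_mask, truth=truth)
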