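# Methods

`lungstrain` quantifies regional lung mechanics from paired end-expiratory
(EE) and end-inspiratory (EI) CT volumes of a mechanically ventilated,
surfactant-depleted (lavage-injured) lung. This note records the models,
the numerical choices, and what the synthetic test bed does and does not
establish.

## Geometry conventions

All volumes live on a fixed internal axis order — x: right→left,
y: ventral→dorsal, z: caudal→cranial (LPS) — with the subject supine, so
gravity points along +y and "ROI 1" is always the most dorsal slab.
NIfTI files in other orientations are reoriented on read. Displacements
are stored in millimetres (world units) so Jacobians are spacing-aware;
voxel indexing is 0-based and all bins and slabs are half-open
[low, high) except the topmost aeration/PRM bin, which closes at 1.

## Aeration densitometry

Gas fraction is F_gas = HU/−1000 (air −1000 HU → 1, tissue 0 HU → 0); HU
are clamped to [−1000, 0] first so residual dense material inside the
mask cannot leave the unit interval. Compartments follow the standard
half-open bounds: non- (< 0.1), poorly- (0.1–0.5), normally- (0.5–0.9)
and hyper-aerated (≥ 0.9), with the boundary value belonging to the
upper compartment. Voxel tissue mass is (1 − F_gas)·voxel volume at a
water-equivalent tissue density of 1 g/ml; compartment masses are
reported as percentages of total lung mass, and the in-mask gas volume
of the EE image is the end-expiratory lung volume (EELV).

Spatial heterogeneity is the coefficient of variation (SD/mean) of a map
whose effective in-plane resolution has first been matched to the slice
thickness (default 2.5 mm): the added in-plane Gaussian FWHM is
√(2.5² − d²) for native in-plane spacing d (FWHM adds in quadrature),
with no smoothing along z. Smoothing is renormalized to the mask support
so tissue outside the lung does not bleed into boundary voxels. The SD
uses the population convention (ddof = 0); the normalizer is the mean of
all in-mask voxels. Percentiles everywhere use linear interpolation
between closest ranks (so values 1…100 give a 95th percentile of 95.05).

## Registration and volumetric strain

The EE→EI correspondence T(x) = x + u(x) is estimated on preprocessed
images: parenchymal HU rescaled to intensity 1 (air) … 0 (tissue) using
each image's in-mask extremes, cropped to the EI-mask bounding box, and
padded with a constant 50-voxel margin.

The estimator is a multiresolution, B-spline-regularized greedy scheme:

* **Similarity** — windowed (local) cross-correlation with a box window
  of radius 4 voxels, computed with O(N) uniform filters. Windows whose
  intensity variance falls below a floor (default 5·10⁻⁴, ≈16 HU on a
  720-HU parenchymal range — above typical reconstruction noise) are
  treated as textureless: they contribute neither force nor metric.
  Metric and forces are further restricted to the EI lung dilated by 8
  voxels; the surrounding soft tissue is homogeneous and carries no
  correspondence information.
* **Transform** — per-iteration dense updates are projected onto a cubic
  B-spline control grid whose knot spacing starts at 26 mm and halves at
  each of three subsequent stages (26, 13, 6.5, 3.25 mm) while image
  resolution increases (default shrink factors 4, 2, 2, 1, applied
  per-axis so coarse levels stay quasi-isotropic despite 2.5 mm slices).
* **Optimization** — steepest ascent on the mean windowed correlation
  with a backtracking line search; each candidate step is accepted only
  if it improves the metric *and* keeps the accumulated field's Jacobian
  positive. Steps are bounded to 0.4 of the level's smallest voxel, and
  the accumulated field is smoothed with a 1-voxel Gaussian after every
  accepted step (total-field regularization), which keeps the Jacobian
  well conditioned. Stages stop when the metric plateaus (10⁻⁵ over an
  8-iteration window) or the iteration cap (100/70/50/30) is reached.
* **Strain** — J = det(I + ∇u) by spacing-aware central differences
  (one-sided at grid boundaries); volumetric strain s = J − 1, i.e.
  local tidal volume change relative to the end-expiratory volume.
  Strain statistics are reported inside the EE mask eroded by one voxel
  to keep boundary derivative artifacts out. A non-positive in-mask
  Jacobian is a hard error. The central-difference Jacobian is
  cross-checked in the test suite against ITK's displacement-field
  Jacobian-determinant filter on random smooth fields.

EI aeration is compared to strain on the EE grid by pull-back: the value
at EE voxel x is the linear interpolation of the EI gas-fraction map at
T(x). The parametric response map bins paired (EE, EI) gas fractions on
a 100×100 grid over [0, 1]; per occupied bin it reports the fraction of
lung volume and the mean strain, and bins below 0.05 % of the lung
volume are suppressed from the reported map.

## Tidal recruitment and vertical distributions

Whole-lung tidal recruitment is
TR = (M_non_EE − M_non_EI)/M_total_EE — the fraction of lung mass
leaving the non-aerated compartment between expiration and inspiration.
The denominator is the end-expiratory total mass (tissue mass is
phase-invariant and EE is the reference frame); the EE/EI mean is
available as a config switch.

Vertical analysis splits the lung's dorsoventral extent into ten
contiguous slabs of equal height (remainder rows assigned dorsal-first),
numbered 1 (dorsal) to 10 (ventral). ROI *profiles* (mean and 95th
percentile of aeration and strain) use each image's own partition. For
*regional recruitment* the default applies the end-expiratory slab
boundaries to both phases, with the outermost slabs extended to cover
any extra end-inspiratory rows: equal-height partitions recomputed per
phase land on different anatomical rows whenever the lung's extent
changes, and with the dense non-aerated slab near the dorsal boundaries
that mislabels plain tissue shift as (de)recruitment. Independent
per-phase partitioning remains available (`align="independent"`).

## Respiratory mechanics

Each breath is fitted with the single-compartment equation of motion
P(t) = V(t)/C + R·V̇(t) + P0 by ordinary least squares over the full
cycle (breaths arrive pre-segmented), yielding compliance C (ml/cmH₂O),
resistance R (cmH₂O/l/s), and the end-expiratory pressure offset P0.
During a decremental PEEP trial, per-level compliance is the mean over
the provided breaths and the selected PEEP is the level of maximal
compliance; ties break toward the higher (more recruitment-preserving)
PEEP. The synthetic breath generator produces a volume-controlled cycle
(constant inspiratory flow, passive exponential expiration) with
defaults matching a moderately injured lung: C = 9 ml/cmH₂O,
R = 14 cmH₂O/l/s, tidal volume 0.17 l, 26 breaths/min, I:E = 1:2; its
volume channel is the discrete trapezoidal integral of flow so the two
are consistent at any sampling rate.

## Statistics

Paired two-tailed Student's t-tests (t = mean(d)/(sd(d)/√n), df = n−1),
Pearson and Spearman correlations (average ranks for ties; p by the
t transform), and a two-way repeated-measures ANOVA for
region × ventilatory strategy on complete balanced subject×region×
strategy arrays. Each within-subject effect is tested against its own
subject-interaction error term; no sphericity correction is applied
(documented limitation). The ANOVA's sums of squares are verified in
the tests against both a nested-loop mean-subtraction oracle and
statsmodels' AnovaRM.

## The synthetic phantom

The phantom emulates the study conditions of a supine, lavage-injured
lung on a 96×96×48 grid of 1×1×2.5 mm voxels: an ellipsoidal lung
(semi-axes 36×34×48 mm) with a linear ventral→dorsal aeration gradient
(F_gas 0.75 → 0.15), a dorsal atelectatic slab covering 25 % of the
dorsoventral extent at F_gas 0.03 — giving the bimodal gas-fraction
histogram characteristic of this injury model — plus additive Gaussian
HU noise (default SD 10 HU, clipped to [−1024, 100]) and a transported
parenchymal texture: a seeded band-limited random field (48 plane-wave
cosines, wavelengths 6–18 mm, amplitude 0.05 in F_gas, tapered by
4F(1−F) so compartment structure is preserved). The texture stands in
for the vascular/parenchymal detail of real CT; without it, local
cross-correlation has no signal inside homogeneous regions and
registration of the phantom would be ill-posed in a way real images are
not.

The EE→EI warp composes anisotropic scaling about the lung center with
a dorsally anchored exponential stretch
y ↦ y − α(1 − e^{−(y0−y)/λ}) for y ≤ y0 (defaults α = 3.6 mm,
λ = 12 mm, y0 at the slab's ventral boundary), whose Jacobian
J = s_x s_y s_z (1 + (α/λ)e^{−(y0−y′)/λ}) is closed-form, strictly
positive by construction, and peaks at ≈ 0.3 volumetric strain on the
anchor plane, decaying ventrally. The dorsal anchoring reflects the
physiology of the dependent lung resting against the chest wall: the
dorsal boundary and the non-aerated slab stay fixed while expansion
displaces tissue ventrally. The stretch profile is continuous but only
C⁰ in its derivative at the anchor plane; finite-difference/closed-form
comparisons therefore exclude a two-row band at y0, where central
differences cannot estimate the one-sided derivative (elsewhere they
agree to < 10⁻³).

Tissue is transported with local mass conservation,
(1 − F_gas_EI)(T(x)) = (1 − F_gas_EE)(x)/J(x), evaluated from the
continuous phantom fields at exactly inverted warp locations (Newton
inversion of the monotone 1-D stretch), so whole-lung tissue mass is
conserved to the voxelization of the lung boundary (measured ≈ 0.02 %,
bound 0.5 %). Tidal recruitment is modeled as an EI-only aeration
overwrite of a tracked block of dorsal-most non-aerated voxels,
accumulated until a requested fraction of whole-lung mass is reached
(the achieved fraction is recorded as ground truth); this mirrors how
recruitment appears in images without asserting a micromechanism. The
identity warp short-circuits transport so EE and EI are bit-identical
in that limit.

What the phantom does **not** emulate: cardiac and diaphragmatic motion,
airway/vessel trees and their sliding interfaces, CT reconstruction
artifacts (beam hardening, streaks), hysteresis between inspiratory and
expiratory pathways, and genuinely three-dimensional strain
heterogeneity (the true warp varies only along the gravity axis).
Passing the recovery tests therefore shows the pipeline is correct and
well-conditioned under controlled conditions with known truth; it does
not bound errors on clinical images, whose registration difficulty is
dominated by features the phantom lacks.

## Problem sizes and numerical tolerances

Phantom-based checks run at the default 96×96×48 grid; registration
unit tests that do not need that resolution use a 48×48×24 grid with
2×2×5 mm voxels and a knot schedule ending at 5.5 mm (knots must stay
above the voxel size). Measured recovery on the default phantom at
noise SD 10 HU: median endpoint error ≈ 0.2 mm, median absolute strain
error ≈ 0.04 (bounds 1.0 mm and 0.05), whole-lung mean-strain error
≈ 0.01 (bound 0.02), registration-derived volume integral within 1 % of
the EI lung volume (bound 2 %), and tidal recruitment within 0.01 of
truth across recruited fractions {0, 0.02, 0.05}. Degenerate inputs
(empty masks, zero-variance differences, constant correlation inputs,
rank-deficient mechanics designs, non-positive Jacobians) raise errors
rather than returning silent values.
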