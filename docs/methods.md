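# Methods

`tubeorient` quantifies the orientation of smooth muscle cells (SMCs)
across the wall of an intact tubular organ from a 3D stack of
nucleus-stained optical sections. This note documents the model behind
each stage, the parameters that matter, the conventions chosen where the
design was genuinely open, and what the synthetic-data tests do and do not
show about real data.

## Imaging model and coordinates

The organ is modelled as a circular cylinder of outer radius `R` whose
muscular wall occupies the shell `R − t ≤ r ≤ R` (`t` = wall thickness).
Flat optical sections are acquired at increasing depth `z` below the
topmost point of the outer surface, ordered from the adventitial (outer)
to the proprial (inner) side. In image coordinates the tube's longitudinal
axis is the x (column) direction and the lateral axis is y (rows); the
"apex line" — the line of the image directly above the cylinder axis —
defaults to the lateral center of the field and can be offset in the
configuration for decentered mounts.

Orientation angles α are *axial* quantities (α and α + 180° are the same
orientation). The stored representative lies in (−90°, 90°], measured from
the longitudinal axis, positive toward +y. All dispersion statistics use
the standard angle-doubling treatment: double the angles, apply circular
statistics, halve the result. The circular SD is `sqrt(−2 ln R̄)/2`
(degrees) with `R̄` the mean resultant length of the doubled angles;
perfectly uniform data has undefined dispersion and is reported as
infinite.

## Cellness filtering

Nuclei of SMCs are elongated bright blobs. Each slice is convolved with
Gaussian second-derivative kernels at scale `sigma_kernel` (default
1.5 µm ≈ half a nucleus width, so the ridge response peaks on the nucleus
core), the Hessian is γ-normalized (multiplied by σ²), and its eigenvalues
ordered |h1| ≤ |h2| feed the bright-structure vesselness response of
Frangi et al.:

    V = 0                                                  if h2 > 0
    V = exp(−(h1/h2)² / (2 β²)) · (1 − exp(−(h1²+h2²)/(2 c²)))   else

with blobness weight β = 0.5 (the conventional choice) and structure
weight `c` selected adaptively per slice as half the maximum Hessian norm,
because the appropriate value tracks image intensity. The slice mean is
subtracted before filtering: the sampled derivative kernels carry a small
DC leak, and removing the mean makes the response exactly invariant under
constant intensity offsets. The response is normalized to [0, 1] per slice
and thresholded at 0.15 (an Otsu mode exists but is not the default).
The threshold sits slightly above the response plateau of an isotropic
blob — exp(−1/(2β²)) times its structure term, about 0.11 of the
normalized maximum at β = 0.5 — so round nuclei are largely suppressed
already at this stage, with the eigenvalue-ratio filter catching the
remainder. Lowering the threshold below ~0.11 would instead segment round
nuclei as coherent disks, at the measured cost of admitting fainter,
noisier detections that inflate the recovered mid-depth dispersion by a
few degrees; the default favors orientation fidelity. Connected components
(8-connectivity, so thin diagonal nuclei do not fragment) become candidate
clusters, retained when their area lies in [8, 120] µm² — the lower bound
removes dye particles, the upper bound removes adjacent cells merged into
one component. The bounds bracket the
elliptical estimate π/4 · short · long ≈ 33 µm² for typical SMC nucleus
axes. Filtering is strictly slice-wise; no 3D filtering is attempted.

Single-scale filtering is used deliberately: the target structure has one
characteristic width. The threshold and area bounds are package
conventions, configurable in the `cellness:` block.

## Region of interest

A flat section of a curved tube mixes wall depths: a point at lateral
offset `y` in the plane at nominal depth `z` sits at wall depth
`z_wall(y) = R − sqrt((R − z)² + y²)`. Two closed-form half-widths bound
the usable band around the apex line:

* crosstalk limit `w_c = sqrt((R − z + Δ)² − (R − z)²)` — beyond this
  offset the true wall depth deviates from `z` by more than `Δ`
  (`delta_max`, default 2 µm: a trade-off between depth fidelity and
  sample count);
* filling limit `w_f = sqrt(z (2R − z))` — beyond this offset the plane
  has left the tissue, so densities could not be formed as count/area.

The effective ROI is the band |y| ≤ min(w_c, w_f, field half-width),
parallel to the tube axis. Slice 0 (the tangent plane) is always invalid
(`w_f = 0`). Membership is decided by the cluster *centroid* (closed
boundary) — simple and unbiased for symmetric nuclei. A cluster's depth is
its slice's nominal `z`; the crosstalk bound guarantees the error is at
most `delta_max`. The cylinder is assumed perfectly circular; for slightly
oval cross-sections the true curvature radius is larger and the band is
conservative.

## Orientation from the second-moment tensor

The "structure tensor" of a cluster is interpreted as the second central
moment (inertia) tensor of its binary pixel set, in µm², with uniform
pixel weights — a deterministic, well-defined quantity even on small
clusters, whose principal direction coincides with the gradient-based
tensor for filled convex shapes. Clusters pass the anisotropy filter when
the eigenvalue ratio λ1/λ2 exceeds 1.5 (λ2 = 0 passes), excluding round
nuclei — urothelial nuclei and foreshortened, transversely oriented
nuclei. α is the angle of the λ1 eigenvector, validated against the
closed-form half-angle solution `0.5·atan2(2 cov_xy, cov_xx − cov_yy)` to
1e−9 degrees in the tests. Whether the original ratio convention applied
to eigenvalues or axis lengths is not decidable from the available
description; the tensor-eigenvalue ratio is used.

Depth is normalized per stack, `z_n = z / LM thickness`, clipped to
[0, 1]. The muscle-layer thickness is measured input; an optional
estimator takes the longest contiguous depth range where cell density
exceeds 25 % of its maximum, for stacks without a measured value. Nuclei
are *not* deduplicated across slices (each appears in several sections);
consequences for the statistics are discussed below.

## Distributions and dispersion

The joint density over (z_n, α) is a product-kernel Gaussian KDE:
depth is linear on [0, 1] with each sample's kernel renormalized by its
mass inside [0, 1] (edge correction by renormalization keeps the estimate
positive and exactly mass-preserving; reflection would be the
alternative); the angle dimension is wrapped with period 180° by summing
replicas at α + 180k, k ∈ {−2…2} (truncation < 1e−12 for bandwidths up to
20°). Defaults: h_z = 0.08, h_α = 6°, grid 101 × 181. Pooling across
stacks weights every stack equally (each stack contributes total mass
1/n_stacks), so a sample-rich stack cannot dominate; raw-sample pooling is
available via the same API by omitting stack ids.

Octile curves are the seven interior k/8 quantiles of the per-depth
conditional angle density. At each depth the conditional is re-centered at
its axial circular mean before the CDF is formed, so quantiles are taken
on an interval with no wrap discontinuity and the curves remain continuous
across ±90°; ties are resolved by linear interpolation on the gridded CDF.
Depths carrying (numerically) no mass are reported as missing.

The between-stack dispersion table computes, per stack and per normalized
depth in {0.2, 0.4, 0.6, 0.8}, the axial circular SD of samples within
|z_n − depth| ≤ 0.1 (the window half-width is a package convention — some
window is required and 0.1 balances bias against sample count), then the
25th/50th/75th percentiles across stacks with linear interpolation between
order statistics (the "type 7" convention).

Cell density divides the number of detected nuclei per slice inside the
ROI by the ROI area (cells per 10⁴ µm²). Counting uses clusters after
area filtering but *before* the anisotropy filter: density is about
detected nuclei, orientation about the stricter elongated subset.

## Synthetic stacks

The simulator is the package's oracle: every downstream stage is tested
against known ground truth. It renders nucleus-like blobs into the
cylindrical shell, samples their in-plane orientation from a
depth-dependent axial von Mises distribution (concentration chosen so the
axial circular SD equals the requested σ at the nucleus's normalized wall
depth), adds isotropic round nuclei (equal axes, default fraction 0.1,
emulating urothelial and foreshortened transversely aligned nuclei that
the anisotropy filter must reject), small bright clutter below the area
bound ("dye particles"), and
finally Poisson shot noise plus Gaussian read noise (defaults give nucleus
SNR ≈ 10; the real acquisitions' noise characteristics are not published,
so these are conventions).

Geometry defaults are the study conditions: outer radius 150 µm, wall
thickness 55 µm (near the reported median thickness of the rat ureter
muscle layer), isotropic 0.5 µm sampling, 512 × 512 px fields, 112
slices. Nucleus axes default to 12 × 3.5 × 3.5 µm. Blobs are Gaussian
intensity profiles whose full width at half maximum equals the nominal
axis length — FWHM is the standard object-size convention in fluorescence
imaging, and a solid stained nucleus blurred by the optics is well
approximated by a Gaussian whose FWHM matches the object boundary. A
hard-ellipsoid mode exists behind a flag.

Placement is rejection sampling with a minimum center distance of one
short axis (allowing realistic near-contact without pathological
merging), bounded at 10⁴ attempts per nucleus; infeasible densities raise
an error reporting the achieved density. The areal density target
(default 20 cells per 10⁴ µm², the reported mid-wall value) is converted
to a volume density as ρ_v = target / (10⁴ · depth_axis): the expected
number of centers per unit area within a slab one nucleus-depth-extent
thick. Because slice-wise counting detects each nucleus over
approximately its depth extent, this makes the target directly comparable
to the measured per-slice density, without any deduplication.

Preset scenarios: `ureter_like` (mean 0° everywhere, σ rising linearly
25°→32° across the wall — the gradually dispersing single-layer
architecture), `intestine_like` (0° outer half, 90° inner half, σ = 15° —
the two-layer control), `uniform_null` (axial-uniform angles).

### What the synthetic tests do not show

The simulator omits the extracellular-matrix signal, depth-dependent
attenuation and point-spread-function physics, photobleaching, nucleus
shape irregularity, and intensity heterogeneity between cells. Passing
recovery tests therefore demonstrates the correctness of the geometry,
statistics, and detection chain under the stated assumptions — not
robustness to every property of real tissue. Out-of-plane (transverse)
orientation is not measurable by construction (foreshortened nuclei look
round and are filtered out), and per-slice counts over-represent large
nuclei; both limitations are inherited from the slice-wise design.

A measured limitation of round-nucleus exclusion under noise: because an
isotropic blob's cellness response peaks at only ~0.11 of the slice
maximum, its detections at the default threshold are partial, noise-carved
masks whose shapes scatter around circular; roughly a quarter of them
acquire a moment ratio above 1.5 and leak through the anisotropy filter
(isolated, full-amplitude round blobs are rejected essentially always, so
the ratio test itself is sound). The leaked detections carry near-random
angles and amount to ~2–3 % of the final orientation samples, which
measurably does not perturb the recovered dispersion profiles; the tests
pin the contamination below 5 %. A lower threshold segments rounds as
coherent disks and raises their rejection rate to ~88 %, but admits
fainter elongated detections whose angle noise inflates the mid-depth
dispersion — the default favors orientation fidelity.

## Numerical choices and degenerate inputs

* Constant or structureless slices yield an all-zero cellness map (no
  division-by-zero paths); non-finite pixels raise.
* Single-pixel clusters have no orientation and raise; isotropic clusters
  (λ1 = λ2) raise in `principal_angle` and fail the anisotropy filter.
* `R̄ = 0` (exactly antipodal doubled angles) yields infinite circular SD,
  propagated as such and excluded from dispersion percentiles.
* The von Mises concentration for a requested axial SD is solved by
  Brent's method on `I1(κ)/I0(κ) = exp(−s²/2)`; σ below the resolution of
  that inversion falls back to the Gaussian limit, σ = 0 returns the mean
  exactly, σ = ∞ samples uniformly.
* ROI boundary membership uses a 1e−9 relative tolerance so the closed
  boundary survives floating-point offset arithmetic.
* KDE determinism: identical inputs give bit-identical grids; the 180°
  wrap identity holds to ~1e−12 relative (limited by wrap arithmetic).

## Problem sizes used in tests and the acceptance script

Recovery experiments use 12 simulated stacks (512 px field, 112 slices)
for the gradually dispersing scenario and 3 for the two-layer control —
sizes at which per-window dispersion estimates stabilize (each depth
window then holds on the order of 50–80 independent nuclei per stack)
while a full experiment completes in minutes. Monte-Carlo checks of the
circular statistics use 10⁵ draws (±0.5° at σ = 25°); KDE coverage checks
use 10⁴ samples.

## Design choices not taken

Per-stage result caching keyed on content hashes was considered and
dropped: at these problem sizes a full per-stack run takes seconds, so
caching would add complexity without benefit. No mixture-model layer
detection, no statistical testing between anatomical sites, and no 3D
(non-slice-wise) processing are provided; the latter is the natural next
step to remove the double-counting and transverse-orientation
limitations.
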