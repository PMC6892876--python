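# Methods

This note records the models, conventions and numerical choices behind
`habrush`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinate and unit conventions

Arrays are `(C, Z, Y, X)`; voxel indices are 0-based with half-open
extents, and the physical coordinate of voxel *i* along an axis is
`i · pitch` (voxel 0 centred at the origin). All internal lengths are
nanometres; reports use micrometres. Masses are daltons, currents
picoamperes, ECDs pA·s. Anisotropic voxels are handled by converting
indices to physical coordinates before any distance computation; stacks are
never resampled.

## Brush physics

A single closed-form chain links all derived quantities: with monomer mass
m₀ = 400 Da and length b = 1 nm per disaccharide, N = M/m₀ and L = N·b.
The dry (collapsed) brush thickness obeys H = N τ⁻¹ σ b³ with τ = 1 in poor
solvent, inverted as σ = H τ/(N b³); densities are also reported per µm²
with mean spacing σ^(−1/2). The hydrodynamic radius uses the scaling
R_H = R_a (M/M_a)^ν with ν = 0.7 (warning outside 0.6–0.8) and a mandatory
anchor, default (0.72 MDa, 100 nm) — the scaling law fixes no absolute
prefactor, so an un-anchored call is a configuration error. The brush/
mushroom classification compares 2·R_H with the spacing; exactly 1.0 is
labelled "boundary". Synthase surface density multiplies the total membrane
protein density by the synthase mass fraction, i.e. it treats all membrane
proteins as equal-mass — a deliberate first-order approximation. The UV
micropatterning dose check computes P·t/A and treats the deactivation
threshold 2.13×10⁻⁴ J/µm² as inclusive (the measured value is a sufficiency
bound; the boundary is assigned to the sufficient side).

## Synthetic data: what is emulated

All generators route randomness through one seeded `numpy.random.Generator`;
a fixed seed reproduces outputs bit for bit, and truth records carry the
seed.

**Molecular weights.** Log-normal by default. Given targets (Mn, Mw), the
parameters follow uniquely from PDI = Mw/Mn = exp(s²) and
µ = ln Mn − s²/2. The monodisperse limit returns the target exactly. The
default study targets are the 4 h values Mn = 2.42 MDa, Mw = 6.76 MDa.
Note an intrinsic statistical fact: with PDI ≈ 2.8 the sample Mw of 10⁵
i.i.d. draws still has a relative standard deviation of ~2.2%, so
moment-recovery checks at the few-percent level are dominated by sampling
noise, not by the pipeline.

**Spherical brushes.** Default 8 µm silica beads (R = 4 µm) imaged at
100 nm lateral pixels and a 470 nm axial step (the lateral pixel is
configurable; the instrument regime is 30–60 nm, and 100 nm keeps full
stacks cheap without changing any conclusion at the 0.1 µm scale of the
radial bins). The brush channel follows I(r) = I₀ exp(−(r−R)/λ) for
0 ≤ r−R ≤ h and is truncated beyond the brush height h; λ defaults to
1.5 µm. A surface-marker (GFPn-like) channel is a Gaussian shell (σ =
150 nm) at the bead surface; an optional nanoparticle channel applies a
logistic exclusion factor per sphere. SNR is defined as I₀ over the
Gaussian background sd (study condition: SNR 20, emulating the
3.75 ± 0.30 µm regime). Because the profile is truncated at h, the
generator requires exactly h of lateral clearance around each sphere (an
untruncated exponential would need h + 3λ); spheres whose envelopes touch
are flagged `overlap`.

**Planar brushes.** 100 nm axial step. Exponential brush decay above the
substrate, truncated at h (default study condition h = 2.62 µm); the
nanoparticle channel rises from 0 to its bulk plateau through a logistic
edge of width 2 axial voxels centred at substrate + h (the measured
exclusion edge is sharp but has no stated analytic shape); the dextran
channel penetrates with a linear gradient reaching 1 − depletion of bulk at
the surface (default depletion 0.5); a surface-marker peak sits at the
substrate.

**Nanopore traces.** 200 kHz sampling, 4 nA baseline, 10 pA Gaussian
noise. Each molecule produces one rectangular pulse of fixed depth 150 pA
and duration (M/1 MDa)·5 ms, so ECD ∝ M — only the ECD, never the pulse
shape, is used downstream. Durations are quantised to the sample grid and
the recorded per-event truth ECD is the realised depth × samples × dt, so a
noiseless trace integrates back to it exactly. Pulses are laid out
sequentially with exponential gaps (10 s⁻¹) plus a 5 ms minimum, so events
never overlap. The four-pole Bessel hardware filter is not emulated; only
the digital 5 kHz low-pass contract matters for synthetic traces.

**Biofilms.** Ellipsoidal cell bodies (default 2 × 1 × 1 µm rods lying on
the substrate, random in-plane orientation, Poisson counts at the requested
surface density) rendered on a 100 × 100 × 100 nm grid — the axial step
matches planar imaging; at coarser steps (200–470 nm) the voxelisation
error of a 1 µm body alone exceeds the 5% accuracy the volume checks
demand. The exact pre-blur voxelised volume is the ground truth; the
rendered image adds a 150 nm Gaussian blur and Gaussian noise.

**Not emulated:** optical PSF beyond Gaussian blur, photobleaching, pore
conductance physics, baseline drift, folded/multi-level translocations,
biofilm architecture. Passing tests therefore demonstrate correctness of
the measurement chain under idealised imaging, not robustness to structured
artefacts of real micrographs.

## Confocal profile analysis

Microspheres are segmented on the surface-marker channel: light Gaussian
smoothing (1 voxel — sparse bright shells otherwise make the Otsu split
unstable), Otsu threshold, a guard that returns no detections when the
threshold merely splits noise (foreground/background class separation
< 4 background sd), hole filling, labelling; centroids in physical nm,
radius from the equivalent sphere of the filled volume, border-touching
components flagged.

Radial profiles are azimuthal averages over cones (full aperture 30°, i.e.
15° half-angle) from the sphere centre, binned at the lateral pixel size;
the profile stops where the cone axis exits the stack. The default cone set
is the four equatorial axes ±x, ±y. A cone is "clear" only if no
neighbouring sphere's brush envelope (radius + configurable h_max)
intersects its angular sector. Background mean and sd come from the
outermost 50 populated bins; shorter profiles raise rather than silently
shrinking the tail.

The brush edge is the outermost bin at or above `mean + 2 sd` sustained for
3 consecutive bins inward (single background spikes cannot fake an edge),
refined by linear interpolation to the crossing; the surface is the
interior maximum of the surface-marker profile with parabolic sub-bin
refinement, falling back (flagged) to the nominal radius when no interior
peak exists. Height = edge − surface per cone. Per sphere, the cone set is
summarised by its **median**: radial bins near the sphere hold fewer voxels
than the far-tail bins the background sd is estimated from, so a lone cone
occasionally latches onto a sustained background fluctuation; the median of
the cone set is insensitive to one such outlier (the mean remains available
via configuration). Population statistics are the mean ± sd over spheres.

Planar heights use laterally averaged axial profiles. The exclusion height
is the half-maximum of the nanoparticle rise (plateau from the topmost 20%
of slices, floor from the bottommost slices above the surface) minus the
substrate position; a bright but flat particle channel reads as height 0
("no exclusion"), a channel with no plateau at all is flagged invalid. The
half-maximum convention is this package's own definition of the exclusion
edge. The labelled-brush (GFPn) height applies the same 2σ edge rule with
the background taken from the topmost 50 slices. Exponential profile fits
(I₀, λ, bg by least squares) require ≥ 5 bins between surface and edge and
reject fits whose amplitude is indistinguishable from the background noise.

## Nanopore analysis

The baseline is the linear interpolation of non-overlapping window medians
with σ = 1.4826 × median |x − baseline| (MAD); both are insensitive to
events occupying a minority of each window. The end-to-end pipeline
defaults the window to 1 s (clamped to half the trace) so that even
100 ms-class events never dominate a window. Detection runs on the
filtered trace (filtering precedes detection in the measurement chain):
maximal runs deeper than k·σ (k = 5) below baseline form cores, each core
extends to the nearest baseline re-crossings so shallow shoulders count
toward the ECD, overlapping extents merge, and the inclusive duration gate
[25 µs, 2.5 s] rejects the rest with reason codes. Events touching the
first or last sample are rejected too — their boundaries are unresolvable
and the zero-phase filter leaves settling transients at the trace ends.
σ = 0 on a non-constant trace is a degenerate-noise error. ECD is the
left-Riemann sum of the deficit (exact for on-grid rectangles; trapezoidal
optional), clamped at ≥ 0. Calibration fits log M = a + b log ECD to ≥ 2
monotone standards; predictions outside the standards' ECD range are
flagged extrapolations. Overlapping events are not split (no multi-level
fitting).

## Biofilm quantification

High-pass = image minus its Gaussian blur (default σ = 2 µm, well above the
cell size and below the field size). The default threshold is
"otsu-midpoint": with sparse compact bodies the raw Otsu cut (like
isodata/Li/Yen/triangle, all evaluated) falls well below the bodies'
half-maximum and sweeps the optical-blur skirt into the foreground,
inflating volumes by >10%; the refinement takes Otsu's split, estimates the
core-foreground level with a second Otsu cut inside the foreground, and
thresholds at the background/core midpoint — approximately the half-maximum
boundary (measured ≈ −5% on generator truth). Plain Otsu and a fixed
threshold remain available; a guard empties the mask when the split
separates classes by < 4 background sd (all-noise stacks). Biovolume is
nonzero voxels × voxel volume, totals plus a near-surface band (default
0–5 µm above the configured surface; bands beyond the stack are clipped
with a warning). Cell counts divide by a per-cell volume (default 1 µm³, a
typical rod bacterium — the conversion factor is this package's choice).
Retention compares mean biovolumes across regions as percent reduction and
fold ratio, with SEM over regions and an explicit infinite-fold flag.

## Problem sizes and tolerances

The test suite and acceptance script use: 30 single-sphere stacks
(~270 × 270 × 23 voxels each) for spherical height recovery; one planar
stack (120 × 48 × 48); 10⁵ draws for direct MW moment checks and 200
molecules (~26 s of 200 kHz trace) for the end-to-end pipeline; 100 random
traces of ≤ 10⁵ samples for detector/oracle equivalence; 128 × 128-pixel
biofilm fields. These sizes keep the whole suite around a minute while
leaving every statistical check dominated by the quantity under test.
Fixed seeds (0, or enumerated small integers) are used throughout;
`scripts/acceptance.py` derives all sub-seeds from its `--seed` argument.

## Known limitations

* The edge rule assumes homoscedastic profile noise; radial bins with few
  voxels are noisier than the far tail, which is why the cone-median
  summary exists. A per-bin, count-aware threshold would be the principled
  extension.
* Exclusion heights depend weakly on the configured plateau/floor
  fractions for strongly non-monotone particle profiles.
* The ECD→MW map is only as good as its standards; synthetic standards are
  generated from the same forward map, so calibration-model mismatch is not
  probed.
* Biovolume accuracy degrades with axial steps ≳ 200 nm for micron-sized
  cells (voxelisation) and with cell densities high enough that bodies
  merge (threshold bias).
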