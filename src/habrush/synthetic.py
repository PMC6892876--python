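"""Synthetic confocal stacks, nanopore traces and MW samples with ground truth.

Every generator emulates one class of raw data the analysis pipeline
consumes, at the conditions of the emulated experiments:

* polydisperse HA molecular weights — log-normal by default, parameterised by
  (Mn, Mw) through PDI = Mw/Mn = exp(sigma^2);
* spherical brushes on 8 um microspheres (exponential radial concentration
  profile, truncated at the brush height, with a surface-marker shell and an
  optional nanoparticle-exclusion channel);
* planar brushes (exponential axial profile, logistic nanoparticle exclusion
  edge, linear dextran depletion gradient);
* resistive-pulse current traces (rectangular negative pulses on a noisy
  baseline, with ECD = amplitude x duration mapped linearly from MW);
* sparse fluorescent bacterial voxel fields (blurred ellipsoids near the
  substrate) with an exact voxelised biovolume.

All randomness flows through one seeded ``numpy.random.Generator``; a fixed
seed reproduces every output bit-for-bit.  Truth records carry the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

from .errors import DomainError, GeometryError, InvalidSpecError
from .geometry import ImageStack, VoxelGeometry
from .nanopore import MWDistribution, NanoporeTrace

__all__ = [
    "MWGeneratorSpec",
    "sample_mw_distribution",
    "SphericalBrushTruth",
    "PlanarBrushTruth",
    "generate_spherical_brush_stack",
    "generate_planar_brush_stack",
    "spherical_scene",
    "planar_scene",
    "SyntheticTraceSpec",
    "TrueEvent",
    "generate_nanopore_trace",
    "BiofilmTruth",
    "generate_biofilm_stack",
    "ellipsoid_mask",
]


# --------------------------------------------------------------------------
# molecular-weight sampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MWGeneratorSpec:
    """Specification for sampling a polydisperse MW distribution.

    Either (mn_da, mw_da) targets or explicit log-normal (mu, sigma) must be
    given.  For the log-normal family the targets determine the parameters
    uniquely: PDI = Mw/Mn = exp(sigma^2) and Mn = exp(mu + sigma^2/2).
    """

    n: int
    mn_da: float | None = None
    mw_da: float | None = None
    mu: float | None = None
    sigma: float | None = None
    family: str = "lognormal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidSpecError("n must be >= 1")
        if self.family != "lognormal":
            raise InvalidSpecError(f"unknown MW family {self.family!r}")
        by_targets = self.mn_da is not None or self.mw_da is not None
        by_params = self.mu is not None or self.sigma is not None
        if by_targets and by_params:
            raise InvalidSpecError("give either (mn_da, mw_da) or (mu, sigma), not both")
        if by_targets:
            if self.mn_da is None or self.mw_da is None:
                raise InvalidSpecError("both mn_da and mw_da are required")
            if not self.mn_da > 0:
                raise InvalidSpecError("Mn must be > 0")
            if self.mw_da < self.mn_da:
                raise InvalidSpecError("Mw must be >= Mn (PDI >= 1)")
        elif by_params:
            if self.mu is None or self.sigma is None:
                raise InvalidSpecError("both mu and sigma are required")
            if self.sigma < 0:
                raise InvalidSpecError("sigma must be >= 0")
        else:
            raise InvalidSpecError("no distribution parameters given")

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of ln(M)."""
        if self.mu is not None:
            return float(self.mu), float(self.sigma)
        var = math.log(self.mw_da / self.mn_da)  # sigma^2 = ln(PDI)
        return math.log(self.mn_da) - var / 2.0, math.sqrt(var)


def sample_mw_distribution(
    spec: MWGeneratorSpec, rng: np.random.Generator | None = None
) -> MWDistribution:
    """Draw ``spec.n`` molecular weights; moments converge to the targets."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    mu, sigma = spec.lognormal_params()
    if sigma == 0.0:  # monodisperse limit: exact, not exp(log(M))
        value = spec.mn_da if spec.mn_da is not None else math.exp(mu)
        weights = np.full(spec.n, value)
    else:
        weights = rng.lognormal(mean=mu, sigma=sigma, size=spec.n)
    return MWDistribution(weights)


# --------------------------------------------------------------------------
# confocal brush stacks
# --------------------------------------------------------------------------

@dataclass
class SphericalBrushTruth:
    """Ground truth for one brush-coated microsphere.

    ``center_nm`` is (z, y, x).  The brush channel follows
    ``I(r) = amplitude * exp(-(r - R)/decay)`` for R <= r <= R + height and is
    zero beyond; the surface-marker channel is a Gaussian shell at r = R.
    """

    center_nm: tuple[float, float, float]
    height_nm: float
    decay_nm: float
    radius_nm: float = 4000.0
    amplitude: float = 100.0
    bg_mean: float = 10.0
    bg_sd: float = 5.0
    surface_width_nm: float = 150.0
    overlap: bool = False

    def __post_init__(self) -> None:
        if not self.height_nm >= 0:
            raise InvalidSpecError("brush height must be >= 0")
        if not self.decay_nm > 0:
            raise InvalidSpecError("decay length must be > 0")
        if not self.radius_nm > 0:
            raise InvalidSpecError("sphere radius must be > 0")
        if self.bg_sd < 0:
            raise InvalidSpecError("background sd must be >= 0")


def _voxel_coords(shape_zyx, geom: VoxelGeometry):
    nz, ny, nx = shape_zyx
    z = (np.arange(nz) * geom.dz)[:, None, None]
    y = (np.arange(ny) * geom.dy)[None, :, None]
    x = (np.arange(nx) * geom.dx)[None, None, :]
    return z, y, x


def generate_spherical_brush_stack(
    truths: list[SphericalBrushTruth] | SphericalBrushTruth,
    geom: VoxelGeometry,
    shape_zyx: tuple[int, int, int],
    seed: int | None = 0,
    *,
    include_particles: bool = False,
    particle_plateau: float = 80.0,
    particle_edge_nm: float | None = None,
) -> tuple[ImageStack, list[SphericalBrushTruth]]:
    """Render microsphere brushes into a (brush, surface[, particles]) stack.

    Spheres must fit inside the stack everywhere and keep a lateral clearance
    of ``height + 3*decay`` (the analysed sides) to the stack boundary.
    Spheres whose brush envelopes touch (centre distance < sum of R + h) get
    their ``overlap`` flag set in the returned truth records.
    """
    if isinstance(truths, SphericalBrushTruth):
        truths = [truths]
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape_zyx
    extent = geom.extent_nm(shape_zyx)

    for t in truths:
        cz, cy, cx = t.center_nm
        for c, hi, label in ((cz, extent[0], "z"), (cy, extent[1], "y"), (cx, extent[2], "x")):
            if c - t.radius_nm < 0 or c + t.radius_nm > hi:
                raise GeometryError(f"sphere clipped by stack bounds along {label}")
        # the rendered profile is truncated at the brush height, so the signal
        # needs exactly `height` of clearance on the analysed (lateral) sides
        clearance = t.height_nm
        for c, hi in ((cy, extent[1]), (cx, extent[2])):
            if c - t.radius_nm - clearance < 0 or c + t.radius_nm + clearance > hi:
                raise GeometryError(
                    "insufficient lateral clearance: the brush envelope must fit the stack"
                )

    for i, a in enumerate(truths):
        for b in truths[i + 1 :]:
            d = math.dist(a.center_nm, b.center_nm)
            if d < (a.radius_nm + a.height_nm) + (b.radius_nm + b.height_nm):
                a.overlap = b.overlap = True

    z, y, x = _voxel_coords(shape_zyx, geom)
    brush = np.zeros(shape_zyx, dtype=np.float64)
    surface = np.zeros_like(brush)
    particles = None
    if include_particles:
        particles = np.full(shape_zyx, 1.0)

    for t in truths:
        cz, cy, cx = t.center_nm
        r = np.sqrt((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2)
        rs = r - t.radius_nm  # distance from the sphere surface
        shell = (rs >= 0) & (rs <= t.height_nm)
        with np.errstate(over="ignore"):
            brush[shell] += t.amplitude * np.exp(-rs[shell] / t.decay_nm)
        surface += t.amplitude * np.exp(-(rs**2) / (2 * t.surface_width_nm**2))
        if particles is not None:
            w = particle_edge_nm if particle_edge_nm is not None else 2 * geom.dx
            particles *= 1.0 / (1.0 + np.exp(np.clip(-(rs - t.height_nm) / w, -500, 500)))

    ref = truths[0]
    layers = [brush, surface]
    names = ["brush", "surface"]
    if particles is not None:
        layers.append(particle_plateau * particles)
        names.append("particles")
    data = np.stack(layers).astype(np.float64)
    data += rng.normal(ref.bg_mean, ref.bg_sd, size=data.shape) if ref.bg_sd > 0 else ref.bg_mean
    stack = ImageStack(
        data.astype(np.float32),
        geom,
        tuple(names),
        metadata={"seed": seed, "kind": "spherical-brush"},
    )
    return stack, truths


def spherical_scene(
    height_nm: float = 3750.0,
    decay_nm: float = 1500.0,
    *,
    snr: float = 20.0,
    radius_nm: float = 4000.0,
    geom: VoxelGeometry | None = None,
    n_tail: int = 50,
    seed: int | None = 0,
    include_particles: bool = False,
) -> tuple[ImageStack, SphericalBrushTruth]:
    """One centred microsphere in a stack just large enough for analysis.

    The lateral half-extent leaves room for the sphere, the brush, the
    spec'd clearance and ``n_tail`` background bins; the axial extent covers
    the sphere with a small margin (profiles are taken near the equator).
    ``snr`` is amplitude / background sd.
    """
    geom = geom or VoxelGeometry(dx=100.0, dy=100.0, dz=470.0)
    amplitude = 100.0
    truth = SphericalBrushTruth(
        center_nm=(0.0, 0.0, 0.0),  # placeholder, set below
        height_nm=height_nm,
        decay_nm=decay_nm,
        radius_nm=radius_nm,
        amplitude=amplitude,
        bg_sd=amplitude / snr if snr > 0 else 0.0,
    )
    half_lateral = radius_nm + height_nm + 3 * decay_nm + (n_tail + 10) * geom.dx
    half_axial = radius_nm + 2 * geom.dz
    nx = 2 * int(math.ceil(half_lateral / geom.dx)) + 1
    nz = 2 * int(math.ceil(half_axial / geom.dz)) + 1
    center = ((nz // 2) * geom.dz, (nx // 2) * geom.dy, (nx // 2) * geom.dx)
    truth.center_nm = center
    stack, (truth,) = generate_spherical_brush_stack(
        truth, geom, (nz, nx, nx), seed, include_particles=include_particles
    )
    return stack, truth


@dataclass
class PlanarBrushTruth:
    """Ground truth for a planar brush grown up from a substrate plane.

    Brush intensity decays exponentially above ``substrate_z_nm`` and is
    truncated at the brush height; the nanoparticle channel rises from ~0 to
    its bulk plateau through a logistic edge of width ``particle_edge_nm``
    centred at substrate + height; the dextran channel penetrates with a
    linear gradient reaching ``1 - dextran_depletion`` of bulk at the surface.
    """

    height_nm: float
    decay_nm: float
    substrate_z_nm: float = 500.0
    amplitude: float = 100.0
    bg_mean: float = 10.0
    bg_sd: float = 5.0
    particle_plateau: float = 80.0
    particle_edge_nm: float | None = None  # default: 2 axial voxels
    dextran_plateau: float = 80.0
    dextran_depletion: float = 0.5
    surface_width_nm: float = 100.0

    def __post_init__(self) -> None:
        if self.height_nm < 0 or self.substrate_z_nm < 0:
            raise InvalidSpecError("height and substrate z must be >= 0")
        if not self.decay_nm > 0:
            raise InvalidSpecError("decay length must be > 0")
        if not 0 <= self.dextran_depletion <= 1:
            raise InvalidSpecError("dextran depletion must lie in [0, 1]")
        if self.bg_sd < 0:
            raise InvalidSpecError("background sd must be >= 0")


def generate_planar_brush_stack(
    truth: PlanarBrushTruth,
    geom: VoxelGeometry,
    shape_zyx: tuple[int, int, int],
    seed: int | None = 0,
) -> tuple[ImageStack, PlanarBrushTruth]:
    """Render a planar brush into a (brush, particles, dextran, surface) stack."""
    nz, ny, nx = shape_zyx
    z_top = (nz - 1) * geom.dz
    if z_top < truth.substrate_z_nm + truth.height_nm + 3 * truth.decay_nm:
        raise GeometryError(
            "stack z-extent must reach substrate + height + 3*decay"
        )
    rng = np.random.default_rng(seed)
    z = np.arange(nz) * geom.dz
    z0, h = truth.substrate_z_nm, truth.height_nm
    zr = z - z0

    brush_z = np.where(
        (zr >= 0) & (zr <= h), truth.amplitude * np.exp(-np.maximum(zr, 0) / truth.decay_nm), 0.0
    )
    w = truth.particle_edge_nm if truth.particle_edge_nm is not None else 2 * geom.dz
    if h > 0:
        particles_z = truth.particle_plateau / (1.0 + np.exp(np.clip(-(zr - h) / w, -500, 500)))
        particles_z = np.where(zr >= 0, particles_z, 0.0)
    else:
        particles_z = np.where(zr >= 0, truth.particle_plateau, 0.0)
    if h > 0:
        frac = np.clip(zr / h, 0.0, 1.0)
        dex_z = truth.dextran_plateau * ((1 - truth.dextran_depletion) + truth.dextran_depletion * frac)
        dex_z = np.where(zr >= 0, dex_z, 0.0)
    else:
        dex_z = np.where(zr >= 0, truth.dextran_plateau, 0.0)
    surface_z = truth.amplitude * np.exp(-(zr**2) / (2 * truth.surface_width_nm**2))

    data = np.stack(
        [np.broadcast_to(c[:, None, None], shape_zyx) for c in (brush_z, particles_z, dex_z, surface_z)]
    ).astype(np.float64)
    data = data + (
        rng.normal(truth.bg_mean, truth.bg_sd, size=data.shape) if truth.bg_sd > 0 else truth.bg_mean
    )
    stack = ImageStack(
        data.astype(np.float32),
        geom,
        ("brush", "particles", "dextran", "surface"),
        metadata={"seed": seed, "kind": "planar-brush"},
    )
    return stack, truth


def planar_scene(
    height_nm: float = 2620.0,
    decay_nm: float = 1000.0,
    *,
    snr: float = 20.0,
    geom: VoxelGeometry | None = None,
    lateral: int = 48,
    n_tail: int = 50,
    seed: int | None = 0,
) -> tuple[ImageStack, PlanarBrushTruth]:
    """A planar brush stack sized for both exclusion and edge-rule analysis."""
    geom = geom or VoxelGeometry(dx=100.0, dy=100.0, dz=100.0)
    truth = PlanarBrushTruth(
        height_nm=height_nm,
        decay_nm=decay_nm,
        bg_sd=100.0 / snr if snr > 0 else 0.0,
    )
    nz = int(
        math.ceil((truth.substrate_z_nm + height_nm + 3 * decay_nm) / geom.dz)
    ) + n_tail + 10
    return generate_planar_brush_stack(truth, geom, (nz, lateral, lateral), seed)


# --------------------------------------------------------------------------
# nanopore traces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Forward model for a resistive-pulse recording.

    Each molecule of weight M produces a rectangular pulse of fixed depth
    ``amplitude_pa`` and duration ``(M / 1 MDa) * duration_s_per_mda``, so the
    event charge deficit is proportional to M.  Pulses are laid out
    sequentially with exponential gaps (rate ``event_rate_hz``) plus a
    minimum spacing, so events never overlap.
    """

    sampling_rate_hz: float = 200e3
    baseline_pa: float = 4000.0
    noise_sd_pa: float = 10.0
    event_rate_hz: float = 10.0
    amplitude_pa: float = 150.0
    duration_s_per_mda: float = 5e-3
    min_gap_s: float = 5e-3
    pad_s: float = 0.1
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not self.sampling_rate_hz > 0:
            raise InvalidSpecError("sampling rate must be > 0")
        if self.noise_sd_pa < 0:
            raise InvalidSpecError("noise sd must be >= 0")
        if not self.amplitude_pa > 0 or not self.duration_s_per_mda > 0:
            raise InvalidSpecError("amplitude and duration scale must be > 0")
        if not self.event_rate_hz > 0:
            raise InvalidSpecError("event rate must be > 0")

    def duration_s(self, mw_da: float) -> float:
        return (mw_da / 1e6) * self.duration_s_per_mda

    def ecd_pas(self, mw_da: float) -> float:
        """Forward-map ECD for a molecule, before sample-grid quantisation."""
        return self.amplitude_pa * self.duration_s(mw_da)


@dataclass
class TrueEvent:
    """Generator-side record of one rendered pulse (half-open sample indices)."""

    start: int
    end: int
    mw_da: float
    amplitude_pa: float
    duration_s: float
    ecd_pas: float  # realised (grid-quantised) amplitude x duration


def generate_nanopore_trace(
    mw: MWDistribution | None,
    spec: SyntheticTraceSpec,
) -> tuple[NanoporeTrace, list[TrueEvent]]:
    """Render one pulse per molecule onto a noisy baseline.

    Durations are quantised to the sample grid (minimum one sample); the
    recorded per-event ECD is the realised ``amplitude x n_samples x dt`` so
    that a noiseless trace integrates back to it exactly.  An empty or None
    distribution yields a pure-baseline trace.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_hz
    dt = 1.0 / fs
    weights = np.empty(0) if mw is None else np.asarray(mw.weights_da, dtype=float)

    durations = np.array([spec.duration_s(m) for m in weights])
    if durations.size and np.any(durations < dt):
        raise InvalidSpecError(
            "requested pulse durations fall below one sample interval"
        )
    n_samp = np.maximum(1, np.round(durations * fs).astype(int)) if durations.size else np.empty(0, int)

    events: list[TrueEvent] = []
    cursor = int(round(spec.pad_s * fs))
    gaps = rng.exponential(1.0 / spec.event_rate_hz, size=weights.size)
    for m, ns, gap in zip(weights, n_samp, gaps):
        cursor += int(round((gap + spec.min_gap_s) * fs))
        start, end = cursor, cursor + int(ns)
        events.append(
            TrueEvent(
                start=start,
                end=end,
                mw_da=float(m),
                amplitude_pa=spec.amplitude_pa,
                duration_s=ns * dt,
                ecd_pas=spec.amplitude_pa * ns * dt,
            )
        )
        cursor = end
    total = cursor + int(round(spec.pad_s * fs))
    total = max(total, 2)

    x = np.full(total, spec.baseline_pa, dtype=np.float64)
    for ev in events:
        x[ev.start : ev.end] -= ev.amplitude_pa
    if spec.noise_sd_pa > 0:
        x += rng.normal(0.0, spec.noise_sd_pa, size=total)
    trace = NanoporeTrace(
        x,
        fs,
        metadata={"seed": spec.seed, "baseline_pa": spec.baseline_pa, "noise_sd_pa": spec.noise_sd_pa},
    )
    return trace, events


# --------------------------------------------------------------------------
# biofilm stacks
# --------------------------------------------------------------------------

def ellipsoid_mask(
    shape_zyx: tuple[int, int, int],
    geom: VoxelGeometry,
    center_nm: tuple[float, float, float],
    semi_axes_nm: tuple[float, float, float],
    theta_rad: float = 0.0,
) -> np.ndarray:
    """Boolean mask of voxel centres inside an ellipsoid.

    ``semi_axes_nm`` are (in-plane long, in-plane short, axial); ``theta_rad``
    rotates the long axis within the xy-plane.
    """
    a, b, c = semi_axes_nm
    if min(a, b, c) <= 0:
        raise DomainError("semi-axes must be > 0")
    z, y, x = _voxel_coords(shape_zyx, geom)
    cz, cy, cx = center_nm
    u = math.cos(theta_rad) * (x - cx) + math.sin(theta_rad) * (y - cy)
    v = -math.sin(theta_rad) * (x - cx) + math.cos(theta_rad) * (y - cy)
    return (u / a) ** 2 + (v / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


@dataclass
class BiofilmTruth:
    """Ground truth for a synthetic bacterial field."""

    n_cells: int
    biovolume_um3: float  # exact voxelised volume of the union of cell bodies
    mask: np.ndarray = field(repr=False)
    seed: int | None = None


def generate_biofilm_stack(
    surface_density_per_um2: float,
    geom: VoxelGeometry | None = None,
    shape_zyx: tuple[int, int, int] = (52, 256, 256),
    seed: int | None = 0,
    *,
    axes_um: tuple[float, float, float] = (2.0, 1.0, 1.0),
    amplitude: float = 100.0,
    bg_mean: float = 10.0,
    bg_sd: float = 2.0,
    blur_sigma_nm: float = 150.0,
    z_jitter_um: float = 0.3,
    n_cells: int | None = None,
) -> tuple[ImageStack, BiofilmTruth]:
    """Scatter blurred ellipsoidal cell bodies near the substrate plane.

    ``axes_um`` are full ellipsoid axes (long in-plane, short in-plane,
    axial) — the default is a 2 x 1 x 1 um rod lying on the surface.  The cell
    count is Poisson with mean density x area unless ``n_cells`` is forced.
    Returns the stack plus the exact pre-blur voxelised biovolume.
    """
    if surface_density_per_um2 < 0:
        raise DomainError("surface density must be >= 0")
    geom = geom or VoxelGeometry(dx=100.0, dy=100.0, dz=100.0)  # planar-imaging z step
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape_zyx
    area_um2 = (ny * geom.dy * 1e-3) * (nx * geom.dx * 1e-3)
    n = rng.poisson(surface_density_per_um2 * area_um2) if n_cells is None else n_cells

    semi = (axes_um[0] * 500.0, axes_um[1] * 500.0, axes_um[2] * 500.0)  # nm
    mask = np.zeros(shape_zyx, dtype=bool)
    for _ in range(n):
        cy = rng.uniform(semi[0], (ny - 1) * geom.dy - semi[0])
        cx = rng.uniform(semi[0], (nx - 1) * geom.dx - semi[0])
        cz = semi[2] + rng.uniform(0.0, z_jitter_um * 1000.0)
        theta = rng.uniform(0.0, math.pi)
        mask |= ellipsoid_mask(shape_zyx, geom, (cz, cy, cx), semi, theta)

    biovolume = float(mask.sum()) * geom.voxel_volume_um3
    img = mask.astype(np.float64) * amplitude
    if blur_sigma_nm > 0:
        img = ndi.gaussian_filter(img, sigma=blur_sigma_nm / geom.spacing_zyx_nm)
    img += rng.normal(bg_mean, bg_sd, size=img.shape) if bg_sd > 0 else bg_mean
    stack = ImageStack(
        img.astype(np.float32)[None],
        geom,
        ("bacteria",),
        metadata={"seed": seed, "kind": "biofilm"},
    )
    return stack, BiofilmTruth(n_cells=int(n), biovolume_um3=biovolume, mask=mask, seed=seed)
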