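"""Brush concentration-profile extraction from confocal stacks.

The spherical-brush pipeline mirrors how giant HA brushes on microspheres
are measured: segment the microspheres, extract azimuthally averaged radial
intensity profiles from 30-degree cones around each centre (skipping cones
aimed at neighbouring brushes), estimate the background from the outermost
50 profile points, place the brush edge at the outermost sustained crossing
of ``background mean + 2 sd``, and take the surface-marker (GFPn) peak as
the sphere surface.  Brush height = edge - surface.

Planar brushes use either the same edge rule on the axial profile or the
particle-exclusion readout: the height is where the nanoparticle intensity
rises to half of its bulk plateau above the substrate.

Anisotropic voxels are handled by converting indices to physical nm before
binning; the stack is never resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogramError, ProfileError
from .geometry import ImageStack, VoxelGeometry

__all__ = [
    "RadialProfile",
    "AxialProfile",
    "BackgroundStats",
    "EdgeResult",
    "SurfaceResult",
    "BrushHeightResult",
    "SphereDetection",
    "SphereAnalysisConfig",
    "PlanarAnalysisConfig",
    "SphericalHeightReport",
    "ExponentialFit",
    "otsu_threshold",
    "segment_sphere_centers",
    "cone_profile",
    "background_stats",
    "detect_brush_edge",
    "detect_surface",
    "spherical_brush_height",
    "planar_exclusion_height",
    "planar_edge_height",
    "axial_profile",
    "fit_exponential_profile",
]


@dataclass
class RadialProfile:
    """Mean intensity versus distance, with bin geometry and provenance.

    ``r_nm`` are strictly increasing bin centres; bins with ``counts == 0``
    hold NaN intensity.  For axial (planar) profiles ``r_nm`` is the z
    coordinate and axis/aperture are None.
    """

    r_nm: np.ndarray
    intensity: np.ndarray
    counts: np.ndarray
    axis: tuple[float, float, float] | None = None
    aperture_deg: float | None = None
    channel: str | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        self.r_nm = np.asarray(self.r_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.r_nm) <= 0):
            raise ProfileError("bin centers must be strictly increasing")
        if self.aperture_deg is not None and not 0 < self.aperture_deg <= 180:
            raise ProfileError("aperture must lie in (0, 180] degrees")

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, intensity) restricted to populated bins."""
        m = self.counts > 0
        return self.r_nm[m], self.intensity[m]


AxialProfile = RadialProfile


@dataclass(frozen=True)
class BackgroundStats:
    """Mean/sd of the far-field background, from the profile tail."""

    mean: float
    sd: float
    n_tail: int


@dataclass(frozen=True)
class EdgeResult:
    r_nm: float
    found: bool
    flag: str = ""


@dataclass(frozen=True)
class SurfaceResult:
    r_nm: float
    method: str  # "peak" | "nominal"
    flag: str = ""


@dataclass
class BrushHeightResult:
    """A brush height with the locations it was derived from and QC flags."""

    height_nm: float
    method: str  # edge_2sigma | particle_exclusion | gfpn
    surface_nm: float
    edge_nm: float
    flags: tuple[str, ...] = ()
    n_cones: int = 0

    @property
    def valid(self) -> bool:
        return math.isfinite(self.height_nm) and self.height_nm >= 0


def otsu_threshold(intensities) -> float:
    """Otsu's histogram threshold (maximal between-class variance).

    Raises on (near-)constant input, where no threshold separates anything.
    """
    arr = np.asarray(intensities).ravel()
    if arr.size < 2 or np.ptp(arr) == 0:
        raise DegenerateHistogramError("need >= 2 distinct intensity values")
    return float(threshold_otsu(arr))


@dataclass(frozen=True)
class SphereDetection:
    """One segmented microsphere: centroid and equivalent-sphere radius."""

    center_nm: tuple[float, float, float]
    radius_nm: float
    n_voxels: int
    touches_border: bool


def segment_sphere_centers(
    stack: ImageStack,
    channel: str = "surface",
    *,
    smooth_sigma_vox: float = 1.0,
    min_voxels: int = 500,
) -> list[SphereDetection]:
    """Locate microsphere centres by Otsu segmentation of a marker channel.

    The channel is lightly smoothed (sparse bright structures make the raw
    Otsu split unstable), thresholded, hole-filled and labelled; component
    centroids are returned in physical nm with an equivalent-sphere radius
    from the filled component volume.  Components touching the stack border
    are flagged.  Returns an empty list when nothing exceeds ``min_voxels``
    or when the threshold merely splits noise (weak class separation).
    """
    img = np.asarray(stack.channel(channel), dtype=float)
    sm = ndi.gaussian_filter(img, smooth_sigma_vox) if smooth_sigma_vox > 0 else img
    thr = otsu_threshold(sm)
    raw = sm > thr
    if raw.any() and not raw.all():
        bg = sm[~raw]
        separation = (sm[raw].mean() - bg.mean()) / max(bg.std(), 1e-30)
        if separation < 4.0:  # Otsu found nothing but a noise split
            return []
    mask = ndi.binary_fill_holes(raw)
    labels, n = ndi.label(mask)
    if n == 0:
        return []
    geom = stack.geom
    voxvol_nm3 = geom.dx * geom.dy * geom.dz
    out: list[SphereDetection] = []
    objects = ndi.find_objects(labels)
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    coms = ndi.center_of_mass(mask, labels, index=np.arange(1, n + 1))
    for idx, (size, com, sl) in enumerate(zip(sizes, coms, objects)):
        if size < min_voxels:
            continue
        center = tuple(c * p for c, p in zip(com, geom.spacing_zyx_nm))
        radius = (3.0 * size * voxvol_nm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
        touches = any(
            s.start == 0 or s.stop == dim for s, dim in zip(sl, mask.shape)
        )
        out.append(
            SphereDetection(
                center_nm=center,
                radius_nm=float(radius),
                n_voxels=int(size),
                touches_border=touches,
            )
        )
    return out


def cone_profile(
    image: np.ndarray,
    geom: VoxelGeometry,
    center_nm: tuple[float, float, float],
    axis: tuple[float, float, float],
    *,
    aperture_deg: float = 30.0,
    bin_width_nm: float | None = None,
    r_max_nm: float | None = None,
    channel: str | None = None,
) -> RadialProfile:
    """Azimuthally averaged radial profile over a cone from ``center_nm``.

    ``axis`` is a (z, y, x) direction; every voxel whose direction from the
    centre lies within ``aperture_deg / 2`` of it contributes to the radial
    bin of its physical distance.  Bin width defaults to the lateral pixel
    size.  The profile stops where the cone axis exits the stack; if a larger
    ``r_max_nm`` was requested the profile is flagged truncated.
    """
    if not 0 < aperture_deg <= 180:
        raise ProfileError("aperture must lie in (0, 180] degrees")
    image = np.asarray(image, dtype=float)
    a = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ProfileError("cone axis must be a nonzero direction")
    a = a / norm
    cz, cy, cx = center_nm

    # distance along the axis to the stack boundary (voxel-centre extents)
    extent = geom.extent_nm(image.shape)
    t_exit = math.inf
    for comp, c, hi in zip(a, (cz, cy, cx), extent):
        if comp > 0:
            t_exit = min(t_exit, (hi - c) / comp)
        elif comp < 0:
            t_exit = min(t_exit, -c / comp)
    truncated = r_max_nm is not None and r_max_nm > t_exit
    r_stop = min(r_max_nm, t_exit) if r_max_nm is not None else t_exit

    z = (np.arange(image.shape[0]) * geom.dz - cz)[:, None, None]
    y = (np.arange(image.shape[1]) * geom.dy - cy)[None, :, None]
    x = (np.arange(image.shape[2]) * geom.dx - cx)[None, None, :]
    r = np.sqrt(z**2 + y**2 + x**2)
    dot = z * a[0] + y * a[1] + x * a[2]
    cos_half = math.cos(math.radians(aperture_deg / 2.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        member = (dot >= cos_half * r) & (r <= r_stop) & (r > 0)

    bw = bin_width_nm if bin_width_nm is not None else geom.dx
    idx = (r[member] / bw).astype(np.intp)
    nbins = int(r_stop / bw) + 1
    sums = np.bincount(idx, weights=image[member], minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(nbins) + 0.5) * bw
    return RadialProfile(
        r_nm=centers,
        intensity=mean,
        counts=counts,
        axis=tuple(a),
        aperture_deg=aperture_deg,
        channel=channel,
        truncated=truncated,
    )


def background_stats(profile: RadialProfile, n_tail: int = 50) -> BackgroundStats:
    """Mean and sd of the outermost ``n_tail`` populated bins.

    Profiles shorter than ``n_tail`` raise rather than silently shrinking the
    tail (the background estimate would be biased by brush signal).
    """
    if n_tail < 2:
        raise ProfileError("n_tail must be >= 2")
    _, intensity = profile.valid()
    if intensity.size < n_tail:
        raise ProfileError(
            f"profile has {intensity.size} populated bins; n_tail={n_tail} required"
        )
    tail = intensity[-n_tail:]
    return BackgroundStats(
        mean=float(np.mean(tail)), sd=float(np.std(tail, ddof=1)), n_tail=n_tail
    )


def detect_brush_edge(
    profile: RadialProfile,
    bg: BackgroundStats,
    *,
    n_sigma: float = 2.0,
    k_sustain: int = 3,
) -> EdgeResult:
    """Outermost sustained crossing of ``bg.mean + n_sigma * bg.sd``.

    Scanning from the outermost bin inward, the edge is the outermost bin at
    which the intensity is at or above threshold for ``k_sustain`` consecutive
    bins (continuing inward) — single noise spikes in the background cannot
    fake an edge.  The location is refined by linear interpolation between
    the crossing bin and its outer neighbour.
    """
    if bg.sd < 0:
        raise ProfileError("background sd must be >= 0")
    if k_sustain < 1:
        raise ProfileError("k_sustain must be >= 1")
    r, intensity = profile.valid()
    if r.size < k_sustain:
        return EdgeResult(math.nan, False, "profile-too-short")
    thr = bg.mean + n_sigma * bg.sd
    above = intensity >= thr
    edge_idx = -1
    for i in range(r.size - 1, k_sustain - 2, -1):
        if above[i - k_sustain + 1 : i + 1].all():
            edge_idx = i
            break
    if edge_idx < 0:
        return EdgeResult(math.nan, False, "no-crossing")
    if edge_idx == r.size - 1:
        return EdgeResult(float(r[edge_idx]), True, "edge-at-profile-end")
    i0, i1 = edge_idx, edge_idx + 1
    if intensity[i1] < thr and intensity[i0] > intensity[i1]:
        frac = (intensity[i0] - thr) / (intensity[i0] - intensity[i1])
        r_edge = r[i0] + frac * (r[i1] - r[i0])
    else:
        r_edge = r[i0]
    return EdgeResult(float(r_edge), True)


def detect_surface(
    profile: RadialProfile, nominal_radius_nm: float | None = None
) -> SurfaceResult:
    """Surface location as the interior peak of a surface-marker profile.

    The peak is refined with a parabolic fit through its neighbours.  A peak
    on the first/last bin is not an interior maximum; in that case the
    nominal sphere radius is used (flagged), or an error raised without one.
    """
    r, intensity = profile.valid()
    if r.size < 3:
        raise ProfileError("surface profile needs >= 3 populated bins")
    i = int(np.argmax(intensity))
    interior = 0 < i < r.size - 1
    if not interior or np.ptp(intensity) == 0:
        if nominal_radius_nm is None:
            raise ProfileError("no interior surface peak and no nominal radius")
        return SurfaceResult(float(nominal_radius_nm), "nominal", "no-interior-peak")
    denom = intensity[i - 1] - 2 * intensity[i] + intensity[i + 1]
    delta = 0.0 if denom == 0 else 0.5 * (intensity[i - 1] - intensity[i + 1]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    r_peak = r[i] + delta * (r[min(i + 1, r.size - 1)] - r[i])
    return SurfaceResult(float(r_peak), "peak")


def _default_axes() -> tuple[tuple[float, float, float], ...]:
    # four equatorial cone axes (z, y, x): +/-x and +/-y
    return ((0.0, 0.0, 1.0), (0.0, 0.0, -1.0), (0.0, 1.0, 0.0), (0.0, -1.0, 0.0))


@dataclass
class SphereAnalysisConfig:
    """Tunables of the spherical-brush height pipeline (defaults as measured)."""

    brush_channel: str = "brush"
    surface_channel: str = "surface"
    segment_channel: str = "surface"
    aperture_deg: float = 30.0
    n_tail: int = 50
    n_sigma: float = 2.0
    k_sustain: int = 3
    bin_width_nm: float | None = None
    axes: tuple[tuple[float, float, float], ...] = field(default_factory=_default_axes)
    h_max_nm: float = 5000.0  # generous brush envelope for the clear-cone test
    min_component_voxels: int = 500
    smooth_sigma_vox: float = 1.0
    cone_aggregate: str = "median"  # per-sphere summary over clear cones


@dataclass
class SphericalHeightReport:
    """Per-sphere heights plus population statistics."""

    per_sphere: list[BrushHeightResult]
    mean_nm: float
    sd_nm: float
    n_spheres: int
    n_segmented: int
    flags: tuple[str, ...] = ()


def _cone_is_clear(
    center: np.ndarray,
    axis: np.ndarray,
    others: list[SphereDetection],
    h_max: float,
    half_aperture_deg: float,
) -> bool:
    """True if no neighbouring brush envelope intersects the cone's look direction."""
    for o in others:
        v = np.asarray(o.center_nm) - center
        dist = float(np.linalg.norm(v))
        if dist == 0:
            return False
        blocked_radius = o.radius_nm + h_max
        if dist <= blocked_radius:
            return False
        ang_to_axis = math.acos(float(np.clip(np.dot(v / dist, axis), -1, 1)))
        ang_halo = math.asin(min(1.0, blocked_radius / dist))
        if ang_to_axis <= math.radians(half_aperture_deg) + ang_halo:
            return False
    return True


def spherical_brush_height(
    stack: ImageStack, config: SphereAnalysisConfig | None = None
) -> SphericalHeightReport:
    """Measure brush heights for every segmentable microsphere in a stack.

    Per sphere, each clear cone yields ``height = edge - surface``; the
    sphere's height summarises its clear cones (median by default: radial
    bins near the sphere hold fewer voxels than the far tail the background
    sd is estimated from, so a lone cone can occasionally latch onto a
    sustained background fluctuation, and the median of the cone set is
    insensitive to one such outlier).  The report carries the population
    mean +/- sd.  Spheres with no valid cone are flagged.
    """
    cfg = config or SphereAnalysisConfig()
    detections = segment_sphere_centers(
        stack,
        cfg.segment_channel,
        smooth_sigma_vox=cfg.smooth_sigma_vox,
        min_voxels=cfg.min_component_voxels,
    )
    if not detections:
        return SphericalHeightReport([], math.nan, math.nan, 0, 0, ("no-spheres",))

    brush_img = stack.channel(cfg.brush_channel)
    surf_img = stack.channel(cfg.surface_channel)
    results: list[BrushHeightResult] = []
    for i, det in enumerate(detections):
        others = detections[:i] + detections[i + 1 :]
        center = np.asarray(det.center_nm)
        heights: list[float] = []
        flags: list[str] = []
        n_clear = 0
        for axis in cfg.axes:
            a = np.asarray(axis, dtype=float)
            a /= np.linalg.norm(a)
            if not _cone_is_clear(center, a, others, cfg.h_max_nm, cfg.aperture_deg / 2.0):
                flags.append("cone-overlap")
                continue
            n_clear += 1
            prof = cone_profile(
                brush_img,
                stack.geom,
                det.center_nm,
                tuple(a),
                aperture_deg=cfg.aperture_deg,
                bin_width_nm=cfg.bin_width_nm,
                channel=cfg.brush_channel,
            )
            sprof = cone_profile(
                surf_img,
                stack.geom,
                det.center_nm,
                tuple(a),
                aperture_deg=cfg.aperture_deg,
                bin_width_nm=cfg.bin_width_nm,
                channel=cfg.surface_channel,
            )
            try:
                bg = background_stats(prof, cfg.n_tail)
            except ProfileError:
                flags.append("short-profile")
                continue
            edge = detect_brush_edge(prof, bg, n_sigma=cfg.n_sigma, k_sustain=cfg.k_sustain)
            if not edge.found:
                flags.append(edge.flag)
                continue
            surface = detect_surface(sprof, nominal_radius_nm=det.radius_nm)
            if surface.flag:
                flags.append(surface.flag)
            h = edge.r_nm - surface.r_nm
            if h >= 0:
                heights.append(h)
            else:
                flags.append("negative-height")
        if heights:
            agg = np.median if cfg.cone_aggregate == "median" else np.mean
            h_sphere = float(agg(heights))
            results.append(
                BrushHeightResult(
                    height_nm=h_sphere,
                    method="edge_2sigma",
                    surface_nm=float(det.radius_nm),
                    edge_nm=h_sphere + float(det.radius_nm),
                    flags=tuple(sorted(set(flags))),
                    n_cones=len(heights),
                )
            )
        else:
            results.append(
                BrushHeightResult(
                    height_nm=math.nan,
                    method="edge_2sigma",
                    surface_nm=float(det.radius_nm),
                    edge_nm=math.nan,
                    flags=tuple(sorted(set(flags))) or ("all-cones-failed",),
                    n_cones=0,
                )
            )
    valid = [r.height_nm for r in results if r.valid]
    mean = float(np.mean(valid)) if valid else math.nan
    sd = float(np.std(valid, ddof=1)) if len(valid) > 1 else 0.0 if valid else math.nan
    return SphericalHeightReport(
        per_sphere=results,
        mean_nm=mean,
        sd_nm=sd,
        n_spheres=len(valid),
        n_segmented=len(detections),
    )


def axial_profile(
    stack: ImageStack,
    channel: str,
    roi: tuple[slice, slice] | None = None,
) -> AxialProfile:
    """Laterally averaged intensity per z-slice, as an axial profile."""
    img = np.asarray(stack.channel(channel), dtype=float)
    if roi is not None:
        img = img[:, roi[0], roi[1]]
    mean = img.mean(axis=(1, 2))
    counts = np.full(mean.size, img.shape[1] * img.shape[2])
    z = np.arange(mean.size) * stack.geom.dz
    # bin centres must be strictly increasing and non-degenerate for a 1-bin profile
    return AxialProfile(r_nm=z, intensity=mean, counts=counts, channel=channel)


@dataclass
class PlanarAnalysisConfig:
    """Tunables of the planar-brush height readouts."""

    particle_channel: str = "particles"
    surface_channel: str = "surface"
    brush_channel: str = "brush"
    plateau_frac: float = 0.2  # topmost fraction of slices defining the bulk plateau
    floor_frac: float = 0.1  # bottommost fraction defining the floor
    min_contrast: float = 3.0  # required (plateau - floor) / plateau-noise
    n_tail: int = 50
    n_sigma: float = 2.0
    k_sustain: int = 3
    roi: tuple[slice, slice] | None = None
    surface_z_nm: float | None = None  # override; else surface-marker peak, else z=0


def _locate_planar_surface(stack: ImageStack, cfg: PlanarAnalysisConfig) -> tuple[float, str]:
    if cfg.surface_z_nm is not None:
        return float(cfg.surface_z_nm), ""
    if cfg.surface_channel in stack.channels:
        prof = axial_profile(stack, cfg.surface_channel, cfg.roi)
        try:
            res = detect_surface(prof, nominal_radius_nm=0.0)
            return res.r_nm, res.flag
        except ProfileError:
            return 0.0, "surface-fallback-z0"
    return 0.0, "surface-fallback-z0"


def planar_exclusion_height(
    stack: ImageStack, config: PlanarAnalysisConfig | None = None
) -> BrushHeightResult:
    """Planar brush height from the nanoparticle-exclusion profile.

    The laterally averaged particle intensity rises from ~0 (inside the
    brush) to a bulk plateau above it; the brush top is taken at the
    half-maximum of that rise, and the height is measured from the substrate
    surface.  A profile with no resolvable rise above the surface reads as
    height 0 ("no exclusion"); a channel with no plateau at all is invalid.
    """
    cfg = config or PlanarAnalysisConfig()
    prof = axial_profile(stack, cfg.particle_channel, cfg.roi)
    z, intensity = prof.valid()
    n = z.size
    n_top = max(2, int(round(cfg.plateau_frac * n)))
    n_floor = max(2, int(round(cfg.floor_frac * n)))
    surface_nm, sflag = _locate_planar_surface(stack, cfg)
    flags = [sflag] if sflag else []

    plateau = float(np.mean(intensity[-n_top:]))
    noise = float(np.std(intensity[-n_top:], ddof=1))
    above = z >= surface_nm
    floor_vals = intensity[above][:n_floor]
    floor = float(np.mean(floor_vals)) if floor_vals.size else float(intensity[0])
    rise = plateau - floor

    if rise <= cfg.min_contrast * max(noise, 1e-12):
        if plateau > cfg.min_contrast * max(noise, 1e-12) and floor > 0.5 * plateau:
            return BrushHeightResult(
                0.0, "particle_exclusion", surface_nm, surface_nm,
                tuple(flags + ["no-exclusion"]),
            )
        return BrushHeightResult(
            math.nan, "particle_exclusion", surface_nm, math.nan,
            tuple(flags + ["no-plateau"]),
        )

    half = floor + 0.5 * rise
    below = np.flatnonzero((intensity < half) & above)
    if below.size == 0:
        return BrushHeightResult(
            0.0, "particle_exclusion", surface_nm, surface_nm,
            tuple(flags + ["no-exclusion"]),
        )
    j = int(below[-1])
    if j + 1 < n:
        frac = (half - intensity[j]) / (intensity[j + 1] - intensity[j])
        z_cross = z[j] + float(np.clip(frac, 0, 1)) * (z[j + 1] - z[j])
    else:
        z_cross = z[j]
        flags.append("edge-at-profile-end")
    height = max(0.0, float(z_cross) - surface_nm)
    return BrushHeightResult(
        height, "particle_exclusion", surface_nm, float(z_cross), tuple(flags)
    )


def planar_edge_height(
    stack: ImageStack, config: PlanarAnalysisConfig | None = None
) -> BrushHeightResult:
    """Planar brush height from the labelled-brush (GFPn) channel.

    Applies the same background + 2-sigma sustained-crossing edge rule as the
    spherical pipeline to the axial brush profile, with the background taken
    from the topmost ``n_tail`` slices.
    """
    cfg = config or PlanarAnalysisConfig()
    prof = axial_profile(stack, cfg.brush_channel, cfg.roi)
    surface_nm, sflag = _locate_planar_surface(stack, cfg)
    bg = background_stats(prof, cfg.n_tail)
    edge = detect_brush_edge(prof, bg, n_sigma=cfg.n_sigma, k_sustain=cfg.k_sustain)
    flags = [sflag] if sflag else []
    if not edge.found:
        return BrushHeightResult(
            math.nan, "gfpn", surface_nm, math.nan, tuple(flags + [edge.flag])
        )
    if edge.flag:
        flags.append(edge.flag)
    return BrushHeightResult(
        max(0.0, edge.r_nm - surface_nm), "gfpn", surface_nm, edge.r_nm, tuple(flags)
    )


@dataclass
class ExponentialFit:
    """Parameters of ``I(r) = I0 exp(-(r - surface)/lambda) + bg``."""

    i0: float
    decay_nm: float
    bg: float
    rmse: float
    converged: bool
    flag: str = ""


def fit_exponential_profile(
    profile: RadialProfile,
    surface_nm: float,
    *,
    edge_nm: float | None = None,
    bg_stats: BackgroundStats | None = None,
) -> ExponentialFit:
    """Least-squares exponential fit of a brush profile between surface and edge.

    At least 5 populated bins above background are required; a profile that
    is pure background is rejected (flagged, not raised).
    """
    r, intensity = profile.valid()
    hi = edge_nm if edge_nm is not None else r[-1]
    sel = (r >= surface_nm) & (r <= hi)
    if sel.sum() < 5:
        raise ProfileError("need >= 5 profile bins between surface and edge")
    bg0 = bg_stats.mean if bg_stats is not None else float(np.min(intensity[sel]))
    bg_sd = bg_stats.sd if bg_stats is not None else 0.0
    if np.max(intensity[sel]) < bg0 + 2 * bg_sd + 1e-12:
        return ExponentialFit(math.nan, math.nan, bg0, math.nan, False, "pure-background")

    rr, ii = r[sel], intensity[sel]
    span = max(hi - surface_nm, 1.0)

    def model(rv, i0, lam, bg):
        return i0 * np.exp(-(rv - surface_nm) / lam) + bg

    p0 = (float(np.max(ii) - bg0), span / 3.0, bg0)
    try:
        popt, _ = curve_fit(
            model, rr, ii, p0=p0,
            bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return ExponentialFit(math.nan, math.nan, bg0, math.nan, False, "no-convergence")
    if bg_sd > 0 and popt[0] < 2 * bg_sd:  # amplitude indistinguishable from noise
        return ExponentialFit(math.nan, math.nan, bg0, math.nan, False, "pure-background")
    resid = ii - model(rr, *popt)
    return ExponentialFit(
        i0=float(popt[0]),
        decay_nm=float(popt[1]),
        bg=float(popt[2]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        converged=True,
    )
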