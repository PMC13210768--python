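"""Seeded synthetic fields of view for fluorescence fiber counting.

This module generates ground-truth scenes — fluorescently stained mineral
fibers plus abundant non-fibrous fluorescent particles on a textured
membrane-filter background — and renders them as focal-plane stacks
(z-stacks) with depth-dependent defocus blur, the raw material the rest of
the pipeline (focus stacking, detection, counting statistics) operates on.

Geometry is expressed in micrometres in field coordinates; intensities are
arbitrary fluorescence units. Everything is deterministic under a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi

from .errors import FormatError, GeometryError, InputError, ParameterError

__all__ = [
    "FiberTruth",
    "ParticleTruth",
    "SceneSpec",
    "SceneParams",
    "StackSpec",
    "ZStack",
    "TruthLabel",
    "sample_scene",
    "render_zstack",
    "true_countable_fibers",
    "write_stack",
    "read_stack",
]

# FWHM-to-sigma conversion for Gaussian cross profiles.
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class FiberTruth:
    """Ground truth for one fiber: a constant-width curved line segment.

    ``length`` is the arc length of the fiber axis, ``width`` the full width
    at half maximum of its fluorescence cross profile, ``curvature`` the
    approximate reciprocal radius of curvature (0 = straight) and ``z_depth``
    the depth of the fiber below the filter surface.
    """

    centroid_xy: tuple[float, float]
    length: float
    width: float
    orientation: float = 0.0
    curvature: float = 0.0
    z_depth: float = 0.0
    intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ParameterError("fiber length and width must be positive")
        if self.intensity <= 0:
            raise ParameterError("fiber intensity must be positive")
        if self.z_depth < 0:
            raise ParameterError("fiber z_depth must be non-negative")

    def polyline(self, n: int = 65) -> np.ndarray:
        """Sample the fiber axis as an (n, 2) array of (x, y) µm points.

        The axis is a quadratic Bézier whose chord lies along
        ``orientation`` and whose sagitta matches a circular arc of the
        requested curvature; points are rescaled so the sampled arc length
        equals ``length``.
        """
        t = np.linspace(0.0, 1.0, n)
        half = self.length / 2.0
        # Chord endpoints in the fiber frame; control point offset gives a
        # mid-curve sagitta of curvature * L^2 / 8 (circular-arc approx).
        sag = self.curvature * self.length**2 / 8.0
        p0 = np.array([-half, 0.0])
        p2 = np.array([half, 0.0])
        p1 = np.array([0.0, 2.0 * sag])
        pts = (
            np.outer((1 - t) ** 2, p0)
            + np.outer(2 * (1 - t) * t, p1)
            + np.outer(t**2, p2)
        )
        arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        if arc > 0:
            pts *= self.length / arc
        pts -= pts.mean(axis=0)
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        pts = pts @ rot.T
        pts += np.asarray(self.centroid_xy)
        return pts


@dataclass
class ParticleTruth:
    """Ground truth for one non-fibrous fluorescent particle (a disk)."""

    centroid_xy: tuple[float, float]
    radius: float
    z_depth: float = 0.0
    intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("particle radius must be positive")
        if self.intensity <= 0:
            raise ParameterError("particle intensity must be positive")


@dataclass
class SceneSpec:
    """Complete ground-truth description of one field of view.

    The default field matches the instrument's composite field of view,
    660 µm x 440 µm, at 0.33 µm/pixel.
    """

    field_size_xy: tuple[float, float] = (660.0, 440.0)
    pixel_size: float = 0.33
    fibers: list[FiberTruth] = field(default_factory=list)
    particles: list[ParticleTruth] = field(default_factory=list)
    background_level: float = 20.0
    background_texture_scale: float = 5.0
    gaussian_sd: float = 0.4
    poisson_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.field_size_xy
        if w <= 0 or h <= 0 or self.pixel_size <= 0:
            raise ParameterError("field size and pixel size must be positive")
        for obj in list(self.fibers) + list(self.particles):
            x, y = obj.centroid_xy
            if not (0 <= x <= w and 0 <= y <= h):
                raise GeometryError(
                    f"object centroid {obj.centroid_xy} outside field {self.field_size_xy}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape (rows, cols) implied by field size and pixel size."""
        w, h = self.field_size_xy
        return (int(round(h / self.pixel_size)), int(round(w / self.pixel_size)))

    def to_dict(self) -> dict:
        return {
            "field_size_xy": list(self.field_size_xy),
            "pixel_size": self.pixel_size,
            "background_level": self.background_level,
            "background_texture_scale": self.background_texture_scale,
            "gaussian_sd": self.gaussian_sd,
            "poisson_gain": self.poisson_gain,
            "seed": self.seed,
            "fibers": [
                {
                    "x": f.centroid_xy[0],
                    "y": f.centroid_xy[1],
                    "length": f.length,
                    "width": f.width,
                    "orientation": f.orientation,
                    "curvature": f.curvature,
                    "z_depth": f.z_depth,
                    "intensity": f.intensity,
                }
                for f in self.fibers
            ],
            "particles": [
                {
                    "x": p.centroid_xy[0],
                    "y": p.centroid_xy[1],
                    "radius": p.radius,
                    "z_depth": p.z_depth,
                    "intensity": p.intensity,
                }
                for p in self.particles
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(
            field_size_xy=tuple(d["field_size_xy"]),
            pixel_size=d["pixel_size"],
            background_level=d["background_level"],
            background_texture_scale=d["background_texture_scale"],
            gaussian_sd=d["gaussian_sd"],
            poisson_gain=d["poisson_gain"],
            seed=d["seed"],
            fibers=[
                FiberTruth(
                    centroid_xy=(f["x"], f["y"]),
                    length=f["length"],
                    width=f["width"],
                    orientation=f["orientation"],
                    curvature=f["curvature"],
                    z_depth=f["z_depth"],
                    intensity=f["intensity"],
                )
                for f in d["fibers"]
            ],
            particles=[
                ParticleTruth(
                    centroid_xy=(p["x"], p["y"]),
                    radius=p["radius"],
                    z_depth=p["z_depth"],
                    intensity=p["intensity"],
                )
                for p in d["particles"]
            ],
        )


@dataclass
class StackSpec:
    """Focal-stack acquisition geometry.

    Defaults mirror the instrument: 25 planes advanced in 2 µm steps.
    The defocus model blurs each object by a Gaussian of
    sigma = sqrt(sigma0^2 + (slope * |z_plane - z_depth|)^2).
    """

    n_planes: int = 25
    z_step: float = 2.0
    z_origin: float = 0.0
    sigma0: float = 0.25
    defocus_slope: float = 0.5

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ParameterError("n_planes must be >= 1")
        if self.z_step <= 0:
            raise ParameterError("z_step must be positive")
        if self.sigma0 < 0 or self.defocus_slope < 0:
            raise ParameterError("defocus parameters must be non-negative")

    @property
    def z_positions(self) -> np.ndarray:
        return self.z_origin + self.z_step * np.arange(self.n_planes)

    def covers(self, z_depth: float) -> bool:
        return self.z_origin <= z_depth <= self.z_origin + self.n_planes * self.z_step

    def blur_sigma(self, z_plane: float, z_depth: float) -> float:
        dz = abs(z_plane - z_depth)
        return math.hypot(self.sigma0, self.defocus_slope * dz)


@dataclass
class ZStack:
    """An ordered stack of co-registered focal-plane images."""

    planes: np.ndarray  # (n_planes, H, W)
    z_positions: np.ndarray  # µm, strictly increasing
    pixel_size: float  # µm / pixel

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float32)
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        if self.planes.ndim != 3:
            raise InputError("planes must be a 3-D array (n_planes, H, W)")
        if len(self.planes) != len(self.z_positions):
            raise InputError("number of planes must match number of z positions")
        if len(self.z_positions) > 1 and not np.all(np.diff(self.z_positions) > 0):
            raise InputError("z_positions must be strictly increasing")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def n_planes(self) -> int:
        return len(self.planes)


@dataclass
class SceneParams:
    """Distributional parameters for random scene sampling.

    Defaults emulate the annotated dataset the instrument's detector was
    developed on: on average 6.5 fibers and 86.2 non-fibrous particles per
    field, fibers within roughly the top 14 µm of the filter. Geometry
    distributions are lognormal, which keeps support positive and gives the
    long right tails typical of pulverized mineral fibers.
    """

    expected_fibers: float = 6.5
    expected_particles: float = 86.2
    field_size_xy: tuple[float, float] = (660.0, 440.0)
    pixel_size: float = 0.33
    fiber_length_log_mean: float = math.log(9.0)
    fiber_length_log_sd: float = 0.55
    fiber_width_log_mean: float = math.log(1.0)
    fiber_width_log_sd: float = 0.35
    fiber_curvature_sd: float = 0.01
    fiber_depth_range: tuple[float, float] = (0.0, 14.0)
    fiber_intensity_log_mean: float = math.log(120.0)
    fiber_intensity_log_sd: float = 0.3
    particle_radius_log_mean: float = math.log(0.6)
    particle_radius_log_sd: float = 0.4
    particle_depth_range: tuple[float, float] = (0.0, 14.0)
    particle_intensity_log_mean: float = math.log(80.0)
    particle_intensity_log_sd: float = 0.4
    background_level: float = 20.0
    background_texture_scale: float = 5.0
    gaussian_sd: float = 0.4
    poisson_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.expected_fibers < 0 or self.expected_particles < 0:
            raise ParameterError("expected object counts must be >= 0")
        if self.fiber_length_log_sd < 0 or self.fiber_width_log_sd < 0:
            raise ParameterError("geometry spread parameters must be >= 0")


def sample_scene(params: SceneParams, seed: int) -> SceneSpec:
    """Draw one random scene: Poisson object counts, lognormal geometry.

    Identical ``(params, seed)`` yield an identical :class:`SceneSpec`
    (bitwise-identical JSON serialization).
    """
    rng = np.random.default_rng([int(seed), 0x5CE7E])
    w, h = params.field_size_xy
    n_fib = int(rng.poisson(params.expected_fibers))
    n_par = int(rng.poisson(params.expected_particles))
    fibers = []
    for _ in range(n_fib):
        fibers.append(
            FiberTruth(
                centroid_xy=(float(rng.uniform(0, w)), float(rng.uniform(0, h))),
                length=float(rng.lognormal(params.fiber_length_log_mean, params.fiber_length_log_sd)),
                width=float(rng.lognormal(params.fiber_width_log_mean, params.fiber_width_log_sd)),
                orientation=float(rng.uniform(0, math.pi)),
                curvature=float(abs(rng.normal(0.0, params.fiber_curvature_sd))),
                z_depth=float(rng.uniform(*params.fiber_depth_range)),
                intensity=float(rng.lognormal(params.fiber_intensity_log_mean, params.fiber_intensity_log_sd)),
            )
        )
    particles = []
    for _ in range(n_par):
        particles.append(
            ParticleTruth(
                centroid_xy=(float(rng.uniform(0, w)), float(rng.uniform(0, h))),
                radius=float(rng.lognormal(params.particle_radius_log_mean, params.particle_radius_log_sd)),
                z_depth=float(rng.uniform(*params.particle_depth_range)),
                intensity=float(rng.lognormal(params.particle_intensity_log_mean, params.particle_intensity_log_sd)),
            )
        )
    return SceneSpec(
        field_size_xy=params.field_size_xy,
        pixel_size=params.pixel_size,
        fibers=fibers,
        particles=particles,
        background_level=params.background_level,
        background_texture_scale=params.background_texture_scale,
        gaussian_sd=params.gaussian_sd,
        poisson_gain=params.poisson_gain,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _object_patch(scene: SceneSpec, obj, pad_um: float):
    """Sharp (in-focus) rendering of one object on a cropped patch.

    Returns (patch, (row0, col0)) where patch is the noiseless in-focus
    intensity contribution and (row0, col0) its origin in the full raster.
    """
    px = scene.pixel_size
    H, W = scene.shape
    if isinstance(obj, FiberTruth):
        pts = obj.polyline()
        sigma_w = obj.width / _FWHM
        lo = pts.min(axis=0) - (pad_um + 3 * sigma_w)
        hi = pts.max(axis=0) + (pad_um + 3 * sigma_w)
    else:
        c = np.asarray(obj.centroid_xy)
        lo = c - (pad_um + obj.radius + 2.0)
        hi = c + (pad_um + obj.radius + 2.0)
    col0 = max(0, int(math.floor(lo[0] / px)))
    row0 = max(0, int(math.floor(lo[1] / px)))
    col1 = min(W, int(math.ceil(hi[0] / px)) + 1)
    row1 = min(H, int(math.ceil(hi[1] / px)) + 1)
    if col1 <= col0 or row1 <= row0:
        return np.zeros((0, 0)), (0, 0)
    # Pixel-centre coordinates in µm.
    xs = (np.arange(col0, col1) + 0.5) * px
    ys = (np.arange(row0, row1) + 0.5) * px
    gx, gy = np.meshgrid(xs, ys)
    if isinstance(obj, FiberTruth):
        d = _dist_to_polyline(gx, gy, obj.polyline())
        sigma_w = obj.width / _FWHM
        patch = obj.intensity * np.exp(-(d**2) / (2 * sigma_w**2))
    else:
        d = np.hypot(gx - obj.centroid_xy[0], gy - obj.centroid_xy[1])
        # Soft-edged disk: half-pixel roll-off keeps rendering resolution-stable.
        edge = 0.5 * px
        patch = obj.intensity / (1.0 + np.exp((d - obj.radius) / edge))
    return patch, (row0, col0)


def _dist_to_polyline(gx: np.ndarray, gy: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Minimum distance from each grid point to a polyline (segment-exact)."""
    p = np.stack([gx.ravel(), gy.ravel()], axis=1)
    a = pts[:-1]
    b = pts[1:]
    ab = b - a  # (S, 2)
    ab2 = np.maximum((ab**2).sum(axis=1), 1e-12)
    # (N, S) projections clipped to the segment.
    ap = p[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / ab2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(p[:, None, :] - proj, axis=2).min(axis=1)
    return d.reshape(gx.shape)


def _add_patch(plane: np.ndarray, patch: np.ndarray, r0: int, c0: int) -> None:
    """Add a patch into a plane at (r0, c0), clipping at the field edges."""
    H, W = plane.shape
    h, w = patch.shape
    r_lo, r_hi = max(r0, 0), min(r0 + h, H)
    c_lo, c_hi = max(c0, 0), min(c0 + w, W)
    if r_hi <= r_lo or c_hi <= c_lo:
        return
    plane[r_lo:r_hi, c_lo:c_hi] += patch[r_lo - r0 : r_hi - r0, c_lo - c0 : c_hi - c0]


def render_zstack(scene: SceneSpec, stack: StackSpec) -> ZStack:
    """Render a scene into a focal stack with depth-dependent defocus.

    Each object's in-focus footprint is convolved, per plane, with a
    Gaussian of sigma = sqrt(sigma0^2 + (slope * |z_plane - z_depth|)^2);
    Poisson shot noise (disabled when ``poisson_gain`` is 0) and additive
    Gaussian read noise are then applied per plane. Deterministic under the
    scene seed.
    """
    px = scene.pixel_size
    H, W = scene.shape
    zs = stack.z_positions
    objects = list(scene.fibers) + list(scene.particles)
    for obj in objects:
        if not stack.covers(obj.z_depth):
            raise GeometryError(
                f"object z_depth {obj.z_depth} µm outside stack range "
                f"[{stack.z_origin}, {stack.z_origin + stack.n_planes * stack.z_step}] µm"
            )

    planes = np.zeros((stack.n_planes, H, W), dtype=np.float64)

    # Membrane background: constant level plus seeded low-pass texture,
    # shared across planes (texture scale >> defocus-induced changes).
    if scene.background_level > 0:
        bg = np.full((H, W), float(scene.background_level))
        if scene.background_texture_scale > 0:
            rng_bg = np.random.default_rng([scene.seed, 0xB6])
            tex = rng_bg.standard_normal((H, W))
            tex = ndi.gaussian_filter(tex, scene.background_texture_scale / px)
            sd = tex.std()
            if sd > 0:
                bg = bg + tex / sd * (0.1 * scene.background_level)
        planes += np.clip(bg, 0.0, None)[None, :, :]

    for obj in objects:
        # Tight in-focus support; each plane's defocus spread is absorbed by
        # zero-padding before the blur, keeping the distance computation small.
        patch, (r0, c0) = _object_patch(scene, obj, pad_um=1.0)
        if patch.size == 0:
            continue
        for j, z in enumerate(zs):
            sig_px = stack.blur_sigma(z, obj.z_depth) / px
            if sig_px > 0:
                pad = int(math.ceil(4.0 * sig_px)) + 1
                blurred = ndi.gaussian_filter(np.pad(patch, pad), sig_px)
                _add_patch(planes[j], blurred, r0 - pad, c0 - pad)
            else:
                _add_patch(planes[j], patch, r0, c0)

    rng = np.random.default_rng([scene.seed, 0x4E0])
    if scene.poisson_gain > 0:
        planes = rng.poisson(np.clip(planes, 0, None) / scene.poisson_gain).astype(
            np.float64
        ) * scene.poisson_gain
    if scene.gaussian_sd > 0:
        planes = planes + rng.normal(0.0, scene.gaussian_sd, planes.shape)

    return ZStack(planes=planes.astype(np.float32), z_positions=zs, pixel_size=px)


# ---------------------------------------------------------------------------
# Ground-truth countability
# ---------------------------------------------------------------------------


@dataclass
class TruthLabel:
    """Countability verdict for one ground-truth fiber."""

    fiber: FiberTruth
    countable: bool
    reason: str  # 'none' | 'too_short' | 'too_thick' | 'low_AR' | 'aggregate'


def true_countable_fibers(scene: SceneSpec, criteria) -> list[TruthLabel]:
    """Label each ground-truth fiber countable or not under the criteria.

    A fiber is countable iff length > L_min, width < W_max and
    length/width > AR_min (all strict); fibers whose footprints intersect
    another fiber's footprint form an aggregate and are not countable
    (when the criteria exclude aggregates).
    """
    n = len(scene.fibers)
    polylines = [f.polyline() for f in scene.fibers]
    aggregate = [False] * n
    if getattr(criteria, "exclude_aggregates", True):
        for i in range(n):
            for j in range(i + 1, n):
                if _polylines_touch(
                    polylines[i],
                    polylines[j],
                    (scene.fibers[i].width + scene.fibers[j].width) / 2.0,
                ):
                    aggregate[i] = aggregate[j] = True
    labels = []
    for f, agg in zip(scene.fibers, aggregate):
        if not f.length > criteria.L_min:
            labels.append(TruthLabel(f, False, "too_short"))
        elif not f.width < criteria.W_max:
            labels.append(TruthLabel(f, False, "too_thick"))
        elif not f.length / f.width > criteria.AR_min:
            labels.append(TruthLabel(f, False, "low_AR"))
        elif agg:
            labels.append(TruthLabel(f, False, "aggregate"))
        else:
            labels.append(TruthLabel(f, True, "none"))
    return labels


def _polylines_touch(a: np.ndarray, b: np.ndarray, gap: float) -> bool:
    """True when the minimum distance between two polylines is below gap."""
    # Sampled-point distance is adequate at the sampling density used.
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return bool(d.min() < gap)


# ---------------------------------------------------------------------------
# Stack I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ZStack, path) -> None:
    """Write a stack as a multi-page float32 TIFF plus a JSON sidecar.

    The sidecar records ``pixel_size_um`` and ``z_positions_um`` so that a
    round trip preserves physical calibration.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.planes.astype(np.float32), photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size,
        "z_positions_um": [float(z) for z in stack.z_positions],
        "n_planes": int(stack.n_planes),
    }
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True))


def read_stack(path) -> ZStack:
    """Read a stack written by :func:`write_stack`, validating the sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {sidecar}: {exc}") from exc
    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None, :, :]
    if planes.shape[0] != meta.get("n_planes"):
        raise FormatError(
            f"plane count mismatch: file has {planes.shape[0]} planes, "
            f"metadata declares {meta.get('n_planes')}"
        )
    zpos = meta.get("z_positions_um")
    if zpos is None or len(zpos) != planes.shape[0]:
        raise FormatError(
            f"z position list length {None if zpos is None else len(zpos)} "
            f"does not match plane count {planes.shape[0]}"
        )
    return ZStack(planes=planes, z_positions=np.asarray(zpos), pixel_size=meta["pixel_size_um"])
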