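"""Parametric tricuspid-valve and right-ventricle phantoms with closed-form truth.

The phantoms produced here are the test substrate for the measurement
pipeline: every geometric quantity the pipeline reports (perimeters, areas,
diameters, tenting volume, cavity volume) can be computed directly on the
parametric forms by dense quadrature, independently of any pipeline code
path.

Conventions
-----------
* All lengths in mm, volumes in mL, angles in radians unless a name says
  otherwise.
* ``AnnulusModel.axis_direction`` points *atrially* (away from the
  ventricle); the tented leaflet surface bulges toward ``-axis_direction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from .errors import BoundsError, InvalidParameterError

__all__ = [
    "AnnulusModel",
    "LeafletPhantomSpec",
    "VoxelVolume",
    "RVPhantomSpec",
    "MetricTarget",
    "CohortConfig",
    "build_annulus",
    "analytic_truth",
    "leaflet_surface_points",
    "voxelize_valve",
    "build_rv_phantom",
    "sample_cohort",
]

N_STATIONS = 18
STATION_STEP_DEG = 360.0 / N_STATIONS

_BACKGROUND_INTENSITY = 30.0
_TISSUE_INTENSITY = 200.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnulusModel:
    """Closed 3D curve as per-coordinate truncated Fourier series in theta.

    ``point(theta) = sum_k cos_coeffs[:, k] cos(k theta) + sin_coeffs[:, k] sin(k theta)``
    """

    order: int
    cos_coeffs: np.ndarray  # (3, order + 1)
    sin_coeffs: np.ndarray  # (3, order + 1); column 0 is unused and must be 0
    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        cos_c = np.asarray(self.cos_coeffs, dtype=float)
        sin_c = np.asarray(self.sin_coeffs, dtype=float)
        if cos_c.shape != (3, self.order + 1) or sin_c.shape != (3, self.order + 1):
            raise InvalidParameterError(
                f"coefficient arrays must have shape (3, {self.order + 1})"
            )
        direction = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
            raise InvalidParameterError("axis_direction must be a unit vector")
        object.__setattr__(self, "cos_coeffs", cos_c)
        object.__setattr__(self, "sin_coeffs", sin_c)
        object.__setattr__(self, "axis_origin", np.asarray(self.axis_origin, dtype=float))
        object.__setattr__(self, "axis_direction", direction)

    def evaluate(self, theta: np.ndarray) -> np.ndarray:
        """Curve points at parameter values ``theta``, shape (n, 3)."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        k = np.arange(self.order + 1)
        ang = np.outer(theta, k)  # (n, order+1)
        return np.cos(ang) @ self.cos_coeffs.T + np.sin(ang) @ self.sin_coeffs.T

    @property
    def mean_point(self) -> np.ndarray:
        """Average of the curve over theta (the constant Fourier term)."""
        return self.cos_coeffs[:, 0].copy()


@dataclass(frozen=True)
class LeafletPhantomSpec:
    """A tented leaflet surface hanging ventricularly from an annulus."""

    annulus: AnnulusModel
    tenting_profile: str = "paraboloid"  # paraboloid | cone | flat
    tenting_depth: float = 0.0  # mm, depth of the surface centre below the plane
    commissure_angles: tuple[float, ...] = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
    free_margin_fraction: float = 1.0  # radial extent of the leaflets, (0, 1]

    def __post_init__(self):
        if self.tenting_profile not in ("paraboloid", "cone", "flat"):
            raise InvalidParameterError(
                f"unknown tenting profile {self.tenting_profile!r}"
            )
        if self.tenting_depth < 0:
            raise InvalidParameterError("tenting_depth must be >= 0")
        if self.tenting_profile == "flat" and self.tenting_depth != 0:
            raise InvalidParameterError("flat profile requires tenting_depth == 0")
        if not 0.0 < self.free_margin_fraction <= 1.0:
            raise InvalidParameterError("free_margin_fraction must be in (0, 1]")


@dataclass
class VoxelVolume:
    """3D scalar image with isotropic spacing and a world-space origin (mm)."""

    data: np.ndarray
    spacing: float = 0.5
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise InvalidParameterError("volume must be 3D with >= 2 voxels per axis")
        if self.spacing <= 0:
            raise InvalidParameterError("spacing must be > 0")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing


@dataclass(frozen=True)
class RVPhantomSpec:
    """Ellipsoidal RV cavity embedded in brighter wall tissue."""

    semi_axes: tuple[float, float, float] = (50.0, 40.0, 22.2)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cavity_intensity: float = _BACKGROUND_INTENSITY
    wall_intensity: float = _TISSUE_INTENSITY
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise InvalidParameterError("semi_axes must be strictly positive")
        if self.cavity_intensity == self.wall_intensity:
            raise InvalidParameterError("cavity and wall intensities must differ")

    @property
    def true_volume_ml(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


class MetricTarget(NamedTuple):
    fresh_mean: float
    fresh_sd: float
    defrosted_mean: float
    defrosted_sd: float


@dataclass(frozen=True)
class CohortConfig:
    """Targets for a paired fresh/defrosted synthetic cohort."""

    targets: Mapping[str, MetricTarget]
    n_samples: int = 10
    paired_correlation: float = 0.8
    seed: int = 0
    match_moments: bool = False

    def __post_init__(self):
        if self.n_samples < 2:
            raise InvalidParameterError("n_samples must be >= 2")
        if not 0.0 <= self.paired_correlation < 1.0:
            raise InvalidParameterError("paired_correlation must be in [0, 1)")
        for name, t in self.targets.items():
            if t.fresh_sd < 0 or t.defrosted_sd < 0:
                raise InvalidParameterError(f"negative SD for metric {name!r}")


class PairedTruth(NamedTuple):
    """Per-sample generator truths for one metric."""

    fresh: np.ndarray
    defrosted: np.ndarray


# ---------------------------------------------------------------------------
# annulus construction
# ---------------------------------------------------------------------------


def build_annulus(
    kind: str,
    *,
    radius: float | None = None,
    semi_axis_a: float | None = None,
    semi_axis_b: float | None = None,
    saddle_height: float = 0.0,
    center: Iterable[float] = (0.0, 0.0, 0.0),
) -> AnnulusModel:
    """Build a circle / ellipse / saddle annulus in Fourier form.

    The saddle adds a ``saddle_height * cos(2 theta)`` out-of-plane term to a
    circle of the given radius (the classic bimodal atrioventricular saddle).
    """
    order = 4
    cos_c = np.zeros((3, order + 1))
    sin_c = np.zeros((3, order + 1))
    center = np.asarray(tuple(center), dtype=float)
    cos_c[:, 0] = center

    if kind == "circle":
        if radius is None or radius <= 0:
            raise InvalidParameterError("circle requires radius > 0")
        cos_c[0, 1] = radius
        sin_c[1, 1] = radius
    elif kind == "ellipse":
        if semi_axis_a is None or semi_axis_b is None:
            raise InvalidParameterError("ellipse requires semi_axis_a and semi_axis_b")
        if semi_axis_a <= 0 or semi_axis_b <= 0:
            raise InvalidParameterError("ellipse semi-axes must be > 0")
        cos_c[0, 1] = semi_axis_a
        sin_c[1, 1] = semi_axis_b
    elif kind == "saddle":
        if radius is None or radius <= 0:
            raise InvalidParameterError("saddle requires radius > 0")
        if saddle_height < 0:
            raise InvalidParameterError("saddle_height must be >= 0")
        cos_c[0, 1] = radius
        sin_c[1, 1] = radius
        cos_c[2, 2] = saddle_height
    else:
        raise InvalidParameterError(f"unknown annulus kind {kind!r}")

    return AnnulusModel(
        order=order,
        cos_coeffs=cos_c,
        sin_coeffs=sin_c,
        axis_origin=center,
        axis_direction=np.array([0.0, 0.0, 1.0]),
    )


# ---------------------------------------------------------------------------
# internal geometry helpers (self-contained: the oracle must not share code
# with the measurement pipeline)
# ---------------------------------------------------------------------------


def _arc_weights(closed_curve_points: np.ndarray) -> np.ndarray:
    """Per-point arc-length weights of a closed polyline (wrap-around).

    Weighting by arc length makes centroid and best-fit plane properties of
    the curve itself, independent of how densely any parameterization
    samples it.
    """
    nxt = np.roll(closed_curve_points, -1, axis=0)
    prv = np.roll(closed_curve_points, 1, axis=0)
    return 0.5 * (
        np.linalg.norm(nxt - closed_curve_points, axis=1)
        + np.linalg.norm(closed_curve_points - prv, axis=1)
    )


def _plane_frame(points: np.ndarray, prefer_normal: np.ndarray | None = None):
    """Arc-length-weighted total-least-squares plane of a closed curve
    sampling -> (centroid, normal, u, v)."""
    w = _arc_weights(points)
    centroid = (w[:, None] * points).sum(axis=0) / w.sum()
    _, _, vt = np.linalg.svd(
        np.sqrt(w)[:, None] * (points - centroid), full_matrices=False
    )
    normal = vt[2]
    if prefer_normal is not None and np.dot(normal, prefer_normal) < 0:
        normal = -normal
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return centroid, normal, u, v


def _profile(profile: str, u: np.ndarray) -> np.ndarray:
    if profile == "paraboloid":
        return 1.0 - u**2
    if profile == "cone":
        return 1.0 - u
    return np.zeros_like(u)


class _SurfaceFrame(NamedTuple):
    centroid: np.ndarray
    normal: np.ndarray  # atrial
    u_vec: np.ndarray
    v_vec: np.ndarray


def _surface_frame(annulus: AnnulusModel, n_dense: int = 4096) -> _SurfaceFrame:
    pts = annulus.evaluate(np.linspace(0, 2 * np.pi, n_dense, endpoint=False))
    c, n, u, v = _plane_frame(pts, prefer_normal=annulus.axis_direction)
    return _SurfaceFrame(c, n, u, v)


def leaflet_surface_points(
    spec: LeafletPhantomSpec, theta: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Evaluate the leaflet surface on a (theta, u) grid -> (n_theta, n_u, 3).

    ``u`` is the radial fraction from the surface centre (0) to the annulus
    (1).  At ``u = 1`` the surface coincides with the 3D annulus curve; at
    ``u = 0`` it sits ``tenting_depth * profile(0)`` below the annulus
    best-fit plane, on the ventricular side.
    """
    frame = _surface_frame(spec.annulus)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    u = np.atleast_1d(np.asarray(u, dtype=float))
    ring = spec.annulus.evaluate(theta)  # (n_theta, 3)
    offset = (ring - frame.centroid) @ frame.normal  # atrial offset d(theta)
    in_plane = ring - frame.centroid - np.outer(offset, frame.normal)

    # S(theta, u) = c + u * in_plane(theta) + (u * d(theta) - h * p(u)) * n
    axial = u[None, :] * offset[:, None] - spec.tenting_depth * _profile(
        spec.tenting_profile, u
    )[None, :]
    pts = (
        frame.centroid[None, None, :]
        + u[None, :, None] * in_plane[:, None, :]
        + axial[:, :, None] * frame.normal[None, None, :]
    )
    return pts


def analytic_truth(
    annulus: AnnulusModel,
    leaflets: LeafletPhantomSpec | None = None,
    n_quad: int = 100_000,
) -> dict[str, float]:
    """Ground-truth morphometrics by dense quadrature on the parametric forms.

    Returns a dict with keys ``L2D, L3D, A2D, A3D, Dmax, Dmin, Tvol`` (mm,
    mm^2, mL).  This is the independent oracle for the measurement pipeline
    and deliberately shares no code with it.
    """
    if n_quad < 10_000:
        raise InvalidParameterError("n_quad must be >= 10^4")
    if leaflets is not None and leaflets.annulus is not annulus:
        leaflets = replace(leaflets, annulus=annulus)

    theta = np.linspace(0, 2 * np.pi, n_quad, endpoint=False)
    pts = annulus.evaluate(theta)
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    l3d = float(np.linalg.norm(seg, axis=1).sum())

    centroid, normal, u_vec, v_vec = _plane_frame(pts, prefer_normal=annulus.axis_direction)
    rel = pts - centroid
    xy = np.column_stack([rel @ u_vec, rel @ v_vec])
    xy_closed = np.vstack([xy, xy[:1]])
    l2d = float(np.linalg.norm(np.diff(xy_closed, axis=0), axis=1).sum())
    a2d = float(
        0.5
        * abs(
            np.sum(
                xy_closed[:-1, 0] * xy_closed[1:, 1]
                - xy_closed[1:, 0] * xy_closed[:-1, 1]
            )
        )
    )

    e1 = closed[:-1] - centroid
    e2 = closed[1:] - centroid
    a3d = float(0.5 * np.linalg.norm(np.cross(e1, e2), axis=1).sum())

    # diameters on the projected curve, polar about the projected (arc-length
    # weighted) centroid
    w = _arc_weights(pts)
    c2 = (w[:, None] * xy).sum(axis=0) / w.sum()
    d = xy - c2
    phi = np.arctan2(d[:, 1], d[:, 0])
    r = np.linalg.norm(d, axis=1)
    sort = np.argsort(phi)
    phi_s, r_s = phi[sort], r[sort]
    phi_ext = np.concatenate([phi_s, phi_s[:1] + 2 * np.pi])
    r_ext = np.concatenate([r_s, r_s[:1]])

    def _radius(angles):
        a = np.mod(angles - phi_ext[0], 2 * np.pi) + phi_ext[0]
        return np.interp(a, phi_ext, r_ext)

    grid = np.linspace(0, np.pi, 1800, endpoint=False)
    chords = _radius(grid) + _radius(grid + np.pi)
    dmax, dmin = float(chords.max()), float(chords.min())

    # Tvol: for a non-planar annulus even a "flat" (h = 0) ruled surface dips
    # ventricularly where the rim sits below the best-fit plane, so the
    # quadrature runs for every profile.
    tvol = 0.0
    if leaflets is not None:
        n_t = min(n_quad, 4000)
        n_u = 1200
        th = np.linspace(0, 2 * np.pi, n_t, endpoint=False)
        uu = np.linspace(1.0 - leaflets.free_margin_fraction, 1.0, n_u)
        ring = annulus.evaluate(th)
        offs = (ring - centroid) @ normal
        v3 = ring - centroid - np.outer(offs, normal)
        v2 = np.column_stack([v3 @ u_vec, v3 @ v_vec])
        dv2 = np.gradient(v2, th, axis=0)
        jac = np.abs(v2[:, 0] * dv2[:, 1] - v2[:, 1] * dv2[:, 0])  # per theta
        depth = (
            leaflets.tenting_depth * _profile(leaflets.tenting_profile, uu)[None, :]
            - uu[None, :] * offs[:, None]
        )
        integrand = np.clip(depth, 0.0, None) * uu[None, :] * jac[:, None]
        du = uu[1] - uu[0]
        dth = th[1] - th[0]
        tvol = float(np.trapezoid(integrand, dx=du, axis=1).sum() * dth / 1000.0)

    return {
        "L2D": l2d,
        "L3D": l3d,
        "A2D": a2d,
        "A3D": a3d,
        "Dmax": dmax,
        "Dmin": dmin,
        "Tvol": tvol,
    }


# ---------------------------------------------------------------------------
# azimuth sampling used to place annotation stations
# ---------------------------------------------------------------------------


def _points_at_azimuth(
    annulus: AnnulusModel, frame: _SurfaceFrame, azimuth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Curve parameter and point where the curve crosses each azimuthal
    half-plane of the long-axis frame.  Requires a star-shaped projection."""
    tau = np.linspace(0, 2 * np.pi, 8192, endpoint=False)
    pts = annulus.evaluate(tau)
    rel = pts - frame.centroid
    psi = np.unwrap(np.arctan2(rel @ frame.v_vec, rel @ frame.u_vec))
    if psi[-1] < psi[0]:  # curve winds clockwise in this frame
        tau, psi = tau[::-1].copy(), psi[::-1].copy()
    azimuth = np.atleast_1d(np.asarray(azimuth, dtype=float))
    a = np.mod(azimuth - psi[0], 2 * np.pi) + psi[0]
    tau_ext = np.concatenate([tau, [2 * np.pi + tau[0]]])
    psi_ext = np.concatenate([psi, [psi[0] + 2 * np.pi]])
    tau_at = np.interp(a, psi_ext, tau_ext)
    return tau_at, annulus.evaluate(tau_at)


def phantom_annotation(
    spec: LeafletPhantomSpec,
    n_trace_points: int = 24,
    spacing: float = 0.5,
) -> dict:
    """Ground-truth annotation for a leaflet phantom.

    One record per diametric image plane (9 planes at 0..160 deg), each
    carrying the two annular points, the two free-margin points and the two
    leaflet trace polylines of the opposite half-planes, mirroring what an
    operator would mark on rotated long-axis views.
    """
    frame = _surface_frame(spec.annulus)
    station_deg = np.arange(N_STATIONS) * STATION_STEP_DEG
    tau, annular = _points_at_azimuth(spec.annulus, frame, np.deg2rad(station_deg))

    u_fm = 1.0 - spec.free_margin_fraction
    u_grid = np.linspace(u_fm, 1.0, n_trace_points)
    surf = leaflet_surface_points(spec, tau, u_grid)  # (18, n_trace, 3)
    free_margin = surf[:, 0, :]

    apm = frame.centroid - frame.normal * (spec.tenting_depth + 15.0)

    planes = []
    for k in range(N_STATIONS // 2):
        j = k + N_STATIONS // 2
        rec = {
            "plane_angle_deg": float(station_deg[k]),
            "annular_points": [annular[k].tolist(), annular[j].tolist()],
            "free_margin_points": [free_margin[k].tolist(), free_margin[j].tolist()],
            "leaflet_traces": [surf[k].tolist(), surf[j].tolist()],
        }
        if k == 0:
            rec["apm_point"] = apm.tolist()
        planes.append(rec)
    return {
        "schema": "trimorph-annotation-v1",
        "spacing_mm": float(spacing),
        "planes": planes,
    }


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def _auto_grid(points: np.ndarray, spacing: float, margin: float):
    lo = points.min(axis=0) - margin
    hi = points.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    return lo, tuple(int(s) for s in shape)


def voxelize_valve(
    spec: LeafletPhantomSpec,
    spacing: float = 0.5,
    margin: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    origin: Iterable[float] | None = None,
    n_trace_points: int = 24,
) -> tuple[VoxelVolume, dict]:
    """Render the leaflet phantom into an echo-like volume plus annotation.

    Tissue (leaflet surface and annulus rim) is drawn at high intensity over
    a low-intensity background; the annotation carries the exact geometric
    landmark positions (landmarks are operator-picked in the modelled
    workflow, not re-detected from intensities).
    """
    n_theta = max(720, int(np.ceil(4 * np.pi * 30 / spacing)))
    n_u = max(64, int(np.ceil(60 / spacing)))
    surf = leaflet_surface_points(
        spec, np.linspace(0, 2 * np.pi, n_theta, endpoint=False), np.linspace(0, 1, n_u)
    ).reshape(-1, 3)

    if shape is None:
        origin_arr, shape = _auto_grid(surf, spacing, margin)
    else:
        if origin is None:
            raise InvalidParameterError("explicit shape requires explicit origin")
        origin_arr = np.asarray(tuple(origin), dtype=float)
        extent_hi = origin_arr + (np.asarray(shape) - 1) * spacing
        if (surf.min(axis=0) < origin_arr).any() or (surf.max(axis=0) > extent_hi).any():
            raise BoundsError("leaflet surface exceeds the requested volume extents")

    data = np.full(shape, _BACKGROUND_INTENSITY, dtype=float)
    idx = np.rint((surf - origin_arr) / spacing).astype(int)
    idx = idx[(idx >= 0).all(axis=1) & (idx < np.asarray(shape)).all(axis=1)]
    data[idx[:, 0], idx[:, 1], idx[:, 2]] = _TISSUE_INTENSITY

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 255.0)

    vol = VoxelVolume(data=data, spacing=spacing, origin=origin_arr)
    ann = phantom_annotation(spec, n_trace_points=n_trace_points, spacing=spacing)
    return vol, ann


def build_rv_phantom(
    spec: RVPhantomSpec,
    spacing: float = 0.5,
    margin: float = 8.0,
    shape: tuple[int, int, int] | None = None,
    origin: Iterable[float] | None = None,
) -> tuple[VoxelVolume, float]:
    """Voxelize an ellipsoidal RV cavity; returns (volume, true volume mL)."""
    axes = np.asarray(spec.semi_axes, dtype=float)
    center = np.asarray(spec.center, dtype=float)
    corners = np.vstack([center - axes, center + axes])

    if shape is None:
        origin_arr, shape = _auto_grid(corners, spacing, margin)
    else:
        if origin is None:
            raise InvalidParameterError("explicit shape requires explicit origin")
        origin_arr = np.asarray(tuple(origin), dtype=float)
        extent_hi = origin_arr + (np.asarray(shape) - 1) * spacing
        if (corners.min(axis=0) < origin_arr).any() or (
            corners.max(axis=0) > extent_hi
        ).any():
            raise BoundsError("ellipsoid exceeds the requested volume extents")

    coords = [
        origin_arr[d] + np.arange(shape[d]) * spacing - center[d] for d in range(3)
    ]
    xx = (coords[0] / axes[0]) ** 2
    yy = (coords[1] / axes[1]) ** 2
    zz = (coords[2] / axes[2]) ** 2
    inside = (
        xx[:, None, None] + yy[None, :, None] + zz[None, None, :]
    ) <= 1.0

    data = np.full(shape, spec.wall_intensity, dtype=float)
    data[inside] = spec.cavity_intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 255.0)
    return VoxelVolume(data=data, spacing=spacing, origin=origin_arr), spec.true_volume_ml


# ---------------------------------------------------------------------------
# paired cohort sampling
# ---------------------------------------------------------------------------


def sample_cohort(config: CohortConfig) -> dict[str, PairedTruth]:
    """Draw paired per-sample generator truths for every configured metric.

    Fresh and defrosted draws for a metric are bivariate normal with the
    configured marginal moments and within-pair correlation.  With
    ``match_moments`` the draws are affinely rescaled so the empirical mean
    and SD equal the targets exactly (useful when calibrating a small cohort
    to printed summary statistics).
    """
    rng = np.random.default_rng(config.seed)
    rho = config.paired_correlation
    n = config.n_samples
    out: dict[str, PairedTruth] = {}
    for name, t in config.targets.items():
        zf = rng.standard_normal(n)
        zd = rho * zf + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        if config.match_moments:
            for z in (zf, zd):
                z -= z.mean()
                sd = z.std(ddof=1)
                if sd > 0:
                    z /= sd
        fresh = t.fresh_mean + t.fresh_sd * zf
        defrosted = t.defrosted_mean + t.defrosted_sd * zd
        out[name] = PairedTruth(fresh=fresh, defrosted=defrosted)
    return out
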