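"""Tricuspid-valve morphometry from rotational-plane landmarks.

Pipeline: long-axis definition -> 18 evenly rotated half-planes (20 deg)
-> landmark ingestion -> 4th-order Fourier annulus fit -> best-fit-plane
projection -> perimeters / areas / diameters -> Delaunay leaflet surface
-> tenting volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay
from shapely import contains_xy
from shapely.geometry import Polygon

from .errors import (
    DegenerateGeometryError,
    IncompleteAnnotationError,
    InvalidParameterError,
    NonStarShapedError,
)
from .synth_valve import (
    N_STATIONS,
    STATION_STEP_DEG,
    AnnulusModel,
    LeafletPhantomSpec,
)
from . import synth_valve as _sv

__all__ = [
    "LongAxis",
    "AnnulusLandmarks",
    "FittedAnnulus",
    "BestFitPlane",
    "LeafletMesh",
    "MorphoResult",
    "define_long_axis",
    "generate_planes",
    "extract_landmarks",
    "landmarks_from_phantom",
    "fit_annulus",
    "best_fit_plane",
    "compute_perimeters",
    "compute_areas",
    "compute_diameters",
    "reconstruct_leaflet_surface",
    "tenting_volume",
    "run_morphometry",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LongAxis:
    origin: np.ndarray
    direction: np.ndarray  # unit, pointing ventricularly (toward the free margin)

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise InvalidParameterError("long-axis direction must be a unit vector")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class HalfPlanes:
    """18 half-planes through the long axis at 20-degree azimuthal steps."""

    axis: LongAxis
    u_vec: np.ndarray  # in-plane reference direction for azimuth 0
    v_vec: np.ndarray
    angles_deg: np.ndarray

    def direction(self, k: int) -> np.ndarray:
        a = np.deg2rad(self.angles_deg[k])
        return np.cos(a) * self.u_vec + np.sin(a) * self.v_vec


@dataclass
class AnnulusLandmarks:
    """Per-station landmarks on the 18 rotational half-planes."""

    angles_deg: np.ndarray  # (18,), strictly increasing, 20-degree spacing
    annular: np.ndarray  # (18, 3) mm
    free_margin: np.ndarray  # (18, 3) mm
    apm: np.ndarray | None = None  # (3,) mm, optional
    traces: list[np.ndarray] | None = None  # per station (n_i, 3) polylines

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.annular = np.asarray(self.annular, dtype=float)
        self.free_margin = np.asarray(self.free_margin, dtype=float)
        if self.angles_deg.shape != (N_STATIONS,):
            raise IncompleteAnnotationError(
                set(np.arange(N_STATIONS) * STATION_STEP_DEG) - set(self.angles_deg)
            )
        spacing = np.diff(self.angles_deg)
        if (np.abs(spacing - STATION_STEP_DEG) > 1e-9).any():
            raise InvalidParameterError("stations must be evenly spaced at 20 degrees")
        if self.annular.shape != (N_STATIONS, 3) or self.free_margin.shape != (
            N_STATIONS,
            3,
        ):
            raise InvalidParameterError("landmark arrays must have shape (18, 3)")


@dataclass(frozen=True)
class BestFitPlane:
    point: np.ndarray
    normal: np.ndarray  # unit

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise InvalidParameterError("plane normal must be a unit vector")
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", n)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.point) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, self.normal)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = ref - np.dot(ref, self.normal) * self.normal
        u /= np.linalg.norm(u)
        return u, np.cross(self.normal, u)

    def project_2d(self, pts: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        rel = np.atleast_2d(pts) - self.point
        return np.column_stack([rel @ u, rel @ v])


@dataclass
class FittedAnnulus:
    model: AnnulusModel
    polyline: np.ndarray  # (n_samples, 3), closed implicitly (last != first)
    centroid: np.ndarray
    rms_residual: float


@dataclass
class LeafletMesh:
    vertices: np.ndarray  # (n, 3)
    triangles: np.ndarray  # (m, 3) int


@dataclass
class MorphoResult:
    L2D: float
    L3D: float
    A2D: float
    A3D: float
    Dmax: float
    Dmin: float
    Tvol: float
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "L2D": self.L2D,
            "L3D": self.L3D,
            "A2D": self.A2D,
            "A3D": self.A3D,
            "Dmax": self.Dmax,
            "Dmin": self.Dmin,
            "Tvol": self.Tvol,
        }


# ---------------------------------------------------------------------------
# axis, planes, landmarks
# ---------------------------------------------------------------------------


def _arc_weights(closed_poly: np.ndarray) -> np.ndarray:
    """Arc-length weights of a closed polyline; make centroid/plane
    properties of the curve rather than of its sampling density."""
    nxt = np.roll(closed_poly, -1, axis=0)
    prv = np.roll(closed_poly, 1, axis=0)
    return 0.5 * (
        np.linalg.norm(nxt - closed_poly, axis=1)
        + np.linalg.norm(closed_poly - prv, axis=1)
    )


def best_fit_plane(
    points: np.ndarray,
    orient_with: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> BestFitPlane:
    """Total-least-squares plane (smallest principal component), optionally
    weighted.

    ``orient_with`` flips the normal, if needed, to have a positive dot
    product with the given vector.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise DegenerateGeometryError("need at least 3 points in 3D")
    if weights is None:
        weights = np.ones(pts.shape[0])
    weights = np.asarray(weights, dtype=float)
    centroid = (weights[:, None] * pts).sum(axis=0) / weights.sum()
    _, s, vt = np.linalg.svd(np.sqrt(weights)[:, None] * (pts - centroid),
                             full_matrices=False)
    if s[1] <= max(s[0], 1.0) * 1e-10:
        raise DegenerateGeometryError("points are collinear; no unique plane")
    normal = vt[2]
    if orient_with is not None and np.dot(normal, orient_with) < 0:
        normal = -normal
    return BestFitPlane(point=centroid, normal=normal)


def define_long_axis(landmarks: AnnulusLandmarks, mode: str = "from_annulus") -> LongAxis:
    """Long axis from the annular-point centroid and best-fit-plane normal,
    oriented ventricularly (toward the mean free-margin offset)."""
    if mode != "from_annulus":
        raise InvalidParameterError(f"unknown long-axis mode {mode!r}")
    plane = best_fit_plane(landmarks.annular)
    normal = plane.normal
    toward = landmarks.free_margin.mean(axis=0) - plane.point
    if np.dot(normal, toward) < 0:
        normal = -normal
    return LongAxis(origin=plane.point, direction=normal)


def generate_planes(axis: LongAxis) -> HalfPlanes:
    """18 half-planes through the axis, azimuthal spacing exactly 20 deg.

    Opposite half-planes (k, k+9) are coplanar and together form one
    diametric image plane.
    """
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis.direction)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, axis.direction) * axis.direction
    u /= np.linalg.norm(u)
    v = np.cross(axis.direction, u)
    return HalfPlanes(
        axis=axis,
        u_vec=u,
        v_vec=v,
        angles_deg=np.arange(N_STATIONS) * STATION_STEP_DEG,
    )


def extract_landmarks(annotation: dict | str | Path) -> AnnulusLandmarks:
    """Ingest an annotation (dict or JSON path) into per-station landmarks.

    The file format groups opposite half-planes into 9 diametric planes;
    the second point of each pair belongs to the station at angle + 180 deg.
    """
    if isinstance(annotation, (str, Path)):
        with open(annotation) as fh:
            annotation = json.load(fh)

    station_angles = np.arange(N_STATIONS) * STATION_STEP_DEG
    annular = np.full((N_STATIONS, 3), np.nan)
    free_margin = np.full((N_STATIONS, 3), np.nan)
    traces: list[np.ndarray | None] = [None] * N_STATIONS
    apm = None

    for rec in annotation.get("planes", []):
        angle = float(rec["plane_angle_deg"]) % 360.0
        for half, offset in enumerate((0.0, 180.0)):
            a = (angle + offset) % 360.0
            k = int(round(a / STATION_STEP_DEG)) % N_STATIONS
            if abs(station_angles[k] - a) > 1e-6:
                raise InvalidParameterError(
                    f"plane angle {a:g} deg is not a multiple of {STATION_STEP_DEG:g}"
                )
            annular[k] = rec["annular_points"][half]
            free_margin[k] = rec["free_margin_points"][half]
            if "leaflet_traces" in rec:
                traces[k] = np.asarray(rec["leaflet_traces"][half], dtype=float)
        if "apm_point" in rec:
            apm = np.asarray(rec["apm_point"], dtype=float)

    missing = station_angles[np.isnan(annular).any(axis=1)]
    if missing.size:
        raise IncompleteAnnotationError(missing)

    return AnnulusLandmarks(
        angles_deg=station_angles,
        annular=annular,
        free_margin=free_margin,
        apm=apm,
        traces=None if all(t is None for t in traces) else [t for t in traces],
    )


def landmarks_from_phantom(
    spec: LeafletPhantomSpec, n_trace_points: int = 24
) -> AnnulusLandmarks:
    """Exact landmarks straight from a phantom (no voxel quantization)."""
    return extract_landmarks(_sv.phantom_annotation(spec, n_trace_points=n_trace_points))


# ---------------------------------------------------------------------------
# Fourier fit and planar metrics
# ---------------------------------------------------------------------------


def fit_annulus(
    landmarks: AnnulusLandmarks, order: int = 4, n_samples: int = 360
) -> FittedAnnulus:
    """Per-coordinate linear least squares on {1, cos k th, sin k th}, k=1..order.

    With 18 exact samples of a curve of Fourier order <= 4 the residuals are
    at machine precision; the station angle is used as the curve parameter.
    """
    n_params = 2 * order + 1
    if landmarks.angles_deg.size < n_params:
        raise InvalidParameterError(
            f"need >= {n_params} stations for order {order}, "
            f"got {landmarks.angles_deg.size}"
        )
    theta = np.deg2rad(landmarks.angles_deg)
    k = np.arange(1, order + 1)
    design = np.hstack(
        [
            np.ones((theta.size, 1)),
            np.cos(np.outer(theta, k)),
            np.sin(np.outer(theta, k)),
        ]
    )
    coef, *_ = np.linalg.lstsq(design, landmarks.annular, rcond=None)
    resid = landmarks.annular - design @ coef
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))

    cos_c = np.zeros((3, order + 1))
    sin_c = np.zeros((3, order + 1))
    cos_c[:, 0] = coef[0]
    cos_c[:, 1:] = coef[1 : order + 1].T
    sin_c[:, 1:] = coef[order + 1 :].T

    axis = define_long_axis(landmarks)
    model = AnnulusModel(
        order=order,
        cos_coeffs=cos_c,
        sin_coeffs=sin_c,
        axis_origin=axis.origin,
        axis_direction=axis.direction,
    )
    poly = model.evaluate(np.linspace(0, 2 * np.pi, n_samples, endpoint=False))
    return FittedAnnulus(
        model=model, polyline=poly, centroid=cos_c[:, 0].copy(), rms_residual=rms
    )


def _closed(poly: np.ndarray) -> np.ndarray:
    return np.vstack([poly, poly[:1]])


def compute_perimeters(fitted: FittedAnnulus, plane: BestFitPlane) -> tuple[float, float]:
    """(L2D, L3D): arc lengths of the projected and 3D annulus polylines."""
    closed3 = _closed(fitted.polyline)
    l3d = float(np.linalg.norm(np.diff(closed3, axis=0), axis=1).sum())
    xy = plane.project_2d(fitted.polyline)
    closed2 = _closed(xy)
    l2d = float(np.linalg.norm(np.diff(closed2, axis=0), axis=1).sum())
    return l2d, l3d


def compute_areas(fitted: FittedAnnulus, plane: BestFitPlane) -> tuple[float, float]:
    """(A2D, A3D): shoelace area of the projection and centroid-fan area in 3D."""
    xy = plane.project_2d(fitted.polyline)
    ring = Polygon(xy)
    if not ring.is_valid:
        raise InvalidParameterError("projected annulus polygon is self-intersecting")
    closed2 = _closed(xy)
    a2d = float(
        0.5
        * abs(
            np.sum(
                closed2[:-1, 0] * closed2[1:, 1] - closed2[1:, 0] * closed2[:-1, 1]
            )
        )
    )
    closed3 = _closed(fitted.polyline)
    w = _arc_weights(fitted.polyline)
    c3 = (w[:, None] * fitted.polyline).sum(axis=0) / w.sum()
    a3d = float(
        0.5
        * np.linalg.norm(np.cross(closed3[:-1] - c3, closed3[1:] - c3), axis=1).sum()
    )
    return a2d, a3d


def compute_diameters(
    fitted: FittedAnnulus, plane: BestFitPlane | None = None
) -> tuple[float, float]:
    """(Dmax, Dmin): extreme chords through the centroid of the projected
    annulus, searched on a 1-degree grid with 0.1-degree refinement."""
    if plane is None:
        plane = best_fit_plane(fitted.polyline)
    xy = plane.project_2d(fitted.polyline)
    w = _arc_weights(fitted.polyline)
    c = (w[:, None] * xy).sum(axis=0) / w.sum()
    rel = xy - c
    r = np.linalg.norm(rel, axis=1)
    if (r <= 0).any():
        raise NonStarShapedError("projected centroid lies on the annulus curve")
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    sort = np.argsort(phi)
    phi_s, r_s = phi[sort], r[sort]
    gaps = np.diff(np.concatenate([phi_s, [phi_s[0] + 2 * np.pi]]))
    if gaps.max() > np.deg2rad(4 * STATION_STEP_DEG):
        raise NonStarShapedError(
            "projected annulus is not star-shaped about its centroid"
        )
    phi_ext = np.concatenate([phi_s, [phi_s[0] + 2 * np.pi]])
    r_ext = np.concatenate([r_s, [r_s[0]]])

    def radius(angles: np.ndarray) -> np.ndarray:
        a = np.mod(angles - phi_ext[0], 2 * np.pi) + phi_ext[0]
        return np.interp(a, phi_ext, r_ext)

    def chord(angles: np.ndarray) -> np.ndarray:
        return radius(angles) + radius(angles + np.pi)

    coarse = np.deg2rad(np.arange(0.0, 180.0, 1.0))
    c_len = chord(coarse)

    def refine(idx: int, pick):
        centre = coarse[idx]
        fine = centre + np.deg2rad(np.arange(-1.0, 1.0001, 0.1))
        vals = chord(fine)
        return float(pick(vals))

    dmax = refine(int(np.argmax(c_len)), np.max)
    dmin = refine(int(np.argmin(c_len)), np.min)
    return dmax, dmin


# ---------------------------------------------------------------------------
# leaflet surface and tenting volume
# ---------------------------------------------------------------------------


def reconstruct_leaflet_surface(
    landmarks: AnnulusLandmarks,
    fitted: FittedAnnulus,
    plane: BestFitPlane,
) -> LeafletMesh:
    """Delaunay surface of all leaflet points in best-fit-plane projection.

    Surface points are the fitted annulus polyline, the free-margin points
    and any leaflet trace polylines.  The triangulation is computed on the
    2D projection (single-valued closed-valve assumption) and lifted back to
    3D; triangles whose centroid falls outside the projected annulus polygon
    are discarded.
    """
    pts = [fitted.polyline, landmarks.free_margin]
    if landmarks.traces is not None:
        pts.extend(t for t in landmarks.traces if t is not None)
    pts3 = np.vstack(pts)
    # deduplicate coincident points (e.g. a closed free margin meeting centrally)
    _, keep = np.unique(np.round(pts3, 6), axis=0, return_index=True)
    pts3 = pts3[np.sort(keep)]
    if pts3.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 surface points")

    xy = plane.project_2d(pts3)
    tri = Delaunay(xy)
    simplices = tri.simplices

    ring = Polygon(plane.project_2d(fitted.polyline))
    centers = xy[simplices].mean(axis=1)
    inside = contains_xy(ring, centers[:, 0], centers[:, 1])
    simplices = simplices[inside]

    # drop degenerate (zero-projected-area) triangles
    p = xy[simplices]
    area2 = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    simplices = simplices[area2 > 1e-12]

    used = np.unique(simplices)
    remap = -np.ones(pts3.shape[0], dtype=int)
    remap[used] = np.arange(used.size)
    return LeafletMesh(vertices=pts3[used], triangles=remap[simplices])


def tenting_volume(mesh: LeafletMesh, plane: BestFitPlane) -> float:
    """Volume (mL) between the annulus plane and the leaflet surface.

    Sum over triangles of (projected area) x (mean ventricular depth), with
    per-vertex signed distances clipped at zero so that only the ventricular
    side counts; the plane normal must point atrially.
    """
    depth = np.clip(-mesh.vertices @ plane.normal + plane.point @ plane.normal, 0.0, None)
    xy = plane.project_2d(mesh.vertices)
    p = xy[mesh.triangles]
    area = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    mean_depth = depth[mesh.triangles].mean(axis=1)
    return float((area * mean_depth).sum() / 1000.0)


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------


def run_morphometry(
    source: AnnulusLandmarks | LeafletPhantomSpec | dict | str | Path,
    order: int = 4,
    provenance: dict | None = None,
) -> MorphoResult:
    """Full morphometric pipeline from landmarks, an annotation, or a phantom."""
    if isinstance(source, AnnulusLandmarks):
        landmarks = source
    elif isinstance(source, LeafletPhantomSpec):
        landmarks = landmarks_from_phantom(source)
    else:
        landmarks = extract_landmarks(source)

    axis = define_long_axis(landmarks)
    fitted = fit_annulus(landmarks, order=order)
    # plane normal oriented atrially: opposite the ventricular long axis
    plane = best_fit_plane(
        fitted.polyline,
        orient_with=-axis.direction,
        weights=_arc_weights(fitted.polyline),
    )
    l2d, l3d = compute_perimeters(fitted, plane)
    a2d, a3d = compute_areas(fitted, plane)
    dmax, dmin = compute_diameters(fitted, plane)
    mesh = reconstruct_leaflet_surface(landmarks, fitted, plane)
    tvol = tenting_volume(mesh, plane)
    return MorphoResult(
        L2D=l2d,
        L3D=l3d,
        A2D=a2d,
        A3D=a3d,
        Dmax=dmax,
        Dmin=dmin,
        Tvol=tvol,
        provenance=provenance or {},
    )
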