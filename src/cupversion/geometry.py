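"""Projection geometry of a hemispherical acetabular cup onto plain films.

Coordinate frame (supine AP acquisition):

* ``x`` — transverse, toward the patient's left (mm)
* ``y`` — superior / cephalad (mm)
* ``z`` — posterior; the AP beam travels along +z, anterior is -z (mm)

The AP film is the x-y plane.  A cup is described by its opening-plane
axis (unit vector pointing out of the opening), outer radius and centre
of rotation.  Radiographic anteversion is the angle between that axis
and the coronal (film) plane, signed positive when the axis points
anteriorly.  Under a parallel beam the opening rim (a circle of radius
``r`` with unit normal ``n``) projects to an ellipse with semi-major
axis ``r`` and semi-minor axis ``r*|sin(anteversion)|``.

The cross-table lateral film is modelled as a vertical cassette held
against the side of the hip, parallel to the patient's long axis (film
normal along +/-x), while the horizontal beam travels across the table
at a configurable cephalad angle.  Because the beam is oblique to the
cassette, the projection distorts angles; this is what makes the
direct lateral opening-angle reading systematically overestimate true
anteversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "CupPose",
    "BeamGeometry",
    "EllipseParams",
    "SilhouettePoints",
    "LateralProjection",
    "project_rim",
    "project_silhouette",
    "project_lateral",
    "ray_trace_oracle",
    "RasterImage",
]

_ANTERIOR = np.array([0.0, 0.0, -1.0])


@dataclass(frozen=True)
class CupPose:
    """Ground-truth state of an implanted acetabular component.

    Parameters
    ----------
    anteversion_deg : float
        Radiographic anteversion: angle between the opening-plane axis
        and the coronal plane, degrees.  Negative values denote
        retroversion.
    inclination_deg : float
        Angle of the projected opening-ellipse major axis to the
        transverse film axis, degrees, in (0, 90).
    radius_mm : float
        Cup outer radius, mm.
    centre_mm : tuple of float
        3-D centre of rotation (x, y, z), mm.
    side : {"left", "right"}
    tilt_deg : float, optional
        Pelvic tilt nuisance rotation about the transverse (x) axis.
    rotation_deg : float, optional
        Pelvic rotation nuisance rotation about the longitudinal (y)
        axis.
    """

    anteversion_deg: float
    inclination_deg: float
    radius_mm: float
    centre_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    side: Literal["left", "right"] = "right"
    tilt_deg: float = 0.0
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 < self.anteversion_deg < 90.0:
            raise ValueError("anteversion_deg must lie in (-90, 90)")
        if not 0.0 < self.inclination_deg < 90.0:
            raise ValueError("inclination_deg must lie in (0, 90)")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    # ------------------------------------------------------------------
    def axis(self) -> np.ndarray:
        """Unit opening-plane axis in world coordinates.

        Built from anteversion/inclination, then perturbed by the
        pelvic tilt and rotation nuisance angles.
        """
        av = math.radians(self.anteversion_deg)
        n = math.cos(av) * np.append(self._opening_dir_film(), 0.0) + math.sin(
            av
        ) * _ANTERIOR
        if self.tilt_deg or self.rotation_deg:
            n = _rot_x(self.tilt_deg) @ _rot_y(self.rotation_deg) @ n
        return n

    def _opening_dir_film(self) -> np.ndarray:
        """In-film unit direction the opening faces (infero-lateral)."""
        th = math.radians(self.inclination_deg)
        sx = -1.0 if self.side == "right" else 1.0
        return np.array([sx * math.sin(th), -math.cos(th)])

    @property
    def effective_anteversion_deg(self) -> float:
        """Anteversion of the (possibly tilt-perturbed) axis."""
        return math.degrees(math.asin(float(self.axis() @ _ANTERIOR)))

    def rim_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal pair spanning the opening plane."""
        n = self.axis()
        v1 = np.cross(n, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(v1) < 1e-12:
            v1 = np.cross(n, np.array([1.0, 0.0, 0.0]))
        v1 /= np.linalg.norm(v1)
        v2 = np.cross(n, v1)
        return v1, v2

    def rim_points_3d(self, n_points: int) -> np.ndarray:
        """``n_points`` points on the opening rim circle, shape (n, 3)."""
        v1, v2 = self.rim_basis()
        t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
        c = np.asarray(self.centre_mm, dtype=float)
        return c + self.radius_mm * (np.outer(np.cos(t), v1) + np.outer(np.sin(t), v2))


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


@dataclass(frozen=True)
class BeamGeometry:
    """X-ray beam and film configuration.

    ``mode='parallel'`` is the default (the plain-film formulas assume
    it); ``mode='point_source'`` models a diverging beam from a focal
    spot at ``source_film_distance_mm`` above the film.
    """

    mode: Literal["parallel", "point_source"] = "parallel"
    source_film_distance_mm: float = 1150.0
    film: Literal["ap", "crosstable_lateral"] = "ap"
    crosstable_cephalad_deg: float = 45.0
    object_film_distance_mm: float = 100.0
    film_halfwidth_mm: float = 215.0

    def __post_init__(self) -> None:
        if self.mode not in ("parallel", "point_source"):
            raise ValueError("mode must be 'parallel' or 'point_source'")
        if self.film not in ("ap", "crosstable_lateral"):
            raise ValueError("film must be 'ap' or 'crosstable_lateral'")
        if self.source_film_distance_mm <= 0:
            raise ValueError("source_film_distance_mm must be positive")
        if not 0.0 < self.crosstable_cephalad_deg < 90.0:
            raise ValueError("crosstable_cephalad_deg must lie in (0, 90)")

    def validate_for(self, pose: CupPose) -> None:
        if (
            self.mode == "point_source"
            and self.source_film_distance_mm <= 4.0 * pose.radius_mm
        ):
            raise ValueError(
                "source_film_distance_mm must exceed twice the cup diameter"
            )


@dataclass(frozen=True)
class EllipseParams:
    """Projected opening-rim ellipse on the film, all lengths in mm."""

    centre_film_mm: tuple[float, float]
    semi_major_mm: float
    semi_minor_mm: float
    orientation_deg: float  # major-axis angle to film x-axis, [0, 180)

    def __post_init__(self) -> None:
        if not 0.0 <= self.semi_minor_mm <= self.semi_major_mm:
            raise ValueError("require 0 <= semi_minor <= semi_major")
        if not 0.0 <= self.orientation_deg < 180.0:
            raise ValueError("orientation_deg must lie in [0, 180)")

    @property
    def axis_ratio(self) -> float:
        return self.semi_minor_mm / self.semi_major_mm

    def major_dir(self) -> np.ndarray:
        w = math.radians(self.orientation_deg)
        return np.array([math.cos(w), math.sin(w)])

    def minor_dir(self) -> np.ndarray:
        w = math.radians(self.orientation_deg)
        return np.array([-math.sin(w), math.cos(w)])

    def implicit_residual(self, points: np.ndarray) -> np.ndarray:
        """Algebraic residual ``xi^2/a^2 + eta^2/b^2 - 1`` per point."""
        pts = np.atleast_2d(points) - np.asarray(self.centre_film_mm)
        xi = pts @ self.major_dir()
        eta = pts @ self.minor_dir()
        b = max(self.semi_minor_mm, 1e-300)
        return xi**2 / self.semi_major_mm**2 + eta**2 / b**2 - 1.0

    def sample(self, n: int) -> np.ndarray:
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        c = np.asarray(self.centre_film_mm)
        return (
            c
            + np.outer(self.semi_major_mm * np.cos(t), self.major_dir())
            + np.outer(self.semi_minor_mm * np.sin(t), self.minor_dir())
        )


@dataclass
class SilhouettePoints:
    """Film point sets for the three implant boundary curves (mm).

    ``opening_dir_film`` records the in-film unit direction the cup
    opening faces, which disambiguates the rim side of the short axis
    from the dome side.
    """

    rim_points: np.ndarray
    dome_points: np.ndarray
    head_points: np.ndarray
    opening_dir_film: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -1.0])
    )


# ----------------------------------------------------------------------
# projection onto the AP film
# ----------------------------------------------------------------------

def _ap_project(points: np.ndarray, beam: BeamGeometry) -> np.ndarray:
    """Project world points (n, 3) onto the AP film, returning (n, 2)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if beam.mode == "parallel":
        return pts[:, :2].copy()
    z_film = float(np.mean(pts[:, 2])) + beam.object_film_distance_mm
    source = np.array([0.0, 0.0, z_film - beam.source_film_distance_mm])
    t = (z_film - source[2]) / (pts[:, 2] - source[2])
    out = source[:2] + t[:, None] * (pts[:, :2] - source[:2])
    return out


def _check_in_cone(pose: CupPose, beam: BeamGeometry) -> None:
    if beam.mode != "point_source":
        return
    proj = _ap_project(np.asarray(pose.centre_mm)[None, :], beam)[0]
    if np.max(np.abs(proj)) > beam.film_halfwidth_mm:
        raise ValueError(
            "cup centre projects outside the beam cone / film extent"
        )


def project_rim(pose: CupPose, beam: BeamGeometry) -> EllipseParams:
    """Project the cup opening rim onto the AP film.

    For a parallel beam the result is exact and closed-form: the
    semi-major axis equals the cup radius, the axis ratio equals
    ``|sin(anteversion)|`` and the major axis lies along the
    inclination direction.  For a point source the rim is sampled
    densely and an exact conic is recovered from the perspective image
    (the perspective image of a circle is a conic).
    """
    if beam.film != "ap":
        raise ValueError("project_rim requires an AP beam geometry")
    beam.validate_for(pose)
    _check_in_cone(pose, beam)

    n = pose.axis()
    av_eff = math.asin(float(np.clip(n @ _ANTERIOR, -1.0, 1.0)))
    nf = n[:2]
    norm_nf = np.linalg.norm(nf)
    if norm_nf < 1e-12:  # axis along the beam: projects to a circle
        u = pose._opening_dir_film()
    else:
        u = nf / norm_nf
    major = np.array([-u[1], u[0]])
    theta = math.degrees(math.atan2(major[1], major[0])) % 180.0

    if beam.mode == "parallel":
        return EllipseParams(
            centre_film_mm=(pose.centre_mm[0], pose.centre_mm[1]),
            semi_major_mm=pose.radius_mm,
            semi_minor_mm=pose.radius_mm * abs(math.sin(av_eff)),
            orientation_deg=theta,
        )

    pts = _ap_project(pose.rim_points_3d(360), beam)
    if abs(math.sin(av_eff)) < 1e-6:
        # Degenerate (near-line) projection: scale the parallel result
        # by the central-ray magnification instead of fitting a conic.
        mag = beam.source_film_distance_mm / (
            beam.source_film_distance_mm - beam.object_film_distance_mm
        )
        c = _ap_project(np.asarray(pose.centre_mm)[None, :], beam)[0]
        return EllipseParams(
            centre_film_mm=(c[0], c[1]),
            semi_major_mm=pose.radius_mm * mag,
            semi_minor_mm=pose.radius_mm * abs(math.sin(av_eff)) * mag,
            orientation_deg=theta,
        )
    return fit_ellipse_points(pts)


def fit_ellipse_points(points: np.ndarray) -> EllipseParams:
    """Unconstrained 5-parameter ellipse fit through film points."""
    from skimage.measure import EllipseModel

    pts = np.asarray(points, dtype=float)
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise ValueError("ellipse fit failed")
        (xc, yc), (a, b), th = model.center, model.axis_lengths, model.theta
    else:  # older scikit-image
        model = EllipseModel()
        if not model.estimate(pts):
            raise ValueError("ellipse fit failed")
        xc, yc, a, b, th = model.params
    if b > a:
        a, b = b, a
        th += math.pi / 2.0
    return EllipseParams(
        centre_film_mm=(float(xc), float(yc)),
        semi_major_mm=float(a),
        semi_minor_mm=float(b),
        orientation_deg=math.degrees(th) % 180.0,
    )


def project_silhouette(
    pose: CupPose,
    beam: BeamGeometry,
    n_points: int = 100,
    rng_seed: int | None = None,
    noise_sd_mm: float = 0.0,
    head_radius_mm: float = 14.0,
) -> SilhouettePoints:
    """Sample film points on the rim ellipse, dome outline and head border.

    The dome outline is the half of the cup-sphere silhouette circle on
    the side away from the opening; the prosthetic head projects to a
    circle concentric with the rim-ellipse centre.  With
    ``noise_sd_mm > 0`` isotropic Gaussian jitter is added,
    deterministically for a fixed ``rng_seed``.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3 per curve")
    ellipse = project_rim(pose, beam)
    c = np.asarray(ellipse.centre_film_mm)

    rim = _ap_project(pose.rim_points_3d(n_points), beam)

    n = pose.axis()
    nf = n[:2]
    u = nf / np.linalg.norm(nf) if np.linalg.norm(nf) > 1e-12 else pose._opening_dir_film()
    # dome silhouette: semicircle of the sphere outline on the -u side
    phi0 = math.atan2(-u[1], -u[0])
    phi = phi0 + np.linspace(-np.pi / 2.0, np.pi / 2.0, n_points)
    dome3 = np.asarray(pose.centre_mm) + pose.radius_mm * np.stack(
        [np.cos(phi), np.sin(phi), np.zeros_like(phi)], axis=1
    )
    dome = _ap_project(dome3, beam)

    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    head3 = np.asarray(pose.centre_mm) + head_radius_mm * np.stack(
        [np.cos(t), np.sin(t), np.zeros_like(t)], axis=1
    )
    head = _ap_project(head3, beam)

    if noise_sd_mm > 0.0:
        rng = np.random.default_rng(rng_seed)
        rim = rim + rng.normal(0.0, noise_sd_mm, rim.shape)
        dome = dome + rng.normal(0.0, noise_sd_mm, dome.shape)
        head = head + rng.normal(0.0, noise_sd_mm, head.shape)

    return SilhouettePoints(
        rim_points=rim, dome_points=dome, head_points=head, opening_dir_film=u
    )


# ----------------------------------------------------------------------
# cross-table lateral film
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LateralProjection:
    """Result of projecting a cup onto the cross-table lateral film.

    ``opening_line`` is a pair of film points on the line touching the
    projected opening face; ``reference_line`` is a pair of points on
    the table-perpendicular (vertical) reference.  ``angle_deg`` is the
    signed angle between them: positive = anteversion.
    """

    opening_line: tuple[tuple[float, float], tuple[float, float]]
    reference_line: tuple[tuple[float, float], tuple[float, float]]
    angle_deg: float


def _lateral_frame(pose: CupPose, beam: BeamGeometry):
    """Beam direction, film normal and film basis for the lateral view.

    The film is vertical and parallel to the patient's long axis
    (cassette against the lateral hip); the horizontal beam crosses the
    table toward the operated side at the cephalad angle.
    """
    c = math.radians(beam.crosstable_cephalad_deg)
    sx = -1.0 if pose.side == "right" else 1.0
    d = np.array([sx * math.sin(c), math.cos(c), 0.0])
    f = np.array([sx, 0.0, 0.0])
    e_v = np.array([0.0, 0.0, -1.0])  # up (= anterior for a supine patient)
    e_h = np.cross(f, e_v)
    e_h /= np.linalg.norm(e_h)
    # horizontal film axis points cephalad; with the vertical axis
    # pointing anteriorly this makes anteversion read positive on
    # either side
    if e_h[1] < 0:
        e_h = -e_h
    return d, f, e_h, e_v


def project_lateral(pose: CupPose, beam: BeamGeometry) -> LateralProjection:
    """Project the opening face onto the cross-table lateral film.

    Returns the opening-surface line, the table-perpendicular reference
    line and the signed angle between them (the raw direct-lateral
    anteversion reading).
    """
    if beam.film != "crosstable_lateral":
        raise ValueError("project_lateral requires a cross-table lateral beam")
    ce = beam.crosstable_cephalad_deg
    if not 0.0 < ce < 90.0:
        raise ValueError("degenerate cephalad angle")
    d, f, e_h, e_v = _lateral_frame(pose, beam)

    def proj_dir(a: np.ndarray) -> np.ndarray:
        # oblique parallel projection along d onto the film plane
        return a - (a @ f) / (d @ f) * d

    v1, v2 = pose.rim_basis()
    A = pose.radius_mm * np.array(
        [
            [proj_dir(v1) @ e_h, proj_dir(v2) @ e_h],
            [proj_dir(v1) @ e_v, proj_dir(v2) @ e_v],
        ]
    )
    U, S, _ = np.linalg.svd(A)
    if S[0] - S[1] < 1e-9 * max(S[0], 1.0):
        raise ValueError("degenerate lateral projection: ellipse is a circle")
    w = U[:, 0]
    if w[1] < 0:
        w = -w
    angle = math.degrees(math.atan2(w[0], w[1]))

    c3 = np.asarray(pose.centre_mm, dtype=float)
    c2 = np.array([(c3 - (c3 @ f) / (d @ f) * d) @ e_h, (c3 - (c3 @ f) / (d @ f) * d) @ e_v])
    half = S[0]
    p1, p2 = c2 - half * w, c2 + half * w
    r1 = np.array([c2[0] - 40.0, c2[1] - half])
    r2 = np.array([c2[0] - 40.0, c2[1] + half])
    return LateralProjection(
        opening_line=(tuple(p1), tuple(p2)),
        reference_line=(tuple(r1), tuple(r2)),
        angle_deg=angle,
    )


# ----------------------------------------------------------------------
# ray-traced oracle
# ----------------------------------------------------------------------

@dataclass
class RasterImage:
    """Label raster on the film: 0 background, 1 cup shell, 2 head.

    ``origin_mm`` is the film position of pixel (row 0, col 0) centre;
    columns advance along +x, rows along +y.
    """

    pixels: np.ndarray
    origin_mm: tuple[float, float]
    pixel_mm: float

    def to_mm(self, rc: np.ndarray) -> np.ndarray:
        """Convert (row, col) coordinates to film mm (x, y)."""
        rc = np.atleast_2d(rc)
        x = self.origin_mm[0] + rc[:, 1] * self.pixel_mm
        y = self.origin_mm[1] + rc[:, 0] * self.pixel_mm
        return np.stack([x, y], axis=1)


def ray_trace_oracle(
    pose: CupPose | None,
    beam: BeamGeometry,
    pixel_mm: float,
    head_radius_mm: float = 14.0,
    extent_mm: tuple[float, float, float, float] | None = None,
    margin_mm: float = 4.0,
) -> RasterImage:
    """Brute-force rasterised silhouette of the cup shell plus head.

    Every film pixel is tested for intersection of its ray with the
    hemispherical outer cup surface (label 1) and the head sphere
    (label 2, drawn on top).  Completely independent of the analytic
    projection path; serves as the geometric oracle.
    """
    if pixel_mm <= 0:
        raise ValueError("pixel_mm must be positive")
    if pose is None:
        px = np.zeros((8, 8), dtype=np.uint8)
        return RasterImage(pixels=px, origin_mm=(0.0, 0.0), pixel_mm=pixel_mm)
    beam.validate_for(pose)
    _check_in_cone(pose, beam)

    c = np.asarray(pose.centre_mm, dtype=float)
    r = pose.radius_mm
    n = pose.axis()

    cf = _ap_project(c[None, :], beam)[0]
    mag = 1.0
    if beam.mode == "point_source":
        mag = beam.source_film_distance_mm / (
            beam.source_film_distance_mm - beam.object_film_distance_mm
        )
    need = r * mag + margin_mm
    if extent_mm is None:
        x0, x1 = cf[0] - need, cf[0] + need
        y0, y1 = cf[1] - need, cf[1] + need
    else:
        x0, x1, y0, y1 = extent_mm
        if x1 - x0 < 2 * r * mag or y1 - y0 < 2 * r * mag:
            raise ValueError("image extent smaller than the projected implant")

    xs = np.arange(x0, x1 + pixel_mm / 2, pixel_mm)
    ys = np.arange(y0, y1 + pixel_mm / 2, pixel_mm)
    X, Y = np.meshgrid(xs, ys)

    if beam.mode == "parallel":
        origins = np.stack([X, Y, np.full_like(X, c[2] - 10.0 * r)], axis=-1)
        dirs = np.broadcast_to(np.array([0.0, 0.0, 1.0]), origins.shape)
    else:
        z_film = c[2] + beam.object_film_distance_mm
        source = np.array([0.0, 0.0, z_film - beam.source_film_distance_mm])
        film_pts = np.stack([X, Y, np.full_like(X, z_film)], axis=-1)
        dirs = film_pts - source
        dirs = dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)
        origins = np.broadcast_to(source, film_pts.shape)

    cup = _ray_hits_hemisphere(origins, dirs, c, r, n)
    head = _ray_hits_sphere(origins, dirs, c, head_radius_mm)

    px = np.zeros(X.shape, dtype=np.uint8)
    px[cup] = 1
    px[head] = 2
    return RasterImage(pixels=px, origin_mm=(float(xs[0]), float(ys[0])), pixel_mm=pixel_mm)


def _ray_sphere_roots(origins, dirs, centre, radius):
    oc = origins - centre
    b = np.einsum("...i,...i->...", oc, dirs)
    cc = np.einsum("...i,...i->...", oc, oc) - radius**2
    disc = b**2 - cc
    hit = disc >= 0.0
    s = np.sqrt(np.where(hit, disc, 0.0))
    return hit, -b - s, -b + s


def _ray_hits_sphere(origins, dirs, centre, radius):
    hit, _, _ = _ray_sphere_roots(origins, dirs, centre, radius)
    return hit


def _ray_hits_hemisphere(origins, dirs, centre, radius, axis):
    """Rays intersecting the dome half of the sphere ((p-c).axis <= 0)."""
    hit, t1, t2 = _ray_sphere_roots(origins, dirs, centre, radius)
    p1 = origins + t1[..., None] * dirs - centre
    p2 = origins + t2[..., None] * dirs - centre
    on_dome = (np.einsum("...i,i->...", p1, axis) <= 0.0) | (
        np.einsum("...i,i->...", p2, axis) <= 0.0
    )
    return hit & on_dome
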