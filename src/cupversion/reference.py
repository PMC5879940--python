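"""Edge-detection reference pipeline.

Re-implements the behaviour of the proprietary reference software:
circle fits to the prosthetic-head border and to the outer cup border,
then a reconstruction of the opening ellipse constrained to be centred
on the head centre with semi-major axis pinned to the shell radius.
Anteversion follows as arcsin(semi-minor / semi-major).

Works either from selected film points (the landmark route) or from a
binary/label silhouette raster (the image route, boundary via
marching squares).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import EllipseParams, RasterImage
from .landmarks import ReferenceLandmarks
from .methods import VersionReading

__all__ = [
    "CircleFit",
    "fit_circle",
    "reconstruct_opening_ellipse",
    "version_reference",
    "measure_reference",
    "measure_reference_from_image",
]


@dataclass(frozen=True)
class CircleFit:
    centre_film_mm: tuple[float, float]
    radius_mm: float
    rms_residual_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.rms_residual_mm < 0:
            raise ValueError("rms residual must be non-negative")


def fit_circle(points: np.ndarray) -> CircleFit:
    """Fit a circle to film points.

    Three points give the exact circumcircle; more give a Kasa-style
    algebraic fit refined by geometric (orthogonal-distance) least
    squares.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    # collinearity check via the span of centred points
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise ValueError("points are collinear")

    # algebraic (Kasa) fit: minimise ||x^2+y^2 + D x + E y + F||
    A = np.column_stack([pts, np.ones(len(pts))])
    b = -(pts[:, 0] ** 2 + pts[:, 1] ** 2)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = -sol[0] / 2.0, -sol[1] / 2.0
    r = math.sqrt(max(cx**2 + cy**2 - sol[2], 1e-12))

    if len(pts) > 3:
        def resid(p):
            return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

        out = least_squares(resid, x0=[cx, cy, r], method="lm")
        cx, cy, r = out.x
        res = resid(out.x)
    else:
        res = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r
    rms = float(np.sqrt(np.mean(res**2)))
    return CircleFit(centre_film_mm=(float(cx), float(cy)), radius_mm=float(r), rms_residual_mm=rms)


def reconstruct_opening_ellipse(
    head: CircleFit,
    shell: CircleFit,
    rim_points: np.ndarray,
) -> EllipseParams:
    """Constrained opening-ellipse reconstruction.

    The ellipse centre is pinned to the head centre (centre of
    rotation) and the semi-major axis to the shell radius; orientation
    and semi-minor axis are estimated from the rim points by least
    squares on the implicit conic equation.
    """
    pts = np.atleast_2d(np.asarray(rim_points, dtype=float))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 rim points")
    if shell.radius_mm <= head.radius_mm:
        raise ValueError("shell radius must exceed head radius")
    c = np.asarray(head.centre_film_mm)
    a = shell.radius_mm
    rel = pts - c

    # initial orientation: direction of largest spread of the rim points
    u, s, vt = np.linalg.svd(rel - rel.mean(axis=0), full_matrices=False)
    th0 = math.atan2(vt[0, 1], vt[0, 0])

    def eta(th):
        return rel[:, 1] * math.cos(th) - rel[:, 0] * math.sin(th)

    def xi(th):
        return rel[:, 0] * math.cos(th) + rel[:, 1] * math.sin(th)

    if np.max(np.abs(eta(th0))) < 1e-7 * a:
        raise ValueError("rim points lie on the major axis: semi-minor unidentifiable")

    def b0_for(th):
        e2 = eta(th) ** 2
        w = np.clip(1.0 - xi(th) ** 2 / a**2, 1e-9, None)
        return math.sqrt(max(float(np.mean(e2 / w)), 1e-12))

    def resid(p):
        th, logb = p
        b = math.exp(logb)
        w = 1.0 - xi(th) ** 2 / a**2
        return eta(th) ** 2 / b**2 - np.clip(w, -1.0, None)

    best = None
    for th_try in (th0, th0 + math.pi / 2.0):
        b_init = b0_for(th_try)
        out = least_squares(resid, x0=[th_try, math.log(min(b_init, a * 0.999))], method="lm")
        if best is None or out.cost < best.cost:
            best = out
    th, logb = best.x
    b = math.exp(logb)
    if not 0.0 < b <= a * (1.0 + 1e-6):
        raise ValueError("rim points inconsistent with a semi-minor in (0, semi-major]")
    b = min(b, a)
    return EllipseParams(
        centre_film_mm=(float(c[0]), float(c[1])),
        semi_major_mm=float(a),
        semi_minor_mm=float(b),
        orientation_deg=math.degrees(th) % 180.0,
    )


def version_reference(e: EllipseParams, anteverted: bool | None = None) -> VersionReading:
    """Reference anteversion: arcsin(b/a), degrees.

    The AP film alone cannot distinguish ante- from retroversion; when
    a lateral disambiguation flag is supplied the value is signed,
    otherwise it is reported unsigned.
    """
    v = math.degrees(math.asin(min(e.axis_ratio, 1.0)))
    if anteverted is False:
        v = -v
    return VersionReading(v, "reference")


def measure_reference(lm: ReferenceLandmarks, anteverted: bool | None = None) -> VersionReading:
    """Full reference pipeline from selected film points."""
    head = fit_circle(lm.head_points)
    shell_pts = np.vstack([np.atleast_2d(lm.shell_points)])
    shell = _shell_fit_through_centre(shell_pts, head)
    ellipse = reconstruct_opening_ellipse(head, shell, lm.rim_points)
    return version_reference(ellipse, anteverted)


def _shell_fit_through_centre(pts: np.ndarray, head: CircleFit) -> CircleFit:
    """Circle fit for the outer border, centre pinned to the head centre.

    Three dome points alone determine a circumcircle poorly when they
    subtend a small arc; the concentric model (shared centre of
    rotation) matches the reconstruction constraint and is far more
    stable.
    """
    c = np.asarray(head.centre_film_mm)
    d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
    r = float(np.mean(d))
    rms = float(np.sqrt(np.mean((d - r) ** 2)))
    return CircleFit(centre_film_mm=head.centre_film_mm, radius_mm=r, rms_residual_mm=rms)


# ----------------------------------------------------------------------
# image route
# ----------------------------------------------------------------------

def extract_boundaries(img: RasterImage):
    """Head border, dome border and rim points from a label raster.

    Contours come from marching squares.  The outer silhouette is split
    into dome-circle points (film distance from the head centre close
    to the maximal radius) and opening-rim points (the remainder).
    """
    from skimage import measure

    head_contours = measure.find_contours(
        (img.pixels == 2).astype(float), 0.5
    )
    if not head_contours:
        raise ValueError("no head region in image")
    head_rc = max(head_contours, key=len)
    head_pts = img.to_mm(head_rc)

    full_contours = measure.find_contours((img.pixels > 0).astype(float), 0.5)
    if not full_contours:
        raise ValueError("no implant silhouette in image")
    outer_rc = max(full_contours, key=len)
    outer_pts = img.to_mm(outer_rc)

    head_fit = fit_circle(head_pts)
    c = np.asarray(head_fit.centre_film_mm)
    d = np.hypot(outer_pts[:, 0] - c[0], outer_pts[:, 1] - c[1])
    r_est = np.percentile(d, 97.5)
    tol = 2.0 * img.pixel_mm
    dome_pts = outer_pts[np.abs(d - r_est) <= tol]
    # the head sphere protrudes beyond the thin opening ellipse, so the
    # outer contour contains head-circle arcs: drop those before
    # keeping the opening-rim points
    not_head = np.abs(d - head_fit.radius_mm) > tol
    rim_pts = outer_pts[(d < r_est - tol) & not_head]
    return head_pts, dome_pts, rim_pts, head_fit


def measure_reference_from_image(
    img: RasterImage, anteverted: bool | None = None
) -> tuple[VersionReading, EllipseParams, CircleFit, CircleFit]:
    """Reference pipeline on a rasterised silhouette.

    Returns the reading plus the fitted ellipse and the two circle
    fits, so oracle tests can compare the geometry directly.
    """
    head_pts, dome_pts, rim_pts, head_fit = extract_boundaries(img)
    if len(dome_pts) < 3 or len(rim_pts) < 3:
        raise ValueError("could not separate dome and rim boundaries")
    shell_fit = _shell_fit_through_centre(dome_pts, head_fit)
    ellipse = reconstruct_opening_ellipse(head_fit, shell_fit, rim_pts)
    return version_reference(ellipse, anteverted), ellipse, head_fit, shell_fit
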