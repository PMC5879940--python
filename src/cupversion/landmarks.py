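"""Per-method landmark extraction and observer-noise perturbation.

Each measurement method needs a small set of film landmarks.  They are
stored as the underlying 2-D points (scalar measurements are derived
from the points), so that a single isotropic jitter model applied to
the points propagates naturally into every method's reading.

The observer model has two components:

* isotropic Gaussian jitter on every landmark point, redrawn per
  session (drives intra-observer variation);
* a per-observer systematic offset for each landmark role, drawn once
  per observer and held fixed across patients and sessions (drives the
  extra inter-observer variation).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, fields, replace
from typing import Union

import numpy as np

from .geometry import EllipseParams, LateralProjection, SilhouettePoints

__all__ = [
    "LiawLandmarks",
    "LewinnekMeasures",
    "WidmerMeasures",
    "HassanMeasures",
    "AcklandMeasures",
    "LateralMeasures",
    "ReferenceLandmarks",
    "MethodLandmarks",
    "ObserverModel",
    "METHODS",
    "AP_ELLIPSE_METHODS",
    "extract_landmarks",
    "extract_lateral_landmarks",
    "perturb",
]

Point = np.ndarray

AP_ELLIPSE_METHODS = ("liaw", "lewinnek", "widmer", "hassan", "ackland")
METHODS = ("reference",) + AP_ELLIPSE_METHODS + ("woo_morrey",)


def _pt(x, y) -> Point:
    return np.array([float(x), float(y)])


def _length(p: Point, q: Point) -> float:
    return float(np.linalg.norm(np.asarray(p) - np.asarray(q)))


@dataclass
class LiawLandmarks:
    """Long-axis endpoints A, B and minor-axis endpoint E."""

    A: Point
    B: Point
    E: Point

    @property
    def beta_deg(self) -> float:
        """Angle at B between the long axis BA and the line BE."""
        v1 = np.asarray(self.A) - np.asarray(self.B)
        v2 = np.asarray(self.E) - np.asarray(self.B)
        cross = abs(v1[0] * v2[1] - v1[1] * v2[0])
        dot = abs(float(v1 @ v2))
        return math.degrees(math.atan2(cross, dot))

    def validate(self) -> None:
        if _length(self.A, self.B) <= 0:
            raise ValueError("degenerate long axis")


@dataclass
class LewinnekMeasures:
    """Short-axis and long-axis endpoint pairs; D1, D2 derived."""

    short_ends: tuple[Point, Point]
    long_ends: tuple[Point, Point]

    @property
    def D1(self) -> float:
        return _length(*self.short_ends)

    @property
    def D2(self) -> float:
        return _length(*self.long_ends)

    def validate(self) -> None:
        if self.D2 <= 0:
            raise ValueError("D2 must be positive")
        if self.D1 > self.D2:
            raise ValueError("D1 must not exceed D2")


@dataclass
class WidmerMeasures:
    """Short-axis endpoints plus the dome apex; S and TL derived.

    TL runs from the rim-side end of the short axis (the end farther
    from the apex) through the centre to the dome apex of the cup
    silhouette.
    """

    short_ends: tuple[Point, Point]
    apex: Point

    @property
    def S(self) -> float:
        return _length(*self.short_ends)

    @property
    def TL(self) -> float:
        return max(_length(p, self.apex) for p in self.short_ends)

    def validate(self) -> None:
        if not 0 < self.S < self.TL:
            raise ValueError("require 0 < S < TL")


@dataclass
class HassanMeasures:
    """Long-axis endpoints and the rim point uncovered by the head.

    ``m`` is the distance along the long axis from the far end to the
    foot of the uncovered rim point (the larger of the two candidate
    distances); ``h`` is the perpendicular distance from that foot to
    the rim.
    """

    long_ends: tuple[Point, Point]
    rim_point: Point

    @property
    def D(self) -> float:
        return _length(*self.long_ends)

    def _foot(self) -> tuple[float, float]:
        p0, p1 = (np.asarray(p) for p in self.long_ends)
        axis = p1 - p0
        L = np.linalg.norm(axis)
        axis = axis / L
        s = float((np.asarray(self.rim_point) - p0) @ axis)
        h = float(
            abs(np.cross(np.append(axis, 0), np.append(np.asarray(self.rim_point) - p0, 0))[2])
        )
        return s, h

    @property
    def m(self) -> float:
        s, _ = self._foot()
        return max(s, self.D - s)

    @property
    def h(self) -> float:
        _, h = self._foot()
        return h

    def validate(self) -> None:
        if not 0 < self.m < self.D:
            raise ValueError("require 0 < m < D")
        if self.m * (self.D - self.m) <= 0:
            raise ValueError("m(D - m) must be positive")


@dataclass
class AcklandMeasures:
    """Diametrical-line endpoints A, C and a rim point on a tangent.

    ``a`` is half of AC, ``x`` the distance from A to the foot of the
    tangent on the diametrical line, and ``y`` the half-chord: the
    perpendicular distance from the foot to the rim point.
    """

    A: Point
    C: Point
    rim_point: Point

    @property
    def a(self) -> float:
        return _length(self.A, self.C) / 2.0

    def _foot(self) -> tuple[float, float]:
        p0, p1 = np.asarray(self.A), np.asarray(self.C)
        axis = p1 - p0
        axis = axis / np.linalg.norm(axis)
        rel = np.asarray(self.rim_point) - p0
        x = float(rel @ axis)
        y = float(abs(axis[0] * rel[1] - axis[1] * rel[0]))
        return x, y

    @property
    def x(self) -> float:
        return self._foot()[0]

    @property
    def y(self) -> float:
        return self._foot()[1]

    def validate(self) -> None:
        if not 0 < self.x < 2.0 * self.a:
            raise ValueError("require 0 < x < 2a")
        if 2.0 * self.a * self.x - self.x**2 <= 0:
            raise ValueError("2ax - x^2 must be positive")


@dataclass
class LateralMeasures:
    """Opening-surface line and table-perpendicular reference line."""

    opening_line: tuple[Point, Point]
    reference_line: tuple[Point, Point]

    def validate(self) -> None:
        if _length(*self.opening_line) <= 0 or _length(*self.reference_line) <= 0:
            raise ValueError("degenerate line")


@dataclass
class ReferenceLandmarks:
    """Point selections for the edge-detection reference pipeline."""

    head_points: np.ndarray   # (>=3, 2) on the prosthetic-head border
    shell_points: np.ndarray  # (>=3, 2) on the outer cup border (dome)
    rim_points: np.ndarray    # (>=3, 2) on the opening-rim edges

    def validate(self) -> None:
        for arr in (self.head_points, self.shell_points, self.rim_points):
            if np.asarray(arr).shape[0] < 3:
                raise ValueError("each point set needs at least 3 points")


MethodLandmarks = Union[
    LiawLandmarks,
    LewinnekMeasures,
    WidmerMeasures,
    HassanMeasures,
    AcklandMeasures,
    LateralMeasures,
    ReferenceLandmarks,
]


@dataclass(frozen=True)
class ObserverModel:
    """Gaussian landmark-noise model for one observer.

    ``landmark_sd_mm`` is the RMS magnitude of the isotropic 2-D
    jitter displacement (per-coordinate sd is ``sd / sqrt(2)``).
    ``observer_bias_mm`` scales per-observer systematic offsets, drawn
    once per (observer, landmark role) and centred across the observer
    pool so rater effects sum to zero.
    """

    landmark_sd_mm: float = 0.5
    observer_bias_mm: float = 0.3
    seed: int = 0
    observer_id: int = 0
    n_observer_pool: int = 3

    def __post_init__(self) -> None:
        if self.landmark_sd_mm < 0 or self.observer_bias_mm < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0 <= self.observer_id < max(self.n_observer_pool, 1):
            raise ValueError("observer_id must index into the observer pool")


# ----------------------------------------------------------------------
# extraction
# ----------------------------------------------------------------------

def _ellipse_frame(ellipse: EllipseParams, silhouette: SilhouettePoints | None):
    """Centre, major direction, and opening-side minor direction."""
    c = np.asarray(ellipse.centre_film_mm)
    md = ellipse.major_dir()
    nd = ellipse.minor_dir()
    if silhouette is not None and len(silhouette.dome_points):
        # opening side is opposite the dome apex
        s = np.asarray(silhouette.dome_points) - c
        proj = s @ nd
        if proj[np.argmax(np.abs(proj))] > 0:
            nd = -nd
    elif silhouette is not None:
        u = silhouette.opening_dir_film
        if float(u @ nd) < 0:
            nd = -nd
    return c, md, nd


def _dome_apex(ellipse: EllipseParams, silhouette: SilhouettePoints) -> Point:
    """Silhouette dome point farthest from the centre along -minor."""
    c, _, nd = _ellipse_frame(ellipse, silhouette)
    pts = np.asarray(silhouette.dome_points)
    if len(pts) == 0:
        raise ValueError("silhouette has no dome points")
    i = int(np.argmin((pts - c) @ nd))
    return pts[i].copy()


def extract_landmarks(
    ellipse: EllipseParams,
    silhouette: SilhouettePoints | None,
    head_radius_mm: float,
    method: str,
    ackland_x_fraction: float = 0.3,
) -> MethodLandmarks:
    """Derive a method's landmarks from the projected geometry.

    Noise-free extraction satisfies the closed-form identities:
    ``D1 = 2b``, ``D2 = 2a``, ``S = D1``, ``TL = a + b``, and the
    half-chords of the Hassan and Ackland constructions lie on the
    generating ellipse.
    """
    c, md, nd = _ellipse_frame(ellipse, silhouette)
    a, b = ellipse.semi_major_mm, ellipse.semi_minor_mm

    if method == "liaw":
        return LiawLandmarks(A=c - a * md, B=c + a * md, E=c + b * nd)

    if method == "lewinnek":
        return LewinnekMeasures(
            short_ends=(c - b * nd, c + b * nd),
            long_ends=(c - a * md, c + a * md),
        )

    if method == "widmer":
        if silhouette is None:
            raise ValueError("widmer extraction needs the silhouette (dome apex)")
        apex = _dome_apex(ellipse, silhouette)
        return WidmerMeasures(short_ends=(c + b * nd, c - b * nd), apex=apex)

    if method == "hassan":
        if head_radius_mm >= a:
            raise ValueError(
                "hassan landmarks unidentifiable: head covers the whole rim"
            )
        if head_radius_mm > b:
            xi = a * math.sqrt((head_radius_mm**2 - b**2) / (a**2 - b**2))
        else:
            xi = 0.0  # whole rim uncovered: fall back to the mid chord
        eta = b * math.sqrt(max(1.0 - xi**2 / a**2, 0.0))
        # superior-side rim point (larger film y)
        cand = [c + xi * md + eta * nd, c + xi * md - eta * nd]
        rim = max(cand, key=lambda p: p[1])
        return HassanMeasures(long_ends=(c - a * md, c + a * md), rim_point=rim)

    if method == "ackland":
        if not 0.0 < ackland_x_fraction < 1.0:
            raise ValueError("ackland_x_fraction must lie in (0, 1)")
        A = c - a * md
        x = ackland_x_fraction * 2.0 * a
        xi = x - a
        eta = b * math.sqrt(max(1.0 - xi**2 / a**2, 0.0))
        cand = [c + xi * md + eta * nd, c + xi * md - eta * nd]
        rim = max(cand, key=lambda p: p[1])
        return AcklandMeasures(A=A, C=c + a * md, rim_point=rim)

    if method == "reference":
        if silhouette is None:
            raise ValueError("reference extraction needs the silhouette")
        head = np.asarray(silhouette.head_points)
        dome = np.asarray(silhouette.dome_points)
        rim = np.asarray(silhouette.rim_points)
        # well-spread selections: the head circle is periodic, so avoid
        # picking both endpoints of the angular range
        h_idx = (np.arange(3) * len(head)) // 3
        d_idx = np.linspace(0, len(dome) - 1, 5).astype(int)[1:4]
        # opening edges: rim points well away from the major axis
        off = np.abs((rim - c) @ nd)
        r_idx = np.argsort(off)[-6:]
        return ReferenceLandmarks(
            head_points=head[h_idx].copy(),
            shell_points=dome[d_idx].copy(),
            rim_points=rim[r_idx].copy(),
        )

    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def extract_lateral_landmarks(lat) -> LateralMeasures:
    """Wrap a lateral projection into jitterable landmark lines."""
    if isinstance(lat, LateralProjection):
        return LateralMeasures(
            opening_line=(_pt(*lat.opening_line[0]), _pt(*lat.opening_line[1])),
            reference_line=(_pt(*lat.reference_line[0]), _pt(*lat.reference_line[1])),
        )
    raise TypeError("expected a LateralProjection")


# ----------------------------------------------------------------------
# perturbation
# ----------------------------------------------------------------------

_MAX_RETRIES = 100


def _stable_hash(s: str) -> int:
    # hash() is salted per process; CRC32 keeps RNG keys reproducible
    return zlib.crc32(s.encode("utf-8"))


def _iter_points(lm: MethodLandmarks):
    """Yield (role, array) pairs of every landmark point in ``lm``."""
    for f in fields(lm):
        v = getattr(lm, f.name)
        if isinstance(v, np.ndarray) and v.ndim == 2:
            for i in range(v.shape[0]):
                yield f"{f.name}[{i}]", v[i]
        elif isinstance(v, np.ndarray):
            yield f.name, v
        elif isinstance(v, tuple):
            for i, p in enumerate(v):
                yield f"{f.name}[{i}]", np.asarray(p)


def _observer_bias(observer: ObserverModel, method_tag: str, role: str) -> np.ndarray:
    """Systematic per-observer offset for one landmark role.

    Drawn from a stream keyed by (seed, observer, method, role) only,
    so it is identical across patients and sessions; offsets are
    centred over the observer pool (rater effects sum to zero).
    """
    if observer.observer_bias_mm == 0:
        return np.zeros(2)
    draws = []
    for o in range(observer.n_observer_pool):
        key = [observer.seed, o, _stable_hash(method_tag), _stable_hash(role)]
        rng = np.random.default_rng(key)
        draws.append(rng.normal(0.0, observer.observer_bias_mm / math.sqrt(2.0), 2))
    draws = np.asarray(draws)
    return draws[observer.observer_id] - draws.mean(axis=0)


def perturb(
    landmarks: MethodLandmarks,
    observer: ObserverModel,
    session: int,
    patient: int = 0,
) -> MethodLandmarks:
    """Apply the observer noise model to a landmark set.

    Deterministic for fixed ``(seed, observer, session, patient)``.
    Jittered landmarks that violate the type's invariants are redrawn,
    up to a bounded retry budget.
    """
    if observer.landmark_sd_mm == 0 and observer.observer_bias_mm == 0:
        return landmarks
    tag = type(landmarks).__name__
    base = [observer.seed, observer.observer_id, session, patient, _stable_hash(tag)]
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng(base + [attempt])
        new = _copy_landmarks(landmarks)
        sd_coord = observer.landmark_sd_mm / math.sqrt(2.0)
        for role, pt in _iter_points(new):
            jitter = rng.normal(0.0, sd_coord, 2)
            pt += jitter + _observer_bias(observer, tag, role)
        try:
            if hasattr(new, "validate"):
                new.validate()
            return new
        except ValueError:
            continue
    raise ValueError("perturb: retry budget exhausted (noise sd too large?)")


def _copy_landmarks(lm: MethodLandmarks) -> MethodLandmarks:
    kwargs = {}
    for f in fields(lm):
        v = getattr(lm, f.name)
        if isinstance(v, np.ndarray):
            kwargs[f.name] = v.copy()
        elif isinstance(v, tuple):
            kwargs[f.name] = tuple(np.asarray(p, dtype=float).copy() for p in v)
        else:
            kwargs[f.name] = v
    return replace(lm, **kwargs)
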