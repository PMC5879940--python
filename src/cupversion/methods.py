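"""The six plain-film anteversion formulas.

Five AP-film methods map ellipse-derived landmarks to an anteversion
angle; the sixth is the direct cross-table lateral reading.  On exact
(noise-free) landmarks the four pure-ellipse methods are algebraically
the same function arcsin(b/a) of the ellipse semi-axes; the linear
short-axis/total-length method and the lateral reading carry known
systematic biases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .landmarks import (
    AcklandMeasures,
    HassanMeasures,
    LateralMeasures,
    LewinnekMeasures,
    LiawLandmarks,
    MethodLandmarks,
    WidmerMeasures,
)

__all__ = [
    "VersionReading",
    "version_liaw",
    "version_lewinnek",
    "version_widmer",
    "version_widmer_arcsin",
    "version_hassan",
    "version_ackland",
    "version_woo_morrey",
    "compute_version",
]

_CLAMP_TOL = 1e-9

# linear short-axis/total-length mapping, valid for 0.2 < S/TL < 0.6
WIDMER_SLOPE = 48.05
WIDMER_INTERCEPT = -0.3
WIDMER_RANGE = (0.2, 0.6)


@dataclass(frozen=True)
class VersionReading:
    """One anteversion reading in degrees."""

    value_deg: float
    method: str
    in_validity_range: bool = True

    def __post_init__(self) -> None:
        if not -90.0 <= self.value_deg <= 90.0:
            raise ValueError("value_deg out of (-90, 90)")

    @property
    def flags(self) -> str:
        return "" if self.in_validity_range else "out_of_range"


def _safe_arcsin_deg(x: float, what: str) -> float:
    if x > 1.0:
        if x <= 1.0 + _CLAMP_TOL:
            x = 1.0
        else:
            raise ValueError(f"{what}: arcsin argument {x:.6g} > 1 (inconsistent landmarks)")
    if x < -1.0:
        if x >= -1.0 - _CLAMP_TOL:
            x = -1.0
        else:
            raise ValueError(f"{what}: arcsin argument {x:.6g} < -1 (inconsistent landmarks)")
    return math.degrees(math.asin(x))


def version_liaw(lm: LiawLandmarks) -> VersionReading:
    """arcsin(tan beta), beta the angle at the long-axis end."""
    t = math.tan(math.radians(lm.beta_deg))
    if t > 1.0 + _CLAMP_TOL:
        raise ValueError("liaw: tan(beta) > 1 (beta exceeds 45 degrees)")
    return VersionReading(_safe_arcsin_deg(min(t, 1.0), "liaw"), "liaw")


def version_lewinnek(m: LewinnekMeasures) -> VersionReading:
    """arcsin(D1/D2)."""
    if m.D2 <= 0:
        raise ValueError("lewinnek: D2 must be positive")
    if m.D1 > m.D2 * (1.0 + _CLAMP_TOL):
        raise ValueError("lewinnek: D1 > D2")
    return VersionReading(_safe_arcsin_deg(m.D1 / m.D2, "lewinnek"), "lewinnek")


def version_widmer(m: WidmerMeasures) -> VersionReading:
    """Linear mapping of the S/TL ratio (canonical form).

    Returns the linear value even outside the stated validity range,
    but flags the reading.
    """
    if m.TL <= 0:
        raise ValueError("widmer: TL must be positive")
    ratio = m.S / m.TL
    if ratio >= 1.0:
        raise ValueError("widmer: S >= TL")
    value = WIDMER_SLOPE * ratio + WIDMER_INTERCEPT
    ok = WIDMER_RANGE[0] < ratio < WIDMER_RANGE[1]
    return VersionReading(value, "widmer", in_validity_range=ok)


def version_widmer_arcsin(m: WidmerMeasures) -> VersionReading:
    """arcsin(S/TL) variant; kept secondary to the linear form.

    The two printed forms disagree (arcsin(0.5) = 30 deg while the
    linear form gives 23.725 deg at the same ratio); the linear form is
    canonical here.
    """
    if m.TL <= 0:
        raise ValueError("widmer: TL must be positive")
    ratio = m.S / m.TL
    if ratio >= 1.0 + _CLAMP_TOL:
        raise ValueError("widmer: S >= TL")
    ok = WIDMER_RANGE[0] < ratio < WIDMER_RANGE[1]
    return VersionReading(
        _safe_arcsin_deg(min(ratio, 1.0), "widmer"), "widmer_arcsin", in_validity_range=ok
    )


def version_hassan(m: HassanMeasures) -> VersionReading:
    """arcsin(h / sqrt(m (D - m)))."""
    if not 0 < m.m < m.D:
        raise ValueError("hassan: require 0 < m < D")
    denom = math.sqrt(m.m * (m.D - m.m))
    return VersionReading(_safe_arcsin_deg(m.h / denom, "hassan"), "hassan")


def version_ackland(m: AcklandMeasures) -> VersionReading:
    """arcsin(y / sqrt(2ax - x^2)), y the half-chord."""
    if not 0 < m.x < 2.0 * m.a:
        raise ValueError("ackland: require 0 < x < 2a")
    denom = math.sqrt(2.0 * m.a * m.x - m.x**2)
    return VersionReading(_safe_arcsin_deg(m.y / denom, "ackland"), "ackland")


def version_woo_morrey(m: LateralMeasures) -> VersionReading:
    """Signed angle between the opening line and the table perpendicular.

    Positive = anteversion.  The sign convention follows the lateral
    projection: the opening line of an anteverted cup leans so its top
    tilts toward the positive horizontal film axis.
    """
    m.validate()
    v_open = np.asarray(m.opening_line[1]) - np.asarray(m.opening_line[0])
    v_ref = np.asarray(m.reference_line[1]) - np.asarray(m.reference_line[0])
    # canonical orientation: positive vertical component
    if v_open[1] < 0:
        v_open = -v_open
    if v_ref[1] < 0:
        v_ref = -v_ref
    ang = math.degrees(
        math.atan2(v_open[0], v_open[1]) - math.atan2(v_ref[0], v_ref[1])
    )
    ang = (ang + 180.0) % 360.0 - 180.0
    if ang > 90.0:
        ang -= 180.0
    if ang < -90.0:
        ang += 180.0
    if abs(abs(ang) - 90.0) < 1e-9:
        raise ValueError("woo_morrey: lines at 90 degrees, sign ambiguous")
    return VersionReading(ang, "woo_morrey")


_DISPATCH = {
    LiawLandmarks: version_liaw,
    LewinnekMeasures: version_lewinnek,
    WidmerMeasures: version_widmer,
    HassanMeasures: version_hassan,
    AcklandMeasures: version_ackland,
    LateralMeasures: version_woo_morrey,
}


def compute_version(lm: MethodLandmarks) -> VersionReading:
    """Apply the formula matching the landmark family."""
    fn = _DISPATCH.get(type(lm))
    if fn is None:
        raise TypeError(f"no formula for landmark type {type(lm).__name__}")
    return fn(lm)
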