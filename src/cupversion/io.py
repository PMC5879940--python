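"""CSV/JSON round-tripping for landmark tables and measurement records.

Landmark tables use the long schema
``patient_id,method,observer,session,name,value_or_x,y`` where point
rows carry film x/y in mm and scalar rows carry the value with an
empty ``y``.  Scalar rows are accepted for every method (synthetic
points reproducing the scalars are constructed internally).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import EllipseParams, SilhouettePoints
from .landmarks import (
    AcklandMeasures,
    HassanMeasures,
    LateralMeasures,
    LewinnekMeasures,
    LiawLandmarks,
    MethodLandmarks,
    ReferenceLandmarks,
    WidmerMeasures,
    _iter_points,
)

LANDMARK_COLUMNS = ["patient_id", "method", "observer", "session", "name", "value_or_x", "y"]
RECORD_COLUMNS = ["patient_id", "method", "observer", "session", "value_deg", "flags"]

_TYPE_TO_METHOD = {
    LiawLandmarks: "liaw",
    LewinnekMeasures: "lewinnek",
    WidmerMeasures: "widmer",
    HassanMeasures: "hassan",
    AcklandMeasures: "ackland",
    LateralMeasures: "woo_morrey",
    ReferenceLandmarks: "reference",
}


def landmarks_to_rows(lm: MethodLandmarks, patient_id=0, observer=0, session=1) -> list[dict]:
    method = _TYPE_TO_METHOD[type(lm)]
    rows = []
    for role, pt in _iter_points(lm):
        rows.append(
            {
                "patient_id": patient_id,
                "method": method,
                "observer": observer,
                "session": session,
                "name": role,
                "value_or_x": float(pt[0]),
                "y": float(pt[1]),
            }
        )
    return rows


def write_landmarks_csv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def write_landmarks_json(rows: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(rows, indent=1, sort_keys=False) + "\n")


def read_landmarks(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark table missing columns: {missing}")
    return df


def _point_rows(group: pd.DataFrame) -> dict[str, np.ndarray]:
    pts = {}
    for _, r in group.iterrows():
        if not _is_blank(r["y"]):
            pts[str(r["name"])] = np.array([float(r["value_or_x"]), float(r["y"])])
    return pts


def _scalar_rows(group: pd.DataFrame) -> dict[str, float]:
    return {
        str(r["name"]): float(r["value_or_x"])
        for _, r in group.iterrows()
        if _is_blank(r["y"])
    }


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v == ""


def rows_to_landmarks(group: pd.DataFrame) -> MethodLandmarks:
    """Rebuild one landmark set from its table rows.

    Accepts either the point schema written by ``landmarks_to_rows`` or
    plain scalar measurements (D1/D2, S/TL, D/m/h, a/x/y, beta, angle).
    """
    method = str(group["method"].iloc[0])
    pts = _point_rows(group)
    sc = _scalar_rows(group)

    def pair(prefix):
        return (pts[f"{prefix}[0]"], pts[f"{prefix}[1]"])

    if method == "liaw":
        if {"A", "B", "E"} <= pts.keys():
            return LiawLandmarks(A=pts["A"], B=pts["B"], E=pts["E"])
        beta = math.radians(sc["beta"])
        return LiawLandmarks(
            A=np.array([-2.0, 0.0]),
            B=np.array([0.0, 0.0]),
            E=np.array([-math.cos(beta), math.sin(beta)]),
        )
    if method == "lewinnek":
        if "short_ends[0]" in pts:
            return LewinnekMeasures(short_ends=pair("short_ends"), long_ends=pair("long_ends"))
        d1, d2 = sc["D1"], sc["D2"]
        z = np.zeros(2)
        return LewinnekMeasures(
            short_ends=(z, np.array([0.0, d1])), long_ends=(z, np.array([d2, 0.0]))
        )
    if method == "widmer":
        if "short_ends[0]" in pts:
            return WidmerMeasures(short_ends=pair("short_ends"), apex=pts["apex"])
        s, tl = sc["S"], sc["TL"]
        return WidmerMeasures(
            short_ends=(np.array([0.0, 0.0]), np.array([s, 0.0])),
            apex=np.array([s - tl, 0.0]),
        )
    if method == "hassan":
        if "long_ends[0]" in pts:
            return HassanMeasures(long_ends=pair("long_ends"), rim_point=pts["rim_point"])
        d, m, h = sc["D"], sc["m"], sc["h"]
        return HassanMeasures(
            long_ends=(np.zeros(2), np.array([d, 0.0])),
            rim_point=np.array([max(m, d - m), h]),
        )
    if method == "ackland":
        if "A" in pts:
            return AcklandMeasures(A=pts["A"], C=pts["C"], rim_point=pts["rim_point"])
        a, x, y = sc["a"], sc["x"], sc["y"]
        return AcklandMeasures(
            A=np.zeros(2), C=np.array([2.0 * a, 0.0]), rim_point=np.array([x, y])
        )
    if method == "woo_morrey":
        if "opening_line[0]" in pts:
            return LateralMeasures(
                opening_line=pair("opening_line"), reference_line=pair("reference_line")
            )
        ang = math.radians(sc["angle"])
        return LateralMeasures(
            opening_line=(np.zeros(2), np.array([math.sin(ang), math.cos(ang)])),
            reference_line=(np.zeros(2), np.array([0.0, 1.0])),
        )
    if method == "reference":
        head = [v for k, v in sorted(pts.items()) if k.startswith("head_points")]
        shell = [v for k, v in sorted(pts.items()) if k.startswith("shell_points")]
        rim = [v for k, v in sorted(pts.items()) if k.startswith("rim_points")]
        return ReferenceLandmarks(
            head_points=np.array(head), shell_points=np.array(shell), rim_points=np.array(rim)
        )
    raise ValueError(f"unknown method {method!r}")


# ----------------------------------------------------------------------

def write_records(df: pd.DataFrame, path: str | Path, fmt: str = "csv") -> None:
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        Path(path).write_text(df.to_json(orient="records", indent=1) + "\n")
    else:
        raise ValueError("format must be csv or json")


def read_records(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path)
    else:
        df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    if "flags" not in df.columns:
        df["flags"] = ""
    df["flags"] = df["flags"].fillna("")
    return df


def silhouette_to_csv(sil: SilhouettePoints, path: str | Path, patient_id=0) -> None:
    rows = []
    for curve, arr in (
        ("rim", sil.rim_points),
        ("dome", sil.dome_points),
        ("head", sil.head_points),
    ):
        for p in np.atleast_2d(arr):
            rows.append(
                {"patient_id": patient_id, "curve": curve, "x_mm": p[0], "y_mm": p[1]}
            )
    pd.DataFrame(rows, columns=["patient_id", "curve", "x_mm", "y_mm"]).to_csv(path, index=False)


def ellipse_to_csv(e: EllipseParams, path: str | Path, patient_id=0) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": patient_id,
                "cx": e.centre_film_mm[0],
                "cy": e.centre_film_mm[1],
                "a_mm": e.semi_major_mm,
                "b_mm": e.semi_minor_mm,
                "theta_deg": e.orientation_deg,
            }
        ]
    ).to_csv(path, index=False)
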