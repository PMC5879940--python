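"""Reliability (ICC) and accuracy (paired differences) statistics.

The ICC is the two-way random-effects, single-rater, absolute-agreement
coefficient ICC(2,1), with the F-based 95% confidence interval for that
design.  Intra-observer reliability uses the two repeat sessions of
each observer as raters (then averages across observers); inter-
observer reliability uses the observers as raters on session 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .landmarks import METHODS

__all__ = ["ICCResult", "AccuracyRow", "icc", "paired_accuracy", "build_tables"]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    design: str
    n_subjects: int
    n_raters: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.icc <= self.ci_high:
            raise ValueError("CI must bracket the estimate")


@dataclass(frozen=True)
class AccuracyRow:
    method: str
    mean_deg: float
    min_deg: float
    max_deg: float
    mean_diff_vs_reference_deg: float
    t_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def _anova_mean_squares(x: np.ndarray):
    """Two-way mean squares (rows = subjects, columns = raters)."""
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(matrix: np.ndarray, design: str = "ICC(2,1)", alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with its F-based confidence interval.

    Parameters
    ----------
    matrix : array, shape (n_subjects, n_raters)
        Complete readings, one row per subject.
    design : str
        Only ``"ICC(2,1)"`` (two-way random, single rater, absolute
        agreement) is supported.
    """
    if design != "ICC(2,1)":
        raise ValueError("only ICC(2,1) is implemented")
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed")
    if np.allclose(x, x.flat[0]):
        raise ValueError("zero total variance: ICC undefined")
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    val = (msr - mse) / denom if denom != 0 else 0.0

    # McGraw & Wong CI for ICC(A,1)
    if mse <= 0 or (1.0 - val) < 1e-15:
        lo, hi = val, val
    else:
        a = (k * val) / (n * (1.0 - val))
        b = 1.0 + (k * val * (n - 1.0)) / (n * (1.0 - val))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        )
        f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - n - k) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - n - k) * mse + n * f_u * msr
        )
        lo, hi = min(lo, val), max(hi, val)
    return ICCResult(
        icc=float(val),
        ci_low=float(lo),
        ci_high=float(hi),
        design="two-way random, single rater, absolute agreement",
        n_subjects=n,
        n_raters=k,
    )


def paired_accuracy(
    readings: np.ndarray, reference: np.ndarray, method: str = ""
) -> AccuracyRow:
    """Summary of one method against the per-patient reference values."""
    a = np.asarray(readings, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("readings and reference must be paired (equal length)")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.allclose(diff, diff[0]) and np.allclose(diff[0], 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(a, b)
        if math.isnan(p):  # constant non-zero differences
            t, p = math.copysign(math.inf, diff.mean()), 0.0
    return AccuracyRow(
        method=method,
        mean_deg=float(a.mean()),
        min_deg=float(a.min()),
        max_deg=float(a.max()),
        mean_diff_vs_reference_deg=float(diff.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )


# ----------------------------------------------------------------------
# study tables
# ----------------------------------------------------------------------

def _pivot(records: pd.DataFrame, method: str, observer=None, session=None) -> pd.DataFrame:
    sub = records[records["method"] == method]
    if observer is not None:
        sub = sub[sub["observer"] == observer]
    if session is not None:
        sub = sub[sub["session"] == session]
    cols = "session" if observer is not None else "observer"
    return sub.pivot_table(index="patient_id", columns=cols, values="value_deg")


def reliability_for_method(records: pd.DataFrame, method: str):
    """(intra_mean_icc, intra_cis, inter_icc) for one method.

    Intra: ICC(2,1) over the two sessions per observer, averaged over
    observers.  Inter: ICC(2,1) over observers at session 1.
    """
    observers = sorted(records["observer"].unique())
    intra = []
    for o in observers:
        mat = _pivot(records, method, observer=o)
        if mat.shape[1] < 2:
            continue
        if mat.isna().any().any():
            mat = mat.dropna()
        intra.append(icc(mat.to_numpy()))
    inter = None
    if len(observers) >= 2:
        mat = _pivot(records, method, session=1).dropna()
        inter = icc(mat.to_numpy())
    return intra, inter


def build_tables(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reliability and accuracy tables, one column/row per method.

    Reliability: mean intra-observer ICC (with pooled CI bounds) and
    inter-observer ICC per method.  Accuracy: per-method mean (range),
    mean difference against the reference, paired t and p.  Raises if
    the design has gaps.
    """
    methods = [m for m in METHODS if m in set(records["method"])]
    if not methods:
        raise ValueError("no known methods in records")
    gaps = _design_gaps(records, methods)
    if gaps:
        raise ValueError("incomplete design: " + "; ".join(gaps))

    rel_rows = []
    for m in methods:
        intra, inter = reliability_for_method(records, m)
        row = {"method": m}
        if intra:
            row["icc_intra"] = float(np.mean([r.icc for r in intra]))
            row["icc_intra_ci_low"] = float(np.mean([r.ci_low for r in intra]))
            row["icc_intra_ci_high"] = float(np.mean([r.ci_high for r in intra]))
        if inter is not None:
            row["icc_inter"] = inter.icc
            row["icc_inter_ci_low"] = inter.ci_low
            row["icc_inter_ci_high"] = inter.ci_high
        rel_rows.append(row)
    reliability = pd.DataFrame(rel_rows)

    # accuracy on per-patient means over observers and sessions
    per_patient = (
        records.groupby(["method", "patient_id"])["value_deg"].mean().unstack(0)
    )
    acc_rows = []
    if "reference" not in per_patient.columns:
        raise ValueError("accuracy table needs reference records")
    ref = per_patient["reference"]
    for m in methods:
        vals = per_patient[m]
        if m == "reference":
            acc_rows.append(
                {
                    "method": m,
                    "mean_deg": round(float(ref.mean()), 2),
                    "min_deg": round(float(ref.min()), 2),
                    "max_deg": round(float(ref.max()), 2),
                    "mean_diff_vs_reference_deg": 0.0,
                    "t_statistic": float("nan"),
                    "p_value": float("nan"),
                }
            )
            continue
        row = paired_accuracy(vals.to_numpy(), ref.to_numpy(), method=m)
        acc_rows.append(
            {
                "method": m,
                "mean_deg": round(row.mean_deg, 2),
                "min_deg": round(row.min_deg, 2),
                "max_deg": round(row.max_deg, 2),
                "mean_diff_vs_reference_deg": round(row.mean_diff_vs_reference_deg, 2),
                "t_statistic": round(row.t_statistic, 3),
                "p_value": row.p_value,
            }
        )
    accuracy = pd.DataFrame(acc_rows)
    return reliability, accuracy


def _design_gaps(records: pd.DataFrame, methods) -> list[str]:
    gaps = []
    patients = set(records["patient_id"].unique())
    observers = set(records["observer"].unique())
    sessions = set(records["session"].unique())
    idx = records.set_index(["method", "patient_id", "observer", "session"]).index
    have = set(idx)
    for m in methods:
        missing = [
            (p, o, s)
            for p in patients
            for o in observers
            for s in sessions
            if (m, p, o, s) not in have
        ]
        if missing:
            gaps.append(f"{m}: {len(missing)} missing cells (e.g. {missing[0]})")
    return gaps


def render_tables_markdown(reliability: pd.DataFrame, accuracy: pd.DataFrame) -> str:
    """Human-readable rendering mirroring the published table layout."""
    out = ["## Reliability", ""]
    hdr = "| | " + " | ".join(reliability["method"]) + " |"
    out.append(hdr)
    out.append("|" + "---|" * (len(reliability) + 1))
    if "icc_intra" in reliability:
        cells = [
            f"{r.icc_intra:.3f} ({r.icc_intra_ci_low:.3f} to {r.icc_intra_ci_high:.3f})"
            for r in reliability.itertuples()
        ]
        out.append("| intra-observer ICC (95% CI) | " + " | ".join(cells) + " |")
    if "icc_inter" in reliability:
        cells = [
            f"{r.icc_inter:.3f} ({r.icc_inter_ci_low:.3f} to {r.icc_inter_ci_high:.3f})"
            for r in reliability.itertuples()
        ]
        out.append("| inter-observer ICC (95% CI) | " + " | ".join(cells) + " |")
    out += ["", "## Accuracy", ""]
    out.append("| | " + " | ".join(accuracy["method"]) + " |")
    out.append("|" + "---|" * (len(accuracy) + 1))
    cells = [
        f"{r.mean_deg:.2f} ({r.min_deg:.2f} to {r.max_deg:.2f})"
        for r in accuracy.itertuples()
    ]
    out.append("| mean anteversion (range), deg | " + " | ".join(cells) + " |")
    cells = [
        "-" if math.isnan(r.p_value) else (f"{r.p_value:.3f}" if r.p_value >= 0.001 else "< 0.001")
        for r in accuracy.itertuples()
    ]
    out.append("| p value (paired t) | " + " | ".join(cells) + " |")
    return "\n".join(out) + "\n"
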