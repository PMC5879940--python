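"""Study-shaped synthetic cohort generation.

Builds a virtual cohort of patients with ground-truth cup poses drawn
from configurable distributions, then produces the full measurement
table (method x observer x session) by running each patient through
projection -> landmark extraction -> observer perturbation -> formula.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .geometry import BeamGeometry, CupPose, project_lateral, project_rim, project_silhouette
from .landmarks import (
    AP_ELLIPSE_METHODS,
    METHODS,
    ObserverModel,
    extract_landmarks,
    extract_lateral_landmarks,
    perturb,
)
from .methods import compute_version
from .reference import measure_reference

__all__ = ["CohortConfig", "CohortDataset", "generate_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Distribution parameters for the virtual cohort.

    Defaults emulate the published study design: 71 patients, cup
    anteversion centred on 19.4 degrees truncated to the observed
    12.6-27.8 range, cup outer diameters 46-60 mm with mode 50, three
    observers reading twice.
    """

    n_patients: int = 71
    anteversion_mean_deg: float = 19.4
    anteversion_sd_deg: float = 3.5
    anteversion_range_deg: tuple[float, float] = (12.6, 27.8)
    inclination_mean_deg: float = 45.0
    inclination_sd_deg: float = 5.0
    cup_diameter_range_mm: tuple[float, float] = (46.0, 60.0)
    cup_diameter_mode_mm: float = 50.0
    head_diameter_mm: float = 28.0
    pelvic_tilt_sd_deg: float = 2.0
    pelvic_rotation_sd_deg: float = 2.0
    n_observers: int = 3
    n_sessions_intra: int = 2
    landmark_sd_mm: float = 0.5
    observer_bias_mm: float = 0.3
    ackland_x_fraction: float = 0.3
    n_silhouette_points: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        lo, hi = self.anteversion_range_deg
        if not lo < hi:
            raise ValueError("degenerate anteversion range")
        if self.anteversion_sd_deg < 0 or self.inclination_sd_deg < 0:
            raise ValueError("sds must be non-negative")
        if self.anteversion_sd_deg > 0:
            zlo = (lo - self.anteversion_mean_deg) / self.anteversion_sd_deg
            zhi = (hi - self.anteversion_mean_deg) / self.anteversion_sd_deg
            if zlo > 6.0 or zhi < -6.0:
                raise ValueError("truncation range excludes mean +/- 6 sd")
        dlo, dhi = self.cup_diameter_range_mm
        if not dlo <= self.cup_diameter_mode_mm <= dhi or dlo >= dhi:
            raise ValueError("cup diameter mode must lie inside a non-degenerate range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["anteversion_range_deg"] = list(d["anteversion_range_deg"])
        d["cup_diameter_range_mm"] = list(d["cup_diameter_range_mm"])
        return d


@dataclass
class CohortDataset:
    """Ground-truth poses plus the full measurement record table."""

    poses: list[CupPose]
    truth: pd.DataFrame       # patient_id, anteversion/inclination/... truth
    records: pd.DataFrame     # patient_id, method, observer, session, value_deg, flags
    config: CohortConfig

    def provenance_yaml(self) -> str:
        meta = {
            "config": self.config.to_dict(),
            "n_records": int(len(self.records)),
            "methods": list(METHODS),
            "assumptions": [
                "inclination distribution 45 +/- 5 deg is an assumption; "
                "the source cohort reports no inclination summary",
                "truth anteversion is truncated-normal (mean/range only "
                "are published)",
            ],
        }
        return yaml.safe_dump(meta, sort_keys=False)


def _sample_truncnorm(rng, mean, sd, lo, hi, n):
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_poses(config: CohortConfig) -> list[CupPose]:
    """Draw per-patient ground-truth poses (deterministic in the seed)."""
    rng = np.random.default_rng([config.seed, 101])
    av = _sample_truncnorm(
        rng,
        config.anteversion_mean_deg,
        config.anteversion_sd_deg,
        *config.anteversion_range_deg,
        config.n_patients,
    )
    lo, hi = 5.0, 85.0
    incl = _sample_truncnorm(
        rng, config.inclination_mean_deg, config.inclination_sd_deg, lo, hi, config.n_patients
    )
    dlo, dhi = config.cup_diameter_range_mm
    diam = rng.triangular(dlo, config.cup_diameter_mode_mm, dhi, config.n_patients)
    tilt = rng.normal(0.0, config.pelvic_tilt_sd_deg, config.n_patients)
    rot = rng.normal(0.0, config.pelvic_rotation_sd_deg, config.n_patients)
    sides = np.where(rng.random(config.n_patients) < 0.5, "right", "left")
    return [
        CupPose(
            anteversion_deg=float(av[i]),
            inclination_deg=float(incl[i]),
            radius_mm=float(diam[i]) / 2.0,
            centre_mm=(0.0, 0.0, 0.0),
            side=str(sides[i]),
            tilt_deg=float(tilt[i]),
            rotation_deg=float(rot[i]),
        )
        for i in range(config.n_patients)
    ]


def _patient_landmarks(pose: CupPose, config: CohortConfig, ap_beam: BeamGeometry, lat_beam: BeamGeometry):
    """Noise-free landmark sets for every method for one patient."""
    head_r = config.head_diameter_mm / 2.0
    ellipse = project_rim(pose, ap_beam)
    sil = project_silhouette(
        pose, ap_beam, n_points=config.n_silhouette_points, head_radius_mm=head_r
    )
    out = {}
    for method in AP_ELLIPSE_METHODS + ("reference",):
        out[method] = extract_landmarks(
            ellipse, sil, head_r, method, ackland_x_fraction=config.ackland_x_fraction
        )
    out["woo_morrey"] = extract_lateral_landmarks(project_lateral(pose, lat_beam))
    return out


def generate_cohort(
    config: CohortConfig,
    ap_beam: BeamGeometry | None = None,
    lat_beam: BeamGeometry | None = None,
) -> CohortDataset:
    """Generate the full synthetic dataset.

    Every record is produced via projection -> extraction ->
    perturbation -> formula; regenerating with the same config
    reproduces the table exactly.
    """
    ap_beam = ap_beam or BeamGeometry(film="ap")
    lat_beam = lat_beam or BeamGeometry(film="crosstable_lateral")
    poses = sample_poses(config)

    observers = [
        ObserverModel(
            landmark_sd_mm=config.landmark_sd_mm,
            observer_bias_mm=config.observer_bias_mm,
            seed=config.seed,
            observer_id=o,
            n_observer_pool=config.n_observers,
        )
        for o in range(config.n_observers)
    ]

    rows = []
    failures = []
    for pid, pose in enumerate(poses):
        clean = _patient_landmarks(pose, config, ap_beam, lat_beam)
        anteverted = pose.effective_anteversion_deg >= 0
        for method in METHODS:
            for obs in observers:
                for session in range(1, config.n_sessions_intra + 1):
                    try:
                        lm = perturb(clean[method], obs, session, patient=pid)
                        if method == "reference":
                            reading = measure_reference(lm, anteverted=anteverted)
                        else:
                            reading = compute_version(lm)
                        rows.append(
                            {
                                "patient_id": pid,
                                "method": method,
                                "observer": obs.observer_id,
                                "session": session,
                                "value_deg": round(reading.value_deg, 4),
                                "flags": reading.flags,
                            }
                        )
                    except ValueError as exc:  # logged, not fatal
                        failures.append((pid, method, obs.observer_id, session, str(exc)))

    records = pd.DataFrame(
        rows, columns=["patient_id", "method", "observer", "session", "value_deg", "flags"]
    )
    truth = pd.DataFrame(
        {
            "patient_id": range(config.n_patients),
            "anteversion_deg": [p.anteversion_deg for p in poses],
            "effective_anteversion_deg": [round(p.effective_anteversion_deg, 4) for p in poses],
            "inclination_deg": [p.inclination_deg for p in poses],
            "radius_mm": [p.radius_mm for p in poses],
            "side": [p.side for p in poses],
            "tilt_deg": [p.tilt_deg for p in poses],
            "rotation_deg": [p.rotation_deg for p in poses],
        }
    )
    ds = CohortDataset(poses=poses, truth=truth, records=records, config=config)
    ds.failures = failures  # type: ignore[attr-defined]
    return ds
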