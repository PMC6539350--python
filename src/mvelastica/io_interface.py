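"""Configuration I/O, synthetic cohorts, structured reports and figures.

Patient configuration files are YAML or JSON mappings whose keys mirror
:class:`~mvelastica.valve_system.ValveMeasurements`.  Lengths are mm, the
bending stiffness mN mm^2, stresses mN/mm^2; the leaflet and chorda angles
are given in *degrees* at this boundary and converted to radians internally.
Missing keys fall back to the reference-case values.

The synthetic cohort generator draws independent truncated-normal values per
measurement around the reference means/spreads, emulating between-patient
echocardiographic variability (it does not emulate intra-measurement
correlation or imaging error structure).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .chordae import ChordaMaterial
from .elastica import ElasticaSolution, shape
from .valve_system import REFERENCE_MATERIAL, ValveMeasurements

__all__ = [
    "CohortSpec",
    "RunReport",
    "read_patient_config",
    "measurements_from_dict",
    "generate_cohort",
    "write_report",
    "export_shape_csv",
    "COHORT_DISTRIBUTIONS",
]

logger = logging.getLogger("mvelastica")

#: angle keys accepted in degrees at the file boundary
_DEGREE_KEYS = {"delta_a", "delta_p"}

#: plausibility bounds (mm / mN mm^2 / degrees) used to catch unit mistakes
_BOUNDS = {
    "MAD_pre": (10.0, 80.0),
    "IPD_pre": (10.0, 90.0),
    "TH_pre": (2.0, 30.0),
    "TH_opt": (1.0, 25.0),
    "delta_a": (1.0, 89.0),
    "delta_p": (1.0, 89.0),
    "h_a": (10.0, 90.0),
    "h_p": (10.0, 90.0),
    "l_a": (5.0, 40.0),
    "l_p": (4.0, 35.0),
    "B": (10.0, 1e5),
}

#: population means and spreads of the measured quantities (cohort report);
#: deterministic model constants carry zero spread
COHORT_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "MAD_pre": (40.0, 1.9),
    "IPD_pre": (44.6, 0.39),
    "TH_pre": (12.4, 0.13),
    "TH_opt": (6.8, 0.0),
    "delta_a": (32.6, 2.5),
    "delta_p": (56.8, 5.2),
    "h_a": (45.0, 8.6),
    "h_p": (28.0, 8.1),
    "l_a": (18.0, 0.0),
    "l_p": (13.0, 0.0),
    "B": (500.0, 0.0),
}


class ConfigError(ValueError):
    """Schema or plausibility violation in a patient configuration."""


def measurements_from_dict(data: dict, source: str = "<dict>") -> ValveMeasurements:
    """Validated ValveMeasurements from a plain mapping (angles in degrees)."""
    if not isinstance(data, dict):
        raise ConfigError(f"{source}: expected a mapping, got {type(data).__name__}")
    defaults = dataclasses.asdict(ValveMeasurements.reference_case())
    material = defaults.pop("material")
    known = set(defaults) | {"material", "c1", "c2", "A_ref"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{source}: unknown keys {sorted(unknown)}")

    values = {}
    for key, default in defaults.items():
        if key in data:
            raw = data[key]
            if not isinstance(raw, (int, float)) or isinstance(raw, bool):
                raise ConfigError(f"{source}: key '{key}' must be a number, got {raw!r}")
            raw = float(raw)
            lo, hi = _BOUNDS[key]
            if not (lo <= raw <= hi):
                raise ConfigError(
                    f"{source}: key '{key}'={raw} outside plausible range "
                    f"[{lo}, {hi}] (check units: mm, mN mm^2, degrees)"
                )
            values[key] = math.radians(raw) if key in _DEGREE_KEYS else raw
        else:
            logger.info("config %s: key '%s' missing, using default", source, key)
            values[key] = default

    mat_data = data.get("material", {})
    if not isinstance(mat_data, dict):
        raise ConfigError(f"{source}: 'material' must be a mapping")
    for short in ("c1", "c2", "A_ref"):
        if short in data:
            mat_data.setdefault(short, data[short])
    mat = ChordaMaterial(
        c1=float(mat_data.get("c1", REFERENCE_MATERIAL.c1)),
        c2=float(mat_data.get("c2", REFERENCE_MATERIAL.c2)),
        A_ref=float(mat_data.get("A_ref", REFERENCE_MATERIAL.A_ref)),
    )
    try:
        return ValveMeasurements(material=mat, **values)
    except ValueError as exc:
        raise ConfigError(f"{source}: {exc}") from exc


def read_patient_config(path: str | Path) -> ValveMeasurements:
    """Read and validate a YAML/JSON patient configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"patient config not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return measurements_from_dict(data or {}, source=str(path))


# ---------------------------------------------------------------------------
# synthetic cohort

@dataclass(frozen=True)
class CohortSpec:
    """Sampling frame for a synthetic patient cohort.

    ``distributions`` maps measurement keys to (mean, std) pairs in boundary
    units (degrees for angles); entries not listed fall back to the
    reference-population values.
    """

    n_patients: int
    seed: int | None = 0
    distributions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for key, (mu, sd) in self.distributions.items():
            if key not in COHORT_DISTRIBUTIONS:
                raise ValueError(f"unknown measurement '{key}' in cohort spec")
            if sd < 0:
                raise ValueError(f"negative std for '{key}'")


def generate_cohort(spec: CohortSpec) -> list[ValveMeasurements]:
    """Independent truncated-normal draws per measurement, one per patient.

    Truncation at the plausibility bounds keeps every draw physical; a zero
    std collapses the distribution onto its mean.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    dists = {**COHORT_DISTRIBUTIONS, **spec.distributions}
    patients = []
    for _ in range(spec.n_patients):
        row = {}
        for key, (mu, sd) in dists.items():
            if sd == 0:
                row[key] = mu
                continue
            lo, hi = _BOUNDS[key]
            a, b = (lo - mu) / sd, (hi - mu) / sd
            row[key] = float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
        # keep the target height below the sampled tenting height
        row["TH_opt"] = min(row["TH_opt"], 0.9 * row["TH_pre"])
        patients.append(measurements_from_dict(row, source="<cohort>"))
    return patients


# ---------------------------------------------------------------------------
# reports

@dataclass
class RunReport:
    """Machine-readable record of one preop->postop analysis run."""

    inputs: dict
    preop: dict
    scenarios: dict                 # scenario value -> postop summary dict
    indicators: list[dict]          # one row per scenario
    diagnostics: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunReport":
        return cls(**data)


def _canonical_json(data) -> str:
    return json.dumps(data, sort_keys=True, indent=2, allow_nan=False)


def write_report(report: RunReport, path: str | Path, format: str = "json") -> Path:
    """Write a report as canonical JSON or as the indicator CSV table."""
    path = Path(path)
    try:
        if format == "json":
            path.write_text(_canonical_json(report.to_dict()) + "\n")
        elif format == "csv":
            cols = ["scenario", "Mr_a", "Mr_p", "Tr_a", "Tr_p", "lr_a", "lr_p"]
            df = pd.DataFrame(report.indicators)
            df = df.reindex(columns=cols)
            df.to_csv(path, index=False)
        else:
            raise ValueError(f"unknown report format {format!r}")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return path


def read_report(path: str | Path) -> RunReport:
    return RunReport.from_dict(json.loads(Path(path).read_text()))


def export_shape_csv(solution: ElasticaSolution, path: str | Path,
                     n_points: int = 101) -> Path:
    """Write the deformed leaflet centreline as a CSV with s, x_mm, y_mm."""
    s = np.linspace(0.0, 1.0, n_points)
    x, y = shape(s, solution)
    pd.DataFrame({"s": s, "x_mm": x, "y_mm": y}).to_csv(Path(path), index=False)
    return Path(path)


def plot_configuration(preop, postop=None, path: str | Path | None = None):
    """Overlay of the pre- (and optionally post-) operative valve geometry."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    s = np.linspace(0, 1, 80)
    for label, cfg, style in [("preoperative", preop.system, "-")] + (
            [("postoperative", postop.system, "--")] if postop is not None else []):
        xa, ya = shape(s, cfg.elastica_a)
        xp, yp = shape(s, cfg.elastica_p)
        ax.plot(cfg.a_a[0] + xa, ya, "b" + style, label=f"anterior {label}")
        ax.plot(cfg.a_p[0] - xp, yp, "r" + style, label=f"posterior {label}")
        for b, m, c in ((cfg.b_a, cfg.m_a, "b"), (cfg.b_p, cfg.m_p, "r")):
            ax.plot([b[0], m[0]], [b[1], m[1]], c + style, alpha=0.5)
            ax.plot(*m, c + "o", ms=6)
    ax.invert_yaxis()               # apex down in anatomical orientation
    ax.set_xlabel("x [mm]")
    ax.set_ylabel("depth below annular plane [mm]")
    ax.legend(fontsize=8)
    ax.set_aspect("equal")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
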