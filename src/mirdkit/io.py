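"""CSV/JSON/YAML readers and writers for the pipeline's table dialects.

All tables are UTF-8 CSV with required headers; units are encoded in column
names (``time_min``, ``conc_kBq_per_mL``, ``tiac_h``, ``s_mGy_per_MBq_h``) —
no unit inference.  Floats are written with 6 significant digits and rows in
deterministic order so repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bladder import UrineSeries
from .kinetics import PatientMeta, TimeActivityCurve, build_tac
from .pk import PlasmaSeries

__all__ = [
    "FLOAT_FORMAT",
    "RunConfig",
    "read_patients",
    "read_tacs",
    "read_urine",
    "read_plasma",
    "read_lesions",
    "write_table",
    "packaged_data_path",
]

FLOAT_FORMAT = "%.6g"

_REQUIRED = {
    "patients": ["patient_id", "weight_kg", "injected_activity_MBq"],
    "tacs": ["patient_id", "region", "time_min", "conc_kBq_per_mL", "decay_corrected"],
    "urine": ["patient_id", "void_time_min"],
    "plasma": ["patient_id", "time_min", "rel_conc", "decay_corrected"],
    "lesions": ["patient_id", "group", "timepoint", "suv_max", "suv_mean"],
}


def _load_checked(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{kind} table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} for {kind}")
    return df


def packaged_data_path(name: str):
    """Context manager yielding a real filesystem path to a packaged fixture."""
    return resources.as_file(resources.files("mirdkit.data").joinpath(name))


def read_patients(path: str | Path) -> dict[str, PatientMeta]:
    """Patient metadata keyed by id; validates weight/activity ranges."""
    df = _load_checked(path, "patients")
    out: dict[str, PatientMeta] = {}
    for i, row in enumerate(df.itertuples(), start=2):
        pid = str(row.patient_id)
        if pid in out:
            raise ValueError(f"{path}: line {i}: duplicate patient_id {pid!r}")
        try:
            out[pid] = PatientMeta(
                patient_id=pid,
                weight_kg=float(row.weight_kg),
                injected_activity_MBq=float(row.injected_activity_MBq),
            )
        except ValueError as err:
            raise ValueError(f"{path}: line {i}: {err}") from None
    return out


def read_tacs(path: str | Path) -> dict[str, dict[str, TimeActivityCurve]]:
    """Time–activity curves as {patient_id: {region: curve}}."""
    df = _load_checked(path, "tacs")
    out: dict[str, dict[str, TimeActivityCurve]] = {}
    for (pid, region), sub in df.groupby(["patient_id", "region"], sort=True):
        flags = set(sub.decay_corrected.astype(bool))
        if len(flags) != 1:
            raise ValueError(
                f"{path}: mixed decay_corrected flags for patient {pid!r} "
                f"region {region!r}"
            )
        curve = build_tac(
            region=str(region),
            samples=list(zip(sub.time_min.astype(float), sub.conc_kBq_per_mL.astype(float))),
            decay_corrected=flags.pop(),
        )
        out.setdefault(str(pid), {})[str(region)] = curve
    return out


def read_urine(
    path: str | Path, patients: dict[str, PatientMeta] | None = None
) -> list[UrineSeries]:
    """Urine series as fractions of injected activity.

    Accepts either a ``cum_activity_frac`` column (already normalized) or
    ``cum_activity_MBq_decay_corrected`` plus patient metadata for the A₀
    normalization at load time.
    """
    df = _load_checked(path, "urine")
    if "cum_activity_frac" in df.columns:
        frac_col = "cum_activity_frac"
        norm = {pid: 1.0 for pid in df.patient_id.astype(str).unique()}
    elif "cum_activity_MBq_decay_corrected" in df.columns:
        if patients is None:
            raise ValueError(
                f"{path}: absolute MBq urine activity requires patient metadata "
                "for normalization"
            )
        frac_col = "cum_activity_MBq_decay_corrected"
        norm = {pid: meta.injected_activity_MBq for pid, meta in patients.items()}
    else:
        raise ValueError(
            f"{path}: need column cum_activity_frac or "
            "cum_activity_MBq_decay_corrected"
        )
    out = []
    for pid, sub in df.groupby("patient_id", sort=True):
        pid = str(pid)
        if pid not in norm:
            raise KeyError(f"{path}: urine for unknown patient {pid!r}")
        sub = sub.sort_values("void_time_min")
        out.append(
            UrineSeries(
                patient_id=pid,
                void_times_min=sub.void_time_min.to_numpy(dtype=float),
                cum_activity_frac=sub[frac_col].to_numpy(dtype=float) / norm[pid],
            )
        )
    return out


def read_plasma(path: str | Path) -> list[PlasmaSeries]:
    df = _load_checked(path, "plasma")
    if not df.decay_corrected.astype(bool).all():
        raise ValueError(
            f"{path}: plasma series must be decay-corrected before fitting"
        )
    return [
        PlasmaSeries(
            patient_id=str(pid),
            times_min=sub.sort_values("time_min").time_min.to_numpy(dtype=float),
            rel_conc=sub.sort_values("time_min").rel_conc.to_numpy(dtype=float),
        )
        for pid, sub in df.groupby("patient_id", sort=True)
    ]


def read_lesions(path: str | Path) -> pd.DataFrame:
    return _load_checked(path, "lesions")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV output: fixed float format, no index."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass(frozen=True)
class RunConfig:
    """Validated paths and options for an end-to-end run.

    All referenced input files must exist before any computation starts.
    """

    patients: Path
    tacs: Path
    urine: Path | None
    plasma: Path | None
    lesions: Path | None
    out_dir: Path
    voiding_interval_min: float = 60.0
    administration_MBq: float = 200.0

    def __post_init__(self) -> None:
        for name in ("patients", "tacs", "urine", "plasma", "lesions"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")
        if not self.voiding_interval_min > 0:
            raise ValueError("voiding_interval_min must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def _p(key, required=False):
            if key not in raw or raw[key] is None:
                if required:
                    raise ValueError(f"{path}: missing required key {key!r}")
                return None
            return base / raw[key]

        return cls(
            patients=_p("patients", required=True),
            tacs=_p("tacs", required=True),
            urine=_p("urine"),
            plasma=_p("plasma"),
            lesions=_p("lesions"),
            out_dir=base / raw.get("out_dir", "report"),
            voiding_interval_min=float(raw.get("voiding_interval_min", 60.0)),
            administration_MBq=float(raw.get("administration_MBq", 200.0)),
        )
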