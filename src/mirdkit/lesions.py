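"""Lesion uptake statistics: group mean ± SEM of SUV metrics and
tumor-to-organ ratios.

Conventions: SEM uses the n−1 sample standard deviation over √n; a single
observation reports SEM 0 with a flag.  Tumor-to-organ ratios are computed
per patient first and then averaged within group (mean of ratios, not ratio
of means).  Report-time rounding is half-up to 2 decimal places and happens
only at report time — all comparisons use unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "RATIO_ORGANS",
    "LesionRecord",
    "group_mean_sem",
    "tumor_to_organ",
    "group_ratio_summary",
    "pick_hottest_lesion",
    "round_half_up",
    "load_lesion_table",
    "summarize_suv",
]

GROUPS = ("BC", "NEN")
TIMEPOINTS = ("PET_10", "PET_1h", "PET_2h")
RATIO_ORGANS = ("blood", "liver", "kidney", "muscle")


@dataclass(frozen=True)
class LesionRecord:
    """One lesion's SUV readout at one time point."""

    patient_id: str
    group: str
    timepoint: str
    suv_max: float
    suv_mean: float
    tumor_size_cm: float | None = None
    lesion_id: str = ""
    metastasis_site: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if self.suv_max < 0 or self.suv_mean < 0:
            raise ValueError("SUV values must be >= 0")
        if self.suv_mean > self.suv_max:
            raise ValueError(
                f"suv_mean ({self.suv_mean}) cannot exceed suv_max ({self.suv_max})"
            )
        if self.tumor_size_cm is not None and not self.tumor_size_cm > 0:
            raise ValueError("tumor_size_cm must be > 0 when given")


def group_mean_sem(values) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean (n−1 SD / √n).

    n = 1 returns SEM 0 (the flagged single-observation convention).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    mean = float(v.mean())
    if v.size == 1 or np.ptp(v) == 0.0:  # identical values: exactly zero spread
        return mean, 0.0
    return mean, float(v.std(ddof=1) / np.sqrt(v.size))


def tumor_to_organ(lesion_suv_max: float, organ_suv_mean: float) -> float:
    """Single-patient tumor-to-organ ratio: lesion SUVmax / organ SUVmean."""
    if organ_suv_mean <= 0:
        raise ValueError(
            f"organ background SUVmean must be > 0, got {organ_suv_mean}"
        )
    if lesion_suv_max < 0:
        raise ValueError("lesion SUVmax must be >= 0")
    return lesion_suv_max / organ_suv_mean


def group_ratio_summary(ratios) -> tuple[float, float]:
    """Group mean ± SEM of per-patient ratios (mean of ratios)."""
    return group_mean_sem(ratios)


def pick_hottest_lesion(lesions: list[LesionRecord]) -> LesionRecord:
    """The lesion with the highest SUVmax; ties broken by lesion id order."""
    if not lesions:
        raise ValueError("no lesions to choose from")
    return max(
        sorted(lesions, key=lambda l: l.lesion_id),
        key=lambda l: l.suv_max,
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for report tables (5 always rounds away)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def load_lesion_table() -> pd.DataFrame:
    """The packaged per-patient primary-lesion SUV table (long format)."""
    with resources.files("mirdkit.data").joinpath("lesion_uptake_table.csv").open(
        encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh)
    # validate through the record type
    for row in df.itertuples():
        LesionRecord(
            patient_id=str(row.patient_id),
            group=row.group,
            timepoint=row.timepoint,
            suv_max=row.suv_max,
            suv_mean=row.suv_mean,
            tumor_size_cm=row.tumor_size_cm,
            metastasis_site=bool(row.metastasis_site),
        )
    return df


def summarize_suv(df: pd.DataFrame, metric: str = "suv_max") -> pd.DataFrame:
    """Group × timepoint mean and SEM of an SUV metric.

    Returns a tidy frame with columns group, timepoint, n, mean, sem, and the
    report-rounded (2 d.p., half-up) mean/sem alongside the exact values.
    """
    rows = []
    for group in GROUPS:
        for tp in TIMEPOINTS:
            vals = df.loc[(df.group == group) & (df.timepoint == tp), metric]
            if vals.empty:
                continue
            mean, sem = group_mean_sem(vals)
            rows.append(
                {
                    "group": group,
                    "timepoint": tp,
                    "metric": metric,
                    "n": int(vals.size),
                    "mean": mean,
                    "sem": sem,
                    "mean_2dp": round_half_up(mean),
                    "sem_2dp": round_half_up(sem),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)
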