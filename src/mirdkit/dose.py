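"""MIRD-schema absorbed dose and ICRP-103 effective dose.

Absorbed dose to a target region per unit administered activity is the
TIAC-weighted sum of S-values,

    D(r_T) = Σ_S ã(r_S) [h] · S(r_T ← r_S) [mGy/(MBq·h)],

and the effective dose is the tissue-weighted sum of sex-averaged organ
equivalent doses with the ICRP Publication 103 weights.  The radiation
weighting factor for positrons and photons is 1, so absorbed (mGy) and
equivalent (mSv) doses coincide numerically throughout.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "SMatrix",
    "TissueWeights",
    "DoseReport",
    "ICRP103_WEIGHTS",
    "absorbed_doses",
    "effective_dose",
    "scale_to_administration",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SMatrix:
    """Dose-per-decay factors S(target ← source) in mGy/(MBq·h) for one phantom."""

    phantom_name: str
    entries: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (target, source), v in self.entries.items():
            if v < 0:
                raise ValueError(f"S({target!r} <- {source!r}) must be >= 0, got {v}")

    @property
    def targets(self) -> set[str]:
        return {t for t, _ in self.entries}

    @property
    def sources(self) -> set[str]:
        return {s for _, s in self.entries}

    def __call__(self, target: str, source: str) -> float:
        try:
            return self.entries[(target, source)]
        except KeyError:
            raise KeyError(
                f"no S-value for target {target!r} <- source {source!r} "
                f"in phantom {self.phantom_name!r}"
            ) from None

    @classmethod
    def from_csv(cls, path: str | Path, phantom_name: str | None = None) -> "SMatrix":
        """Load from CSV with columns phantom, target, source, s_mGy_per_MBq_h.

        If the file holds several phantoms, ``phantom_name`` selects one.
        """
        entries: dict[tuple[str, str], float] = {}
        names: set[str] = set()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                if phantom_name is not None and row["phantom"] != phantom_name:
                    continue
                names.add(row["phantom"])
                entries[(row["target"], row["source"])] = float(row["s_mGy_per_MBq_h"])
        if not entries:
            raise ValueError(f"no S-matrix rows for phantom {phantom_name!r} in {path}")
        if len(names) > 1:
            raise ValueError(
                f"{path} holds phantoms {sorted(names)}; pass phantom_name to select one"
            )
        return cls(phantom_name=names.pop(), entries=entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["phantom", "target", "source", "s_mGy_per_MBq_h"])
            for (target, source), v in sorted(self.entries.items()):
                writer.writerow([self.phantom_name, target, source, f"{v:.6g}"])


@dataclass(frozen=True)
class TissueWeights:
    """ICRP-style tissue weighting factors, normalized to 1."""

    w_T: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.w_T.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tissue weights must sum to 1, got {total!r}")
        for tissue, w in self.w_T.items():
            if w < 0:
                raise ValueError(f"weight for {tissue!r} must be >= 0")


#: ICRP Publication 103 tissue weighting factors.  The thirteen ICRP
#: "remainder tissues" are handled as a single aggregate target named
#: ``remainder``; tissue keys match the dose-map target names used by the
#: shipped phantoms.
ICRP103_WEIGHTS = TissueWeights(
    {
        "gonads": 0.08,
        "red_marrow": 0.12,
        "colon": 0.12,
        "lungs": 0.12,
        "stomach_wall": 0.12,
        "breasts": 0.12,
        "urinary_bladder_wall": 0.04,
        "esophagus": 0.04,
        "liver": 0.04,
        "thyroid": 0.04,
        "bone_surfaces": 0.01,
        "brain": 0.01,
        "salivary_glands": 0.01,
        "skin": 0.01,
        "remainder": 0.12,
    }
)


@dataclass(frozen=True)
class DoseReport:
    """Absorbed dose coefficients per target plus the effective dose."""

    phantom_names: tuple[str, ...]
    absorbed_mGy_per_MBq: dict[str, float]
    effective_mSv_per_MBq: float
    per_sex: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for target, d in self.absorbed_mGy_per_MBq.items():
            if d < 0:
                raise ValueError(f"absorbed dose for {target!r} must be >= 0")
        if self.effective_mSv_per_MBq < 0:
            raise ValueError("effective dose must be >= 0")


def absorbed_doses(
    tiacs: dict[str, float],
    s: SMatrix,
    aliases: dict[str, str] | None = None,
) -> dict[str, float]:
    """Absorbed dose (mGy/MBq) to every S-matrix target from the given TIACs.

    ``aliases`` maps TIAC source-region names onto S-matrix source names.
    Sources that resolve to nothing are a hard error listing them, so a
    mis-spelled region cannot silently drop its dose contribution.
    """
    aliases = aliases or {}
    resolved: dict[str, float] = {}
    for region, a in tiacs.items():
        if a < 0:
            raise ValueError(f"negative TIAC for {region!r}")
        name = aliases.get(region, region)
        resolved[name] = resolved.get(name, 0.0) + a
    missing = sorted(set(resolved) - s.sources)
    if missing:
        raise KeyError(
            f"TIAC source regions {missing} have no S-matrix source in "
            f"phantom {s.phantom_name!r}; add an alias or an S-value"
        )
    return {
        target: sum(a * s(target, source) for source, a in sorted(resolved.items()))
        for target in sorted(s.targets)
    }


def effective_dose(
    doses_by_sex: dict[str, dict[str, float]],
    weights: TissueWeights = ICRP103_WEIGHTS,
) -> float:
    """ICRP-103 effective dose (mSv/MBq) from per-sex absorbed dose maps.

    The canonical definition averages male and female organ doses before
    applying w_T; a single-sex map is accepted with a logged caveat (the
    result is then that sex's weighted sum).
    """
    if not doses_by_sex or len(doses_by_sex) > 2:
        raise ValueError("supply dose maps for one or two sexes")
    if len(doses_by_sex) == 1:
        (sex,) = doses_by_sex
        log.warning(
            "effective dose computed from a single phantom (%s); "
            "ICRP 103 defines it as the male/female average",
            sex,
        )
    missing = sorted(
        {
            tissue
            for tissue, w in weights.w_T.items()
            if w > 0
            for doses in doses_by_sex.values()
            if tissue not in doses
        }
    )
    if missing:
        raise KeyError(f"weighted tissues missing from dose map: {missing}")
    ed = 0.0
    for tissue, w in weights.w_T.items():
        if w == 0.0:
            continue
        mean_dose = sum(d[tissue] for d in doses_by_sex.values()) / len(doses_by_sex)
        ed += w * mean_dose
    return ed


def scale_to_administration(coeff_mSv_per_MBq: float, activity_MBq: float) -> float:
    """Total dose (mSv) for an administered activity: coefficient × activity."""
    if coeff_mSv_per_MBq < 0 or activity_MBq < 0:
        raise ValueError("dose coefficient and activity must both be >= 0")
    return coeff_mSv_per_MBq * activity_MBq
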