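#!/usr/bin/env python
"""Lesion uptake statistics: group mean ± SEM and tumor-to-organ ratios.

Two parts: (1) the packaged per-patient primary-lesion SUV table is
summarized per disease group and time point; (2) tumor-to-organ ratios
(lesion SUVmax over organ SUVmean from the simulated TACs) are averaged per
group.  Writes results/lesions/.
"""

from pathlib import Path

import pandas as pd

from mirdkit import load_lesion_table, summarize_suv
from mirdkit import io as mio
from mirdkit.pipeline import _ratio_table, organ_suv_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "lesions"

    # packaged observed per-patient lesion table
    observed = load_lesion_table()
    stats = pd.concat(
        [summarize_suv(observed, "suv_max"), summarize_suv(observed, "suv_mean")],
        ignore_index=True,
    )
    mio.write_table(stats, out / "suv_statistics_observed.csv")
    print(f"group SUV statistics -> {out}")
    for row in stats[stats.metric == "suv_max"].itertuples():
        print(
            f"  {row.group:3s} {row.timepoint:6s} SUVmax "
            f"{row.mean_2dp:.2f} (SEM {row.sem_2dp:.2f}, "
            f"range {row.min:.2f}-{row.max:.2f})"
        )

    # tumor-to-organ ratios on the simulated cohort
    data_dir = ROOT / "synthetic_cohort"
    patients = mio.read_patients(data_dir / "patients.csv")
    tacs = mio.read_tacs(data_dir / "tacs.csv")
    lesions = mio.read_lesions(data_dir / "lesions.csv")
    ratios = _ratio_table(lesions, organ_suv_table(tacs, patients))
    mio.write_table(ratios, out / "tumor_to_organ_synthetic.csv")
    one_h = ratios.query("timepoint == 'PET_1h' and group == 'All'")
    for row in one_h.itertuples():
        print(
            f"  tumor-to-{row.organ:6s} at 1 h: "
            f"{row.ratio_mean:.2f} (SEM {row.ratio_sem:.2f})"
        )


if __name__ == "__main__":
    main()
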