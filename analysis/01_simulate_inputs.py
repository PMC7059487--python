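#!/usr/bin/env python
"""Generate the synthetic inputs the later stages consume.

Writes a QOF-like annual diagnosed-diabetes series (near-linear counts in
millions, fiscal years 2004/05-2017/18) and age schedules standing in for
the survey age distributions of each glycaemic state, under results/inputs/.
"""

from pathlib import Path

import yaml

from t2dproj import io as tio
from t2dproj.synthetic import gen_age_schedule, gen_qof_series

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "inputs"

# age-skew per state: the adult population is younger-weighted (negative
# skew); IH and T2D populations are older than the normoglycaemic one.
# Values chosen so HR x weighted reference mortality lands at the English
# 2015 magnitudes (NG 0.6%, all adults 0.9%, IH ~1.9%, T2D ~2.3%).
STATE_SKEWS = {"general": -1.22, "ng": -2.11, "ih": 0.74, "t2d": 0.57}


def main() -> None:
    cfg = yaml.safe_load((ROOT / "analysis" / "config.yaml").read_text())
    seed = cfg["seed"]
    OUT.mkdir(parents=True, exist_ok=True)

    series = gen_qof_series(seed=seed)
    tio.write_series_csv(series, OUT / "qof_series.csv")
    print(f"QOF-like series: {len(series)} fiscal years "
          f"({series.years[0]}/{series.years[0]+1} to {series.years[-1]}/{series.years[-1]+1}), "
          f"{series.values[0]:.2f} -> {series.values[-1]:.2f} million diagnosed")

    for state, skew in STATE_SKEWS.items():
        sched = gen_age_schedule(skew=skew, n_bands=7, base_rate=0.0005, gradient=2.2)
        tio.write_age_schedule_csv(sched, OUT / f"age_schedule_{state}.csv")
    print(f"age schedules written for states: {', '.join(STATE_SKEWS)}")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
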