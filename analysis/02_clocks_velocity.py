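#!/usr/bin/env python
"""Apply the biological-age clocks and estimate aging velocities.

Reads the study written by 01_simulate.py, predicts DNAm and RNA ages for
the in-vivo cohort and the in-vitro time course, and reports: clock accuracy
in vivo (slope ~1x against chronological age), per-donor in-vitro aging
velocities, their averages, and years aged over the first five months.

Writes results/velocities.csv and scratch/tables/age_predictions.csv.
"""

from pathlib import Path

import pandas as pd

from agevelo import (
    average_velocity, fit_velocity, load_clock, predict_clock_age,
    prediction_error_summary, years_aged,
)
from agevelo import io as avio

study = Path("scratch/study")
if not study.exists():
    raise SystemExit("run analysis/01_simulate.py first")
results = Path("results")
results.mkdir(exist_ok=True)

dnam_clock = load_clock(study / "clock_dnam.csv")
rna_clock = load_clock(study / "clock_rna.csv")

preds, fits = [], []
for cohort in ("invivo", "invitro"):
    sheet = avio.read_sample_sheet(study / f"{cohort}_sheet.csv")
    betas = avio.read_beta_matrix(study / f"{cohort}_betas.tsv")
    fpkm = avio.read_expression_matrix(study / f"{cohort}_fpkm.tsv", "fpkm")
    p_dnam = predict_clock_age(betas, dnam_clock)
    p_rna = predict_clock_age(fpkm, rna_clock)
    preds += [p_dnam.assign(cohort=cohort, clock="dnam"),
              p_rna.assign(cohort=cohort, clock="rna")]

    group = "cohort" if cohort == "invivo" else "donor"
    for name, p in (("dnam", p_dnam), ("rna", p_rna)):
        fit = fit_velocity(p, sheet, group_by=group).assign(cohort=cohort)
        fits.append(fit)
        avg = average_velocity(fit)
        print(f"{cohort:8s} {name:4s} velocity: {avg['mean']:6.2f}x "
              f"+/- {avg['sd']:.2f} (n={avg['n']})")
        if cohort == "invivo" and name == "dnam":
            err = prediction_error_summary(p, sheet)
            print(f"  in-vivo DNAm clock offset: {err['mean_offset']:+.2f} "
                  f"+/- {err['sd_offset']:.2f} years")
        if cohort == "invitro":
            ya = years_aged(p, sheet, 0, 5)
            print(f"  mean years aged in 5 months ({name}): "
                  f"{ya['delta'].mean():.2f}")

tables = Path("scratch/tables")
tables.mkdir(parents=True, exist_ok=True)
pd.concat(preds).to_csv(tables / "age_predictions.csv")
pd.concat(fits, ignore_index=True).to_csv(results / "velocities.csv",
                                          index=False)
print(f"wrote {results / 'velocities.csv'}")
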