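#!/usr/bin/env python
"""Anti-aging treatment response.

Compares aging velocities between untreated and drug-treated cultures
(paired per donor), runs differential expression against the untreated
baseline at month 6, overlaps the DE genes with the aging pathways, and
classifies per-pathway slowing.

Writes results/treatment_velocities.csv and results/treatment_de_significant.csv
(the full per-gene DE table goes under scratch/tables/).
"""

import warnings
from pathlib import Path

import pandas as pd

from agevelo import (
    compare_velocities, correlate_aging_genes, de_pathway_overlap,
    fit_velocity, load_clock, pathway_overlap_table, predict_clock_age,
    treatment_de,
)
from agevelo import io as avio

study = Path("scratch/study")
if not study.exists():
    raise SystemExit("run analysis/01_simulate.py first")
results = Path("results")
results.mkdir(exist_ok=True)

sheet = avio.read_sample_sheet(study / "treatment_sheet.csv")
betas = avio.read_beta_matrix(study / "treatment_betas.tsv")
fpkm = avio.read_expression_matrix(study / "treatment_fpkm.tsv", "fpkm")
dnam_clock = load_clock(study / "clock_dnam.csv")
rna_clock = load_clock(study / "clock_rna.csv")
sets = avio.read_gmt(study / "pathways.gmt")

p_dnam = predict_clock_age(betas, dnam_clock)
p_rna = predict_clock_age(fpkm, rna_clock)
ctrl = sheet[sheet["condition"] == "in_vitro_control"]
rows = []
for arm in ("metformin", "rapamycin"):
    arm_sheet = sheet[sheet["condition"] == arm]
    for assay, preds in (("dnam", p_dnam), ("rna", p_rna)):
        cmp = compare_velocities(fit_velocity(preds, ctrl),
                                 fit_velocity(preds, arm_sheet))
        rows.append({"arm": arm, "assay": assay,
                     "velocity_control": cmp["mean_velocity_control"],
                     "velocity_treated": cmp["mean_velocity_treated"],
                     "paired_t": cmp["t"], "p_value": cmp["p_value"]})
        print(f"{arm:10s} {assay:4s}: {cmp['mean_velocity_control']:5.1f}x -> "
              f"{cmp['mean_velocity_treated']:5.1f}x "
              f"(paired t={cmp['t']:.1f}, p={cmp['p_value']:.3f})")
pd.DataFrame(rows).to_csv(results / "treatment_velocities.csv", index=False)

de = treatment_de(fpkm, sheet, "metformin", 6.0, method="moderated")
tables = Path("scratch/tables")
tables.mkdir(parents=True, exist_ok=True)
de.to_csv(tables / "treatment_de.csv", index=False)
de[de["significant"]].to_csv(results / "treatment_de_significant.csv",
                             index=False)
n_up = int((de["significant"] & (de["log2_fold_change"] > 0)).sum())
n_down = int((de["significant"] & (de["log2_fold_change"] < 0)).sum())
print(f"metformin vs control at month 6: {n_up} up / {n_down} down "
      f"significant genes (BH p<0.05, pooled-variance test)")

# overlap of DE genes with the aging pathways (needs the aging screens)
inv_sheet = avio.read_sample_sheet(study / "invivo_sheet.csv")
inv_fpkm = avio.read_expression_matrix(study / "invivo_fpkm.tsv", "fpkm")
vit_sheet = avio.read_sample_sheet(study / "invitro_sheet.csv")
vit_fpkm = avio.read_expression_matrix(study / "invitro_fpkm.tsv", "fpkm")
tab_vivo = correlate_aging_genes(inv_fpkm, inv_sheet, "in_vivo")
tab_vitro = correlate_aging_genes(vit_fpkm, vit_sheet, "in_vitro")
universe = sorted(tab_vivo["gene"])
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    aging_overlap = pathway_overlap_table(tab_vitro, tab_vivo, sets, universe)
tiers = de_pathway_overlap(de, aging_overlap, sets, universe)
if tiers.empty:
    print("no pathways enriched in metformin DE genes")
else:
    counts = tiers["tier"].value_counts().to_dict()
    print(f"pathways enriched in metformin DE genes: {counts}")
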