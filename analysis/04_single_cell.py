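#!/usr/bin/env python
"""Single-cell aging heterogeneity.

Normalizes the single-cell counts, computes per-cell LTA and clock-gene
scores, quartile contributions per donor and timepoint, Levene tests of
score-variance growth, per-pathway heterogeneity (variable loss of
down-regulated programs), the G2/M fraction, and the pseudobulk-vs-bulk
clock consistency check.

Writes results/sc_quartiles.csv and results/sc_pathway_sd.csv; the per-cell
score table goes under scratch/tables/.
"""

from pathlib import Path

import pandas as pd

from agevelo import (
    cell_cycle_fraction, clockgene_score, heterogeneity_test, load_clock,
    lta_score, normalize_cells, per_pathway_cell_scores, predict_clock_age,
    pseudobulk, quartile_contribution,
)
from agevelo import io as avio

study = Path("scratch/study")
if not study.exists():
    raise SystemExit("run analysis/01_simulate.py first")
results = Path("results")
results.mkdir(exist_ok=True)

counts = avio.read_mtx_triplet(study / "sc")
cell_sheet = pd.read_csv(study / "sc_cell_sheet.csv")
sets = avio.read_gmt(study / "pathways.gmt")
rna_clock = load_clock(study / "clock_rna.csv")

norm, report = normalize_cells(counts)
print(f"normalized {report['n_kept']} cells "
      f"({report['n_dropped']} dropped by the gene filter)")

g2m = cell_cycle_fraction(norm, sets["G2M_SET"])
print(f"G2/M-scoring cells: {100 * g2m['fraction_above']:.1f}% "
      f"(non-proliferative, G0-dominant population)")

# direction-tagged aging gene sets from the GMT (up/down pathway families)
up_genes = sorted({g for n, gs in sets.items() if n.startswith("UP_PATH")
                   for g in gs})
down_genes = sorted({g for n, gs in sets.items() if n.startswith("DOWN_PATH")
                     for g in gs})
scores = pd.DataFrame({
    "lta_score": lta_score(norm, up_genes, down_genes),
    "clockgene_score": clockgene_score(norm, rna_clock),
})
scores.index.name = "cell_id"
tables = Path("scratch/tables")
tables.mkdir(parents=True, exist_ok=True)
scores.join(cell_sheet.set_index("cell_id")).to_csv(tables / "sc_scores.csv")

quart = quartile_contribution(scores["lta_score"], cell_sheet)
quart.to_csv(results / "sc_quartiles.csv", index=False)
print("oldest-quartile contribution per sample:")
for _, row in quart.iterrows():
    print(f"  {row['donor_id']} month {row['timepoint']:>2}: "
          f"{100 * row['Q4_oldest']:.0f}% of cells")

sheet_idx = cell_sheet.set_index("cell_id").loc[scores.index]
for donor, cells in sheet_idx.groupby("donor_id").groups.items():
    tp = sheet_idx.loc[cells, "timepoint"]
    groups = {f"month {t}": scores.loc[tp.index[tp == t], "lta_score"]
              for t in sorted(tp.unique())}
    het = heterogeneity_test(groups)
    sds = ", ".join(f"{k}: SD={v:.2f}" for k, v in het["group_sd"].items())
    print(f"{donor} LTA heterogeneity — {sds}; Levene F="
          f"{het['levene_F']:.1f}, p={het['levene_p']:.2g}")

directions = {n: ("up" if n.startswith("UP_PATH") else "down")
              for n in sets if n.startswith(("UP_PATH", "DOWN_PATH"))}
pp = per_pathway_cell_scores(norm, cell_sheet,
                             {n: sets[n] for n in directions}, directions)
pp["sd_table"].to_csv(results / "sc_pathway_sd.csv", index=False)
for direction, test in pp["paired_tests"].items():
    print(f"{direction}-regulated pathways: mean per-sample score SD "
          f"{test['mean_sd_t0']:.2f} -> {test['mean_sd_t1']:.2f} "
          f"(paired t={test['t']:.1f}, p={test['p_value']:.2g})")

# pseudobulk ages vs matched bulk predictions
groups = cell_sheet.set_index("cell_id").apply(
    lambda r: f"{r.donor_id}_m{r.timepoint}", axis=1)
pb_pred = predict_clock_age(pseudobulk(counts, groups).to_fpkm(), rna_clock)
bulk_fpkm = avio.read_expression_matrix(study / "invitro_fpkm.tsv", "fpkm")
bulk_pred = predict_clock_age(bulk_fpkm, rna_clock)
print("pseudobulk vs bulk RNA age:")
for g in pb_pred.index:
    donor, month = g.split("_m")
    b = bulk_pred.loc[f"{donor}_m{month}_rna", "predicted_age"]
    p = pb_pred.loc[g, "predicted_age"]
    print(f"  {g}: pseudobulk {p:.1f} vs bulk {b:.1f} (diff {p - b:+.1f}y)")
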