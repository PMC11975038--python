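#!/usr/bin/env python
"""Concordance of in-vivo and in-vitro transcriptomic aging.

Runs the aging-gene correlation screens in both contexts, the pathway
enrichment/contribution analysis with its recapitulation summary, pathway
aging-velocity trajectories, and the promoter-methylation coupling check.

Writes results/pathway_overlap.csv, results/pathway_velocities.csv and the
full per-gene screen tables under scratch/tables/.
"""

import warnings
from pathlib import Path

import pandas as pd

from agevelo import (
    aging_gene_counts, correlate_aging_genes, pathway_overlap_table,
    pathway_trajectory, promoter_methylation, recapitulation_from_overlap,
)
from agevelo import io as avio
from agevelo.signatures import (
    acceleration_ratio, methylation_expression_coupling, rowwise_slopes,
)

study = Path("scratch/study")
if not study.exists():
    raise SystemExit("run analysis/01_simulate.py first")
results = Path("results")
results.mkdir(exist_ok=True)
tables = Path("scratch/tables")
tables.mkdir(parents=True, exist_ok=True)

sets = avio.read_gmt(study / "pathways.gmt")
annot = avio.read_probe_annotation(study / "probe_annotation.tsv")

data = {}
for cohort, context in (("invivo", "in_vivo"), ("invitro", "in_vitro")):
    sheet = avio.read_sample_sheet(study / f"{cohort}_sheet.csv")
    fpkm = avio.read_expression_matrix(study / f"{cohort}_fpkm.tsv", "fpkm")
    table = correlate_aging_genes(fpkm, sheet, context, p_threshold=0.05)
    counts = aging_gene_counts(table)
    print(f"{context}: {counts['up']} up / {counts['down']} down aging genes "
          f"(p<0.05; {counts['excluded']} zero-variance excluded)")
    table.to_csv(tables / f"aging_genes_{cohort}.csv", index=False)
    data[context] = (table, fpkm, sheet)

universe = sorted(data["in_vivo"][0]["gene"])
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    overlap = pathway_overlap_table(data["in_vitro"][0], data["in_vivo"][0],
                                    sets, universe)
overlap.to_csv(results / "pathway_overlap.csv", index=False)
recap = recapitulation_from_overlap(overlap)
print(f"in-vivo pathways recapitulated in vitro: "
      f"up {recap['up'][0]}/{recap['up'][1]}, "
      f"down {recap['down'][0]}/{recap['down'][1]} "
      f"-> pooled {recap['pooled_pct']:.0f}%")
n_overlapping = int((overlap['classification'] == 'overlapping').sum())
print(f"{n_overlapping} pathway x direction entries classified overlapping "
      f"(contribution 30-70%)")

# pathway aging velocities and in-vitro acceleration
rows = []
for name, genes in sets.items():
    if name.startswith("NULL") or name == "G2M_SET":
        continue
    trajs = {}
    for context in ("in_vivo", "in_vitro"):
        _, fpkm, sheet = data[context]
        trajs[context] = pathway_trajectory(fpkm, sheet, genes, context, name)
    rows.append({
        "pathway": name,
        "slope_invivo": trajs["in_vivo"]["slope"],
        "slope_invitro": trajs["in_vitro"]["slope"],
        "acceleration": acceleration_ratio(trajs["in_vitro"],
                                           trajs["in_vivo"]),
    })
traj = pd.DataFrame(rows)
traj.to_csv(results / "pathway_velocities.csv", index=False)
print(f"median in-vitro pathway acceleration: "
      f"{traj['acceleration'].median():.1f}-fold")

# promoter methylation couples inversely to expression
_, fpkm, sheet = data["in_vitro"]
betas = avio.read_beta_matrix(study / "invitro_betas.tsv")
aging_genes = sorted(set(annot["gene"]))
prom = promoter_methylation(betas, annot, aging_genes)
coup = methylation_expression_coupling(
    rowwise_slopes(fpkm.log2_plus1(), sheet, "in_vitro").loc[aging_genes],
    rowwise_slopes(prom, sheet, "in_vitro", assay="dnam"))
print(f"promoter DNAm vs expression slope correlation (in vitro): "
      f"r={coup['r']:.2f}, p={coup['p_value']:.2g}, n={coup['n_genes']} genes")
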