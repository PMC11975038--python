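#!/usr/bin/env python
"""Generate the full synthetic aging study.

Writes every dataset of the study design — in-vivo cohort, in-vitro
time course, treatment arms, single-cell snapshots, embedded clocks, probe
annotation and pathway GMT — under scratch/study/ (matrices are too large
for the results/ tables, which hold only derived summaries).

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import sys
from pathlib import Path

from agevelo import AgingSimConfig, simulate_study

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
outdir = Path("scratch/study")
cfg = AgingSimConfig(seed=seed)
info = simulate_study(cfg, outdir)

print(f"wrote synthetic study (seed={seed}) to {info['outdir']}:")
print(f"  in-vivo samples:    {info['n_invivo_samples']}")
print(f"  in-vitro samples:   {info['n_invitro_samples']}")
print(f"  treatment samples:  {info['n_treatment_samples']}")
print(f"  single cells:       {info['n_cells']}")
print("study design: 22 donors aged 0-92 in vivo; donors aged "
      f"{cfg.donor_ages} cultured {cfg.n_timepoints - 1} months at "
      f"DNAm velocity {cfg.dnam_velocity}x / RNA velocity {cfg.rna_velocity}x;"
      f" treatment arms for donors aged {cfg.treatment_donor_ages}.")
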