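# agevelo

Analysis pipeline for **longitudinal in-vitro aging** of human fibroblasts:
apply linear biological-age clocks to paired DNA-methylation / transcriptome
time courses, estimate **aging velocities**, identify aging genes and pathways
that change concordantly in vivo and in vitro, quantify **single-cell aging
heterogeneity** with a per-cell longitudinal transcriptomic aging (LTA) score,
and evaluate anti-aging drug treatments against the untreated aging baseline.

It is written for researchers studying cellular aging dynamics in confluent,
non-dividing (G0-like) primary cell cultures, where months of culture compress
years of biological aging. Because such studies rarely ship raw data, the
package includes a first-class **synthetic-data generator** with a programmed
latent aging process, so every stage of the pipeline is validated by parameter
recovery against known ground truth.

## The model

A linear biological-age clock predicts age from a weighted combination of
features (CpG beta values or gene expression):

    F(age_hat) = intercept + sum_f  w_f * x_f

where F is either the identity or the piecewise log-linear calibration used
by methylation clocks, F(a) = log(a+1) − log(a0+1) for a ≤ a0 and
(a − a0)/(a0+1) above the adult knot a0 (default 20 years). Predicted ages are
obtained by inverting F; transcriptomic clocks act on log2(FPKM+1).

The **aging velocity** of a donor is the OLS slope of predicted biological age
on chronological time (months in culture are converted to decimal years):
1× means the clock tracks calendar time. **Years aged** is the difference of
predicted ages between two timepoints. Aging genes are detected by Pearson
correlation of log2(FPKM+1) with the aging axis; pathway concordance uses
hypergeometric enrichment (BH-adjusted) plus the input-size-adjusted
contribution

    contribution_invitro = 100 * (h_vitro/N_vitro) / (h_vitro/N_vitro + h_vivo/N_vivo)

with 30–70% classified *overlapping*. The per-cell **LTA score** is
mean z(up-regulated aging genes) − mean z(down-regulated aging genes) on
log-normalized single-cell expression; heterogeneity growth is tested with
Levene/Brown–Forsythe variance tests, and treatment effects use paired
per-donor designs throughout.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(`scratch/study/`), each printing what it found and writing tables under
`results/`:

```bash
python analysis/01_simulate.py 1       # generate the study (seed 1)
python analysis/02_clocks_velocity.py  # clocks + velocities
python analysis/03_aging_signatures.py # aging genes, pathways, methylation
python analysis/04_single_cell.py      # LTA scores + heterogeneity
python analysis/05_treatment.py        # metformin / rapamycin response
```

Selected output from a seed-1 run:

```
invitro  dnam velocity:   8.47x +/- 0.18 (n=4)
invitro  rna  velocity:  48.23x +/- 1.38 (n=4)
in_vivo: 144 up / 239 down aging genes (p<0.05; 0 zero-variance excluded)
in-vivo pathways recapitulated in vitro: up 15/15, down 20/20 -> pooled 100%
promoter DNAm vs expression slope correlation (in vitro): r=-0.95, p=4.7e-175, n=350 genes
D3 LTA heterogeneity — month 0: SD=0.15, month 5: SD=0.25; Levene F=429.7, p=9.7e-91
metformin  dnam:   8.4x ->   2.0x (paired t=-15.7, p=0.004)
```

Reading this: the cultured fibroblasts age 8.5× faster than calendar time on
the methylation clock and ~48× on the RNA clock (the generator's programmed
velocities, recovered by the pipeline); every programmed aging pathway found
in vivo is re-found in vitro with the same direction; promoter methylation
moves opposite to expression; cell-to-cell age spread grows significantly
over five months of culture; metformin slows the methylation clock from 8.4×
to 2.0× in a paired three-donor comparison.

The same machinery is available as a CLI (`agevelo simulate / clock /
velocity / aging-genes / pathways / sc-score / treat-compare`) for use with
externally supplied matrices, sample sheets, GMT gene sets, and clock
coefficient files.

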