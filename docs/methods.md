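# Methods

This note documents the models, statistics, and design choices behind
agevelo, in the order data flows through the pipeline.

## Latent aging process and the synthetic study

All synthetic data derive from one latent process: every sample (and every
single cell) carries a true biological age per assay channel. In the in-vivo
cohort biological age equals chronological age, optionally plus a programmed
clock offset (`dnam_bias`, years) and donor-level scatter
(`dnam_residual_sd`). In confluent culture, biological age advances at a
configurable **velocity** in biological years per chronological year —
separately for the methylation channel (`dnam_velocity`, default 8.5) and the
transcriptome channel (`rna_velocity`, default 48.3), reflecting the
uncoupling of epigenetic and transcriptomic aging rates in long-term
non-dividing fibroblast cultures. Treatment arms multiply these velocities by
a per-arm scale (defaults: metformin 0.21 for DNAm and 0.46 for RNA, the
ratios of the slowed to untreated velocities; rapamycin 0.75, a partial
effect) and share donors with the untreated course, giving a paired design.

The default study design is: 22 in-vivo donors with ages evenly spaced over
0–92 years; four cultured donors aged 53, 55, 67 and 68 followed for six
months with monthly sampling (7 timepoints, months 0–6); treatment arms for
the three donors aged 53, 67 and 68 sampled from month 1; and single-cell
snapshots of the two oldest donors at months 0 and 5.

### Feature models

**Clock CpGs.** Embedded-clock probes are linear in Horvath-transformed
biological age in beta space, `beta_i = 0.5 + d_i * F(bio)`, with drift
magnitudes `|d_i|` drawn from U(0.04, 0.09) and random signs. Over ages
0–120 the betas stay inside (0.07, 0.94), so no clipping is needed and the
emitted linear DNAm clock (weights `w = d / Σd²`, intercept `−0.5 Σw`) is an
*exact* inverse of the generator: at zero technical noise, predictions equal
latent ages to machine precision. This linear-in-F construction is
deliberately different from the logistic drift model used for promoter
probes: a logistic feature model cannot be exactly inverted by a linear
clock, and exact inversion is what makes the clock pipeline testable end to
end. Technical noise is Gaussian in beta space (`noise_sd_beta`, default
0.005 — mid-range array technical noise; betas are finally clipped to (0,1),
which never binds at default noise).

**Promoter CpGs.** Each aging gene gets promoter probes (regions TSS200,
TSS1500, 5'UTR, 1st exon, cycled) plus one gene-body probe. Promoter betas
follow `logistic(logit(beta0) + drift · bio + ε)` with baseline beta0 ~
U(0.2, 0.6) and drift = −`meth_coupling` × the gene's expression slope
(default coupling 0.2 logit units per log2 unit), so promoter methylation and
expression move in opposite directions; ε is logit-space noise scaled 4× the
beta-space SD (the logistic derivative at 0.5 is 1/4). Body probes do not
drift.

**Expression.** Gene expression is linear in biological age on the
log2(FPKM+1) scale: `y_g = y0_g + s_g (bio − 60)`, with baselines anchored
at age 60 and globally rescaled so total FPKM ≈ 10⁶ (making per-million
renormalization scale-compatible with FPKM). A configurable fraction of
genes are aging genes (defaults 5% up, 10% down — the ~1:2 up:down ratio of
reported aging screens) with slope magnitudes U(0.02, 0.05) per biological
year; at the default in-vitro RNA velocity this gives 0.5–1.2 log2 units of
change over five months, the magnitude of strongly aging pathways.
Residual noise is Gaussian on the log scale (`noise_sd_logexpr`, default
0.25, a typical bulk RNA-seq replicate residual). Bulk counts are negative
binomial around FPKM-scaled means with dispersion 0.1.

**Embedded RNA clock.** 150 aging genes are drawn as clock genes with
centered weights `w = (s − s̄)/Σ(s − s̄)²`: Σw·s = 1 preserves exact
zero-noise inversion while Σw = 0 makes predictions invariant to global
log-scale shifts (library-size misnormalization), mirroring how trained
transcriptomic clocks absorb normalization in their intercept. This is what
lets pseudobulk counts-per-million and bulk FPKM be compared on the same
clock.

**Single cells.** Each cell draws a latent age from
Normal(sample mean bioage, SD) with the SD growing from month 0 (default 3
years) to month 5 (default 6 years). Genes belonging to down-regulated aging
pathways additionally receive a per-cell, per-program *retention factor*
κ ~ N(1, sd_t) (clipped at 0, sd growing 0.1 → 0.5 across culture) applied to
the cell's age displacement — so late-timepoint heterogeneity arises
predominantly through variable loss of down-regulated programs, while
up-regulated programs respond more uniformly. Counts are negative binomial
around depth-scaled expression fractions (mean depth 8,000 counts/cell,
lognormal with σ=0.3, within the range of droplet platforms).

The generator writes ground truth (latent ages, gene slopes, probe drifts,
per-cell ages, arm velocities, DE gene lists) to separate truth files that no
estimation code path reads.

### What the generator does not emulate

Array probe chemistry and normalization artifacts, batch effects, genetic
background differences between donors, cell-cycle structure beyond a
G0-dominant population, ambient RNA and doublets, and donor-specific
trajectory shapes (aging is linear in time by construction). Passing tests
therefore demonstrate correct *estimation* under the stated generative
assumptions, not robustness to every artifact of real assays.

## Clocks

`predict_clock_age` computes `inverse_F(intercept + Σ w_f x_f)` per sample,
with the Horvath-style piecewise log-linear F (knot `adult_age`, default 20)
for methylation clocks and the identity for expression clocks; expression
input is log2(FPKM+1) (`input_transform="log2_plus1"`). Missing clock
features are imputed from clock-supplied reference means; a sample missing
more than `max_missing_frac` (default 0.2) of features is a hard error that
lists the absent features — published linear clocks degrade silently under
probe dropout, so silence is the one behavior we refuse. Published
coefficient sets can be supplied through the clock CSV format but are not
bundled; all tests run on the generator-embedded clocks.

## Velocities and years aged

Per-donor OLS of predicted age on chronological time (baseline age +
months/12; 30-day months). The cohort **average velocity is the unweighted
mean of per-donor slopes**, not the slope of pooled data — pooling conflates
donor baseline offsets with the time trend; a pooled `cohort` mode exists and
is the right choice for the cross-sectional in-vivo cohort. Slope p-values
use the t distribution on n−2 df, uncorrected (one test per donor). Years
aged is the plain difference of predicted ages at two timepoints; note that
slope-based velocity and endpoint differences are distinct statistics and are
reported separately, not reconciled.

## Aging genes and pathways

The screen computes per-gene Pearson r of log2(FPKM+1) against donor age
(in vivo) or culture time (in vitro), with two-sided p from the t statistic
on n−2 df. Zero-variance genes get missing r and are excluded from counts
without error. Default threshold p < 0.05 in both contexts; the in-vivo
threshold is configurable (0.1 is a common relaxation for small
heterogeneous cohorts).

Enrichment of the up-/down hit lists in each gene set is one-sided
hypergeometric, BH-adjusted within each (context, direction) family — a
defined, exactly testable statistic standing in for GUI enrichment tools
whose internal tests are unspecified. The contribution statistic normalizes
hit counts by hit-list size before forming the in-vitro share; 50% is an
equal split, 30–70% is classified *overlapping*, and the recapitulation
summary reports per-direction and pooled percentages of in-vivo-significant
pathways re-found in vitro. Pathway trajectories z-score each member gene
across a context's samples before averaging (so high expressors do not
dominate), then regress the per-sample mean z on the time axis; the in-vitro
: in-vivo slope ratio is the pathway's acceleration. Promoter methylation of
a gene is the unweighted mean beta over its TSS200/TSS1500/5'UTR/1st-exon
probes; coupling is the Pearson correlation between per-gene expression
slopes and promoter-methylation slopes.

## Single-cell scores

Cells are filtered (≥200 detected genes), library-size normalized to 10,000
counts, and log1p-transformed — stated as an explicit transform rather than
delegated, since it is load-bearing for every score. The LTA score is
mean z(up genes) − mean z(down genes) with z computed per gene across all
cells of the merged dataset; the up/down sets are the genes of the
overlapping (concordant in-vivo/in-vitro) aging pathways. The score's
functional form is a reconstruction: the simplest signed-z construction
consistent with "lower half = young". The clock-gene score applies the same
construction to the positive/negative-weight genes of a transcriptomic
clock, and accepts one-sided clocks (the absent direction contributes zero).

Quartile contributions use breakpoints from a reference distribution —
per-donor pooled over timepoints by default (timepoints of one donor are
compared on a shared scale; with complete score separation between
timepoints this yields a 50% oldest-quartile contribution at the late
timepoint by construction), with a cohort-pooled mode available since the
reference choice is a genuine free parameter. Heterogeneity uses Levene's
test on absolute deviations from the group center — median by default
(Brown–Forsythe, the robust standard), mean selectable — with F on
(k−1, N−k) df; the implementation is checked against an independent
deviation-ANOVA oracle. Per-pathway heterogeneity compares per-sample score
SDs month 0 vs month 5 by paired t across pathways, separately for up- and
down-regulated families. Pseudobulk is the per-group sum of raw counts,
emitted as a counts matrix that flows through the ordinary
counts → FPKM → clock path.

## Treatment response

Velocity comparison: paired two-sided t on per-donor slope differences.
Differential expression vs the untreated baseline is a per-gene paired test
on log2(FPKM+1) across donors at a fixed timepoint (the paired design —
same donors ± drug — is the dominant structure), BH-adjusted. The default is
the exact per-gene paired t; with only three donor pairs (2 df) per-gene
variance estimates are too unstable to rank by and can never reach BH
significance at genome scale, so a `moderated` mode replaces each gene's
variance with the genome-wide mean paired-difference variance (a z-test) —
the pooling assumption that variance is exchangeable across genes is the
standard small-n RNA-seq compromise. Pathway-level effects are slope deltas
classified *slowed* when treatment moves the slope against the pathway's
aging direction; DE–pathway overlap tiers enriched pathways as
exact-overlap (itself a significant aging pathway), related (sharing ≥20% of
genes with one), or treatment-specific.

## Numerical choices and degenerate inputs

Fractions of quartiles sum to 1 to 1e−12; the age transform round-trips to
1e−10; Pearson/hypergeometric/Levene match closed-form or exact-enumeration
oracles to 1e−9 (hypergeometric to 1e−12 on single tables). Ties in quartile
assignment go to the lower quartile (right-open breakpoints). Degenerate
inputs raise typed errors naming the offending field, group, or cell: <2
timepoints or zero time variance (velocity), zero-variance quartile
reference, <3 cells per Levene group, <2 matched donors (paired tests), <2
member genes (pathway trajectories), missing-feature excess (clocks).
Identical paired samples return t=0, p=1 rather than 0/0.

## Problem sizes

Default analyses run at 2,000 genes, 100 clock CpGs, ~1,750 annotated
probes, 41 gene sets, and 1,000–2,000 cells per single-cell sample — sizes
chosen so the full pipeline, test suite, and acceptance script complete on a
laptop-class single core in minutes while keeping every statistical check
well-powered. Null-calibration simulations (Levene size, DE false-discovery)
use reduced designs (400–600 genes/cells, 50–100 replicates) with the
replicate counts stated in the tests.

## Known limitations

Aging is linear in time by construction, so the pipeline's straight-line
fits are well-specified on synthetic data in a way they may not be on real
trajectories. The LTA score formula is a reconstruction (see above). The DE
moderated mode assumes exchangeable gene variances. Clock transfer across
tissues, clock retraining, and count-model DE (negative-binomial GLMs) are
out of scope; the latter is an extension point behind the `method` argument.
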