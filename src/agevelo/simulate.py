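"""Synthetic aging-study generator with programmed ground truth.

A single latent process drives every dataset: each sample (or cell) carries a
true biological age per assay channel.  In vivo, biological age equals
chronological age (plus optional programmed clock bias and donor scatter); in
confluent culture it advances at a configurable velocity — biological years
per chronological year — separately for the methylation and transcriptome
channels, mirroring the uncoupling of epigenetic and transcriptomic aging
rates observed in long-term non-dividing fibroblast cultures.

Feature model
-------------
* Embedded-clock CpGs are linear in Horvath-transformed biological age in
  beta space, ``beta_i = 0.5 + d_i * F(bio)``, with drift magnitudes chosen so
  betas stay inside (0, 1) for ages 0-120 without clipping.  This makes the
  emitted linear DNAm clock an exact inverse of the generator: at zero noise,
  predictions equal latent ages to machine precision, so the whole clock
  pipeline is testable end to end.
* Promoter CpGs of aging genes follow the logistic drift model
  ``beta = logistic(logit(beta0) + drift * bio + eps)``, with drift
  proportional to minus the gene's expression slope — promoter methylation
  and expression move in opposite directions.
* Gene expression is linear in biological age on the log2(FPKM+1) scale:
  ``y_g = y0_g + s_g * (bio - 60)``.  Up-/down-regulated aging genes have
  positive/negative slopes; all other genes have slope zero.  Bulk counts are
  negative binomial around FPKM-scaled means; single-cell counts are negative
  binomial around depth-scaled expression fractions.
* Single cells draw latent ages from a normal around the sample mean with a
  timepoint-specific SD, and additionally draw a per-cell *program retention*
  factor for each down-regulated pathway, so age heterogeneity at late
  timepoints arises predominantly through the variable loss of down-regulated
  programs.

Everything downstream (clock application, velocity fits, aging-gene screens,
pathway statistics, per-cell scores, treatment comparisons) can therefore be
validated by parameter recovery against the truth object, which is kept apart
from the generated matrices and never consumed by estimation code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.special

from .clocks import ClockModel, age_transform, save_clock
from .config import ARMS, AgingSimConfig
from .errors import ConfigError
from .io import (
    PROMOTER_REGIONS,
    ExpressionMatrix,
    SparseCountMatrix,
    write_beta_matrix,
    write_expression_matrix,
    write_gmt,
    write_json,
    write_mtx_triplet,
    write_probe_annotation,
    write_sample_sheet,
)

REF_AGE = 60.0          # baseline age at which gene baselines are anchored
ADULT_AGE = 20.0        # Horvath-transform knot of the embedded DNAm clock

# fixed spawn keys so independently called generators share one world
_KEY_WORLD, _KEY_INVIVO, _KEY_INVITRO, _KEY_TREAT, _KEY_SC = range(5)


def _rng(config: AgingSimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    )


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------

@dataclass
class LatentAgeTruth:
    """Programmed ground truth stored alongside a generated dataset.

    Held in a separate object (and written to a separate file) so that
    estimation code paths never see it.
    """

    sample_bioage_dnam: pd.Series
    sample_bioage_rna: pd.Series
    gene_slopes: pd.Series          # log2(FPKM+1) units per biological year
    probe_drifts: pd.Series         # clock CpGs: beta per transformed-age unit;
                                    # promoter CpGs: logit-beta per biological year
    aging_genes_up: list
    aging_genes_down: list
    donor_velocity_dnam: dict
    donor_velocity_rna: dict
    cell_bioage: pd.Series | None = None
    de_genes: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "sample_bioage_dnam": self.sample_bioage_dnam.to_dict(),
            "sample_bioage_rna": self.sample_bioage_rna.to_dict(),
            "gene_slopes": self.gene_slopes.to_dict(),
            "probe_drifts": self.probe_drifts.to_dict(),
            "aging_genes_up": list(self.aging_genes_up),
            "aging_genes_down": list(self.aging_genes_down),
            "donor_velocity_dnam": self.donor_velocity_dnam,
            "donor_velocity_rna": self.donor_velocity_rna,
        }
        if self.cell_bioage is not None:
            out["cell_bioage"] = self.cell_bioage.to_dict()
        if self.de_genes is not None:
            out["de_genes"] = self.de_genes
        return out

    def write(self, path) -> None:
        write_json(self.to_dict(), path)


@dataclass
class BulkDataset:
    betas: pd.DataFrame
    counts: ExpressionMatrix
    fpkm: ExpressionMatrix
    sheet: pd.DataFrame
    truth: LatentAgeTruth


@dataclass
class SingleCellDataset:
    counts: SparseCountMatrix
    cell_sheet: pd.DataFrame
    truth: LatentAgeTruth


# ---------------------------------------------------------------------------
# the shared world: genes, slopes, probes, pathways, embedded clocks
# ---------------------------------------------------------------------------

class AgingWorld:
    """Deterministic gene/probe/pathway universe derived from config + seed."""

    def __init__(self, config: AgingSimConfig):
        self.config = config
        rng = _rng(config, _KEY_WORLD)
        n = config.n_genes

        self.genes = pd.Index([f"GENE{i + 1:05d}" for i in range(n)])
        perm = rng.permutation(n)
        n_up = int(round(config.frac_aging_genes_up * n))
        n_down = int(round(config.frac_aging_genes_down * n))
        self.up_idx = np.sort(perm[:n_up])
        self.down_idx = np.sort(perm[n_up:n_up + n_down])
        self.null_idx = np.sort(perm[n_up + n_down:])
        self.aging_genes_up = list(self.genes[self.up_idx])
        self.aging_genes_down = list(self.genes[self.down_idx])

        slopes = np.zeros(n)
        slopes[self.up_idx] = rng.uniform(0.02, 0.05, n_up)
        slopes[self.down_idx] = -rng.uniform(0.02, 0.05, n_down)
        self.gene_slopes = pd.Series(slopes, index=self.genes)

        y0 = rng.uniform(1.0, 9.0, n)
        y0[self.up_idx] = rng.uniform(2.0, 7.0, n_up)
        y0[self.down_idx] = rng.uniform(5.0, 9.0, n_down)
        # anchor the transcriptome so total FPKM at the reference age is ~1e6,
        # which makes per-million renormalization (pseudobulk) scale-compatible
        fpkm0 = np.exp2(y0) - 1.0
        fpkm0 *= 1e6 / fpkm0.sum()
        self.gene_baseline = pd.Series(np.log2(fpkm0 + 1.0), index=self.genes)

        # ---- embedded DNAm clock ------------------------------------------
        m = config.n_clock_features
        self.clock_probes = pd.Index([f"cg_clk_{i + 1:05d}" for i in range(m)])
        d = rng.uniform(0.04, 0.09, m) * rng.choice([-1.0, 1.0], m)
        self.clock_probe_drift = pd.Series(d, index=self.clock_probes)
        w = d / np.sum(d * d)
        ref_f = age_transform(REF_AGE, ADULT_AGE)
        self.dnam_clock = ClockModel(
            name="sim_dnam_clock",
            feature_space="cpg",
            intercept=-0.5 * w.sum(),
            weights=pd.Series(w, index=self.clock_probes),
            transform="log_linear_adult",
            adult_age=ADULT_AGE,
            input_transform="none",
            reference_means=pd.Series(0.5 + d * ref_f, index=self.clock_probes),
        )

        # ---- embedded RNA clock -------------------------------------------
        aging_idx = np.concatenate([self.up_idx, self.down_idx])
        k = min(config.n_rna_clock_genes, len(aging_idx))
        if k < 2:
            raise ConfigError("n_rna_clock_genes: fewer than 2 aging genes available")
        pick = np.sort(rng.choice(aging_idx, size=k, replace=False))
        s = slopes[pick]
        # centered weights: sum(w)=0 makes the clock invariant to global
        # log-scale shifts (library-size misnormalization), while sum(w*s)=1
        # keeps it an exact inverse of the latent aging process
        sc = s - s.mean()
        wg = sc / np.sum(sc * sc)
        clock_genes = self.genes[pick]
        self.rna_clock = ClockModel(
            name="sim_rna_clock",
            feature_space="gene",
            intercept=REF_AGE - float(np.sum(wg * self.gene_baseline.iloc[pick])),
            weights=pd.Series(wg, index=clock_genes),
            transform="identity",
            input_transform="log2_plus1",
            reference_means=pd.Series(
                self.gene_baseline.iloc[pick].to_numpy(), index=clock_genes),
        )

        # ---- promoter probes ----------------------------------------------
        annotated = np.concatenate([self.up_idx, self.down_idx, self.null_idx[:50]])
        rows, probe_ids, beta0s, drifts = [], [], [], []
        ppg = config.promoter_probes_per_gene
        for gi in annotated:
            gene = self.genes[gi]
            drift = -config.meth_coupling * slopes[gi]
            for j in range(ppg):
                pid = f"cg_{gene}_p{j + 1}"
                region = PROMOTER_REGIONS[j % len(PROMOTER_REGIONS)]
                rows.append((pid, gene, region))
                probe_ids.append(pid)
                beta0s.append(rng.uniform(0.2, 0.6))
                drifts.append(drift)
            body = f"cg_{gene}_body"
            rows.append((body, gene, "Body"))
            probe_ids.append(body)
            beta0s.append(rng.uniform(0.2, 0.8))
            drifts.append(0.0)
        self.promoter_probes = pd.Index(probe_ids)
        self.promoter_beta0 = pd.Series(beta0s, index=self.promoter_probes)
        self.promoter_drift = pd.Series(drifts, index=self.promoter_probes)
        self.probe_annotation = pd.DataFrame(
            rows, columns=["probe_id", "gene", "region"])

        # ---- pathways ------------------------------------------------------
        self.gene_sets: dict[str, list[str]] = {}
        self.pathway_directions: dict[str, str] = {}

        def make_sets(prefix, count, pool_idx, direction):
            pool = self.genes[pool_idx]
            null_pool = self.genes[self.null_idx]
            for i in range(count):
                size = int(rng.integers(config.pathway_size_min,
                                        config.pathway_size_max + 1))
                n_core = max(2, int(round(size * 0.8)))
                n_core = min(n_core, len(pool))
                core = rng.choice(len(pool), size=n_core, replace=False)
                extra = rng.choice(len(null_pool), size=size - n_core, replace=False)
                members = sorted(set(pool[core]) | set(null_pool[extra]))
                name = f"{prefix}_{i + 1:02d}"
                self.gene_sets[name] = members
                self.pathway_directions[name] = direction

        make_sets("UP_PATH", config.n_pathways_up, self.up_idx, "up")
        make_sets("DOWN_PATH", config.n_pathways_down, self.down_idx, "down")
        make_sets("NULL_PATH", config.n_pathways_null, self.null_idx, "none")
        g2m = sorted(rng.choice(self.genes[self.null_idx], 20, replace=False))
        self.gene_sets["G2M_SET"] = list(g2m)
        self.pathway_directions["G2M_SET"] = "none"

        up_set = set(self.aging_genes_up)
        down_set = set(self.aging_genes_down)
        self.overlap_up_genes = sorted(
            {g for p, gs in self.gene_sets.items()
             if self.pathway_directions[p] == "up" for g in gs} & up_set)
        self.overlap_down_genes = sorted(
            {g for p, gs in self.gene_sets.items()
             if self.pathway_directions[p] == "down" for g in gs} & down_set)

    # -- sampling -----------------------------------------------------------
    def sample_betas(self, bioage: np.ndarray, sample_ids, rng) -> pd.DataFrame:
        """Draw a beta matrix (clock + promoter probes) at given DNAm bioages."""
        bio = np.asarray(bioage, dtype=float)
        f = age_transform(bio, ADULT_AGE)
        d = self.clock_probe_drift.to_numpy()[:, None]
        clock = 0.5 + d * f[None, :]
        if self.config.noise_sd_beta > 0:
            clock = clock + rng.normal(0.0, self.config.noise_sd_beta, clock.shape)
        clock = np.clip(clock, 1e-9, 1 - 1e-9)

        logit0 = scipy.special.logit(self.promoter_beta0.to_numpy())[:, None]
        drift = self.promoter_drift.to_numpy()[:, None]
        z = logit0 + drift * bio[None, :]
        if self.config.noise_sd_beta > 0:
            # logit-space noise scaled so that near beta=0.5 it matches the
            # beta-space technical SD (d beta / d logit = 1/4 at 0.5)
            z = z + rng.normal(0.0, 4.0 * self.config.noise_sd_beta, z.shape)
        promoter = scipy.special.expit(z)

        values = np.vstack([clock, promoter])
        index = self.clock_probes.append(self.promoter_probes)
        return pd.DataFrame(values, index=index, columns=sample_ids)

    def expression_log(self, bioage: np.ndarray,
                       offsets: np.ndarray | None = None) -> np.ndarray:
        """Noise-free log2(FPKM+1), genes x samples."""
        bio = np.asarray(bioage, dtype=float)
        y = (self.gene_baseline.to_numpy()[:, None]
             + self.gene_slopes.to_numpy()[:, None] * (bio[None, :] - REF_AGE))
        if offsets is not None:
            y = y + offsets
        return y

    def sample_expression(self, bioage: np.ndarray, sample_ids, rng,
                          offsets: np.ndarray | None = None
                          ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
        """Draw FPKM and count matrices at given transcriptomic bioages."""
        cfg = self.config
        y = self.expression_log(bioage, offsets)
        if cfg.noise_sd_logexpr > 0:
            y = y + rng.normal(0.0, cfg.noise_sd_logexpr, y.shape)
        fpkm = np.maximum(np.exp2(y) - 1.0, 0.0)
        mean_counts = fpkm * (cfg.bulk_library_size / 1e6)
        counts = _nb_draw(rng, mean_counts, cfg.nb_dispersion)
        fpkm_df = pd.DataFrame(fpkm, index=self.genes, columns=sample_ids)
        counts_df = pd.DataFrame(counts, index=self.genes, columns=sample_ids)
        return (ExpressionMatrix(fpkm_df, "fpkm"),
                ExpressionMatrix(counts_df, "counts"))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial draw with Var = m + dispersion * m^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        size = 1.0 / dispersion
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _sheet_row(sample_id, donor_id, age, months, condition, assay,
               cell_type="fibroblast"):
    return {
        "sample_id": sample_id, "donor_id": donor_id,
        "chronological_age_at_baseline": age, "time_in_culture": months,
        "condition": condition, "cell_type": cell_type, "assay": assay,
    }


def gen_invivo_cohort(config: AgingSimConfig,
                      world: AgingWorld | None = None) -> BulkDataset:
    """One sample per donor across the in-vivo age range."""
    world = world or AgingWorld(config)
    rng = _rng(config, _KEY_INVIVO)
    ages = np.linspace(config.invivo_age_min, config.invivo_age_max,
                       config.n_invivo_donors)
    donors = [f"VD{i + 1:02d}" for i in range(config.n_invivo_donors)]

    bio_dnam = ages + config.dnam_bias
    if config.dnam_residual_sd > 0:
        bio_dnam = bio_dnam + rng.normal(0, config.dnam_residual_sd, ages.size)
    bio_rna = ages.copy()
    if config.rna_residual_sd > 0:
        bio_rna = bio_rna + rng.normal(0, config.rna_residual_sd, ages.size)
    # latent biological age cannot be negative; donor scatter is truncated
    # at birth for the youngest donors
    bio_dnam = np.maximum(bio_dnam, 0.0)
    bio_rna = np.maximum(bio_rna, 0.0)

    dnam_ids = [f"{d}_dnam" for d in donors]
    rna_ids = [f"{d}_rna" for d in donors]
    betas = world.sample_betas(bio_dnam, dnam_ids, rng)
    fpkm, counts = world.sample_expression(bio_rna, rna_ids, rng)

    rows = [_sheet_row(s, d, a, 0, "in_vivo", "dnam")
            for s, d, a in zip(dnam_ids, donors, ages)]
    rows += [_sheet_row(s, d, a, 0, "in_vivo", "rna_bulk")
             for s, d, a in zip(rna_ids, donors, ages)]
    sheet = pd.DataFrame(rows)

    truth = LatentAgeTruth(
        sample_bioage_dnam=pd.Series(bio_dnam, index=dnam_ids),
        sample_bioage_rna=pd.Series(bio_rna, index=rna_ids),
        gene_slopes=world.gene_slopes,
        probe_drifts=pd.concat([world.clock_probe_drift, world.promoter_drift]),
        aging_genes_up=world.aging_genes_up,
        aging_genes_down=world.aging_genes_down,
        donor_velocity_dnam={d: 1.0 for d in donors},
        donor_velocity_rna={d: 1.0 for d in donors},
    )
    return BulkDataset(betas, counts, fpkm, sheet, truth)


def _invitro_months(config: AgingSimConfig) -> np.ndarray:
    return np.arange(config.n_timepoints) * config.timepoint_spacing


def _fmt_month(m: float) -> str:
    return f"{m:g}".replace(".", "p")


def gen_invitro_timecourse(config: AgingSimConfig,
                           world: AgingWorld | None = None) -> BulkDataset:
    """Monthly-sampled confluent-culture time course for all donors."""
    world = world or AgingWorld(config)
    rng = _rng(config, _KEY_INVITRO)
    months = _invitro_months(config)
    donors = [f"D{i + 1}" for i in range(config.n_donors)]

    dnam_ids, rna_ids, rows = [], [], []
    bio_dnam, bio_rna = [], []
    for donor, age in zip(donors, config.donor_ages):
        for m in months:
            years = m / 12.0
            sid_d = f"{donor}_m{_fmt_month(m)}_dnam"
            sid_r = f"{donor}_m{_fmt_month(m)}_rna"
            dnam_ids.append(sid_d)
            rna_ids.append(sid_r)
            bio_dnam.append(age + config.dnam_velocity * years)
            bio_rna.append(age + config.rna_velocity * years)
            rows.append(_sheet_row(sid_d, donor, age, m, "in_vitro_control", "dnam"))
            rows.append(_sheet_row(sid_r, donor, age, m, "in_vitro_control",
                                   "rna_bulk"))

    bio_dnam = np.array(bio_dnam)
    bio_rna = np.array(bio_rna)
    betas = world.sample_betas(bio_dnam, dnam_ids, rng)
    fpkm, counts = world.sample_expression(bio_rna, rna_ids, rng)

    truth = LatentAgeTruth(
        sample_bioage_dnam=pd.Series(bio_dnam, index=dnam_ids),
        sample_bioage_rna=pd.Series(bio_rna, index=rna_ids),
        gene_slopes=world.gene_slopes,
        probe_drifts=pd.concat([world.clock_probe_drift, world.promoter_drift]),
        aging_genes_up=world.aging_genes_up,
        aging_genes_down=world.aging_genes_down,
        donor_velocity_dnam={d: config.dnam_velocity for d in donors},
        donor_velocity_rna={d: config.rna_velocity for d in donors},
    )
    return BulkDataset(betas, counts, fpkm, pd.DataFrame(rows), truth)


def gen_treatment_arms(config: AgingSimConfig, base: BulkDataset,
                       world: AgingWorld | None = None) -> BulkDataset:
    """Treatment arms sharing donors (paired design) with the untreated course.

    The control arm is the subset of `base` belonging to the treated donors.
    Treated samples run from the first post-baseline timepoint (treatment is
    applied after the month-0 harvest); their latent velocity is the control
    velocity times the per-arm scale, and a configurable subset of aging genes
    receives a constant arm-specific expression offset for DE testing.
    """
    world = world or AgingWorld(config)
    rng = _rng(config, _KEY_TREAT)
    months = _invitro_months(config)
    donors_all = [f"D{i + 1}" for i in range(config.n_donors)]
    age_by_donor = dict(zip(donors_all, config.donor_ages))
    treat_donors = [donors_all[list(config.donor_ages).index(a)]
                    for a in config.treatment_donor_ages]

    ctrl_sheet = base.sheet[base.sheet["donor_id"].isin(treat_donors)].copy()
    ctrl_dnam_ids = ctrl_sheet.loc[ctrl_sheet["assay"] == "dnam", "sample_id"]
    ctrl_rna_ids = ctrl_sheet.loc[ctrl_sheet["assay"] == "rna_bulk", "sample_id"]

    betas_parts = [base.betas[list(ctrl_dnam_ids)]]
    fpkm_parts = [base.fpkm.values[list(ctrl_rna_ids)]]
    counts_parts = [base.counts.values[list(ctrl_rna_ids)]]
    sheets = [ctrl_sheet]
    bio_dnam = base.truth.sample_bioage_dnam.loc[list(ctrl_dnam_ids)]
    bio_rna = base.truth.sample_bioage_rna.loc[list(ctrl_rna_ids)]
    vel_dnam = {d: config.dnam_velocity for d in treat_donors}
    vel_rna = {d: config.rna_velocity for d in treat_donors}
    de_genes: dict[str, list] = {}

    aging_idx = np.concatenate([world.up_idx, world.down_idx])
    for arm in sorted(config.treatment_velocity_scale):
        if arm not in ARMS:
            raise ConfigError(f"unknown treatment arm {arm!r}")
        scale = config.treatment_velocity_scale[arm]
        n_de = min(config.n_de_genes, len(aging_idx))
        de_idx = np.sort(rng.choice(aging_idx, n_de, replace=False))
        de_genes[arm] = list(world.genes[de_idx])
        offset_col = np.zeros(config.n_genes)
        offset_col[de_idx] = config.de_offset_log2

        arm_dnam_ids, arm_rna_ids, arm_bio_d, arm_bio_r = [], [], [], []
        rows = []
        for donor in treat_donors:
            age = age_by_donor[donor]
            for m in months[1:]:
                years = m / 12.0
                sid_d = f"{donor}_{arm}_m{_fmt_month(m)}_dnam"
                sid_r = f"{donor}_{arm}_m{_fmt_month(m)}_rna"
                arm_dnam_ids.append(sid_d)
                arm_rna_ids.append(sid_r)
                arm_bio_d.append(age + scale["dnam"] * config.dnam_velocity * years)
                arm_bio_r.append(age + scale["rna"] * config.rna_velocity * years)
                rows.append(_sheet_row(sid_d, donor, age, m, arm, "dnam"))
                rows.append(_sheet_row(sid_r, donor, age, m, arm, "rna_bulk"))
        arm_bio_d = np.array(arm_bio_d)
        arm_bio_r = np.array(arm_bio_r)
        betas_parts.append(world.sample_betas(arm_bio_d, arm_dnam_ids, rng))
        offsets = np.tile(offset_col[:, None], (1, len(arm_rna_ids)))
        arm_fpkm, arm_counts = world.sample_expression(
            arm_bio_r, arm_rna_ids, rng, offsets=offsets)
        fpkm_parts.append(arm_fpkm.values)
        counts_parts.append(arm_counts.values)
        sheets.append(pd.DataFrame(rows))
        bio_dnam = pd.concat([bio_dnam, pd.Series(arm_bio_d, index=arm_dnam_ids)])
        bio_rna = pd.concat([bio_rna, pd.Series(arm_bio_r, index=arm_rna_ids)])
        for donor in treat_donors:
            vel_dnam[f"{donor}:{arm}"] = scale["dnam"] * config.dnam_velocity
            vel_rna[f"{donor}:{arm}"] = scale["rna"] * config.rna_velocity

    truth = LatentAgeTruth(
        sample_bioage_dnam=bio_dnam,
        sample_bioage_rna=bio_rna,
        gene_slopes=world.gene_slopes,
        probe_drifts=pd.concat([world.clock_probe_drift, world.promoter_drift]),
        aging_genes_up=world.aging_genes_up,
        aging_genes_down=world.aging_genes_down,
        donor_velocity_dnam=vel_dnam,
        donor_velocity_rna=vel_rna,
        de_genes=de_genes,
    )
    return BulkDataset(
        betas=pd.concat(betas_parts, axis=1),
        counts=ExpressionMatrix(pd.concat(counts_parts, axis=1), "counts"),
        fpkm=ExpressionMatrix(pd.concat(fpkm_parts, axis=1), "fpkm"),
        sheet=pd.concat(sheets, ignore_index=True),
        truth=truth,
    )


def gen_single_cell(config: AgingSimConfig,
                    world: AgingWorld | None = None) -> SingleCellDataset:
    """Single-cell counts for the profiled donors at months 0 and N.

    Cell latent ages are normal around the sample mean biological age with a
    timepoint-specific SD.  Genes belonging to down-regulated aging pathways
    additionally see a per-cell, per-program retention factor applied to the
    cell's age displacement, so late-timepoint heterogeneity is dominated by
    variable loss of down-regulated programs.
    """
    world = world or AgingWorld(config)
    if config.sc_n_cells < config.sc_min_cells_check:
        raise ConfigError(
            f"sc_n_cells: need >= {config.sc_min_cells_check} cells per sample, "
            f"got {config.sc_n_cells}")
    rng = _rng(config, _KEY_SC)
    donors_all = [f"D{i + 1}" for i in range(config.n_donors)]

    # map down-regulated genes to their program (first down-pathway membership)
    down_paths = [p for p, d in world.pathway_directions.items() if d == "down"]
    program_of_gene = np.full(config.n_genes, -1)
    gene_pos = {g: i for i, g in enumerate(world.genes)}
    for k, path in enumerate(down_paths):
        for g in world.gene_sets[path]:
            gi = gene_pos[g]
            if world.gene_slopes.iloc[gi] < 0 and program_of_gene[gi] < 0:
                program_of_gene[gi] = k
    n_programs = len(down_paths)

    blocks, cell_rows, bio_cells, cell_ids_all = [], [], [], []
    for donor_age in config.sc_donor_ages:
        donor = donors_all[list(config.donor_ages).index(donor_age)]
        for m, sd_age, sd_ret in (
            (0, config.sc_age_sd_month0, config.sc_retention_sd_month0),
            (config.sc_month, config.sc_age_sd_monthN, config.sc_retention_sd_monthN),
        ):
            mean_bio = donor_age + config.rna_velocity * m / 12.0
            ages = rng.normal(mean_bio, sd_age, config.sc_n_cells)
            cell_ids = [f"{donor}_m{m}_c{j + 1:04d}"
                        for j in range(config.sc_n_cells)]

            # effective age per gene x cell with program retention on down genes
            eff = np.tile(ages, (config.n_genes, 1))
            if n_programs and sd_ret > 0:
                kappa = np.clip(
                    rng.normal(1.0, sd_ret, (n_programs, config.sc_n_cells)),
                    0.0, None)
                has_prog = program_of_gene >= 0
                eff[has_prog, :] = donor_age + kappa[program_of_gene[has_prog], :] * (
                    ages[None, :] - donor_age)

            y = (world.gene_baseline.to_numpy()[:, None]
                 + world.gene_slopes.to_numpy()[:, None] * (eff - REF_AGE))
            fpkm = np.maximum(np.exp2(y) - 1.0, 0.0)
            colsum = fpkm.sum(axis=0)
            frac = np.divide(fpkm, colsum[None, :], out=np.zeros_like(fpkm),
                             where=colsum[None, :] > 0)
            if config.sc_depth_mean > 0:
                sigma = 0.3
                depth = rng.lognormal(
                    np.log(config.sc_depth_mean) - sigma ** 2 / 2.0, sigma,
                    config.sc_n_cells)
            else:
                depth = np.zeros(config.sc_n_cells)
            mu = frac * depth[None, :]
            counts = _nb_draw(rng, mu, config.nb_dispersion)
            blocks.append(scipy.sparse.csr_matrix(counts))
            cell_ids_all.extend(cell_ids)
            bio_cells.extend(ages)
            cell_rows += [
                {"cell_id": cid, "donor_id": donor, "timepoint": m,
                 "chronological_age_at_baseline": donor_age}
                for cid in cell_ids
            ]

    matrix = scipy.sparse.hstack(blocks, format="csr")
    counts = SparseCountMatrix(matrix, world.genes, pd.Index(cell_ids_all))
    cell_sheet = pd.DataFrame(cell_rows)
    truth = LatentAgeTruth(
        sample_bioage_dnam=pd.Series(dtype=float),
        sample_bioage_rna=pd.Series(dtype=float),
        gene_slopes=world.gene_slopes,
        probe_drifts=pd.concat([world.clock_probe_drift, world.promoter_drift]),
        aging_genes_up=world.aging_genes_up,
        aging_genes_down=world.aging_genes_down,
        donor_velocity_dnam={},
        donor_velocity_rna={},
        cell_bioage=pd.Series(bio_cells, index=cell_ids_all),
    )
    return SingleCellDataset(counts, cell_sheet, truth)


# ---------------------------------------------------------------------------
# full-study convenience writer (CLI `agevelo simulate`)
# ---------------------------------------------------------------------------

def simulate_study(config: AgingSimConfig, outdir) -> dict:
    """Generate every dataset of the study design and write it under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = AgingWorld(config)

    def write_bulk(ds: BulkDataset, prefix: str):
        write_beta_matrix(ds.betas, outdir / f"{prefix}_betas.tsv")
        write_expression_matrix(ds.counts, outdir / f"{prefix}_counts.tsv")
        write_expression_matrix(ds.fpkm, outdir / f"{prefix}_fpkm.tsv")
        write_sample_sheet(ds.sheet, outdir / f"{prefix}_sheet.csv")
        ds.truth.write(outdir / f"{prefix}_truth.json")

    invivo = gen_invivo_cohort(config, world)
    invitro = gen_invitro_timecourse(config, world)
    treated = gen_treatment_arms(config, invitro, world)
    sc = gen_single_cell(config, world)

    write_bulk(invivo, "invivo")
    write_bulk(invitro, "invitro")
    write_bulk(treated, "treatment")
    write_mtx_triplet(sc.counts, outdir / "sc")
    sc.cell_sheet.to_csv(outdir / "sc_cell_sheet.csv", index=False)
    sc.truth.write(outdir / "sc_truth.json")

    save_clock(world.dnam_clock, outdir / "clock_dnam.csv")
    save_clock(world.rna_clock, outdir / "clock_rna.csv")
    write_probe_annotation(world.probe_annotation, outdir / "probe_annotation.tsv")
    write_gmt(world.gene_sets, outdir / "pathways.gmt",
              descriptions=world.pathway_directions)
    config.to_yaml(outdir / "config.yaml")
    return {"outdir": str(outdir),
            "n_invivo_samples": invivo.sheet.shape[0],
            "n_invitro_samples": invitro.sheet.shape[0],
            "n_treatment_samples": treated.sheet.shape[0],
            "n_cells": len(sc.counts.cell_ids)}
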