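"""Simulation configuration.

:class:`AgingSimConfig` parameterizes the synthetic study design: an in-vivo
fibroblast cohort (one sample per donor, ages spanning childhood to the tenth
decade), an in-vitro confluent-culture time course with monthly sampling, drug
treatment arms sharing donors with the untreated course, and single-cell
snapshots of two donors at the start and near the end of culture.

Velocities are dimensionless: biological years gained per chronological year
(1.0 means biological age tracks calendar time).  The defaults mirror the
study conditions the package is built to analyse: 22 in-vivo donors aged 0-92,
four cultured donors aged 53/55/67/68 followed for six months at monthly
spacing, a DNA-methylation aging velocity of 8.5x and a transcriptomic
velocity of 48.3x in culture, and treatment arms for three donors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigError

#: Recognised treatment arm names.
ARMS = ("metformin", "rapamycin")

#: Assay channels with independent latent aging velocities.
ASSAYS = ("dnam", "rna")


def _as_assay_scale(value, arm: str) -> dict:
    """Normalize a per-arm velocity scale (scalar or per-assay mapping)."""
    if isinstance(value, Mapping):
        out = {}
        for assay in ASSAYS:
            if assay not in value:
                raise ConfigError(
                    f"treatment_velocity_scale[{arm!r}] missing assay {assay!r}"
                )
            out[assay] = float(value[assay])
        return out
    return {assay: float(value) for assay in ASSAYS}


@dataclass
class AgingSimConfig:
    # ---- in-vitro cohort design -------------------------------------------------
    n_donors: int = 4
    donor_ages: tuple = (53.0, 55.0, 67.0, 68.0)
    n_timepoints: int = 7          # months 0..6 inclusive at unit spacing
    timepoint_spacing: float = 1.0  # months between consecutive samplings
    dnam_velocity: float = 8.5      # biological years per chronological year
    rna_velocity: float = 48.3

    # ---- in-vivo cohort design --------------------------------------------------
    n_invivo_donors: int = 22
    invivo_age_min: float = 0.0
    invivo_age_max: float = 92.0
    dnam_bias: float = 0.0          # systematic clock offset, years
    dnam_residual_sd: float = 0.0   # donor-level scatter of DNAm bioage, years
    rna_residual_sd: float = 0.0

    # ---- feature/gene model -----------------------------------------------------
    n_clock_features: int = 100
    n_genes: int = 2000
    frac_aging_genes_up: float = 0.05
    frac_aging_genes_down: float = 0.10
    n_rna_clock_genes: int = 150
    noise_sd_beta: float = 0.005    # technical noise on beta values
    noise_sd_logexpr: float = 0.25  # residual sd of log2(FPKM+1)
    nb_dispersion: float = 0.1      # negative-binomial dispersion for counts
    bulk_library_size: float = 2.0e7

    # ---- pathway structure ------------------------------------------------------
    n_pathways_up: int = 15
    n_pathways_down: int = 20
    n_pathways_null: int = 5
    pathway_size_min: int = 10
    pathway_size_max: int = 30
    promoter_probes_per_gene: int = 3
    meth_coupling: float = 0.2      # logit-beta drift per unit expression slope

    # ---- treatment arms ---------------------------------------------------------
    treatment_donor_ages: tuple = (53.0, 67.0, 68.0)
    treatment_velocity_scale: dict = field(
        default_factory=lambda: {
            "metformin": {"dnam": 0.21, "rna": 0.46},
            "rapamycin": {"dnam": 0.75, "rna": 0.75},
        }
    )
    n_de_genes: int = 50
    de_offset_log2: float = 1.0

    # ---- single cell ------------------------------------------------------------
    sc_n_cells: int = 2000
    sc_month: int = 5
    sc_donor_ages: tuple = (67.0, 68.0)
    sc_age_sd_month0: float = 3.0   # cell-to-cell latent age SD, years
    sc_age_sd_monthN: float = 6.0
    sc_depth_mean: float = 8000.0   # mean total counts per cell
    sc_retention_sd_month0: float = 0.1  # per-cell program-retention spread
    sc_retention_sd_monthN: float = 0.5
    sc_min_cells_check: int = 100

    seed: int = 0

    # ------------------------------------------------------------------------
    def __post_init__(self):
        self.donor_ages = tuple(float(a) for a in self.donor_ages)
        self.treatment_donor_ages = tuple(float(a) for a in self.treatment_donor_ages)
        self.sc_donor_ages = tuple(float(a) for a in self.sc_donor_ages)
        self.treatment_velocity_scale = {
            arm: _as_assay_scale(v, arm)
            for arm, v in dict(self.treatment_velocity_scale).items()
        }
        self.validate()

    def validate(self) -> None:
        def require(cond: bool, name: str, why: str):
            if not cond:
                raise ConfigError(f"{name}: {why}")

        require(self.n_donors >= 1, "n_donors", "must be >= 1")
        require(len(self.donor_ages) == self.n_donors, "donor_ages",
                f"length {len(self.donor_ages)} != n_donors {self.n_donors}")
        require(all(a >= 0 for a in self.donor_ages), "donor_ages", "ages must be >= 0")
        require(self.n_timepoints >= 2, "n_timepoints", "must be >= 2")
        require(self.timepoint_spacing > 0, "timepoint_spacing", "must be > 0")
        require(self.dnam_velocity > 0, "dnam_velocity", "must be > 0")
        require(self.rna_velocity > 0, "rna_velocity", "must be > 0")
        require(self.n_invivo_donors >= 2, "n_invivo_donors", "must be >= 2")
        require(self.invivo_age_max > self.invivo_age_min >= 0,
                "invivo_age_min/max", "need 0 <= min < max")
        for frac_name in ("frac_aging_genes_up", "frac_aging_genes_down"):
            frac = getattr(self, frac_name)
            require(0 <= frac <= 1, frac_name, "must be in [0, 1]")
        require(self.frac_aging_genes_up + self.frac_aging_genes_down <= 1,
                "frac_aging_genes_up+down", "fractions must sum to <= 1")
        require(self.n_clock_features >= 2, "n_clock_features", "must be >= 2")
        require(self.n_genes >= 10, "n_genes", "must be >= 10")
        require(self.noise_sd_beta >= 0, "noise_sd_beta", "must be >= 0")
        require(self.noise_sd_logexpr >= 0, "noise_sd_logexpr", "must be >= 0")
        require(self.nb_dispersion > 0, "nb_dispersion", "must be > 0")
        require(self.pathway_size_min >= 2, "pathway_size_min", "must be >= 2")
        require(self.pathway_size_max >= self.pathway_size_min,
                "pathway_size_max", "must be >= pathway_size_min")
        for arm, scales in self.treatment_velocity_scale.items():
            require(arm in ARMS, "treatment_velocity_scale",
                    f"unknown arm {arm!r}; known arms: {ARMS}")
            for assay, s in scales.items():
                require(s >= 0, "treatment_velocity_scale",
                        f"{arm}/{assay} scale must be >= 0, got {s}")
        require(set(self.treatment_donor_ages) <= set(self.donor_ages),
                "treatment_donor_ages", "must be a subset of donor_ages")
        require(set(self.sc_donor_ages) <= set(self.donor_ages),
                "sc_donor_ages", "must be a subset of donor_ages")
        require(self.sc_n_cells >= 1, "sc_n_cells", "must be >= 1")
        require(self.sc_age_sd_month0 >= 0, "sc_age_sd_month0", "must be >= 0")
        require(self.sc_age_sd_monthN >= 0, "sc_age_sd_monthN", "must be >= 0")
        require(self.sc_depth_mean >= 0, "sc_depth_mean", "must be >= 0")
        require(self.de_offset_log2 >= 0, "de_offset_log2", "must be >= 0")
        require(0 <= self.n_de_genes, "n_de_genes", "must be >= 0")

    # ------------------------------------------------------------------------
    def replace(self, **kwargs) -> "AgingSimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AgingSimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "AgingSimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
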