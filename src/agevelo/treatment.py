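"""Treatment effects on the aging process.

Treated and untreated cultures of the same donors form a paired design, so:

* velocity comparison is a paired two-sided t-test on per-donor slope
  differences;
* differential expression against the untreated aging baseline is a per-gene
  paired test on log2(FPKM+1) across donors at a fixed timepoint, BH-adjusted
  (an optional pooled-variance moderated mode trades exact per-gene degrees
  of freedom for power at very small donor numbers);
* pathway-level effects are the per-pathway slope differences, classified as
  slowed or accelerated relative to the pathway's aging direction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import AgeVeloError, DomainError
from .io import ExpressionMatrix
from .signatures import pathway_enrichment


# ---------------------------------------------------------------------------
# velocity comparison
# ---------------------------------------------------------------------------

def compare_velocities(fits_control: pd.DataFrame,
                       fits_treated: pd.DataFrame) -> dict:
    """Paired t-test of per-donor aging velocities, control vs treated."""
    ctrl = fits_control.set_index("donor_id")["slope"]
    trt = fits_treated.set_index("donor_id")["slope"]
    common = ctrl.index.intersection(trt.index)
    if len(common) != len(ctrl) or len(common) != len(trt):
        raise AgeVeloError(
            f"compare_velocities: donors not matched between arms "
            f"(control={sorted(ctrl.index)}, treated={sorted(trt.index)})")
    if len(common) < 2:
        raise DomainError("compare_velocities: need >= 2 matched donors")
    diffs = (trt.loc[common] - ctrl.loc[common]).to_numpy(dtype=float)
    if np.allclose(diffs, 0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = scipy.stats.ttest_rel(trt.loc[common], ctrl.loc[common])
    return {
        "donors": list(common),
        "mean_velocity_control": float(ctrl.loc[common].mean()),
        "mean_velocity_treated": float(trt.loc[common].mean()),
        "per_donor": pd.DataFrame({"control": ctrl.loc[common],
                                   "treated": trt.loc[common]}),
        "t": float(t_stat),
        "p_value": float(p),
        "n_pairs": len(common),
    }


# ---------------------------------------------------------------------------
# differential expression vs the untreated baseline
# ---------------------------------------------------------------------------

def treatment_de(expr: ExpressionMatrix, sheet: pd.DataFrame, arm: str,
                 timepoint: float, alpha: float = 0.05,
                 method: str = "paired_t") -> pd.DataFrame:
    """Per-gene paired test of treated vs control log2(FPKM+1) at a timepoint.

    `method="paired_t"` is the exact per-gene paired t on n-1 df;
    `method="moderated"` replaces each gene's variance with the genome-wide
    mean paired-difference variance (z-test), which restores power when only
    a handful of donor pairs exist.
    """
    if method not in ("paired_t", "moderated"):
        raise AgeVeloError(f"unknown DE method {method!r}")
    sub = sheet[(sheet["assay"] == "rna_bulk")
                & (np.isclose(sheet["time_in_culture"].astype(float), timepoint))]
    ctrl = sub[sub["condition"] == "in_vitro_control"].set_index("donor_id")
    trt = sub[sub["condition"] == arm].set_index("donor_id")
    donors = ctrl.index.intersection(trt.index)
    if len(donors) < 2:
        raise DomainError(
            f"treatment_de: need >= 2 donor pairs at month {timepoint}, "
            f"got {len(donors)}")
    logexpr = expr.log2_plus1()
    c = logexpr[[ctrl.loc[d, "sample_id"] for d in donors]].to_numpy()
    t = logexpr[[trt.loc[d, "sample_id"] for d in donors]].to_numpy()
    diffs = t - c
    n = len(donors)
    mean_diff = diffs.mean(axis=1)
    sd_diff = diffs.std(axis=1, ddof=1)

    if method == "paired_t":
        with np.errstate(invalid="ignore", divide="ignore"):
            t_stat = mean_diff / (sd_diff / np.sqrt(n))
        p = 2.0 * scipy.stats.t.sf(np.abs(t_stat), df=n - 1)
        p = np.where(sd_diff == 0, np.where(mean_diff == 0, 1.0, 0.0), p)
        t_stat = np.where(sd_diff == 0, np.where(mean_diff == 0, 0.0, np.inf),
                          t_stat)
    else:
        pooled_sd = float(np.sqrt(np.mean(sd_diff ** 2)))
        if pooled_sd == 0:
            t_stat = np.where(mean_diff == 0, 0.0, np.inf)
            p = np.where(mean_diff == 0, 1.0, 0.0)
        else:
            t_stat = mean_diff / (pooled_sd / np.sqrt(n))
            p = 2.0 * scipy.stats.norm.sf(np.abs(t_stat))

    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": expr.genes,
        "log2_fold_change": mean_diff,
        "t": t_stat,
        "p_value": p,
        "p_adj": p_adj,
        "significant": p_adj < alpha,
    })


# ---------------------------------------------------------------------------
# pathway-level treatment effects
# ---------------------------------------------------------------------------

def treatment_pathway_effect(trajectories_control: dict,
                             trajectories_treated: dict,
                             directions: dict,
                             tol: float = 0.0) -> pd.DataFrame:
    """Per-pathway slope delta and slowed/accelerated classification.

    A pathway is *slowed* when treatment moves its slope against the aging
    direction: for an up-regulated aging pathway a smaller treated slope, for
    a down-regulated one a less negative treated slope.
    """
    rows = []
    for name, ctrl in trajectories_control.items():
        if name not in trajectories_treated:
            warnings.warn(f"pathway {name!r} missing in treated arm; skipped",
                          stacklevel=2)
            continue
        direction = directions.get(name, "none")
        delta = trajectories_treated[name]["slope"] - ctrl["slope"]
        aging_sign = {"up": 1.0, "down": -1.0}.get(direction, 0.0)
        counter = -aging_sign * delta  # positive = moved against aging
        if counter > tol:
            label = "slowed"
        elif counter < -tol:
            label = "accelerated"
        else:
            label = "unchanged"
        rows.append({
            "pathway": name, "direction": direction,
            "slope_control": ctrl["slope"],
            "slope_treated": trajectories_treated[name]["slope"],
            "slope_delta": delta, "classification": label,
        })
    return pd.DataFrame(rows)


def pathway_effect_summary(effects: pd.DataFrame) -> dict:
    """Counts of slowed/accelerated pathways per direction family."""
    out = {}
    for direction in ("up", "down"):
        sub = effects[effects["direction"] == direction]
        out[direction] = {
            "slowed": int((sub["classification"] == "slowed").sum()),
            "accelerated": int((sub["classification"] == "accelerated").sum()),
            "unchanged": int((sub["classification"] == "unchanged").sum()),
            "total": len(sub),
        }
    return out


# ---------------------------------------------------------------------------
# overlap of DE genes with aging pathways
# ---------------------------------------------------------------------------

def de_pathway_overlap(de: pd.DataFrame, aging_overlap: pd.DataFrame,
                       sets: dict, universe: list, alpha: float = 0.05,
                       related_frac: float = 0.2) -> pd.DataFrame:
    """Classify pathways enriched in treatment-DE genes against aging pathways.

    Tiers: *exact_overlap* — the enriched pathway is itself a significant
    aging pathway; *related* — it shares at least `related_frac` of its genes
    with a significant aging pathway without being one; *treatment_specific*
    otherwise.
    """
    de_genes = sorted(de.loc[de["significant"], "gene"])
    if not de_genes:
        return pd.DataFrame(columns=[
            "pathway", "n_hits", "enrichment_p", "enrichment_p_adj", "tier"])
    enr = pathway_enrichment(de_genes, sets, universe, context="treatment")
    enriched = enr[enr["enrichment_p_adj"] < alpha].copy()

    aging_sig = set(
        aging_overlap.loc[
            aging_overlap["significant_invitro"]
            | aging_overlap["significant_invivo"], "pathway"])
    aging_genes = {g for p in aging_sig for g in sets.get(p, [])}

    tiers = []
    for _, row in enriched.iterrows():
        name = row["pathway"]
        if name in aging_sig:
            tiers.append("exact_overlap")
        else:
            members = set(sets[name])
            share = len(members & aging_genes) / len(members) if members else 0
            tiers.append("related" if share >= related_frac
                         else "treatment_specific")
    enriched["tier"] = tiers
    return enriched[["pathway", "n_hits", "enrichment_p",
                     "enrichment_p_adj", "tier"]]
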