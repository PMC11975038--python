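"""Aging-gene screens and pathway-level statistics.

The screen correlates each gene's log2(FPKM+1) with the aging axis of a
context — donor age for the in-vivo cohort, time in culture for the in-vitro
course — and flags significant genes by direction.  Pathway enrichment of the
up-/down-regulated hit lists uses the one-sided hypergeometric test with
Benjamini-Hochberg adjustment within each (context, direction) family.

For pathways enriched in both contexts, the in-vitro *contribution* is the
input-size-normalized share of hits:

    contribution = 100 * (h_vitro/N_vitro) / (h_vitro/N_vitro + h_vivo/N_vivo)

so 50% means equal hit rates, 100% means exclusively in-vitro; pathways with
a contribution in [30, 70] are classified *overlapping* (concordant in-vivo /
in-vitro aging pathways).  A pathway's aging trajectory is the per-sample
mean of member-gene z-scores regressed on the context's time axis; its slope
is the pathway aging velocity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import AgeVeloError, DomainError
from .io import PROMOTER_REGIONS, ExpressionMatrix

CONTEXTS = ("in_vivo", "in_vitro")


# ---------------------------------------------------------------------------
# context helpers
# ---------------------------------------------------------------------------

def context_samples(sheet: pd.DataFrame, context: str,
                    assay: str = "rna_bulk") -> pd.DataFrame:
    """Sheet rows of one screening context, with its time axis in years."""
    if context not in CONTEXTS:
        raise AgeVeloError(f"unknown context {context!r}")
    if context == "in_vivo":
        sub = sheet[(sheet["condition"] == "in_vivo") & (sheet["assay"] == assay)]
        time = sub["chronological_age_at_baseline"].astype(float)
    else:
        sub = sheet[(sheet["condition"] == "in_vitro_control")
                    & (sheet["assay"] == assay)]
        time = sub["time_in_culture"].astype(float) / 12.0
    sub = sub.copy()
    sub["time_axis_years"] = time.to_numpy()
    return sub


def _pearson_rows(values: np.ndarray, x: np.ndarray):
    """Row-wise Pearson r and two-sided p against a shared covariate."""
    n = x.size
    xc = x - x.mean()
    yc = values - values.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / (sx * sy)
    r = np.where(sy == 0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 0.0))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.isinf(t), 0.0, p))
    return r, p


# ---------------------------------------------------------------------------
# aging-gene screen
# ---------------------------------------------------------------------------

def correlate_aging_genes(expr: ExpressionMatrix, sheet: pd.DataFrame,
                          context: str, p_threshold: float = 0.05
                          ) -> pd.DataFrame:
    """Per-gene Pearson correlation to the context's aging axis.

    Zero-variance genes get a missing r and are excluded from the
    significant counts.  Returns one row per gene with pearson_r, p_value,
    direction ('up'/'down'), and passes_threshold.
    """
    sub = context_samples(sheet, context)
    samples = [s for s in sub["sample_id"] if s in expr.samples]
    if len(samples) < 4:
        raise DomainError(
            f"context {context!r}: need >= 4 samples, got {len(samples)}")
    x = sub.set_index("sample_id").loc[samples, "time_axis_years"].to_numpy(float)
    if np.ptp(x) == 0:
        raise DomainError(f"context {context!r}: zero variance on the time axis")
    logexpr = expr.log2_plus1()[samples].to_numpy()
    r, p = _pearson_rows(logexpr, x)
    direction = np.where(np.isnan(r), None,
                         np.where(r >= 0, "up", "down"))
    passes = (~np.isnan(r)) & (p < p_threshold)
    return pd.DataFrame({
        "gene": expr.genes,
        "context": context,
        "pearson_r": r,
        "p_value": p,
        "direction": direction,
        "passes_threshold": passes,
    })


def aging_gene_counts(table: pd.DataFrame) -> dict:
    """Partition of the screen: up/down significant, excluded, non-significant."""
    excluded = int(table["pearson_r"].isna().sum())
    sig = table[table["passes_threshold"].fillna(False)]
    up = int((sig["direction"] == "up").sum())
    down = int((sig["direction"] == "down").sum())
    return {
        "up": up, "down": down, "excluded": excluded,
        "non_significant": len(table) - up - down - excluded,
        "total": len(table),
    }


def hit_list(table: pd.DataFrame, direction: str) -> list:
    sig = table[table["passes_threshold"].fillna(False)]
    return sorted(sig.loc[sig["direction"] == direction, "gene"])


# ---------------------------------------------------------------------------
# pathway enrichment / contribution
# ---------------------------------------------------------------------------

def pathway_enrichment(hits: list, sets: dict, universe: list,
                       context: str = "", direction: str = "") -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a hit list in each gene set.

    p = P(X >= k) with X ~ Hypergeom(M=|universe|, K=|set in universe|,
    n=|hits|); BH-adjusted across the pathways of this (context, direction)
    family.
    """
    universe = set(universe)
    if not universe:
        raise AgeVeloError("pathway_enrichment: empty universe")
    hits = set(hits) & universe
    rows = []
    for name, genes in sets.items():
        in_universe = set(genes) & universe
        k = len(in_universe & hits)
        p = scipy.stats.hypergeom.sf(
            k - 1, len(universe), len(in_universe), len(hits))
        rows.append({
            "pathway": name, "context": context, "direction": direction,
            "n_hits": k, "set_size": len(in_universe),
            "n_hit_list": len(hits), "enrichment_p": float(p),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["enrichment_p_adj"] = multipletests(
            out["enrichment_p"], method="fdr_bh")[1]
    return out


def pathway_contribution(n_hits_invitro: int, list_size_invitro: int,
                         n_hits_invivo: int, list_size_invivo: int) -> dict:
    """Input-size-adjusted in-vitro hit share and overlap classification."""
    if list_size_invitro <= 0 or list_size_invivo <= 0:
        raise DomainError("pathway_contribution: hit-list sizes must be > 0")
    if n_hits_invitro == 0 and n_hits_invivo == 0:
        raise DomainError("pathway_contribution: both hit counts are zero")
    rate_vitro = n_hits_invitro / list_size_invitro
    rate_vivo = n_hits_invivo / list_size_invivo
    contribution = 100.0 * rate_vitro / (rate_vitro + rate_vivo)
    if 30.0 <= contribution <= 70.0:
        classification = "overlapping"
    elif contribution > 70.0:
        classification = "invitro_specific"
    else:
        classification = "invivo_specific"
    return {"contribution_invitro": contribution, "classification": classification}


def pathway_overlap_table(aging_invitro: pd.DataFrame, aging_invivo: pd.DataFrame,
                          sets: dict, universe: list, alpha: float = 0.05
                          ) -> pd.DataFrame:
    """Per-pathway x direction overlap table combining both screening contexts."""
    rows = []
    for direction in ("up", "down"):
        hits_vitro = hit_list(aging_invitro, direction)
        hits_vivo = hit_list(aging_invivo, direction)
        enr_vitro = pathway_enrichment(
            hits_vitro, sets, universe, "in_vitro", direction
        ).set_index("pathway")
        enr_vivo = pathway_enrichment(
            hits_vivo, sets, universe, "in_vivo", direction
        ).set_index("pathway")
        for name in sets:
            ev, ei = enr_vitro.loc[name], enr_vivo.loc[name]
            h_vitro, h_vivo = int(ev["n_hits"]), int(ei["n_hits"])
            if h_vitro == 0 and h_vivo == 0:
                warnings.warn(
                    f"pathway {name!r} ({direction}): no hits in either "
                    "context; dropped", stacklevel=2)
                continue
            contrib = pathway_contribution(
                h_vitro, max(len(hits_vitro), 1),
                h_vivo, max(len(hits_vivo), 1))
            rows.append({
                "pathway": name, "direction": direction,
                "n_hits_invitro": h_vitro, "n_hits_invivo": h_vivo,
                "list_size_invitro": len(hits_vitro),
                "list_size_invivo": len(hits_vivo),
                "enrichment_p_invitro": ev["enrichment_p"],
                "enrichment_p_adj_invitro": ev["enrichment_p_adj"],
                "enrichment_p_invivo": ei["enrichment_p"],
                "enrichment_p_adj_invivo": ei["enrichment_p_adj"],
                "significant_invitro": ev["enrichment_p_adj"] < alpha,
                "significant_invivo": ei["enrichment_p_adj"] < alpha,
                **contrib,
            })
    return pd.DataFrame(rows)


def recapitulation_summary(up_recovered: int, up_total: int,
                           down_recovered: int, down_total: int) -> dict:
    """Per-direction and pooled percentages of in-vivo pathways found in-vitro."""
    for rec, tot, name in ((up_recovered, up_total, "up"),
                           (down_recovered, down_total, "down")):
        if rec > tot:
            raise DomainError(f"{name}: recovered {rec} exceeds total {tot}")
    pooled_total = up_total + down_total
    return {
        "up_pct": 100.0 * up_recovered / up_total if up_total else float("nan"),
        "down_pct": 100.0 * down_recovered / down_total if down_total else float("nan"),
        "pooled_pct": (100.0 * (up_recovered + down_recovered) / pooled_total
                       if pooled_total else float("nan")),
        "up": (up_recovered, up_total),
        "down": (down_recovered, down_total),
    }


def recapitulation_from_overlap(overlap: pd.DataFrame) -> dict:
    """Recapitulation percentages computed from a pathway overlap table."""
    counts = {}
    for direction in ("up", "down"):
        sub = overlap[overlap["direction"] == direction]
        vivo_sig = sub[sub["significant_invivo"]]
        counts[direction] = (int(vivo_sig["significant_invitro"].sum()),
                             len(vivo_sig))
    return recapitulation_summary(*counts["up"], *counts["down"])


# ---------------------------------------------------------------------------
# pathway trajectories
# ---------------------------------------------------------------------------

def pathway_trajectory(expr: ExpressionMatrix, sheet: pd.DataFrame,
                       gene_set: list, context: str,
                       set_name: str = "") -> dict:
    """Per-sample mean z of member genes and its slope on the time axis.

    Each member gene present in the matrix is z-scored across the context's
    samples (mean 0, SD 1) before averaging, so highly expressed genes do not
    dominate; the slope of the per-sample mean against the time axis (years)
    is the pathway aging velocity.
    """
    sub = context_samples(sheet, context)
    samples = [s for s in sub["sample_id"] if s in expr.samples]
    genes = [g for g in dict.fromkeys(gene_set) if g in expr.genes]
    if len(genes) < 2:
        raise DomainError(
            f"pathway {set_name or '<unnamed>'}: fewer than 2 member genes "
            f"present in the expression matrix")
    x = sub.set_index("sample_id").loc[samples, "time_axis_years"].to_numpy(float)
    vals = expr.log2_plus1().loc[genes, samples].to_numpy()
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    mean_z = z.mean(axis=0) if keep.any() else np.zeros(len(samples))
    if np.ptp(x) == 0:
        raise DomainError(f"pathway {set_name!r}: zero time variance")
    if keep.any():
        fit = scipy.stats.linregress(x, mean_z)
        slope, p = fit.slope, fit.pvalue
    else:  # all member genes constant
        slope, p = 0.0, 1.0
    return {
        "pathway": set_name, "context": context,
        "samples": list(samples), "mean_z": mean_z,
        "slope": float(slope), "p_value": float(p),
        "n_genes": int(keep.sum()),
    }


def acceleration_ratio(traj_invitro: dict, traj_invivo: dict) -> float:
    """How many-fold faster the pathway ages in culture than in the body."""
    if traj_invivo["slope"] == 0:
        return float("inf") if traj_invitro["slope"] != 0 else float("nan")
    return traj_invitro["slope"] / traj_invivo["slope"]


# ---------------------------------------------------------------------------
# promoter methylation and coupling
# ---------------------------------------------------------------------------

def promoter_methylation(betas: pd.DataFrame, annot: pd.DataFrame,
                         genes: list) -> pd.DataFrame:
    """Per-gene mean beta over promoter probes (TSS200/TSS1500/5'UTR/1st exon).

    Genes with no annotated promoter probe in the matrix get NaN rows.
    """
    promoter = annot[annot["region"].isin(PROMOTER_REGIONS)]
    out = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene"),
                       columns=betas.columns)
    for gene, probes in promoter.groupby("gene")["probe_id"]:
        if gene not in out.index:
            continue
        present = [p for p in probes if p in betas.index]
        if present:
            out.loc[gene] = betas.loc[present].mean(axis=0).to_numpy()
    return out


def rowwise_slopes(values: pd.DataFrame, sheet: pd.DataFrame, context: str,
                   assay: str = "rna_bulk") -> pd.Series:
    """OLS slope (per year) of each row against the context's time axis."""
    sub = context_samples(sheet, context, assay=assay)
    samples = [s for s in sub["sample_id"] if s in values.columns]
    if len(samples) < 2:
        raise DomainError(f"context {context!r}: need >= 2 samples for slopes")
    x = sub.set_index("sample_id").loc[samples, "time_axis_years"].to_numpy(float)
    y = values[samples].to_numpy(dtype=float)
    xc = x - x.mean()
    denom = (xc ** 2).sum()
    if denom == 0:
        raise DomainError(f"context {context!r}: zero time variance")
    yc = y - np.nanmean(y, axis=1, keepdims=True)
    slopes = np.nansum(yc * xc[None, :], axis=1) / denom
    slopes = np.where(np.isnan(y).all(axis=1), np.nan, slopes)
    return pd.Series(slopes, index=values.index)


def methylation_expression_coupling(expr_slopes: pd.Series,
                                    meth_slopes: pd.Series) -> dict:
    """Pearson correlation between expression and promoter-methylation slopes."""
    joined = pd.concat({"expr": expr_slopes, "meth": meth_slopes},
                       axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise DomainError(
            f"coupling: need >= 3 matched genes, got {len(joined)}")
    r, p = scipy.stats.pearsonr(joined["expr"], joined["meth"])
    return {"r": float(r), "p_value": float(p), "n_genes": len(joined)}
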