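"""Per-cell aging scores and heterogeneity statistics.

The longitudinal transcriptomic aging (LTA) score of a cell is the signed
mean of per-gene z-scores over the genes of the concordant (in-vivo and
in-vitro) aging pathways: mean z over up-regulated aging genes minus mean z
over down-regulated aging genes, with z computed per gene across all cells
of the merged dataset.  Higher scores mean transcriptionally older cells.
The same construction applied to the positive-/negative-weight genes of a
transcriptomic clock gives the clock-gene score.

Aging heterogeneity within a population is quantified by the score SD and by
Levene's test for homogeneity of variance across groups — by default the
Brown-Forsythe variant (absolute deviations from the group *median*), with
the classic mean-centered variant selectable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.stats

from .clocks import ClockModel
from .errors import AgeVeloError, DomainError
from .io import ExpressionMatrix, SparseCountMatrix

TARGET_SUM = 1.0e4
QUARTILE_LABELS = ("Q1_youngest", "Q2", "Q3", "Q4_oldest")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_cells(counts: SparseCountMatrix, min_genes: int = 200
                    ) -> tuple[pd.DataFrame, dict]:
    """Library-size normalize to 10,000 counts per cell, then log1p.

    Cells detecting fewer than `min_genes` genes (and all-zero cells) are
    dropped; the report records how many.  Returns a dense genes x cells
    DataFrame of log-normalized expression plus the filtering report.
    """
    mat = counts.matrix.tocsc()
    detected = (mat > 0).sum(axis=0).A1
    totals = mat.sum(axis=0).A1
    keep = (detected >= min_genes) & (totals > 0)
    report = {
        "n_input_cells": mat.shape[1],
        "n_dropped": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        raise AgeVeloError("normalize_cells: no cell passes the gene filter")
    mat = mat[:, keep]
    scaled = mat.multiply(TARGET_SUM / totals[keep][None, :]).toarray()
    norm = np.log1p(scaled)
    df = pd.DataFrame(norm, index=counts.gene_ids,
                      columns=counts.cell_ids[keep])
    return df, report


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def _zscore_rows(values: pd.DataFrame, genes: list) -> np.ndarray:
    present = [g for g in dict.fromkeys(genes) if g in values.index]
    if not present:
        raise AgeVeloError(f"no score genes found in matrix; missing: "
                           f"{list(dict.fromkeys(genes))[:10]}")
    v = values.loc[present].to_numpy()
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise AgeVeloError("all score genes have zero variance across cells")
    return (v[keep] - mu[keep]) / sd[keep, None]


def lta_score(normexpr: pd.DataFrame, up_genes: list, down_genes: list
              ) -> pd.Series:
    """Signed mean z-score: mean(z, up genes) - mean(z, down genes)."""
    if not up_genes or not down_genes:
        raise AgeVeloError("lta_score: need at least one gene per direction")
    z_up = _zscore_rows(normexpr, up_genes).mean(axis=0)
    z_down = _zscore_rows(normexpr, down_genes).mean(axis=0)
    return pd.Series(z_up - z_down, index=normexpr.columns, name="lta_score")


def clockgene_score(normexpr: pd.DataFrame, clock: ClockModel) -> pd.Series:
    """LTA-style score with up/down sets from the sign of clock weights.

    A clock with only one weight sign is accepted (the absent direction
    contributes zero); a clock with no nonzero weights is an error.
    """
    if clock.feature_space != "gene":
        raise AgeVeloError(
            f"clockgene_score: clock {clock.name!r} is not gene-based")
    up = list(clock.weights.index[clock.weights > 0])
    down = list(clock.weights.index[clock.weights < 0])
    if not up and not down:
        raise AgeVeloError(
            f"clockgene_score: clock {clock.name!r} has no nonzero weights")
    zero = pd.Series(0.0, index=normexpr.columns)
    z_up = _zscore_rows(normexpr, up).mean(axis=0) if up else zero
    z_down = _zscore_rows(normexpr, down).mean(axis=0) if down else zero
    return pd.Series(np.asarray(z_up) - np.asarray(z_down),
                     index=normexpr.columns, name="clockgene_score")


def directional_score(normexpr: pd.DataFrame, genes: list) -> pd.Series:
    """Single-direction mean z-score over one gene set."""
    z = _zscore_rows(normexpr, genes)
    return pd.Series(z.mean(axis=0), index=normexpr.columns)


# ---------------------------------------------------------------------------
# quartiles
# ---------------------------------------------------------------------------

def assign_quartiles(scores: pd.Series, reference: pd.Series) -> pd.Series:
    """Quartile labels from the reference distribution's breakpoints."""
    if reference.std(ddof=0) == 0:
        raise DomainError("quartile reference has zero score variance")
    q1, q2, q3 = np.quantile(reference.to_numpy(), [0.25, 0.5, 0.75])
    idx = np.searchsorted([q1, q2, q3], scores.to_numpy(), side="right")
    return pd.Series([QUARTILE_LABELS[i] for i in idx], index=scores.index)


def quartile_contribution(scores: pd.Series, cell_sheet: pd.DataFrame,
                          reference: str = "per_donor") -> pd.DataFrame:
    """Fraction of each sample's cells in each reference quartile.

    `reference="per_donor"` (default) pools a donor's timepoints to set the
    breakpoints, so the two timepoints of one donor are compared on a shared
    scale; `reference="cohort"` pools every cell.
    """
    if reference not in ("per_donor", "cohort"):
        raise AgeVeloError(f"unknown quartile reference {reference!r}")
    sheet = cell_sheet.set_index("cell_id").loc[scores.index]
    counts_per_donor = sheet.groupby("donor_id").size()
    if (counts_per_donor < 4).any():
        small = counts_per_donor[counts_per_donor < 4].index[0]
        raise DomainError(f"donor {small!r}: fewer than 4 cells")
    rows = []
    for donor, donor_cells in sheet.groupby("donor_id").groups.items():
        ref = scores if reference == "cohort" else scores.loc[donor_cells]
        labels = assign_quartiles(scores.loc[donor_cells], ref)
        tp = sheet.loc[donor_cells, "timepoint"]
        for timepoint, cells in tp.groupby(tp).groups.items():
            frac = labels.loc[cells].value_counts(normalize=True)
            row = {"donor_id": donor, "timepoint": timepoint,
                   "n_cells": len(cells)}
            for lab in QUARTILE_LABELS:
                row[lab] = float(frac.get(lab, 0.0))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------

def heterogeneity_test(scores_by_group: dict, center: str = "median") -> dict:
    """Group score SDs and Levene's homogeneity-of-variance test.

    `center="median"` is the Brown-Forsythe variant (the robust default);
    `center="mean"` gives the classic Levene statistic.  The F statistic is
    the one-way ANOVA F on absolute deviations from the group center, on
    (k-1, N-k) degrees of freedom.
    """
    if center not in ("median", "mean"):
        raise AgeVeloError(f"unknown Levene center {center!r}")
    if len(scores_by_group) < 2:
        raise DomainError("heterogeneity_test: need >= 2 groups")
    groups, sds = {}, {}
    for name, values in scores_by_group.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 3:
            raise DomainError(f"group {name!r}: need >= 3 cells, got {arr.size}")
        groups[name] = arr
        sds[name] = float(np.std(arr, ddof=1))

    devs = []
    for arr in groups.values():
        c = np.median(arr) if center == "median" else np.mean(arr)
        devs.append(np.abs(arr - c))
    k = len(devs)
    n_total = sum(d.size for d in devs)
    grand = np.concatenate(devs).mean()
    ss_between = sum(d.size * (d.mean() - grand) ** 2 for d in devs)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in devs)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        f_stat = 0.0 if ss_between == 0 else float("inf")
    else:
        f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(scipy.stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    return {
        "group_sd": sds, "levene_F": float(f_stat), "levene_p": p,
        "df": (df1, df2), "center": center,
    }


def per_pathway_cell_scores(normexpr: pd.DataFrame, cell_sheet: pd.DataFrame,
                            sets: dict, directions: dict,
                            t0: float = 0, t1: float | None = None) -> dict:
    """Per-pathway per-cell scores, per-sample SDs, and paired SD t-tests.

    For each pathway a single-direction z-mean score is computed per cell;
    the SD of that score within each (donor, timepoint) sample measures the
    pathway's cell-to-cell heterogeneity.  Month-t0 and month-t1 SDs are
    compared by a paired t-test across pathways, separately for the up- and
    down-regulated families — the readout for whether heterogeneity grows
    through variable loss of down-regulated programs.
    """
    sheet = cell_sheet.set_index("cell_id").loc[normexpr.columns]
    timepoints = sorted(sheet["timepoint"].unique())
    if t1 is None:
        t1 = timepoints[-1]
    scores = {}
    sd_rows = []
    for name, genes in sets.items():
        try:
            s = directional_score(normexpr, genes)
        except AgeVeloError:
            continue
        scores[name] = s
        for (donor, tp), cells in sheet.groupby(
                ["donor_id", "timepoint"]).groups.items():
            sd_rows.append({
                "pathway": name, "direction": directions.get(name, "none"),
                "donor_id": donor, "timepoint": tp,
                "score_sd": float(s.loc[cells].std(ddof=1)),
            })
    sd_table = pd.DataFrame(sd_rows)

    tests = {}
    for direction in ("up", "down"):
        sub = sd_table[sd_table["direction"] == direction]
        wide = sub.pivot_table(index=["pathway", "donor_id"],
                               columns="timepoint", values="score_sd")
        if t0 not in wide.columns or t1 not in wide.columns:
            continue
        paired = wide[[t0, t1]].dropna()
        if len(paired) < 2:
            continue
        diffs = paired[t1] - paired[t0]
        if np.allclose(diffs, 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = scipy.stats.ttest_rel(paired[t1], paired[t0])
        tests[direction] = {
            "t": float(t_stat), "p_value": float(p), "n_pairs": len(paired),
            "mean_sd_t0": float(paired[t0].mean()),
            "mean_sd_t1": float(paired[t1].mean()),
        }
    return {"scores": scores, "sd_table": sd_table, "paired_tests": tests}


# ---------------------------------------------------------------------------
# pseudobulk and cell-cycle
# ---------------------------------------------------------------------------

def pseudobulk(counts: SparseCountMatrix, groups: pd.Series) -> ExpressionMatrix:
    """Per-group sum of raw counts, emitted as a counts expression matrix."""
    groups = pd.Series(groups)
    missing = set(counts.cell_ids) - set(groups.index)
    if missing:
        raise AgeVeloError(
            f"pseudobulk: {len(missing)} cells without a group assignment")
    aligned = groups.loc[counts.cell_ids]
    names = aligned.unique()
    cols = {}
    csc = counts.matrix.tocsc()
    positions = pd.Series(np.arange(len(counts.cell_ids)), index=counts.cell_ids)
    for name in names:
        cells = positions[aligned.to_numpy() == name].to_numpy()
        if cells.size == 0:
            raise AgeVeloError(f"pseudobulk: empty group {name!r}")
        cols[name] = np.asarray(csc[:, cells].sum(axis=1)).ravel()
    df = pd.DataFrame(cols, index=counts.gene_ids)
    return ExpressionMatrix(df, "counts")


def cell_cycle_fraction(normexpr: pd.DataFrame, g2m_genes: list,
                        z_threshold: float = 0.5) -> dict:
    """Fraction of cells whose G2/M score exceeds the z threshold.

    A near-zero fraction supports a G0-dominant non-proliferative population.
    Identical cells (zero variance on every score gene) give fraction 0.
    """
    try:
        score = directional_score(normexpr, g2m_genes)
    except AgeVeloError as err:
        if "zero variance" not in str(err):
            raise
        score = pd.Series(0.0, index=normexpr.columns)
    above = score > z_threshold
    return {
        "fraction_above": float(above.mean()),
        "n_above": int(above.sum()),
        "n_cells": int(len(score)),
        "scores": score,
    }
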