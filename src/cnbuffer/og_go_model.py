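"""Oncogene (OG) and proliferation-driver (GO) density scores and the
combined amplification-pattern model.

Per bin, ``og_score`` and ``go_score`` are the fractions of the bin's genes
that belong to the supplied OG / GO sets. The combined predictor is the plain
unweighted sum OG + GO + μ_scaled (μ min–max scaled to [0,1] within the
cohort; the densities are already in [0,1]); no weights are fitted. The
cohort-swap control correlates one cohort's predictor against the other's
amplification frequencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import SegmentGrid, assign_genes_to_bins
from .stratification import CorrelationResult, correlate


def minmax_scale(values) -> np.ndarray:
    """Scale to [0,1] over defined entries; a constant vector maps to 0."""
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    out = np.full_like(x, np.nan)
    if ok.sum() == 0:
        return out
    lo, hi = np.nanmin(x), np.nanmax(x)
    out[ok] = 0.0 if hi == lo else (x[ok] - lo) / (hi - lo)
    return out


def density_scores(
    genes: pd.DataFrame,
    grid: SegmentGrid,
    og_genes,
    go_genes,
) -> pd.DataFrame:
    """Per-bin OG and GO densities by gene-midpoint membership.

    Bins containing zero genes get NaN densities and are excluded downstream.
    """
    og_genes = set(og_genes)
    go_genes = set(go_genes)
    assign = assign_genes_to_bins(genes, grid)
    frame = pd.DataFrame({
        "bin_id": assign.to_numpy(),
        "is_og": genes["gene"].isin(og_genes).to_numpy(),
        "is_go": genes["gene"].isin(go_genes).to_numpy(),
    }).dropna(subset=["bin_id"])
    grouped = frame.groupby("bin_id").agg(
        n_og=("is_og", "sum"), n_go=("is_go", "sum"), n_genes=("is_og", "count")
    )
    grouped = grouped.reindex(grid.bin_ids)
    n = grouped["n_genes"]
    return pd.DataFrame({
        "bin_id": grid.bin_ids,
        "og_score": (grouped["n_og"] / n).to_numpy(),
        "go_score": (grouped["n_go"] / n).to_numpy(),
        "n_genes": grouped["n_genes"].fillna(0).astype(int).to_numpy(),
    }).reset_index(drop=True)


def combined_predictor(density: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Join densities with scores and add the OG+GO+μ_scaled predictor."""
    merged = density.merge(
        scores[["bin_id", "amp_freq", "mu"]], on="bin_id", how="inner"
    )
    merged["mu_scaled"] = minmax_scale(merged["mu"])
    merged["og_go"] = merged["og_score"] + merged["go_score"]
    merged["og_go_mu"] = merged["og_go"] + merged["mu_scaled"]
    return merged


def combined_model(
    density: pd.DataFrame,
    scores: pd.DataFrame,
    *,
    cohort: str = "cohort",
) -> dict[str, CorrelationResult]:
    """Three Spearman correlations against amp_freq: OG+GO, μ alone, OG+GO+μ."""
    merged = combined_predictor(density, scores)
    out = {}
    for name, col in (("og_go", "og_go"), ("mu", "mu_scaled"), ("og_go_mu", "og_go_mu")):
        out[name] = correlate(
            merged, pair=("amp_freq", col), cohort=cohort, stratum_label=name
        )
    return out


def swap_control(
    density_a: pd.DataFrame, scores_a: pd.DataFrame,
    density_b: pd.DataFrame, scores_b: pd.DataFrame,
    *,
    cohorts: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Matched vs swapped predictor correlations between two cohorts.

    Both cohorts must be scored on the same grid (same bin_id universe).
    """
    if set(density_a["bin_id"]) != set(density_b["bin_id"]):
        raise ValueError("cohorts are scored on different grids")
    pa = combined_predictor(density_a, scores_a)
    pb = combined_predictor(density_b, scores_b)
    rows = []
    for label, pred, target, cohort in (
        ("matched", pa, pa, cohorts[0]),
        ("matched", pb, pb, cohorts[1]),
        ("swapped", pa, pb, cohorts[1]),
        ("swapped", pb, pa, cohorts[0]),
    ):
        merged = pred[["bin_id", "og_go_mu"]].merge(
            target[["bin_id", "amp_freq"]], on="bin_id"
        )
        res = correlate(merged, pair=("amp_freq", "og_go_mu"),
                        cohort=cohort, stratum_label=label)
        rows.append({"target_cohort": cohort, "design": label,
                     "rho": res.rho, "p_value": res.p_value, "n_bins": res.n_bins})
    return pd.DataFrame(rows)
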