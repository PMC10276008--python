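"""Per-gene protection index, permutation percentiles, and consensus calls.

For each expressed gene, the protection index is

    P = amp_freq_scaled − μ_scaled

(both scores min–max scaled to [0,1] within the cohort so that neither term
dominates; ``scale="raw"`` preserves the literal difference). A permutation
null re-pairs the amplification-frequency vector with the μ vector across
genes; the observed P is ranked against that null and genes above the 94th
percentile are *protected*, below the 6th *unprotected*. Calls are made
independently per cohort, with a >= 3-cohort consensus across cohorts.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeBuild
from .io_formats import CoverageMask
from .og_go_model import minmax_scale
from .scores import cohort_scores

logger = logging.getLogger(__name__)

PROTECTED_PERCENTILE = 94.0
UNPROTECTED_PERCENTILE = 6.0


def gene_scores(
    cna: pd.DataFrame,
    muts: pd.DataFrame,
    genes: pd.DataFrame,
    build: GenomeBuild,
    *,
    mask: CoverageMask | None = None,
    overlap_frac: float = 0.5,
    patients=None,
) -> pd.DataFrame:
    """Per-gene amp_freq and μ via the scoring pipeline at gene scale.

    Non-expressed genes (median TPM = 0) are removed before scoring; genes
    with undefined μ are excluded and logged.
    """
    expressed = genes[genes["median_tpm"] > 0].reset_index(drop=True)
    scores, _ = cohort_scores(
        cna, muts, expressed, build, scale="gene", mask=mask,
        overlap_frac=overlap_frac, patients=patients,
    )
    out = scores.rename(columns={"bin_id": "gene"})[
        ["gene", "amp_freq", "mu", "n_A", "n_D", "n_N", "n_mut_neutral"]
    ]
    undefined = out["mu"].isna()
    if undefined.any():
        logger.info("excluding %d gene(s) with undefined mu", int(undefined.sum()))
    return out.loc[~undefined].reset_index(drop=True)


def _closed_permutations(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    """Permutation sample closed under inversion (pairs pi, pi^-1)."""
    k = max(1, n_perm // 2)
    perms = np.empty((2 * k, n), dtype=np.intp)
    for i in range(k):
        p = rng.permutation(n)
        perms[2 * i] = p
        inv = np.empty(n, dtype=np.intp)
        inv[p] = np.arange(n)
        perms[2 * i + 1] = inv
    return perms


def protection_index(
    gene_df: pd.DataFrame,
    *,
    n_perm: int = 10_000,
    seed: int,
    null: str = "pooled",
    scale: str = "minmax",
    cohort: str = "cohort",
) -> pd.DataFrame:
    """Protection records (P, permutation percentile, class) per gene.

    ``null``:

    * ``"pooled"`` (default) — every permutation re-pairs the amp vector with
      the μ vector; all null P values are pooled across genes and
      permutations.
    * ``"per-gene"`` — each gene is ranked only against its own null draws.
    * ``"swap"`` — the literal two-point per-gene swap null {P, −P}.

    Each re-pairing contributes both amp[π]−μ and its negation μ−amp[π] (the
    amp↔μ swap applied to the same pairing), and the sampled permutations come
    in inverse-closed pairs; together these make the percentile map exactly
    anti-symmetric under a global amp↔μ exchange. The seed fully determines
    the output.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null", stacklevel=2)
    if len(gene_df) < 2:
        raise ValueError("need at least two genes")
    df = gene_df.reset_index(drop=True).copy()
    if scale == "minmax":
        amp = minmax_scale(df["amp_freq"])
        mu = minmax_scale(df["mu"])
    elif scale == "raw":
        amp = df["amp_freq"].to_numpy(dtype=float)
        mu = df["mu"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    p_obs = amp - mu
    n = len(df)
    rng = np.random.default_rng(seed)

    below = np.zeros(n)
    equal = np.zeros(n)
    total = 0
    if null == "swap":
        # per-gene two-point null {P, -P}
        below = (-np.abs(p_obs) < p_obs).astype(float) + (np.abs(p_obs) < p_obs)
        equal = (-np.abs(p_obs) == p_obs).astype(float) + (np.abs(p_obs) == p_obs)
        total = 2
    else:
        perms = _closed_permutations(rng, n, n_perm)
        chunk = max(1, 2_000_000 // max(n, 1))
        for lo in range(0, len(perms), chunk):
            null_block = amp[perms[lo:lo + chunk]] - mu[None, :]
            signed = np.concatenate([null_block, -null_block], axis=0)
            if null == "per-gene":
                below += (signed < p_obs[None, :]).sum(axis=0)
                equal += (signed == p_obs[None, :]).sum(axis=0)
            elif null == "pooled":
                flat = np.sort(signed.reshape(-1))
                below += np.searchsorted(flat, p_obs, side="left")
                equal += (np.searchsorted(flat, p_obs, side="right")
                          - np.searchsorted(flat, p_obs, side="left"))
            else:
                raise ValueError(f"unknown null {null!r}")
            total += signed.shape[0] if null == "per-gene" else signed.size
    percentile = 100.0 * (below + 0.5 * equal) / total
    klass = np.full(n, "neither", dtype=object)
    klass[percentile > PROTECTED_PERCENTILE] = "protected"
    klass[percentile < UNPROTECTED_PERCENTILE] = "unprotected"
    out = pd.DataFrame({
        "gene": df["gene"],
        "cohort": cohort,
        "amp_freq_gene": df["amp_freq"],
        "mu_gene": df["mu"],
        "p_index": p_obs,
        "percentile": percentile,
        "klass": klass,
    })
    return out.sort_values("gene", kind="mergesort").reset_index(drop=True)


def consensus(records: dict[str, pd.DataFrame], min_cohorts: int = 3) -> pd.DataFrame:
    """Cross-cohort consensus: protected/unprotected in >= ``min_cohorts``."""
    all_genes = sorted(set().union(*[set(df["gene"]) for df in records.values()]))
    n_prot = pd.Series(0, index=all_genes)
    n_unprot = pd.Series(0, index=all_genes)
    for df in records.values():
        prot = df.loc[df["klass"] == "protected", "gene"]
        unprot = df.loc[df["klass"] == "unprotected", "gene"]
        n_prot[prot] += 1
        n_unprot[unprot] += 1
    call = np.full(len(all_genes), "none", dtype=object)
    prot_ok = (n_prot >= min_cohorts).to_numpy()
    unprot_ok = (n_unprot >= min_cohorts).to_numpy()
    pathological = prot_ok & unprot_ok
    if pathological.any():
        logger.warning("%d gene(s) meet both consensus thresholds; set to none",
                       int(pathological.sum()))
    call[prot_ok & ~pathological] = "protected"
    call[unprot_ok & ~pathological] = "unprotected"
    return pd.DataFrame({
        "gene": all_genes,
        "n_cohorts_protected": n_prot.to_numpy(),
        "n_cohorts_unprotected": n_unprot.to_numpy(),
        "consensus": call,
    })


def essentiality_comparison(consensus_df: pd.DataFrame, genes: pd.DataFrame) -> dict:
    """Essentiality and expression contrasts between the consensus sets.

    Returns (i) a two-sided rank-sum test on CRISPR gene effect between the
    protected and unprotected sets, (ii) a Fisher exact test of the overlap
    with common-essential / non-essential flags, (iii) a two-sided rank-sum
    test on median expression. Empty sets skip the affected test with a note.
    """
    ann = genes.set_index("gene")
    prot = consensus_df.loc[consensus_df["consensus"] == "protected", "gene"]
    unprot = consensus_df.loc[consensus_df["consensus"] == "unprotected", "gene"]
    out: dict = {"n_protected": len(prot), "n_unprotected": len(unprot)}
    if len(prot) == 0 or len(unprot) == 0:
        out["note"] = "one of the sets is empty; tests skipped"
        return out

    eff_p = ann.reindex(prot)["crispr_effect"].dropna()
    eff_u = ann.reindex(unprot)["crispr_effect"].dropna()
    if len(eff_p) and len(eff_u):
        res = stats.mannwhitneyu(eff_p, eff_u, alternative="two-sided")
        out["crispr_effect"] = {
            "statistic": float(res.statistic), "p_value": float(res.pvalue),
            "median_protected": float(eff_p.median()),
            "median_unprotected": float(eff_u.median()),
        }
    if "is_common_essential" in ann.columns:
        ess = ann["is_common_essential"].astype(bool)
        noness = ann["is_nonessential"].astype(bool)
        table = np.array([
            [int(ess.reindex(prot).fillna(False).sum()),
             int(noness.reindex(prot).fillna(False).sum())],
            [int(ess.reindex(unprot).fillna(False).sum()),
             int(noness.reindex(unprot).fillna(False).sum())],
        ])
        if table.sum() > 0 and not ((table.sum(axis=0) == 0).any()
                                    or (table.sum(axis=1) == 0).any()):
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            out["essential_overlap"] = {
                "table": table.tolist(), "odds_ratio": float(odds),
                "p_value": float(p),
            }
    expr_p = ann.reindex(prot)["median_tpm"].dropna()
    expr_u = ann.reindex(unprot)["median_tpm"].dropna()
    if len(expr_p) and len(expr_u):
        res = stats.mannwhitneyu(expr_p, expr_u, alternative="two-sided")
        out["expression"] = {
            "statistic": float(res.statistic), "p_value": float(res.pvalue),
            "median_protected": float(expr_p.median()),
            "median_unprotected": float(expr_u.median()),
        }
    return out
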