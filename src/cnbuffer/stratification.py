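"""Rank-correlation analyses: amp/del frequency vs μ, scale sweeps, strata.

All associations are Spearman rank correlations with midrank tie handling and
no multiple-testing correction. Stratified runs recompute μ from the filtered
mutation subset only — amplification and deletion frequencies never change
under stratification.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .scores import score_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    cohort: str
    scale: str
    variable_pair: str
    rho: float
    p_value: float
    n_bins: int
    stratum_label: str = "unfiltered"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n: int
    method: str


def spearman(x, y, *, exact: bool = False) -> tuple[float, float]:
    """Spearman rho and two-sided p with midrank ties.

    With ``exact=True`` (n <= 8) the p-value comes from full enumeration of
    rank permutations; otherwise scipy's t-approximation is used. Degenerate
    inputs (n < 3 or zero variance) return (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    if exact:
        if n > 8:
            raise ValueError("exact permutation p-value supported for n <= 8 only")
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def correlate(
    scores: pd.DataFrame,
    pair: tuple[str, str] = ("amp_freq", "mu"),
    *,
    cohort: str = "cohort",
    scale: str = "",
    stratum_label: str = "unfiltered",
    exact: bool = False,
) -> CorrelationResult:
    """Spearman correlation between two score columns over defined-μ bins."""
    sub = scores.dropna(subset=[pair[0], pair[1]])
    rho, p = spearman(sub[pair[0]], sub[pair[1]], exact=exact)
    if math.isnan(rho) and len(sub) >= 3:
        logger.info("degenerate variance in %s~%s (ties everywhere)", *pair)
    return CorrelationResult(
        cohort=cohort, scale=scale, variable_pair=f"{pair[0]}~{pair[1]}",
        rho=rho, p_value=p, n_bins=len(sub), stratum_label=stratum_label,
    )


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Scale sweep


def sweep_scales(score_fn, scales) -> tuple[list[CorrelationResult], object]:
    """Correlate amp_freq ~ mu at each scale; report the argmax-|rho| scale.

    ``score_fn(scale_spec) -> scores DataFrame`` recomputes the score table at
    one scale; ``scales`` is a list of scale specs (passed through untouched,
    e.g. ``("fixed", 36_000_000)`` or ``("arm", None)``).
    """
    results = []
    for spec in scales:
        scores = score_fn(spec)
        label = spec[0] if spec[1] is None else f"{spec[0]}:{spec[1]}"
        results.append(correlate(scores, scale=label))
    defined = [(r, s) for r, s in zip(results, scales) if r.defined]
    if not defined:
        return results, None
    best = max(defined, key=lambda rs: rs[0].rho)
    return results, best[1]


# ---------------------------------------------------------------------------
# Strata registry (gene- and mutation-level filters, each with complement)


@dataclass(frozen=True)
class StratumSpec:
    """A pure predicate over gene or mutation annotations.

    ``kind`` is 'gene' (filter mutations by the genes they hit) or 'mutation'
    (filter mutation rows directly). ``predicate`` maps the relevant frame to
    a boolean keep-mask; rows where ``discard`` is True belong to neither the
    stratum nor its complement (e.g. null scores, middle score bands).
    """

    name: str
    kind: str
    predicate: object
    complement_name: str
    discard: object = None


def _col_ok(col):
    return lambda df: df[col].notna()


BUILTIN_STRATA: tuple[StratumSpec, ...] = (
    StratumSpec("pli_haploinsufficient", "gene",
                lambda g: g["pli"] > 0.2, "pli_non_haploinsufficient",
                discard=lambda g: g["pli"].isna()),
    StratumSpec("ghis_haploinsufficient", "gene",
                lambda g: g["ghis"] > 0.5, "ghis_non_haploinsufficient",
                discard=lambda g: g["ghis"].isna()),
    StratumSpec("expressed", "gene",
                lambda g: g["median_tpm"] > 0, "non_expressed"),
    StratumSpec("cadd_damaging", "mutation",
                lambda m: m["cadd"] > 3.5, "cadd_benign",
                discard=lambda m: m["cadd"].isna() | (m["cadd"] == 3.5)),
    StratumSpec("polyphen_damaging", "mutation",
                lambda m: m["polyphen"] > 0.6, "polyphen_benign",
                discard=lambda m: m["polyphen"].isna()
                | ((m["polyphen"] >= 0.3) & (m["polyphen"] <= 0.6))),
    StratumSpec("synonymous", "mutation",
                lambda m: m["is_synonymous"], "non_synonymous"),
    StratumSpec("aggregation_causing", "mutation",
                lambda m: (m["aggregation_score"] > 5000)
                & (m["aggregation_fold_change"] > 1),
                "non_aggregation_causing",
                discard=lambda m: m["aggregation_score"].isna()
                | m["aggregation_fold_change"].isna()),
    StratumSpec("no_og", "gene", lambda g: ~g["is_og"], "og_only"),
    StratumSpec("no_tsg", "gene", lambda g: ~g["is_tsg"], "tsg_only"),
    StratumSpec("no_og_tsg", "gene",
                lambda g: ~(g["is_og"] | g["is_tsg"]), "og_tsg_only"),
)


def stratum_masks(spec: StratumSpec, genes: pd.DataFrame, muts: pd.DataFrame):
    """(stratum, complement, discarded) boolean masks over mutation rows."""
    if spec.kind == "gene":
        frame = genes
        keep_genes = spec.predicate(frame).fillna(False)
        discard_genes = (
            spec.discard(frame).fillna(True) if spec.discard is not None
            else pd.Series(False, index=frame.index)
        )
        in_stratum_genes = set(frame.loc[keep_genes & ~discard_genes, "gene"])
        complement_genes = set(frame.loc[~keep_genes & ~discard_genes, "gene"])
        gene_col = muts["gene"]
        stratum = gene_col.isin(in_stratum_genes)
        discarded = ~stratum & ~gene_col.isin(complement_genes)
    else:
        discarded = (
            spec.discard(muts).fillna(True) if spec.discard is not None
            else pd.Series(False, index=muts.index)
        )
        stratum = spec.predicate(muts).fillna(False) & ~discarded
    complement = ~stratum & ~discarded
    return stratum.to_numpy(), complement.to_numpy(), discarded.to_numpy()


def stratified_correlations(
    states: pd.DataFrame,
    muts: pd.DataFrame,
    genes: pd.DataFrame,
    grid,
    coding_bp: pd.Series,
    strata=BUILTIN_STRATA,
    *,
    cohort: str = "cohort",
    restrict_coding_bp: bool = False,
) -> list[CorrelationResult]:
    """Recompute μ per stratum and correlate against the fixed amp_freq.

    The unfiltered control is always first. ``restrict_coding_bp`` optionally
    rebuilds the coding-bp denominator from stratum genes only (gene strata).
    """
    from .scores import coding_bp_per_bin

    results = []
    control = score_table(states, muts, grid, coding_bp)
    results.append(correlate(control, cohort=cohort, stratum_label="unfiltered"))
    for spec in strata:
        in_s, in_c, _ = stratum_masks(spec, genes, muts)
        for label, mask in ((spec.name, in_s), (spec.complement_name, in_c)):
            sub = muts.loc[mask].reset_index(drop=True)
            if len(sub) == 0:
                logger.warning("stratum %s empties all mutations; flagged", label)
                results.append(CorrelationResult(
                    cohort=cohort, scale="", variable_pair="amp_freq~mu",
                    rho=float("nan"), p_value=float("nan"), n_bins=0,
                    stratum_label=label,
                ))
                continue
            cb = coding_bp
            if restrict_coding_bp and spec.kind == "gene":
                gmask, gcomp, _ = _gene_masks(spec, genes)
                gsel = gmask if label == spec.name else gcomp
                cb = coding_bp_per_bin(genes.loc[gsel], grid)
            tbl = score_table(states, sub, grid, cb)
            results.append(correlate(tbl, cohort=cohort, stratum_label=label))
    return results


def _gene_masks(spec: StratumSpec, genes: pd.DataFrame):
    keep = spec.predicate(genes).fillna(False)
    discard = (
        spec.discard(genes).fillna(True) if spec.discard is not None
        else pd.Series(False, index=genes.index)
    )
    return (keep & ~discard).to_numpy(), (~keep & ~discard).to_numpy(), discard.to_numpy()


# ---------------------------------------------------------------------------
# Paired comparisons and meta-analysis


def exact_signed_rank_p(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Wilcoxon signed-rank p via DP over doubled midranks.

    Zero differences are dropped (all-zero input -> statistic at the null
    center, p = 1). Returns (W_plus, p).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    units = np.round(2 * ranks).astype(int)  # doubled midranks are integers
    total = int(units.sum())
    # distribution of doubled W+ over all 2^n sign assignments
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for u in units:
        shifted = np.zeros_like(dist)
        shifted[u:] = dist[: total + 1 - u]
        dist = dist + shifted
    dist /= 2.0 ** n
    w2 = int(round(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return w_plus, float(p)


def compare_strata(results_a, results_b) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test on rho values across cohorts.

    The two lists must cover the same cohorts; mismatches raise naming the
    offenders. Exact null distribution for n <= 25, normal approximation
    beyond.
    """
    a = {r.cohort: r.rho for r in results_a}
    b = {r.cohort: r.rho for r in results_b}
    only_a = sorted(set(a) - set(b))
    only_b = sorted(set(b) - set(a))
    if only_a or only_b:
        raise ValueError(f"unpaired cohorts: {only_a + only_b}")
    cohorts = sorted(a)
    diffs = np.array([b[c] - a[c] for c in cohorts], dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    if len(diffs) < 2:
        raise ValueError("need at least two paired, defined rho values")
    if len(diffs) <= 25:
        w, p = exact_signed_rank_p(diffs)
        return WilcoxonResult(statistic=w, p_value=p, n=len(diffs), method="exact")
    res = stats.wilcoxon(diffs, alternative="two-sided", method="approx")
    return WilcoxonResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          n=len(diffs), method="approx")


def significant_cohorts(results, alpha: float = 0.05) -> list[str]:
    """Cohorts whose amp~μ Spearman p-value passes the significance gate."""
    return [r.cohort for r in results if r.defined and r.p_value <= alpha]


def meta_correlation(summaries, results) -> CorrelationResult:
    """Spearman between per-cohort buffering rho and mutation burden."""
    burden = {s.cohort: s.mutation_burden for s in summaries}
    rhos = {r.cohort: r.rho for r in results}
    cohorts = sorted(set(burden) & set(rhos))
    if len(cohorts) < 3:
        return CorrelationResult(
            cohort="meta", scale="", variable_pair="rho~mutation_burden",
            rho=float("nan"), p_value=float("nan"), n_bins=len(cohorts),
        )
    rho, p = spearman([burden[c] for c in cohorts], [rhos[c] for c in cohorts])
    return CorrelationResult(
        cohort="meta", scale="", variable_pair="rho~mutation_burden",
        rho=rho, p_value=p, n_bins=len(cohorts),
    )
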