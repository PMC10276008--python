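"""Per-bin amplification/deletion frequencies and the copy-neutral μ score.

For a cohort, every bin ``i`` at scale ``j`` gets

* ``amp_freq`` = #patients amplified / #patients,
* ``del_freq`` = #patients deleted / #patients,
* ``mu``       = log10( coding mutations from copy-neutral patients
                        / (coding_bp * #copy-neutral patients) ).

Restricting the μ numerator to copy-neutral patients removes the trivial
confounder that more copies of a segment can simply carry more mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBuild, drop_sex_chromosomes
from .io_formats import CoverageMask, apply_coverage_mask, deduplicate_mutations
from .segmentation import (
    AMP_CUT,
    SegmentGrid,
    assign_genes_to_bins,
    assign_positions_to_bins,
    build_grid,
    patient_bin_states,
)

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["bin_id", "chrom", "start", "end", "amp_freq", "del_freq",
                 "mu", "n_A", "n_D", "n_N", "coding_bp", "n_mut_neutral"]


@dataclass(frozen=True)
class CohortSummary:
    cohort: str
    mean_amp_freq: float
    mean_del_freq: float
    pooled_mu: float
    mutation_burden: float
    n_patients: int
    n_bins_defined: int


def amplification_frequency(states: pd.DataFrame, bin_id) -> float:
    """#A / (#A + #D + #N) for one bin; raises on an empty patient set."""
    sub = states.loc[states["bin_id"] == bin_id, "state"]
    if len(sub) == 0:
        raise ValueError(f"no patients for bin {bin_id!r}")
    return float((sub == "A").sum() / len(sub))


def deletion_frequency(states: pd.DataFrame, bin_id) -> float:
    sub = states.loc[states["bin_id"] == bin_id, "state"]
    if len(sub) == 0:
        raise ValueError(f"no patients for bin {bin_id!r}")
    return float((sub == "D").sum() / len(sub))


def coding_bp_per_bin(genes: pd.DataFrame, grid: SegmentGrid) -> pd.Series:
    """Coding base pairs per bin, apportioned by gene-midpoint assignment.

    At the gene scale each bin is a gene and carries its own coding_bp.
    """
    if grid.scale == "gene":
        per_gene = genes.set_index("gene")["coding_bp"]
        return per_gene.reindex(grid.bin_ids).fillna(0.0).rename("coding_bp")
    assign = assign_genes_to_bins(genes, grid)
    cb = pd.Series(genes["coding_bp"].to_numpy(), index=assign.to_numpy())
    summed = cb.groupby(level=0).sum()
    return summed.reindex(grid.bin_ids).fillna(0.0).rename("coding_bp")


def mu_score(n_mut_neutral: int, n_N: int, coding_bp: float) -> float:
    """Eq.-style μ for one bin; NaN when the ratio is undefined or zero."""
    if coding_bp <= 0 or n_N <= 0 or n_mut_neutral <= 0:
        return float("nan")
    return float(np.log10(n_mut_neutral / (coding_bp * n_N)))


def _assign_mutation_bins(muts: pd.DataFrame, grid: SegmentGrid) -> pd.Series:
    if grid.scale == "gene":
        valid = set(grid.bin_ids)
        return muts["gene"].map(lambda g: g if g in valid else np.nan)
    return pd.Series(
        assign_positions_to_bins(muts["chrom"].to_numpy(), muts["pos"].to_numpy(), grid),
        index=muts.index,
    )


def score_table(
    states: pd.DataFrame,
    muts: pd.DataFrame,
    grid: SegmentGrid,
    coding_bp: pd.Series,
    *,
    mu_zero="drop",
) -> pd.DataFrame:
    """One row of scores per bin from precomputed states and filtered mutations.

    ``muts`` must already be restricted to coding, autosomal, mask-passing
    records (see :func:`cohort_scores` for the full orchestration). ``mu_zero``
    is ``"drop"`` (zero-count bins get NaN μ) or ``("pseudocount", k)``.
    """
    counts = (
        states.pivot_table(index="bin_id", columns="state", values="patient",
                           aggfunc="count", fill_value=0)
        .reindex(grid.bin_ids, fill_value=0)
        .reindex(columns=["A", "D", "N"], fill_value=0)
    )
    n_pat = counts.sum(axis=1)
    if (n_pat == 0).all():
        raise ValueError("no patients in the cohort")

    muts = muts.copy()
    muts["bin_id"] = _assign_mutation_bins(muts, grid)
    muts = muts.dropna(subset=["bin_id"])
    neutral = states.loc[states["state"] == "N", ["patient", "bin_id"]]
    in_neutral = muts.merge(neutral, on=["patient", "bin_id"], how="inner")
    n_mut = (
        in_neutral.groupby("bin_id")["patient"].count()
        .reindex(grid.bin_ids, fill_value=0)
    )

    cb = coding_bp.reindex(grid.bin_ids).fillna(0.0)
    numer = n_mut.to_numpy().astype(float)
    if mu_zero != "drop":
        kind, k = mu_zero
        if kind != "pseudocount":
            raise ValueError(f"unknown mu_zero policy {mu_zero!r}")
        numer = numer + float(k)
    denom = cb.to_numpy() * counts["N"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where((numer > 0) & (denom > 0), np.log10(numer / denom), np.nan)

    bins = grid.bins.set_index("bin_id")
    out = pd.DataFrame({
        "bin_id": grid.bin_ids,
        "chrom": bins["chrom"].to_numpy(),
        "start": bins["start"].to_numpy(),
        "end": bins["end"].to_numpy(),
        "amp_freq": (counts["A"] / n_pat).to_numpy(),
        "del_freq": (counts["D"] / n_pat).to_numpy(),
        "mu": mu,
        "n_A": counts["A"].to_numpy(),
        "n_D": counts["D"].to_numpy(),
        "n_N": counts["N"].to_numpy(),
        "coding_bp": cb.to_numpy(),
        "n_mut_neutral": n_mut.to_numpy(),
    })
    return out.reset_index(drop=True)


def prepare_mutations(
    muts: pd.DataFrame,
    *,
    coding_only: bool = True,
    mask: CoverageMask | None = None,
) -> pd.DataFrame:
    """Central mutation filter: dedupe, autosomes, coverage mask, coding."""
    muts = deduplicate_mutations(muts)
    muts = drop_sex_chromosomes(muts)
    if mask is not None:
        muts = apply_coverage_mask(muts, mask)
    if coding_only:
        muts = muts.loc[muts["is_coding"].astype(bool)].reset_index(drop=True)
    return muts


def cohort_scores(
    cna: pd.DataFrame,
    muts: pd.DataFrame,
    genes: pd.DataFrame,
    build: GenomeBuild,
    *,
    grid: SegmentGrid | None = None,
    scale: str = "fixed",
    bin_size: int | None = None,
    mask: CoverageMask | None = None,
    overlap_frac: float = 0.5,
    amp_cut: float = AMP_CUT,
    event_filter=None,
    patients=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-bin scoring pipeline for one cohort.

    Returns ``(scores, states)``. The patient universe is the intersection of
    CNA- and mutation-profiled patients unless ``patients`` is given
    explicitly; a mismatch is logged.
    """
    if grid is None:
        grid = build_grid(build, scale, bin_size=bin_size, genes=genes)
    cna = drop_sex_chromosomes(cna)
    muts = prepare_mutations(muts, mask=mask)
    if patients is None:
        cna_pat = set(cna["patient"])
        mut_pat = set(muts["patient"])
        patients = sorted(cna_pat & mut_pat)
        if len(patients) == 0:
            raise ValueError("empty intersection of CNA- and mutation-profiled patients")
        dropped = (cna_pat | mut_pat) - set(patients)
        if dropped:
            logger.info("dropping %d patient(s) profiled on only one platform",
                        len(dropped))
    else:
        patients = sorted(patients)
    muts = muts[muts["patient"].isin(patients)].reset_index(drop=True)
    states = patient_bin_states(
        cna, grid, patients, build=build, event_filter=event_filter,
        overlap_frac=overlap_frac, amp_cut=amp_cut,
    )
    cb = coding_bp_per_bin(genes, grid)
    scores = score_table(states, muts, grid, cb)
    return scores, states


def cohort_summary(
    scores: pd.DataFrame,
    muts: pd.DataFrame,
    patients,
    cohort: str = "cohort",
) -> CohortSummary:
    """Cohort-level pooled summary.

    ``pooled_mu`` is the log10 of the mean of the *untransformed* per-bin μ
    values (mean of 10**μ over bins with defined μ, then log10).
    ``mutation_burden`` is total coding autosomal mutations per patient.
    """
    defined = scores["mu"].dropna()
    if len(defined) == 0:
        raise ValueError("no bin has a defined mu score")
    pooled_mu = float(np.log10(np.mean(10.0 ** defined.to_numpy())))
    coding = (muts.loc[muts["is_coding"].astype(bool)]
              if "is_coding" in muts.columns else muts)
    coding = drop_sex_chromosomes(coding)
    n_patients = len(set(patients))
    return CohortSummary(
        cohort=cohort,
        mean_amp_freq=float(scores["amp_freq"].mean()),
        mean_del_freq=float(scores["del_freq"].mean()),
        pooled_mu=pooled_mu,
        mutation_burden=float(len(coding) / n_patients),
        n_patients=n_patients,
        n_bins_defined=int(len(defined)),
    )
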