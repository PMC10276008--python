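"""Segment grids, per-patient bin states, and CNA event classes.

The genome is partitioned into bins at one of four scales — single genes,
fixed-length windows of ``j`` bp, chromosome arms, or whole chromosomes — and
each (patient, bin) pair is classified amplified / deleted / copy-neutral from
the patient's CNA calls. Calls themselves are classified chromosomal / arm /
focal by the fraction of the chromosome or arm they cover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBuild

logger = logging.getLogger(__name__)

#: log2-ratio cutoff: amplified iff segment_mean > +AMP_CUT, deleted iff < -AMP_CUT
AMP_CUT = 0.2

EVENT_CLASSES = ("chromosomal", "arm", "focal")


@dataclass(frozen=True)
class SegmentGrid:
    """Ordered genome partition at a given scale.

    ``bins`` has columns chrom, start, end, bin_id. For fixed/arm/chromosome
    scales the bins tile each autosome without overlap (the last fixed bin may
    be shorter than ``bin_size``). For the gene scale, bins are gene bodies
    and carry the gene name as ``bin_id``.
    """

    scale: str
    bins: pd.DataFrame
    bin_size: int | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("gene", "fixed", "arm", "chromosome"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def bin_ids(self) -> pd.Index:
        return pd.Index(self.bins["bin_id"])

    def lengths(self) -> pd.Series:
        return pd.Series(
            (self.bins["end"] - self.bins["start"]).to_numpy(),
            index=self.bins["bin_id"], name="length",
        )

    def to_bed(self, path) -> None:
        self.bins[["chrom", "start", "end", "bin_id"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def build_grid(
    build: GenomeBuild,
    scale: str,
    bin_size: int | None = None,
    genes: pd.DataFrame | None = None,
) -> SegmentGrid:
    """Construct the segment index at the requested scale (autosomes only)."""
    rows: list[tuple] = []
    if scale == "fixed":
        if bin_size is None or bin_size <= 0:
            raise ValueError("fixed scale requires bin_size > 0")
        for chrom in build.autosomes:
            length = build.chrom_length(chrom)
            for k, start in enumerate(range(0, length, int(bin_size))):
                end = min(start + int(bin_size), length)
                rows.append((chrom, start, end, f"{chrom}:{k}"))
    elif scale == "chromosome":
        for chrom in build.autosomes:
            rows.append((chrom, 0, build.chrom_length(chrom), chrom))
    elif scale == "arm":
        for chrom in build.autosomes:
            bound = build.arm_boundary(chrom)
            rows.append((chrom, 0, bound, f"{chrom}p"))
            rows.append((chrom, bound, build.chrom_length(chrom), f"{chrom}q"))
    elif scale == "gene":
        if genes is None:
            raise ValueError("gene scale requires a gene annotation table")
        g = genes[genes["chrom"].isin(build.autosomes)]
        g = g.sort_values(["chrom", "start", "gene"], kind="mergesort")
        rows = list(zip(g["chrom"], g["start"], g["end"], g["gene"]))
    else:  # pragma: no cover - guarded by SegmentGrid
        raise ValueError(scale)
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "bin_id"])
    return SegmentGrid(scale=scale, bins=bins.reset_index(drop=True),
                       bin_size=int(bin_size) if scale == "fixed" else None)


def classify_call(segment_mean: float, amp_cut: float = AMP_CUT) -> str:
    """'amplified' / 'deleted' / 'neutral' from the log2-ratio segment mean.

    Thresholds are strict: values at exactly +/- amp_cut are neutral.
    """
    if amp_cut <= 0:
        raise ValueError("amp_cut must be > 0")
    if segment_mean > amp_cut:
        return "amplified"
    if segment_mean < -amp_cut:
        return "deleted"
    return "neutral"


def call_states(segment_mean: np.ndarray, amp_cut: float = AMP_CUT) -> np.ndarray:
    """Vectorized :func:`classify_call` -> array of 'A' / 'D' / 'N'."""
    if amp_cut <= 0:
        raise ValueError("amp_cut must be > 0")
    sm = np.asarray(segment_mean, dtype=float)
    out = np.full(sm.shape, "N", dtype="U1")
    out[sm > amp_cut] = "A"
    out[sm < -amp_cut] = "D"
    return out


def classify_event(chrom: str, start: int, end: int, build: GenomeBuild) -> str:
    """Chromosomal (>= 90% of the chromosome), arm (>= 50% of the arm), else focal.

    Centromere-spanning calls use the arm with the larger overlap for the arm
    test.
    """
    length = end - start
    chrom_len = build.chrom_length(chrom)
    if length >= 0.9 * chrom_len:
        return "chromosomal"
    arm = build.arm_of(chrom, start, end)
    if length >= 0.5 * build.arm_length(chrom, arm):
        return "arm"
    return "focal"


def event_classes(calls: pd.DataFrame, build: GenomeBuild) -> pd.Series:
    return pd.Series(
        [classify_event(c, s, e, build)
         for c, s, e in zip(calls["chrom"], calls["start"], calls["end"])],
        index=calls.index, name="event_class",
    )


def _overlap_pairs(calls: pd.DataFrame, grid: SegmentGrid):
    """Indices (call_row, bin_row) for every call/bin overlap."""
    pairs_call: list[int] = []
    pairs_bin: list[int] = []
    bins = grid.bins
    for chrom, bgrp in bins.groupby("chrom", sort=False):
        cgrp = calls[calls["chrom"] == chrom]
        if len(cgrp) == 0:
            continue
        bstart = bgrp["start"].to_numpy()
        bend = bgrp["end"].to_numpy()
        brows = bgrp.index.to_numpy()
        # bins sorted by start; cummax(end) bounds the candidate window even
        # for overlapping gene bins
        cummax_end = np.maximum.accumulate(bend)
        for crow, s, e in zip(cgrp.index, cgrp["start"], cgrp["end"]):
            lo = np.searchsorted(cummax_end, s, side="right")
            hi = np.searchsorted(bstart, e, side="left")
            if hi <= lo:
                continue
            sel = np.flatnonzero(bend[lo:hi] > s) + lo
            pairs_call.extend([crow] * len(sel))
            pairs_bin.extend(brows[sel].tolist())
    return np.asarray(pairs_call, dtype=np.intp), np.asarray(pairs_bin, dtype=np.intp)


def _union_coverage(group_id, starts, ends):
    """Union length of intervals per group (groups need not be contiguous)."""
    if len(group_id) == 0:
        return np.zeros(0), np.zeros(0, dtype=np.int64)
    big = np.int64(ends.max() + 1)
    shifted_s = starts + group_id * big
    shifted_e = ends + group_id * big
    order = np.argsort(shifted_s, kind="stable")
    s, e, g = shifted_s[order], shifted_e[order], group_id[order]
    run = np.maximum.accumulate(e)
    prev = np.empty_like(run)
    prev[0] = np.iinfo(np.int64).min // 2
    prev[1:] = run[:-1]
    contrib = np.clip(e - np.maximum(s, prev), 0, None)
    uniq, inverse = np.unique(g, return_inverse=True)
    sums = np.zeros(len(uniq))
    np.add.at(sums, inverse, contrib)
    return sums, uniq


def patient_bin_states(
    calls: pd.DataFrame,
    grid: SegmentGrid,
    patients,
    *,
    build: GenomeBuild | None = None,
    event_filter=None,
    overlap_frac: float = 0.5,
    amp_cut: float = AMP_CUT,
) -> pd.DataFrame:
    """Classify every (patient, bin) as 'A', 'D' or 'N'.

    A bin is amplified (deleted) for a patient when amplified (deleted) calls
    — optionally restricted to ``event_filter`` classes — cover at least
    ``overlap_frac`` of the bin's length (union over same-state calls).
    When both states qualify, the state with the larger coverage wins; exact
    ties go to 'A' with a warning. Patients with no qualifying call are 'N'.
    """
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must be in (0, 1]")
    patients = pd.Index(pd.unique(pd.Series(list(patients))), name="patient")
    bins = grid.bins
    n_bins = len(bins)
    full_index = pd.MultiIndex.from_product(
        [patients, bins["bin_id"]], names=["patient", "bin_id"]
    )
    calls = calls[calls["patient"].isin(patients)].reset_index(drop=True)
    calls = calls[calls["chrom"].isin(set(bins["chrom"]))].reset_index(drop=True)
    states_long = pd.DataFrame(index=full_index).reset_index()
    states_long["state"] = "N"
    if len(calls) == 0:
        return states_long
    st = call_states(calls["segment_mean"].to_numpy(), amp_cut=amp_cut)
    keep = st != "N"
    if event_filter is not None:
        if build is None:
            raise ValueError("event_filter requires a genome build")
        ec = event_classes(calls, build)
        keep &= ec.isin(set(event_filter)).to_numpy()
    calls = calls.loc[keep].reset_index(drop=True)
    st = st[keep]
    if len(calls) == 0:
        return states_long

    ci, bi = _overlap_pairs(calls, grid)
    if len(ci) == 0:
        return states_long
    bstart = bins["start"].to_numpy()[bi]
    bend = bins["end"].to_numpy()[bi]
    ov_start = np.maximum(calls["start"].to_numpy()[ci], bstart)
    ov_end = np.minimum(calls["end"].to_numpy()[ci], bend)
    pat_codes = patients.get_indexer(calls["patient"].to_numpy()[ci])
    state_codes = (st[ci] == "D").astype(np.int64)  # 0 = A, 1 = D
    group = (pat_codes * n_bins + bi) * 2 + state_codes
    cover, uniq = _union_coverage(group, ov_start, ov_end)

    bin_len = (bins["end"] - bins["start"]).to_numpy()
    a_cov = np.zeros((len(patients), n_bins))
    d_cov = np.zeros((len(patients), n_bins))
    u_state = uniq % 2
    u_bin = (uniq // 2) % n_bins
    u_pat = uniq // (2 * n_bins)
    a_sel = u_state == 0
    a_cov[u_pat[a_sel], u_bin[a_sel]] = cover[a_sel]
    d_cov[u_pat[~a_sel], u_bin[~a_sel]] = cover[~a_sel]

    need = overlap_frac * bin_len[None, :]
    a_ok = a_cov >= need
    d_ok = d_cov >= need
    state = np.full(a_cov.shape, "N", dtype="U1")
    state[a_ok] = "A"
    state[d_ok & ~a_ok] = "D"
    both = a_ok & d_ok
    if both.any():
        d_wins = both & (d_cov > a_cov)
        state[d_wins] = "D"
        ties = both & (d_cov == a_cov)
        if ties.any():
            logger.warning(
                "%d (patient, bin) pair(s) tie between amplified and deleted "
                "coverage; reported as amplified", int(ties.sum())
            )
    states_long["state"] = state.reshape(-1)
    return states_long


def states_matrix(states: pd.DataFrame) -> pd.DataFrame:
    """Long (patient, bin_id, state) -> wide bins x patients matrix."""
    return states.pivot(index="bin_id", columns="patient", values="state")


def assign_genes_to_bins(genes: pd.DataFrame, grid: SegmentGrid) -> pd.Series:
    """Unique gene -> bin_id map by gene midpoint (NaN when outside the grid)."""
    if grid.scale == "gene":
        ids = grid.bin_ids
        return pd.Series(
            [g if g in set(ids) else np.nan for g in genes["gene"]],
            index=genes["gene"], name="bin_id",
        )
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    return pd.Series(
        assign_positions_to_bins(genes["chrom"].to_numpy(), mid, grid),
        index=genes["gene"], name="bin_id",
    )


def assign_positions_to_bins(chrom, pos, grid: SegmentGrid) -> np.ndarray:
    """bin_id per position for non-overlapping grids (NaN when unassigned)."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    out = np.full(len(pos), np.nan, dtype=object)
    for c, bgrp in grid.bins.groupby("chrom", sort=False):
        sel = chrom == c
        if not sel.any():
            continue
        starts = bgrp["start"].to_numpy()
        ends = bgrp["end"].to_numpy()
        ids = bgrp["bin_id"].to_numpy()
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        inside = np.zeros(sel.sum(), dtype=bool)
        inside[ok] = pos[sel][ok] < ends[idx[ok]]
        assigned = np.full(sel.sum(), np.nan, dtype=object)
        assigned[inside] = ids[idx[inside]]
        out[sel] = assigned
    return out
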