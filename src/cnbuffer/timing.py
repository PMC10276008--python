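"""Mutation–amplification relative timing from allele-specific copy number.

A clonal mutation on a segment with allele-specific copy number
(cn_major : cn_minor) is carried by ``m`` genome copies (its multiplicity).
A mutation with m equal to the major allele count predates the amplification
(early); m below the major allele count means it arose after (late). A
mutation is *buffered* when the segment retains at least two unmutated
copies: (cn_major + cn_minor) − m >= 2.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genome import drop_sex_chromosomes

logger = logging.getLogger(__name__)


def estimate_multiplicity(vaf, depth, cn_major, cn_minor, purity):
    """Clonal multiplicity from VAF, purity and allele-specific copy number.

    m = round( vaf * (purity * (cn_major + cn_minor) + 2 * (1 - purity))
               / purity ),
    with round-half-even ties and the result clamped to [1, cn_major].
    Subclonal mutations are out of scope.
    """
    vaf = np.asarray(vaf, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise ValueError("purity must lie in (0, 1]")
    if np.any((vaf <= 0) | (vaf > 1)):
        raise ValueError("vaf must lie in (0, 1]")
    cn_total = np.asarray(cn_major) + np.asarray(cn_minor)
    m_raw = vaf * (purity * cn_total + 2.0 * (1.0 - purity)) / purity
    m = np.rint(m_raw).astype(int)  # round-half-even for determinism
    return np.clip(m, 1, np.asarray(cn_major, dtype=int))


def classify_timing(m, cn_major):
    """'early' iff m equals the major allele count, 'late' iff below it."""
    m = np.asarray(m, dtype=int)
    cn_major = np.asarray(cn_major, dtype=int)
    if np.any(m > cn_major) or np.any(m < 1):
        raise ValueError("multiplicity must satisfy 1 <= m <= cn_major")
    out = np.where(m == cn_major, "early", "late")
    return out if out.shape else str(out)


def classify_buffered(m, cn_major, cn_minor):
    """Buffered iff at least two copies remain unmutated."""
    m = np.asarray(m, dtype=int)
    total = np.asarray(cn_major, dtype=int) + np.asarray(cn_minor, dtype=int)
    out = (total - m) >= 2
    return out if out.shape else bool(out)


def _match_segments(muts: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Attach the containing allele-specific segment to each mutation."""
    seg_cols = ["cn_major", "cn_minor", "purity"]
    pieces = []
    for (patient, chrom), mgrp in muts.groupby(["patient", "chrom"], sort=False):
        sgrp = segments[(segments["patient"] == patient)
                        & (segments["chrom"] == chrom)]
        if len(sgrp) == 0:
            continue
        sgrp = sgrp.sort_values("start")
        starts = sgrp["start"].to_numpy()
        ends = sgrp["end"].to_numpy()
        idx = np.searchsorted(starts, mgrp["pos"].to_numpy(), side="right") - 1
        ok = (idx >= 0)
        ok[ok] = mgrp["pos"].to_numpy()[ok] < ends[idx[ok]]
        matched = mgrp.loc[ok].copy()
        for col in seg_cols:
            matched[col] = sgrp[col].to_numpy()[idx[ok]]
        pieces.append(matched)
    if not pieces:
        return muts.iloc[0:0].assign(**{c: [] for c in seg_cols})
    return pd.concat(pieces, ignore_index=True)


def multiplicity_calls(
    muts: pd.DataFrame,
    segments: pd.DataFrame,
    *,
    min_vaf: float = 0.0,
) -> pd.DataFrame:
    """Per-mutation multiplicity, early/late and buffered calls.

    Mutations are joined to the patient's allele-specific segments by
    position; unmatched or VAF/depth-less records are dropped with a log note.
    Sex chromosomes are excluded, mirroring the scoring modules.
    """
    muts = drop_sex_chromosomes(muts)
    segments = drop_sex_chromosomes(segments)
    usable = muts.dropna(subset=["vaf", "depth"])
    usable = usable[usable["vaf"] > min_vaf]
    dropped = len(muts) - len(usable)
    if dropped:
        logger.info("dropped %d mutation(s) without usable VAF/depth", dropped)
    matched = _match_segments(usable, segments)
    if len(matched) == 0:
        return matched.assign(m=[], timing=[], buffered=[])
    m = estimate_multiplicity(
        matched["vaf"].to_numpy(), matched["depth"].to_numpy(),
        matched["cn_major"].to_numpy(), matched["cn_minor"].to_numpy(),
        matched["purity"].to_numpy(),
    )
    matched["m"] = m
    matched["timing"] = classify_timing(m, matched["cn_major"].to_numpy())
    matched["buffered"] = classify_buffered(
        m, matched["cn_major"].to_numpy(), matched["cn_minor"].to_numpy()
    )
    matched["cn_class"] = (matched["cn_major"].astype(int).astype(str) + ":"
                           + matched["cn_minor"].astype(int).astype(str))
    return matched.reset_index(drop=True)


def timing_association(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Coding-vs-lateness association per allele-specific CN class.

    For each CN class (e.g. '2:0', '3:1') a 2x2 contingency
    (coding / non-coding) x (early / late) is tested with a two-sided Fisher
    exact test; classes with a degenerate margin are skipped with a note. The
    pooled summary reports the overall early fraction both mutation-weighted
    and as an unweighted mean over classes.
    """
    rows = []
    class_early = {}
    for cn_class, grp in calls.groupby("cn_class", sort=True):
        coding = grp["is_coding"].astype(bool)
        early = grp["timing"] == "early"
        table = np.array([
            [int((coding & early).sum()), int((coding & ~early).sum())],
            [int((~coding & early).sum()), int((~coding & ~early).sum())],
        ])
        class_early[cn_class] = float(early.mean())
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            rows.append({"cn_class": cn_class, "n": len(grp),
                         "odds_ratio": np.nan, "p_value": np.nan,
                         "note": "degenerate margin"})
            continue
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"cn_class": cn_class, "n": len(grp),
                     "coding_early": table[0, 0], "coding_late": table[0, 1],
                     "noncoding_early": table[1, 0], "noncoding_late": table[1, 1],
                     "odds_ratio": float(odds), "p_value": float(p), "note": ""})
    pooled = {
        "early_fraction_weighted": float((calls["timing"] == "early").mean())
        if len(calls) else float("nan"),
        "early_fraction_classes": float(np.mean(list(class_early.values())))
        if class_early else float("nan"),
        "n_mutations": int(len(calls)),
        "n_classes": len(class_early),
    }
    return pd.DataFrame(rows), pooled
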