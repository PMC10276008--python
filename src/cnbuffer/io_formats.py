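"""Readers/writers for the external tables the pipeline touches.

External files use the field's 1-based inclusive conventions (SEG, MAF-like
TSV); everything internal is 0-based half-open. The conversion happens here and
nowhere else.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBuild

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared dialect (missing columns, bad types)."""


class CoordinateValidationError(ValueError):
    """Rows whose coordinates are inconsistent with the genome build."""


# ---------------------------------------------------------------------------
# MAF Variant_Classification vocabulary -> (is_coding, is_synonymous).
# The mapping is fixed and documented; unknown terms fall back to non-coding
# with a warning.
CONSEQUENCE_MAP: dict[str, tuple[bool, bool]] = {
    "Missense_Mutation": (True, False),
    "Nonsense_Mutation": (True, False),
    "Nonstop_Mutation": (True, False),
    "Silent": (True, True),
    "Frame_Shift_Del": (True, False),
    "Frame_Shift_Ins": (True, False),
    "In_Frame_Del": (True, False),
    "In_Frame_Ins": (True, False),
    "Translation_Start_Site": (True, False),
    # positions outside the CDS: retained for the timing analysis only
    "Splice_Site": (False, False),
    "Splice_Region": (False, False),
    "Intron": (False, False),
    "3'UTR": (False, False),
    "5'UTR": (False, False),
    "3'Flank": (False, False),
    "5'Flank": (False, False),
    "IGR": (False, False),
    "RNA": (False, False),
    "lincRNA": (False, False),
    "Targeted_Region": (False, False),
}

SEG_COLUMNS = {"Sample": "patient", "Chromosome": "chrom", "Start": "start",
               "End": "end", "Segment_Mean": "segment_mean"}

MUTATION_OPTIONAL_COLUMNS = (
    "cadd", "polyphen", "aggregation_score", "aggregation_fold_change",
    "vaf", "depth",
)


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def read_seg(path, build: GenomeBuild | None = None) -> pd.DataFrame:
    """Read a SEG file (tab-separated, 1-based inclusive coordinates).

    Returns a frame with columns patient, chrom, start, end, segment_mean in
    0-based half-open coordinates. Malformed rows raise with line numbers;
    unknown chromosomes raise listing the offenders.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"Chromosome": str},
                      float_precision="round_trip")
    _require(raw, ["Sample", "Chromosome", "Start", "End", "Segment_Mean"], "SEG")
    df = raw.rename(columns=SEG_COLUMNS)[list(SEG_COLUMNS.values())].copy()
    for col in ("start", "end"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # header is line 1
            raise FormatError(f"SEG: unparseable {col} at line(s) {lines}")
        df[col] = converted.astype("int64")
    df["segment_mean"] = pd.to_numeric(df["segment_mean"])
    # 1-based inclusive -> 0-based half-open
    df["start"] = df["start"] - 1
    bad = df["end"] <= df["start"]
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise CoordinateValidationError(f"SEG: end < start at line(s) {lines}")
    if build is not None:
        unknown = sorted(set(df["chrom"]) - set(build.chromosomes))
        if unknown:
            raise CoordinateValidationError(f"SEG: unknown chromosome(s) {unknown}")
        lengths = df["chrom"].map(build.chrom_lengths)
        over = df["end"] > lengths
        if over.any():
            lines = (np.flatnonzero(over.to_numpy()) + 2).tolist()
            raise CoordinateValidationError(
                f"SEG: segment end beyond chromosome length at line(s) {lines}"
            )
    return df.reset_index(drop=True)


def write_seg(df: pd.DataFrame, path) -> None:
    """Write CNA calls back to the 1-based inclusive SEG dialect."""
    out = pd.DataFrame({
        "Sample": df["patient"],
        "Chromosome": df["chrom"],
        "Start": df["start"] + 1,
        "End": df["end"],
        # shortest round-trip repr so read_seg(write_seg(x)) is bit-identical
        "Segment_Mean": [repr(float(v)) for v in df["segment_mean"]],
    })
    out.to_csv(path, sep="\t", index=False)


def read_mutations(path, build: GenomeBuild | None = None) -> pd.DataFrame:
    """Read a MAF-like TSV with patient/chrom/pos/gene/consequence columns.

    ``is_coding`` and ``is_synonymous`` are derived from the consequence
    vocabulary; positions are converted to 0-based. Sex-chromosome records are
    kept here (downstream filters drop them).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    _require(df, ["patient", "chrom", "pos", "gene", "consequence"], "mutations")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise FormatError(f"mutations: unparseable pos at line(s) {lines}")
    out = pd.DataFrame({
        "patient": df["patient"],
        "chrom": df["chrom"].astype(str),
        "pos": pos.astype("int64") - 1,
        "gene": df["gene"].where(df["gene"].notna(), None),
    })
    unknown_terms = sorted(set(df["consequence"]) - set(CONSEQUENCE_MAP))
    if unknown_terms:
        warnings.warn(
            f"unknown consequence term(s) treated as non-coding: {unknown_terms}",
            stacklevel=2,
        )
    mapped = df["consequence"].map(lambda t: CONSEQUENCE_MAP.get(t, (False, False)))
    out["is_coding"] = [m[0] for m in mapped]
    out["is_synonymous"] = [m[1] for m in mapped]
    for col in MUTATION_OPTIONAL_COLUMNS:
        if col in df.columns:
            out[col] = pd.to_numeric(df[col], errors="coerce")
    if build is not None:
        known = out["chrom"].isin(build.chromosomes)
        lengths = out.loc[known, "chrom"].map(build.chrom_lengths)
        over = out.loc[known, "pos"] >= lengths
        if over.any():
            raise CoordinateValidationError(
                f"mutations: {int(over.sum())} position(s) beyond chromosome length"
            )
    return out


def read_gene_table(path) -> pd.DataFrame:
    """Gene annotation TSV (1-based inclusive start) -> internal frame."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require(df, ["gene", "chrom", "start", "end", "coding_bp"], "gene table")
    df = df.copy()
    df["start"] = df["start"].astype("int64") - 1
    df["end"] = df["end"].astype("int64")
    bad = df["coding_bp"] > (df["end"] - df["start"])
    if bad.any():
        raise CoordinateValidationError(
            f"gene table: coding_bp exceeds gene length for {df.loc[bad, 'gene'].tolist()}"
        )
    for col in ("is_og", "is_tsg", "is_go", "is_common_essential", "is_nonessential"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def deduplicate_mutations(muts: pd.DataFrame) -> pd.DataFrame:
    """Drop exact (patient, chrom, pos) repeats, logging the removed count."""
    before = len(muts)
    out = muts.drop_duplicates(subset=["patient", "chrom", "pos"]).reset_index(drop=True)
    removed = before - len(out)
    if removed:
        logger.info("deduplicated %d repeated mutation row(s)", removed)
    return out


@dataclass(frozen=True)
class CoverageMask:
    """Intervals deemed uncovered by the CNA assay (0-based half-open, merged)."""

    intervals: pd.DataFrame  # chrom, start, end; normalized

    @classmethod
    def from_intervals(cls, intervals: pd.DataFrame) -> "CoverageMask":
        if len(intervals) == 0:
            return cls(pd.DataFrame(columns=["chrom", "start", "end"]))
        df = intervals[["chrom", "start", "end"]].sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        )
        merged: list[tuple] = []
        for chrom, grp in df.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        return cls(pd.DataFrame(merged, columns=["chrom", "start", "end"]))

    def covers(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean array: position falls inside a masked interval."""
        hit = np.zeros(len(pos), dtype=bool)
        if len(self.intervals) == 0:
            return hit
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos)
        for c, grp in self.intervals.groupby("chrom", sort=False):
            sel = chrom == c
            if not sel.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            idx = np.searchsorted(starts, pos[sel], side="right") - 1
            ok = idx >= 0
            inside = np.zeros(sel.sum(), dtype=bool)
            inside[ok] = pos[sel][ok] < ends[idx[ok]]
            hit[sel] = inside
        return hit


def read_bed_mask(path) -> CoverageMask:
    """Coverage mask from a 3-column BED (0-based half-open already)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], dtype={0: str})
    return CoverageMask.from_intervals(df)


def apply_coverage_mask(muts: pd.DataFrame, mask: CoverageMask) -> pd.DataFrame:
    """Keep only mutations outside every masked interval (idempotent)."""
    hit = mask.covers(muts["chrom"].to_numpy(), muts["pos"].to_numpy())
    removed = int(hit.sum())
    if removed:
        logger.info("coverage mask removed %d mutation(s)", removed)
    return muts.loc[~hit].reset_index(drop=True)
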