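"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive everything from first principles with
per-base-pair loops on tiny genomes, so they stay independent of the
vectorized implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# brute-force scoring oracle on per-base-countable genomes


def brute_force_states(cna, patients, bins, amp_cut=0.2, overlap_frac=0.5):
    """Per-base counting re-derivation of (patient, bin) states."""
    out = {}
    for pat in patients:
        calls = cna[cna["patient"] == pat]
        for _, b in bins.iterrows():
            positions = range(int(b["start"]), int(b["end"]))
            amp_cover = 0
            del_cover = 0
            for bp in positions:
                a = d = False
                for _, call in calls.iterrows():
                    if call["chrom"] != b["chrom"]:
                        continue
                    if call["start"] <= bp < call["end"]:
                        if call["segment_mean"] > amp_cut:
                            a = True
                        elif call["segment_mean"] < -amp_cut:
                            d = True
                amp_cover += a
                del_cover += d
            need = overlap_frac * (b["end"] - b["start"])
            a_ok = amp_cover >= need
            d_ok = del_cover >= need
            if a_ok and d_ok:
                state = "D" if del_cover > amp_cover else "A"
            elif a_ok:
                state = "A"
            elif d_ok:
                state = "D"
            else:
                state = "N"
            out[(pat, b["bin_id"])] = state
    return out


def brute_force_scores(cna, muts, patients, bins, coding_bp,
                       amp_cut=0.2, overlap_frac=0.5):
    """Independent recount of per-bin frequencies and μ (plain loops)."""
    states = brute_force_states(cna, patients, bins, amp_cut, overlap_frac)
    rows = []
    for _, b in bins.iterrows():
        n_a = sum(states[(p, b["bin_id"])] == "A" for p in patients)
        n_d = sum(states[(p, b["bin_id"])] == "D" for p in patients)
        n_n = len(patients) - n_a - n_d
        n_mut = 0
        for _, m in muts.iterrows():
            if not m["is_coding"] or m["patient"] not in patients:
                continue
            if m["chrom"] != b["chrom"] or not b["start"] <= m["pos"] < b["end"]:
                continue
            if states[(m["patient"], b["bin_id"])] == "N":
                n_mut += 1
        cb = coding_bp[b["bin_id"]]
        if n_mut > 0 and n_n > 0 and cb > 0:
            mu = math.log10(n_mut / (cb * n_n))
        else:
            mu = float("nan")
        rows.append({"bin_id": b["bin_id"], "amp_freq": n_a / len(patients),
                     "del_freq": n_d / len(patients), "mu": mu,
                     "n_A": n_a, "n_D": n_d, "n_N": n_n,
                     "n_mut_neutral": n_mut})
    return pd.DataFrame(rows)


def random_toy_cohort(seed):
    """Tiny random cohort on a per-base-countable genome (2 chroms x 300 bp)."""
    from cnbuffer.genome import GenomeBuild
    from cnbuffer.segmentation import build_grid

    rng = np.random.default_rng(seed)
    build = GenomeBuild({"c1": 300, "c2": 300}, {"c1": 150, "c2": 140})
    grid = build_grid(build, "fixed", bin_size=100)
    n_pat = int(rng.integers(2, 20))
    patients = [f"p{i}" for i in range(n_pat)]
    cna_rows = []
    for pat in patients:
        for _ in range(int(rng.integers(0, 5))):
            chrom = rng.choice(["c1", "c2"])
            start = int(rng.integers(0, 280))
            end = int(rng.integers(start + 1, 301))
            mean = float(rng.normal(0, 0.5))
            cna_rows.append((pat, chrom, start, end, mean))
    cna = pd.DataFrame(cna_rows or None,
                       columns=["patient", "chrom", "start", "end", "segment_mean"])
    n_mut = int(rng.integers(0, 200))
    muts = pd.DataFrame({
        "patient": rng.choice(patients, n_mut),
        "chrom": rng.choice(["c1", "c2"], n_mut),
        "pos": rng.integers(0, 300, n_mut),
        "gene": "g",
        "is_coding": rng.random(n_mut) < 0.8,
        "is_synonymous": False,
    })
    coding_bp = pd.Series(rng.integers(10, 60, len(grid.bins)).astype(float),
                          index=grid.bins["bin_id"])
    return build, grid, patients, cna, muts, coding_bp


@pytest.fixture
def toy_scoring_inputs():
    return random_toy_cohort(12345)
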