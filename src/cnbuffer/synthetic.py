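"""Synthetic tumor cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a block-constant log-normal regional mutation-rate field λ (block length
  ``block_length``), so the "optimal segment length" sweep has a known truth;
* a CNA event-size mixture (focal / arm / chromosomal) with amplification
  placement tilted by λ**coupling_beta — the tunable amplification–mutation
  coupling;
* gene-property covariates (pLI, GHIS, expression, OG/TSG/GO flags, CRISPR
  effect) and optional restriction of the coupling to a gene stratum;
* allele-specific copy number with known per-mutation multiplicities and
  binomial read sampling for VAF.

Everything is a deterministic function of ``SimConfig.seed``. The truth
record stores λ, per-(patient, bin) states computed by the generator's own
interval arithmetic, and per-mutation true multiplicity and timing labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBuild, simulation_build
from .io_formats import write_seg
from .segmentation import SegmentGrid, build_grid

UNIT = 1_000_000  # λ-field resolution, bp

#: allele-specific CN mixture for amplified events (total CN >= 3 so the
#: log2-ratio clears the +0.2 cutoff at any purity >= 0.6): (major, minor) -> weight
AMP_CN_MIX = (((2, 1), 0.45), ((3, 1), 0.15), ((2, 2), 0.15),
              ((3, 0), 0.15), ((4, 0), 0.05), ((4, 2), 0.05))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    n_patients: int = 100
    n_chromosomes: int = 3
    chrom_length: int = 100_000_000
    arm_fraction: float = 0.5
    # gene layout
    genes_per_mbp: float = 1.0
    gene_length: int = 30_000
    coding_bp_per_gene: int = 1_500
    # regional mutation-rate field
    block_length: int = 3_000_000
    block_offset: int = 0
    rate_sigma: float = 0.8
    # amplification–mutation coupling
    coupling_beta: float = 0.0
    stratum_column: str | None = None   # e.g. "pli": coupling only via these genes
    stratum_threshold: float = 0.2
    # mutation process (coding mutations per coding Mbp per patient)
    base_mut_rate: float = 150.0
    synonymous_fraction: float = 0.25
    noncoding_rate_factor: float = 0.3
    # CNA event process
    events_per_patient: float = 8.0
    event_mix: tuple = (0.80, 0.15, 0.05)   # focal, arm, chromosomal
    focal_length_log_mean: float = float(np.log(5_000_000))
    focal_length_log_sd: float = 0.6
    amp_fraction: float = 0.67
    # sequencing / timing
    purity_range: tuple = (0.6, 1.0)
    depth: int = 100
    early_fraction: float = 0.5
    # analysis grid stored in the truth record
    grid_bin_size: int = 3_000_000

    def __post_init__(self) -> None:
        if self.chrom_length % UNIT:
            raise ValueError("chrom_length must be a multiple of 1 Mbp")
        if abs(sum(self.event_mix) - 1.0) > 1e-9:
            raise ValueError("event_mix proportions must sum to 1")
        if self.coupling_beta < 0 or self.base_mut_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 < self.arm_fraction < 1:
            raise ValueError("arm_fraction must be in (0, 1)")


@dataclass
class Cohort:
    cna: pd.DataFrame
    mutations: pd.DataFrame
    genes: pd.DataFrame
    allele_segments: pd.DataFrame
    truth: dict
    build: GenomeBuild
    config: SimConfig


def _lambda_field(cfg: SimConfig, rng: np.random.Generator, build: GenomeBuild):
    """Block-constant log-normal rate per 1 Mbp unit; returns a unit table."""
    rows = []
    shift = cfg.block_offset // UNIT  # rate domains need not start at the origin
    for chrom in build.autosomes:
        n_units = build.chrom_length(chrom) // UNIT
        n_blocks = int(np.ceil((n_units + shift) * UNIT / cfg.block_length)) + 1
        block_rates = rng.lognormal(mean=0.0, sigma=cfg.rate_sigma, size=n_blocks)
        units_per_block = cfg.block_length // UNIT
        lam = np.repeat(block_rates, units_per_block)[shift:shift + n_units]
        for k in range(n_units):
            rows.append((chrom, k * UNIT, (k + 1) * UNIT, lam[k]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "lam"])


def _make_genes(cfg: SimConfig, rng: np.random.Generator, build: GenomeBuild,
                lam: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chrom in build.autosomes:
        length = build.chrom_length(chrom)
        n_genes = int(round(cfg.genes_per_mbp * length / 1e6))
        spacing = length // n_genes
        offset = max(0, (spacing - cfg.gene_length) // 2)
        for i in range(n_genes):
            start = i * spacing + offset
            rows.append((f"{chrom}_g{i:04d}", chrom, start,
                         start + cfg.gene_length, cfg.coding_bp_per_gene))
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "coding_bp"])
    n = len(genes)
    # bimodal pLI stand-in; paper-style cutoffs split the genes roughly in half
    lo = rng.random(n) < 0.5
    pli = np.where(lo, rng.uniform(0.0, 0.2, n), rng.uniform(0.2, 1.0, n))
    genes["pli"] = pli
    genes["ghis"] = np.clip(rng.normal(0.5, 0.15, n), 0, 1)
    expressed = rng.random(n) >= 0.1
    genes["median_tpm"] = np.where(expressed, rng.lognormal(2.0, 1.0, n), 0.0)
    genes["is_og"] = rng.random(n) < 0.05
    genes["is_tsg"] = rng.random(n) < 0.05
    genes["is_go"] = rng.random(n) < 0.10
    u = rng.random(n)
    genes["is_common_essential"] = u < 0.05
    genes["is_nonessential"] = u > 0.5
    eff = rng.normal(-0.3, 0.3, n)
    eff[genes["is_common_essential"]] = rng.normal(
        -1.0, 0.2, int(genes["is_common_essential"].sum()))
    eff[genes["is_nonessential"]] = rng.normal(
        0.0, 0.15, int(genes["is_nonessential"].sum()))
    genes["crispr_effect"] = eff
    mid_unit = ((genes["start"] + genes["end"]) // 2 // UNIT).to_numpy()
    lam_by_chrom = {c: g["lam"].to_numpy() for c, g in lam.groupby("chrom")}
    genes["_lam"] = [lam_by_chrom[c][u] for c, u in zip(genes["chrom"], mid_unit)]
    return genes


def _sample_events(cfg: SimConfig, rng: np.random.Generator, build: GenomeBuild,
                   lam: pd.DataFrame):
    """Per-patient CNA events, resolved to non-overlapping segments."""
    chroms = list(build.autosomes)
    unit_chrom = lam["chrom"].to_numpy()
    unit_start = lam["start"].to_numpy()
    lam_vals = lam["lam"].to_numpy()
    amp_weight = lam_vals ** cfg.coupling_beta
    amp_prob = amp_weight / amp_weight.sum()
    # whole-arm / whole-chromosome aneuploidies arise from segregation errors,
    # not the regional mutation field: their placement is uniform and only
    # focal amplification placement carries the λ**beta coupling
    arm_ids = []
    for chrom in chroms:
        bound = build.arm_boundary(chrom)
        length = build.chrom_length(chrom)
        arm_ids.append((chrom, 0, bound))
        arm_ids.append((chrom, bound, length))

    cn_pairs = [p for p, _ in AMP_CN_MIX]
    cn_weights = np.array([w for _, w in AMP_CN_MIX])
    cn_weights = cn_weights / cn_weights.sum()

    purity = rng.uniform(*cfg.purity_range, size=cfg.n_patients)
    events = []  # patient_idx, chrom, start, end, is_amp, major, minor
    for p in range(cfg.n_patients):
        n_ev = rng.poisson(cfg.events_per_patient)
        for _ in range(n_ev):
            klass = rng.choice(3, p=np.asarray(cfg.event_mix))
            is_amp = rng.random() < cfg.amp_fraction
            if klass == 2:  # chromosomal
                chrom = chroms[rng.integers(len(chroms))]
                start, end = 0, build.chrom_length(chrom)
            elif klass == 1:  # arm
                chrom, start, end = arm_ids[rng.integers(len(arm_ids))]
            else:  # focal
                if is_amp:
                    u = rng.choice(len(lam_vals), p=amp_prob)
                else:
                    u = rng.integers(len(lam_vals))
                chrom = unit_chrom[u]
                center = unit_start[u] + UNIT // 2
                length = int(np.clip(
                    rng.lognormal(cfg.focal_length_log_mean, cfg.focal_length_log_sd),
                    1_000_000, 60_000_000))
                start = max(0, center - length // 2)
                end = min(build.chrom_length(chrom), center + length // 2)
            if is_amp:
                major, minor = cn_pairs[rng.choice(len(cn_pairs), p=cn_weights)]
            else:
                major, minor = 1, 0
            events.append((p, chrom, start, end, is_amp, major, minor))

    # resolve overlaps per (patient, chrom): earlier start wins, later trimmed
    resolved = []
    events.sort(key=lambda ev: (ev[0], ev[1], ev[2], ev[3]))
    prev_key, running_end = None, 0
    for p, chrom, start, end, is_amp, major, minor in events:
        key = (p, chrom)
        if key != prev_key:
            prev_key, running_end = key, 0
        start = max(start, running_end)
        if start >= end:
            continue
        running_end = end
        resolved.append((p, chrom, start, end, is_amp, major, minor))
    return resolved, purity


def _truth_states(cfg: SimConfig, build: GenomeBuild, grid: SegmentGrid,
                  resolved) -> pd.DataFrame:
    """Bin states recomputed by the generator's own interval arithmetic."""
    bins = grid.bins
    n_bins = len(bins)
    bin_index = {c: (g["start"].to_numpy(), g["end"].to_numpy(), g.index.to_numpy())
                 for c, g in bins.groupby("chrom", sort=False)}
    a_cov = np.zeros((cfg.n_patients, n_bins))
    d_cov = np.zeros((cfg.n_patients, n_bins))
    for p, chrom, start, end, is_amp, _major, _minor in resolved:
        bstart, bend, brows = bin_index[chrom]
        lo = np.searchsorted(bend, start, side="right")
        hi = np.searchsorted(bstart, end, side="left")
        if hi <= lo:
            continue
        ov = (np.minimum(bend[lo:hi], end) - np.maximum(bstart[lo:hi], start))
        target = a_cov if is_amp else d_cov
        target[p, brows[lo:hi]] += ov
    bin_len = (bins["end"] - bins["start"]).to_numpy()
    need = 0.5 * bin_len[None, :]
    a_ok = a_cov >= need
    d_ok = d_cov >= need
    state = np.full(a_cov.shape, "N", dtype="U1")
    state[a_ok] = "A"
    state[d_ok & ~a_ok] = "D"
    state[a_ok & d_ok & (d_cov > a_cov)] = "D"
    idx = pd.MultiIndex.from_product(
        [[f"P{p:03d}" for p in range(cfg.n_patients)], bins["bin_id"]],
        names=["patient", "bin_id"])
    out = pd.DataFrame(index=idx).reset_index()
    out["state"] = state.reshape(-1)
    return out


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate one cohort (CNA, mutations, genes, allele CN, truth record)."""
    rng = np.random.default_rng(cfg.seed)
    build = simulation_build(cfg.n_chromosomes, cfg.chrom_length, cfg.arm_fraction)
    lam = _lambda_field(cfg, rng, build)
    genes = _make_genes(cfg, rng, build, lam)
    resolved, purity = _sample_events(cfg, rng, build, lam)
    patients = [f"P{p:03d}" for p in range(cfg.n_patients)]

    # ----- CNA calls (SEG-style log2 ratios, purity-attenuated)
    cna_rows = []
    for p, chrom, start, end, is_amp, major, minor in resolved:
        cn_total = major + minor
        ratio = (purity[p] * cn_total + 2 * (1 - purity[p])) / 2.0
        seg_mean = float(np.log2(ratio) + rng.normal(0, 0.02))
        cna_rows.append((patients[p], chrom, start, end, seg_mean))
    cna = pd.DataFrame(cna_rows,
                       columns=["patient", "chrom", "start", "end", "segment_mean"])

    # ----- allele-specific segments: events plus the diploid complement
    seg_rows = []
    by_patient_chrom: dict = {}
    for p, chrom, start, end, is_amp, major, minor in resolved:
        by_patient_chrom.setdefault((p, chrom), []).append((start, end, major, minor))
    for p in range(cfg.n_patients):
        for chrom in build.autosomes:
            length = build.chrom_length(chrom)
            evs = sorted(by_patient_chrom.get((p, chrom), []))
            cursor = 0
            for start, end, major, minor in evs:
                if start > cursor:
                    seg_rows.append((patients[p], chrom, cursor, start, 1, 1, purity[p]))
                seg_rows.append((patients[p], chrom, start, end, major, minor, purity[p]))
                cursor = end
            if cursor < length:
                seg_rows.append((patients[p], chrom, cursor, length, 1, 1, purity[p]))
    allele_segments = pd.DataFrame(
        seg_rows, columns=["patient", "chrom", "start", "end",
                           "cn_major", "cn_minor", "purity"])

    # ----- coding mutations: per (gene, patient) Poisson counts
    mean_lam = float(lam["lam"].mean())
    gene_lam = genes["_lam"].to_numpy().copy()
    if cfg.stratum_column is not None:
        outside = genes[cfg.stratum_column].to_numpy() <= cfg.stratum_threshold
        gene_lam[outside] = mean_lam
    rate = (cfg.base_mut_rate * 1e-6
            * genes["coding_bp"].to_numpy()[:, None] * gene_lam[:, None]
            * np.ones((1, cfg.n_patients)))
    counts = rng.poisson(rate)
    g_idx, p_idx = np.nonzero(counts)
    reps = counts[g_idx, p_idx]
    g_idx = np.repeat(g_idx, reps)
    p_idx = np.repeat(p_idx, reps)
    gstart = genes["start"].to_numpy()[g_idx]
    glen = (genes["end"] - genes["start"]).to_numpy()[g_idx]
    pos = gstart + rng.integers(0, glen)
    n_cod = len(pos)
    coding = pd.DataFrame({
        "patient": np.asarray(patients, dtype=object)[p_idx],
        "chrom": genes["chrom"].to_numpy()[g_idx],
        "pos": pos,
        "gene": genes["gene"].to_numpy()[g_idx],
        "is_coding": True,
        "is_synonymous": rng.random(n_cod) < cfg.synonymous_fraction,
        "cadd": rng.lognormal(np.log(3.5), 0.6, n_cod),
        "polyphen": rng.beta(0.5, 0.5, n_cod),
        "aggregation_score": rng.exponential(3000.0, n_cod),
        "aggregation_fold_change": rng.lognormal(0.0, 0.3, n_cod),
    })

    # ----- non-coding mutations, placed by the same rate field
    expected_coding_per_patient = float(rate.sum(axis=0).mean())
    n_nc = rng.poisson(cfg.noncoding_rate_factor * expected_coding_per_patient,
                       size=cfg.n_patients)
    lam_vals = lam["lam"].to_numpy()
    unit_prob = lam_vals / lam_vals.sum()
    nc_pieces = []
    for p in range(cfg.n_patients):
        if n_nc[p] == 0:
            continue
        u = rng.choice(len(lam_vals), size=n_nc[p], p=unit_prob)
        nc_pieces.append(pd.DataFrame({
            "patient": patients[p],
            "chrom": lam["chrom"].to_numpy()[u],
            "pos": lam["start"].to_numpy()[u] + rng.integers(0, UNIT, size=n_nc[p]),
            "gene": None,
            "is_coding": False,
            "is_synonymous": False,
            "cadd": np.nan, "polyphen": np.nan,
            "aggregation_score": np.nan, "aggregation_fold_change": np.nan,
        }))
    mutations = pd.concat([coding, *nc_pieces], ignore_index=True)
    mutations = mutations.sort_values(
        ["patient", "chrom", "pos"], kind="mergesort").reset_index(drop=True)

    # ----- allele-specific state, true multiplicity and VAF per mutation
    purity_by_patient = dict(zip(patients, purity))
    seg_lookup = {
        key: grp.sort_values("start")[["start", "end", "cn_major", "cn_minor"]]
        .to_numpy()
        for key, grp in allele_segments.groupby(["patient", "chrom"], sort=False)
    }
    major = np.ones(len(mutations), dtype=int)
    minor = np.ones(len(mutations), dtype=int)
    for key, grp in mutations.groupby(["patient", "chrom"], sort=False):
        segs = seg_lookup[key]
        idx = np.searchsorted(segs[:, 0], grp["pos"].to_numpy(), side="right") - 1
        major[grp.index] = segs[idx, 2].astype(int)
        minor[grp.index] = segs[idx, 3].astype(int)
    amplified = major >= 2
    is_early = rng.random(len(mutations)) < cfg.early_fraction
    true_m = np.where(amplified & is_early, major, 1)
    cn_total = major + minor
    pur = mutations["patient"].map(purity_by_patient).to_numpy()
    evaf = true_m * pur / (pur * cn_total + 2 * (1 - pur))
    alt = rng.binomial(cfg.depth, evaf)
    mutations["vaf"] = np.maximum(alt, 1) / cfg.depth  # zero-read draws floored
    mutations["depth"] = cfg.depth
    true_timing = np.where(true_m == major, "early", "late")

    grid = build_grid(build, "fixed", bin_size=cfg.grid_bin_size)
    truth = {
        "lambda": lam,
        "mean_lambda": mean_lam,
        "grid": grid,
        "states": _truth_states(cfg, build, grid, resolved),
        "mutations": pd.DataFrame({
            "true_m": true_m, "true_timing": true_timing,
            "cn_major": major, "cn_minor": minor,
        }, index=mutations.index),
        "stratum_genes": (
            genes.loc[genes[cfg.stratum_column] > cfg.stratum_threshold, "gene"]
            .tolist() if cfg.stratum_column else []),
    }
    return Cohort(cna=cna, mutations=mutations,
                  genes=genes.drop(columns=["_lam"]),
                  allele_segments=allele_segments, truth=truth,
                  build=build, config=cfg)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Emit the file dialects the readers consume, plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_seg(cohort.cna, outdir / "cohort.seg")
    muts = cohort.mutations.copy()
    muts["pos"] = muts["pos"] + 1
    consequence = np.where(
        ~muts["is_coding"], "IGR",
        np.where(muts["is_synonymous"], "Silent", "Missense_Mutation"))
    muts.insert(4, "consequence", consequence)
    muts.drop(columns=["is_coding", "is_synonymous"]).to_csv(
        outdir / "mutations.tsv", sep="\t", index=False)
    genes = cohort.genes.copy()
    genes["start"] = genes["start"] + 1
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cohort.allele_segments.to_csv(outdir / "allele_cn.tsv", sep="\t", index=False)
    truth = {
        "mean_lambda": cohort.truth["mean_lambda"],
        "stratum_genes": cohort.truth["stratum_genes"],
        "config": asdict(cohort.config),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def make_sweep_config(seed: int, coupling_beta: float = 2.0) -> SimConfig:
    """Study conditions for the segment-length sweep.

    A larger genome (6 autosomes x 150 Mbp) with the mutation-rate field in
    30 Mbp blocks and coupled focal amplifications of ~25 Mbp placed
    preferentially on mutation-rich units: the coupling lives at a known
    ~30 Mbp scale, so the sweep's argmax segment length has a ground truth.
    The moderate mutation rate (8 coding mutations per coding Mbp per
    patient) makes small bins pay a realistic sampling-noise penalty, while
    uniformly placed arm/chromosome aneuploidies dilute scales much larger
    than the blocks.
    """
    return SimConfig(
        seed=seed, coupling_beta=coupling_beta,
        n_chromosomes=6, chrom_length=150_000_000,
        block_length=30_000_000, block_offset=15_000_000, base_mut_rate=8.0,
        event_mix=(0.65, 0.27, 0.08),
        focal_length_log_mean=float(np.log(25_000_000)),
        focal_length_log_sd=0.3,
    )


def make_stratified_config(seed: int, coupling_beta: float = 2.0) -> SimConfig:
    """Study conditions for the property-stratification contrast.

    The amplification–mutation coupling runs only through haploinsufficient
    genes (pLI > 0.2); mutations in the remaining genes occur at the flat
    field-average rate. A 15-autosome genome (500 analysis bins) keeps the
    per-cohort correlation estimates stable enough that the expected ordering
    rho(stratum) > rho(all mutations) > rho(complement) is resolvable.
    """
    return SimConfig(seed=seed, coupling_beta=coupling_beta,
                     stratum_column="pli", stratum_threshold=0.2,
                     n_chromosomes=15, base_mut_rate=20.0)


# ---------------------------------------------------------------------------
# Score-level generators for the combined-model and protection analyses


def make_additive_score_tables(
    n_bins: int = 100,
    seed: int = 0,
    noise_sd: float = 0.03,
    og_weight: float = 0.5,
    mu_weight: float = 0.5,
):
    """Bin-level tables where amp_freq = w1*(OG+GO) + w2*μ_scaled + noise.

    Returns ``(density, scores)`` frames ready for the combined model; the μ
    column is an affine map of the scaled component onto a log10 range so that
    min–max rescaling recovers its ranks exactly.
    """
    rng = np.random.default_rng(seed)
    bin_id = [f"bin{i:03d}" for i in range(n_bins)]
    og = rng.uniform(0, 0.5, n_bins)
    go = rng.uniform(0, 0.5, n_bins)
    mu_scaled = rng.uniform(0, 1, n_bins)
    amp = (og_weight * (og + go) + mu_weight * mu_scaled
           + rng.normal(0, noise_sd, n_bins))
    density = pd.DataFrame({"bin_id": bin_id, "og_score": og, "go_score": go,
                            "n_genes": 50})
    scores = pd.DataFrame({"bin_id": bin_id, "amp_freq": amp,
                           "mu": -6.0 + 2.0 * mu_scaled})
    return density, scores


def make_protection_scores(
    n_genes: int = 400,
    planted_frac: float = 0.05,
    seed: int = 0,
):
    """Gene-level (amp_freq, μ) table with a planted protected-gene set.

    Planted genes receive top-decile amplification frequency and bottom-decile
    μ. Returns ``(gene_df, planted_genes)``.
    """
    rng = np.random.default_rng(seed)
    gene = [f"g{i:04d}" for i in range(n_genes)]
    amp = rng.uniform(0.0, 0.6, n_genes)
    mu = rng.uniform(-6.0, -4.0, n_genes)
    k = max(1, int(round(planted_frac * n_genes)))
    planted = rng.choice(n_genes, size=k, replace=False)
    amp_hi = np.quantile(amp, 0.9)
    mu_lo = np.quantile(mu, 0.1)
    amp[planted] = rng.uniform(amp_hi, amp.max(), k)
    mu[planted] = rng.uniform(mu.min(), mu_lo, k)
    df = pd.DataFrame({"gene": gene, "amp_freq": amp, "mu": mu})
    return df, [gene[i] for i in sorted(planted)]


# ---------------------------------------------------------------------------
# Hand-computed miniature fixtures


def make_fixture(name: str) -> dict:
    """Tiny cohorts whose every score is computed by hand in the docstrings.

    * ``mini-eq3`` — 5 patients, one 1 Mbp bin, 2 amplified / 3 neutral,
      6 coding mutations all in neutral patients, coding_bp = 2e5:
      amp_freq = 2/5 = 0.4 and μ = log10(6 / (2e5 * 3)) = −5 exactly.
    * ``mini-timing`` — one 3:0 segment at purity 1 with VAFs 1.0 and 1/3:
      multiplicities 3 and 1; m = 3 is early and non-buffered (3+0−3 = 0 < 2),
      m = 1 is late and buffered (3+0−1 = 2 >= 2).
    * ``mini-null`` — as ``mini-eq3`` but with zero mutations: every μ
      undefined while the frequencies stay defined.
    """
    if name not in ("mini-eq3", "mini-timing", "mini-null"):
        raise KeyError(f"unknown fixture {name!r}")
    build = GenomeBuild({"chr1": 1_000_000}, {"chr1": 500_000}, name="mini")
    grid = build_grid(build, "fixed", bin_size=1_000_000)
    genes = pd.DataFrame({
        "gene": ["G1"], "chrom": ["chr1"], "start": [0], "end": [1_000_000],
        "coding_bp": [200_000], "pli": [0.5], "ghis": [0.5],
        "median_tpm": [10.0], "is_og": [False], "is_tsg": [False],
        "is_go": [False], "crispr_effect": [-0.2],
        "is_common_essential": [False], "is_nonessential": [True],
    })
    patients = ["p1", "p2", "p3", "p4", "p5"]
    # every patient is CNA-profiled; p3-p5 have copy-neutral genomes
    cna = pd.DataFrame({
        "patient": patients, "chrom": "chr1",
        "start": 0, "end": 1_000_000,
        "segment_mean": [0.5, 0.5, 0.0, 0.0, 0.0],
    })
    if name == "mini-eq3":
        muts = pd.DataFrame({
            "patient": ["p3", "p3", "p4", "p4", "p5", "p5"],
            "chrom": "chr1",
            "pos": [100, 200, 300, 400, 500, 600],
            "gene": "G1", "is_coding": True, "is_synonymous": False,
        })
        expected = {"amp_freq": 0.4, "mu": -5.0, "n_mut_neutral": 6, "n_N": 3}
    elif name == "mini-null":
        muts = pd.DataFrame(columns=["patient", "chrom", "pos", "gene",
                                     "is_coding", "is_synonymous"])
        expected = {"amp_freq": 0.4, "mu": float("nan")}
    else:  # mini-timing
        muts = pd.DataFrame({
            "patient": ["t1", "t1"], "chrom": "chr1", "pos": [100, 200],
            "gene": "G1", "is_coding": [True, False],
            "is_synonymous": False,
            "vaf": [1.0, 1.0 / 3.0], "depth": [90, 90],
        })
        segments = pd.DataFrame({
            "patient": ["t1"], "chrom": ["chr1"], "start": [0],
            "end": [1_000_000], "cn_major": [3], "cn_minor": [0],
            "purity": [1.0],
        })
        expected = {"m": [3, 1], "timing": ["early", "late"],
                    "buffered": [False, True]}
        return {"build": build, "grid": grid, "genes": genes,
                "mutations": muts, "allele_segments": segments,
                "patients": ["t1"], "expected": expected}
    return {"build": build, "grid": grid, "genes": genes, "cna": cna,
            "mutations": muts, "patients": patients, "expected": expected}
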