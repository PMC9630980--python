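"""Synthetic data with the statistical structure of a pooled barcoded-segregant
infection assay.

The generator emulates a two-parent haploid yeast cross (BY x 3S alleles coded
0/1), chromosomally integrated 20-mer barcodes (a configurable subset of
segregants carried in triplicate), planted general and antagonistically
pleiotropic fitness loci, per-organ exponential selection over days in the
host, a colony-forming-unit (CFU) recovery bottleneck per organ, on-plate
growth shared between organ samples and plate controls, and multinomial
sequencing counts at a fixed read depth.  Every stage of the analysis can
therefore be exercised, and scored against a truth record, with no external
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# S. cerevisiae R64 nuclear chromosome lengths (bp), chromosomes I..XVI.
CHROMOSOME_LENGTHS = {
    1: 230_218, 2: 813_184, 3: 316_620, 4: 1_531_933,
    5: 576_874, 6: 270_161, 7: 1_090_940, 8: 562_643,
    9: 439_888, 10: 745_751, 11: 666_816, 12: 1_078_177,
    13: 924_431, 14: 784_333, 15: 1_091_291, 16: 948_066,
}

ORGANS = ("brain", "gonad", "kidney", "liver", "spleen")
BRAIN_ORGANS = ("brain",)
#: Organs aggregated as the "nonbrain" context downstream.  The gonads are
#: carried through the simulation but are expected to fail the significance
#: filter (their recovery bottleneck is tiny), as in the source study design.
NONBRAIN_ORGANS = ("kidney", "liver", "spleen")

#: Mean CFU recovered per organ sample; sets the recovery bottleneck.
ORGAN_CFU = {
    "brain": 1_741.0,
    "gonad": 69.0,
    "kidney": 3_843.0,
    "liver": 69_150.0,
    "spleen": 32_032.0,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_marker_map(n_markers: int = 512, seed: int = 0) -> pd.DataFrame:
    """Build a marker map over the 16 yeast chromosomes.

    Markers are allotted to chromosomes proportionally to physical length
    (at least 2 per chromosome) and placed at sorted uniform positions.
    Returns a DataFrame with columns ``marker_id, chromosome, position``.
    """
    if n_markers < 2 * len(CHROMOSOME_LENGTHS):
        raise ValueError("need at least 2 markers per chromosome")
    rng = np.random.default_rng(seed)
    lengths = np.array([CHROMOSOME_LENGTHS[c] for c in sorted(CHROMOSOME_LENGTHS)])
    alloc = np.maximum(2, np.round(n_markers * lengths / lengths.sum()).astype(int))
    rows = []
    for chrom, n in zip(sorted(CHROMOSOME_LENGTHS), alloc):
        size = CHROMOSOME_LENGTHS[chrom]
        pos = np.sort(rng.choice(np.arange(1, size + 1), size=n, replace=False))
        for p in pos:
            rows.append((f"chr{chrom:02d}_{p}", chrom, int(p)))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"])


def validate_marker_map(marker_map: pd.DataFrame) -> None:
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    if marker_map["marker_id"].duplicated().any():
        raise ValueError("marker_ids are not unique")
    for _, grp in marker_map.groupby("chromosome"):
        if not grp["position"].is_monotonic_increasing or grp["position"].duplicated().any():
            raise ValueError("positions must be strictly increasing within a chromosome")


def simulate_cross(
    marker_map: pd.DataFrame,
    n_segregants: int,
    expected_crossovers_per_chromosome: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate haploid meiotic progeny of a two-parent cross.

    Each chromosome of each segregant is a mosaic of parental blocks: the
    starting parent is a fair coin flip, crossover counts are Poisson with
    the given mean, and crossover positions are uniform along the chromosome
    (no interference).  Returns segregants x markers DataFrame of 0/1 codes.
    """
    validate_marker_map(marker_map)
    marker_map = marker_map.reset_index(drop=True)
    if n_segregants < 1:
        raise ValueError("n_segregants must be >= 1")
    if expected_crossovers_per_chromosome < 0:
        raise ValueError("expected_crossovers_per_chromosome must be >= 0")
    rng = np.random.default_rng(seed)
    out = np.empty((n_segregants, len(marker_map)), dtype=np.int8)
    for chrom, grp in marker_map.groupby("chromosome", sort=True):
        cols = grp.index.to_numpy()
        pos = grp["position"].to_numpy(dtype=float)
        length = float(CHROMOSOME_LENGTHS.get(chrom, pos[-1] + 1))
        start = rng.integers(0, 2, size=n_segregants).astype(np.int8)
        n_co = rng.poisson(expected_crossovers_per_chromosome, size=n_segregants)
        for i in range(n_segregants):
            if n_co[i] == 0:
                out[i, cols] = start[i]
                continue
            breaks = np.sort(rng.uniform(0.0, length, size=n_co[i]))
            # allele at a marker flips once per crossover to its left
            flips = np.searchsorted(breaks, pos)
            out[i, cols] = (start[i] + flips) % 2
    ids = [f"seg{i:04d}" for i in range(n_segregants)]
    return pd.DataFrame(out, index=ids, columns=marker_map["marker_id"].to_numpy())


@dataclass
class EffectModel:
    """Ground truth for planted fitness loci.

    ``loci`` has one row per locus with columns ``marker_id, chromosome,
    position, locus_class`` (general/antagonistic) and one ``s_<organ>``
    column per organ: the per-day selection coefficient of the 3S allele in
    that organ.  ``beneficial_brain`` / ``beneficial_nonbrain`` name the
    allele favoured in each context.
    """

    loci: pd.DataFrame
    organs: tuple = ORGANS

    def log_fitness(self, genotypes: pd.DataFrame, organ: str) -> np.ndarray:
        """Per-segregant log fitness per day in ``organ``."""
        w = np.zeros(len(genotypes))
        for _, row in self.loci.iterrows():
            w += row[f"s_{organ}"] * genotypes[row["marker_id"]].to_numpy(dtype=float)
        return w


def simulate_effect_model(
    marker_map: pd.DataFrame,
    n_general: int = 10,
    n_antagonistic: int = 8,
    effect_scale: float = 0.25,
    seed: int = 0,
    min_separation_bp: int = 100_000,
    per_chromosome_cap: int = 2,
) -> EffectModel:
    """Plant general and antagonistically pleiotropic loci on the map.

    General loci get same-sign per-day selection coefficients in every organ;
    antagonistic loci get opposite signs between brain and nonbrain organs.
    Magnitudes are ``effect_scale`` jittered by U(0.8, 1.2) per organ.  Loci
    are placed at distinct markers, at most ``per_chromosome_cap`` per
    chromosome and at least ``min_separation_bp`` apart within a chromosome.
    """
    validate_marker_map(marker_map)
    if effect_scale <= 0:
        raise ValueError("effect_scale must be > 0")
    n_loci = n_general + n_antagonistic
    n_chrom = marker_map["chromosome"].nunique()
    if n_loci > n_chrom * per_chromosome_cap:
        raise ValueError(
            f"cannot place {n_loci} loci: cap is {per_chromosome_cap} per "
            f"chromosome over {n_chrom} chromosomes"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(marker_map))
    chosen: list[int] = []
    per_chrom: dict = {}
    chroms = marker_map["chromosome"].to_numpy()
    positions = marker_map["position"].to_numpy()
    for idx in order:
        if len(chosen) == n_loci:
            break
        c = chroms[idx]
        if per_chrom.get(c, 0) >= per_chromosome_cap:
            continue
        if any(chroms[j] == c and abs(positions[j] - positions[idx]) < min_separation_bp
               for j in chosen):
            continue
        chosen.append(idx)
        per_chrom[c] = per_chrom.get(c, 0) + 1
    if len(chosen) < n_loci:
        raise ValueError("could not place all loci under the separation constraints")

    classes = ["general"] * n_general + ["antagonistic"] * n_antagonistic
    rows = []
    for idx, cls in zip(chosen, classes):
        sign = rng.choice([-1.0, 1.0])
        row = {
            "marker_id": marker_map["marker_id"].iloc[idx],
            "chromosome": int(chroms[idx]),
            "position": int(positions[idx]),
            "locus_class": cls,
        }
        for organ in ORGANS:
            mag = effect_scale * rng.uniform(0.8, 1.2)
            if cls == "general" or organ in BRAIN_ORGANS:
                row[f"s_{organ}"] = sign * mag
            else:
                row[f"s_{organ}"] = -sign * mag
        row["beneficial_brain"] = "3S" if row["s_brain"] > 0 else "BY"
        nb = np.mean([row[f"s_{o}"] for o in NONBRAIN_ORGANS])
        row["beneficial_nonbrain"] = "3S" if nb > 0 else "BY"
        rows.append(row)
    columns = (["marker_id", "chromosome", "position", "locus_class"]
               + [f"s_{o}" for o in ORGANS]
               + ["beneficial_brain", "beneficial_nonbrain"])
    loci = (pd.DataFrame(rows, columns=columns)
            .sort_values(["chromosome", "position"]).reset_index(drop=True))
    return EffectModel(loci=loci)


def make_barcode_assignment(
    segregant_ids,
    n_triplicated: int = 86,
    barcode_length: int = 20,
    min_pairwise_hamming: int = 7,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign random 20-mer barcodes to segregants.

    The first ``n_triplicated`` segregants receive three barcodes each
    (internal replication for within-sample heritability); the rest one.
    Barcodes are drawn to be pairwise Hamming-separated by at least
    ``min_pairwise_hamming`` so whitelist assignment at radius 3 is unique.
    """
    segregant_ids = list(segregant_ids)
    if n_triplicated > len(segregant_ids):
        raise ValueError("n_triplicated exceeds segregant count")
    n_barcodes = n_triplicated * 3 + (len(segregant_ids) - n_triplicated)
    rng = np.random.default_rng(seed)
    accepted = np.empty((0, barcode_length), dtype=np.uint8)
    while accepted.shape[0] < n_barcodes:
        cand = rng.integers(0, 4, size=barcode_length).astype(np.uint8)
        if accepted.shape[0] and int((accepted != cand).sum(axis=1).min()) < min_pairwise_hamming:
            continue
        accepted = np.vstack([accepted, cand])
    seqs = ["".join(chr(_BASES[b]) for b in row) for row in accepted]
    rows, k = [], 0
    for i, seg in enumerate(segregant_ids):
        n_bc = 3 if i < n_triplicated else 1
        for r in range(1, n_bc + 1):
            rows.append((seqs[k], seg, r))
            k += 1
    return pd.DataFrame(rows, columns=["barcode", "segregant_id", "replicate_index"])


@dataclass
class ExperimentDesign:
    """Factorial layout and noise scales of the infection experiment."""

    organs: tuple = ORGANS
    sexes: tuple = ("F", "M")
    treatments: tuple = ("dex+", "dex-")
    days: tuple = (1, 2, 5)
    replicates: int = 3
    cfu_scale: dict = field(default_factory=lambda: dict(ORGAN_CFU))
    sequencing_depth: int = 1_000_000
    n_plate_controls: int = 3
    plate_cells: int = 100_000
    t0_lognormal_sigma: float = 0.2
    plate_growth_sigma: float = 0.2

    def organ_sample_grid(self):
        for organ in self.organs:
            for sex in self.sexes:
                for trt in self.treatments:
                    for day in self.days:
                        for rep in range(1, self.replicates + 1):
                            yield organ, sex, trt, day, rep


def simulate_experiment(
    genotypes: pd.DataFrame,
    barcode_assignment: pd.DataFrame,
    effect_model: EffectModel,
    design: ExperimentDesign | None = None,
    seed: int = 0,
):
    """Simulate the full pooled infection assay.

    Model: barcode i in organ ``o`` at day ``t`` has expected frequency
    proportional to ``f0_i * exp(t * w_o(i))`` with ``w_o`` the summed
    per-day selection coefficients of the planted loci.  Recovery applies a
    multinomial bottleneck at the organ's CFU scale; recovered cells then
    grow on plates with a per-segregant log-growth coefficient shared with
    the plate controls (making plate correction identifiable); reads are a
    multinomial draw at the sequencing depth.

    Returns ``(counts, meta, truth)``: a samples x barcodes count table, a
    sample-metadata frame, and the truth record (planted loci, T0
    frequencies, plate growth coefficients).
    """
    design = design or ExperimentDesign()
    if design.sequencing_depth <= 0:
        raise ValueError("sequencing depth must be positive")
    missing = set(barcode_assignment["segregant_id"]) - set(genotypes.index)
    if missing:
        raise ValueError(f"{len(missing)} barcoded segregants lack genotypes")
    rng = np.random.default_rng(seed)

    barcodes = barcode_assignment["barcode"].to_numpy()
    seg_of_bc = barcode_assignment["segregant_id"].to_numpy()
    seg_index = genotypes.index.get_indexer(seg_of_bc)

    # T0 pool: equimolar with mild log-normal jitter.
    f0 = np.exp(rng.normal(0.0, design.t0_lognormal_sigma, size=len(barcodes)))
    f0 /= f0.sum()
    # On-plate growth, one coefficient per segregant, shared across samples.
    g_seg = rng.normal(0.0, design.plate_growth_sigma, size=len(genotypes))
    g = g_seg[seg_index]

    w_organ = {
        organ: effect_model.log_fitness(genotypes, organ)[seg_index]
        for organ in design.organs
    }

    sample_rows, count_rows, sample_ids = [], [], []

    def add(sample_id, stype, organ, sex, trt, day, rep, counts):
        sample_ids.append(sample_id)
        count_rows.append(counts)
        sample_rows.append((sample_id, stype, organ, sex, trt, day, rep))

    add("T0", "T0", "NA", "NA", "NA", 0, 1,
        rng.multinomial(design.sequencing_depth, f0))

    for rep in range(1, design.n_plate_controls + 1):
        p = f0 * np.exp(g)
        cells = rng.multinomial(design.plate_cells, p / p.sum())
        q = cells.astype(float)
        reads = (rng.multinomial(design.sequencing_depth, q / q.sum())
                 if q.sum() else np.zeros(len(barcodes), dtype=np.int64))
        add(f"plate_r{rep}", "plate_control", "NA", "NA", "NA", 0, rep, reads)

    for organ, sex, trt, day, rep in design.organ_sample_grid():
        p = f0 * np.exp(day * w_organ[organ])
        n_cfu = rng.poisson(design.cfu_scale[organ])
        cells = (rng.multinomial(n_cfu, p / p.sum()) if n_cfu
                 else np.zeros(len(barcodes), dtype=np.int64))
        q = cells * np.exp(g)
        reads = (rng.multinomial(design.sequencing_depth, q / q.sum())
                 if q.sum() else np.zeros(len(barcodes), dtype=np.int64))
        add(f"{organ}_{sex}_{trt}_d{day}_r{rep}", "organ", organ, sex, trt, day, rep, reads)

    counts = pd.DataFrame(np.vstack(count_rows), index=sample_ids, columns=barcodes)
    counts.index.name = "sample_id"
    meta = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "type", "organ", "sex", "treatment", "day", "replicate"],
    ).set_index("sample_id")
    truth = {
        "loci": effect_model.loci.copy(),
        "t0_frequencies": pd.Series(f0, index=barcodes, name="f_T0"),
        "plate_log_growth": pd.Series(g_seg, index=genotypes.index, name="log_growth"),
    }
    return counts, meta, truth


def simulate_observed_calls(
    genotypes: pd.DataFrame,
    mean_coverage: float,
    per_read_error: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate low-coverage sequencing of segregant genotypes.

    Per-site read depth is Poisson(``mean_coverage``); each read reports the
    true allele with probability ``1 - per_read_error``.  Returns the
    observed 3S fraction per site, NaN where depth is zero.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    if not 0 <= per_read_error < 0.5:
        raise ValueError("per_read_error must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    truth = genotypes.to_numpy(dtype=np.int8)
    depth = rng.poisson(mean_coverage, size=truth.shape)
    p_3s = np.where(truth == 1, 1.0 - per_read_error, per_read_error)
    k = rng.binomial(depth, p_3s)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, k / np.maximum(depth, 1), np.nan)
    return pd.DataFrame(frac, index=genotypes.index, columns=genotypes.columns)
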