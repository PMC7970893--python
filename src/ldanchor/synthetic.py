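"""Synthetic breeding-panel generator with recorded ground truth.

Emulates a mostly-inbred cultivar panel at the scale of roughly 220
genotypes with 165 year-annotated cultivars (1966-2016): haploblock LD
structure, a sweeping introgression block rising in frequency from its
introduction year, deliberately misplaced markers (with the true position
recorded as the rank-2 alignment hit), injected missingness, and an
array-QC table with a few injected failures. Every derived quantity the
other modules estimate is recorded in :class:`SimTruth`.

Genotypes are generated as haploid block haplotypes doubled to dosage
{0, 2}: within each haploblock a latent allele is drawn per individual at
the block frequency and copied to each marker with a small per-marker flip
noise calibrated so the expected within-block dosage r^2 hits the
configured target; a 1% heterozygosity injection then mimics residual
outcrossing. This mosaic process gives tunable LD without coalescent
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .panel_io import (
    AlignmentHitTable,
    AxiomQCTable,
    GenotypeMatrix,
    MarkerMap,
    PanelMetadata,
)

WHEAT_CHROMOSOMES = tuple(f"{i}{g}" for i in range(1, 8) for g in "ABD")


@dataclass
class IntrogressionConfig:
    chromosome: str = "2A"
    start_bp: int = 1
    end_bp: int = 6_000_000
    start_year: int = 1998
    rate: float = 0.4  # logistic steepness per year after start_year
    final_frequency: float = 0.6  # carrier frequency approached in recent years


@dataclass
class SimConfig:
    n_individuals: int = 220
    n_year_annotated: int = 165
    year_range: tuple[int, int] = (1966, 2016)
    n_markers: int = 1000
    n_chromosomes: int = 21
    block_length_markers: int = 10
    within_block_r2_target: float = 0.85
    marker_spacing_bp: int = 250_000
    block_freq_range: tuple[float, float] = (0.35, 0.65)
    introgression: IntrogressionConfig = field(default_factory=IntrogressionConfig)
    misplacement_fraction: float = 0.05
    misplaced_no_second_hit_fraction: float = 0.0
    missingness_rate: float = 0.02
    heterozygosity_rate: float = 0.01
    intro_noise_rate: float = 0.005
    n_qc_failures: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "within_block_r2_target",
            "misplacement_fraction",
            "misplaced_no_second_hit_fraction",
            "missingness_rate",
            "heterozygosity_rate",
            "intro_noise_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.introgression.final_frequency <= 1.0:
            raise ValueError("introgression final_frequency outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 1 <= self.n_chromosomes <= len(WHEAT_CHROMOSOMES):
            raise ValueError("n_chromosomes must be in 1..21")
        if self.n_year_annotated > self.n_individuals:
            raise ValueError("n_year_annotated exceeds n_individuals")


@dataclass
class SimTruth:
    """Ground-truth ledger for acceptance testing."""

    true_map: MarkerMap
    misplaced: pd.DataFrame  # marker_id, true/false chrom+pos, has_second_hit
    carriers: pd.DataFrame  # individual_id, registration_year
    masked_cells: list[tuple[int, int]]  # (row, col) made missing
    introgression_markers: list[str]
    block_of_marker: dict[str, int]


def _flip_noise_for_target(r2_target: float) -> float:
    """Per-marker flip probability giving the target within-block r^2.

    Solves, at block frequency 0.5, r(e) = c v / (c v + e (1 - e)) =
    sqrt(target) with c = (1 - 2e)^2 and v = 1/4 (haploid variance).
    """
    if r2_target >= 1.0:
        return 0.0
    want = np.sqrt(r2_target)

    def f(e: float) -> float:
        c = (1 - 2 * e) ** 2
        return c * 0.25 / (c * 0.25 + e * (1 - e)) - want

    return float(brentq(f, 1e-9, 0.499))


def _carrier_probability(year: float, cfg: IntrogressionConfig) -> float:
    """Logistic-in-year carrier probability, zero before the start year."""
    if year < cfg.start_year:
        return 0.0
    delta = year - cfg.start_year
    return cfg.final_frequency * (2.0 / (1.0 + np.exp(-cfg.rate * delta)) - 1.0)


def simulate_panel(
    config: SimConfig,
) -> tuple[
    GenotypeMatrix, MarkerMap, AlignmentHitTable, PanelMetadata, AxiomQCTable, SimTruth
]:
    """Generate a full synthetic panel; same config (incl. seed) twice gives
    byte-identical outputs."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (
        rng_geno,
        rng_years,
        rng_carriers,
        rng_misplace,
        rng_missing,
        rng_het,
        rng_qc,
    ) = (np.random.default_rng(s) for s in ss.spawn(7))

    n, m = cfg.n_individuals, cfg.n_markers
    individual_ids = [f"CV{i:03d}" for i in range(1, n + 1)]

    # --- true map: markers dealt round-robin-free: fill chromosomes in order
    chroms_used = WHEAT_CHROMOSOMES[: cfg.n_chromosomes]
    per_chrom = int(np.ceil(m / cfg.n_chromosomes))
    marker_ids, chrom_col, pos_col = [], [], []
    for j in range(m):
        c = chroms_used[j // per_chrom]
        k = j % per_chrom
        marker_ids.append(f"SNP{j:05d}")
        chrom_col.append(c)
        pos_col.append((k + 1) * cfg.marker_spacing_bp)
    source = ["135K" if j % 2 == 0 else "15K" for j in range(m)]
    true_map = MarkerMap(
        pd.DataFrame(
            {
                "marker_id": marker_ids,
                "chromosome": chrom_col,
                "position_bp": pos_col,
                "source_array": source,
            }
        )
    )
    chrom_span = {c: per_chrom * cfg.marker_spacing_bp for c in chroms_used}

    # --- metadata: first n_year_annotated individuals carry years
    lo, hi = cfg.year_range
    years = np.full(n, np.nan)
    if cfg.n_year_annotated:
        sampled = rng_years.integers(lo, hi + 1, size=cfg.n_year_annotated).astype(float)
        sampled[0], sampled[-1] = lo, hi  # span the full breeding period
        # the introduction event is part of the design: one cultivar is
        # registered in the introgression start year itself
        intro_year = cfg.introgression.start_year
        if lo <= intro_year <= hi and intro_year not in sampled:
            later = np.where(sampled > intro_year)[0]
            pick = later[0] if later.size else len(sampled) // 2
            sampled[pick] = intro_year
        years[: cfg.n_year_annotated] = sampled
    meta = PanelMetadata(
        pd.DataFrame(
            {
                "individual_id": individual_ids,
                "cultivar_name": [f"Cultivar-{g}" for g in individual_ids],
                "registration_year": years,
                "origin": [
                    "Germany" if not np.isnan(y) else "world" for y in years
                ],
            }
        )
    )

    # --- introgression carriers
    ic = cfg.introgression
    carrier = np.zeros(n, dtype=bool)
    for i in range(n):
        if np.isnan(years[i]):
            continue
        carrier[i] = rng_carriers.random() < _carrier_probability(years[i], ic)
    eligible = [i for i in range(n) if not np.isnan(years[i]) and years[i] >= ic.start_year]
    if eligible:
        founder = min(eligible, key=lambda i: (years[i], i))
        carrier[founder] = True  # the introduction event itself
    intro_markers = [
        mid
        for mid, c, p in zip(marker_ids, chrom_col, pos_col)
        if c == ic.chromosome and ic.start_bp <= p <= ic.end_bp
    ]
    intro_idx = np.array([marker_ids.index(mid) for mid in intro_markers], dtype=int)

    # --- genotypes: block haplotypes with flip noise, doubled to dosage
    e = _flip_noise_for_target(cfg.within_block_r2_target)
    hap = np.empty((n, m), dtype=float)
    block_of: dict[str, int] = {}
    block_id = 0
    j = 0
    while j < m:
        # blocks never span a chromosome boundary
        chrom_end = min(m, (j // per_chrom + 1) * per_chrom)
        end = min(j + cfg.block_length_markers, chrom_end)
        p_block = rng_geno.uniform(*cfg.block_freq_range)
        z = (rng_geno.random(n) < p_block).astype(float)
        for jj in range(j, end):
            flip = rng_geno.random(n) < e
            hap[:, jj] = np.where(flip, 1.0 - z, z)
            block_of[marker_ids[jj]] = block_id
        block_id += 1
        j = end
    # introgression overrides: carriers carry the donor haplotype
    if intro_idx.size:
        hap[:, intro_idx] = np.where(carrier[:, None], 1.0, 0.0)
        noise = rng_geno.random((n, intro_idx.size)) < cfg.intro_noise_rate
        hap[:, intro_idx] = np.where(noise, 1.0 - hap[:, intro_idx], hap[:, intro_idx])
    dosage = 2.0 * hap
    het = rng_het.random((n, m)) < cfg.heterozygosity_rate
    dosage[het] = 1.0

    # --- misplacement
    n_misplaced = int(round(cfg.misplacement_fraction * m))
    intro_set = set(intro_markers)
    # spread misplaced markers over distinct haploblocks so each one's LD
    # evidence points uniquely to its true home (two block-mates misplaced
    # to nearby false positions would legitimately mask each other)
    by_block: dict[int, list[str]] = {}
    for mid in marker_ids:
        if mid not in intro_set:
            by_block.setdefault(block_of[mid], []).append(mid)
    block_keys = sorted(by_block)
    if n_misplaced <= len(block_keys):
        chosen_blocks = rng_misplace.choice(block_keys, size=n_misplaced, replace=False)
        misplaced_ids = sorted(
            by_block[b][int(rng_misplace.integers(len(by_block[b])))]
            for b in chosen_blocks
        )
    else:
        placeable = [mid for mid in marker_ids if mid not in intro_set]
        misplaced_ids = sorted(
            rng_misplace.choice(placeable, size=n_misplaced, replace=False)
        )
    recorded = true_map.table.copy().set_index("marker_id")
    mis_rows = []
    n_nosecond = int(round(cfg.misplaced_no_second_hit_fraction * n_misplaced))
    nosecond = set(misplaced_ids[:n_nosecond]) if n_nosecond else set()
    for mid in misplaced_ids:
        true_chrom = recorded.loc[mid, "chromosome"]
        others = [c for c in chroms_used if c != true_chrom]
        false_chrom = others[int(rng_misplace.integers(len(others)))]
        false_pos = int(rng_misplace.integers(1, chrom_span[false_chrom] + 1))
        mis_rows.append(
            {
                "marker_id": mid,
                "true_chromosome": true_chrom,
                "true_position_bp": int(recorded.loc[mid, "position_bp"]),
                "false_chromosome": false_chrom,
                "false_position_bp": false_pos,
                "has_second_hit": mid not in nosecond,
            }
        )
        recorded.loc[mid, "chromosome"] = false_chrom
        recorded.loc[mid, "position_bp"] = false_pos
    recorded = recorded.reset_index()
    recorded["position_bp"] = recorded["position_bp"].astype(int)
    recorded_map = MarkerMap(recorded)
    misplaced_df = pd.DataFrame(
        mis_rows,
        columns=[
            "marker_id",
            "true_chromosome",
            "true_position_bp",
            "false_chromosome",
            "false_position_bp",
            "has_second_hit",
        ],
    )

    # --- alignment hits: rank 1 = recorded position; rank 2 = true position
    hit_rows = []
    rec_idx = recorded_map.table.set_index("marker_id")
    for mid in marker_ids:
        hit_rows.append(
            (
                mid,
                1,
                rec_idx.loc[mid, "chromosome"],
                int(rec_idx.loc[mid, "position_bp"]),
                0,
            )
        )
    for row in mis_rows:
        if row["has_second_hit"]:
            hit_rows.append(
                (
                    row["marker_id"],
                    2,
                    row["true_chromosome"],
                    row["true_position_bp"],
                    0,
                )
            )
    hits = AlignmentHitTable(
        pd.DataFrame(
            hit_rows,
            columns=["marker_id", "hit_rank", "chromosome", "position_bp", "mismatches"],
        )
    )

    # --- missingness
    masked_cells: list[tuple[int, int]] = []
    if cfg.missingness_rate > 0:
        total = n * m
        n_mask = int(round(cfg.missingness_rate * total))
        flat = rng_missing.choice(total, size=n_mask, replace=False)
        for f in sorted(flat):
            i, jj = divmod(int(f), m)
            dosage[i, jj] = np.nan
            masked_cells.append((i, jj))

    gm = GenotypeMatrix(individual_ids, marker_ids, dosage)

    # --- QC table with injected failures
    fld = rng_qc.uniform(5.0, 12.0, size=m)
    homfld = rng_qc.uniform(9.0, 20.0, size=m)
    class_label = np.array(["PolyHighResolution"] * m, dtype=object)
    if cfg.n_qc_failures:
        fail = rng_qc.choice(m, size=min(cfg.n_qc_failures, m), replace=False)
        for k, jj in enumerate(sorted(fail)):
            mode = k % 3
            if mode == 0:
                class_label[jj] = "other"
            elif mode == 1:
                fld[jj] = 3.0
            else:
                homfld[jj] = 5.0
    qc = AxiomQCTable(
        pd.DataFrame(
            {
                "marker_id": marker_ids,
                "class_label": class_label,
                "fld": fld,
                "homfld": homfld,
            }
        )
    )

    carriers_df = pd.DataFrame(
        {
            "individual_id": [individual_ids[i] for i in range(n) if carrier[i]],
            "registration_year": [years[i] for i in range(n) if carrier[i]],
        }
    )
    truth = SimTruth(
        true_map=true_map,
        misplaced=misplaced_df,
        carriers=carriers_df,
        masked_cells=masked_cells,
        introgression_markers=intro_markers,
        block_of_marker=block_of,
    )
    return gm, recorded_map, hits, meta, qc, truth


def mask_cells(
    gm: GenotypeMatrix, rate: float, seed: int
) -> tuple[GenotypeMatrix, list[tuple[int, int]]]:
    """Mask an exact fraction of the non-missing cells (without replacement).

    Returns the masked matrix and the list of (row, col) cells masked, for
    imputation-accuracy scoring; originally-missing cells are never chosen.
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError("mask rate must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    X = gm.dosage.copy()
    candidates = np.argwhere(~np.isnan(X))
    n_mask = int(round(rate * len(candidates)))
    if n_mask == 0:
        return GenotypeMatrix(list(gm.individual_ids), list(gm.marker_ids), X), []
    chosen = candidates[rng.choice(len(candidates), size=n_mask, replace=False)]
    cells = [(int(i), int(j)) for i, j in chosen]
    for i, j in cells:
        X[i, j] = np.nan
    return GenotypeMatrix(list(gm.individual_ids), list(gm.marker_ids), X), cells
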