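"""LD-based detection and correction of misanchored markers.

A marker whose recorded position contradicts its LD neighborhood — at most
weak LD (r^2 <= r2_low) with markers near its recorded position but strong
LD (r^2 > r2_high) with markers elsewhere — is flagged as ambiguous. A
flagged marker is relocated to its second-best alignment hit when that hit
falls in the chromosome region indicated by its high-LD partners; otherwise
it is removed. One pass is the default (``max_rounds=1``); the procedure is
deterministic, with partner ties broken by marker-id order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld_engine import r2_matrix
from .panel_io import AlignmentHitTable, GenotypeMatrix, MarkerMap


@dataclass
class AnomalyFlag:
    marker_id: str
    max_local_r2: float
    max_nonlocal_r2: float
    flagged: bool
    candidate_chromosome: str | None = None
    candidate_interval: tuple[int, int] | None = None
    # ids/positions of the non-local high-LD partners on the candidate chromosome
    partner_ids: list[str] = field(default_factory=list)
    partner_positions: list[int] = field(default_factory=list)
    multi_region: bool = False


@dataclass
class CorrectionDecision:
    marker_id: str
    action: str  # keep | relocate | remove
    old_chromosome: str
    old_position_bp: int
    new_chromosome: str | None
    new_position_bp: int | None
    max_local_r2: float
    max_nonlocal_r2: float
    n_supporting_partners: int
    reason: str


@dataclass
class CorrectedMap:
    """Output map plus the per-marker decision ledger and summary counts."""

    marker_map: MarkerMap
    decisions: list[CorrectionDecision]

    @property
    def n_kept(self) -> int:
        return sum(d.action == "keep" for d in self.decisions)

    @property
    def n_relocated(self) -> int:
        return sum(d.action == "relocate" for d in self.decisions)

    @property
    def n_removed(self) -> int:
        return sum(d.action == "remove" for d in self.decisions)

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "marker_id": d.marker_id,
                    "action": d.action,
                    "old_chrom": d.old_chromosome,
                    "old_pos": d.old_position_bp,
                    "new_chrom": d.new_chromosome,
                    "new_pos": d.new_position_bp,
                    "max_local_r2": d.max_local_r2,
                    "max_nonlocal_r2": d.max_nonlocal_r2,
                    "n_partners": d.n_supporting_partners,
                    "reason": d.reason,
                }
                for d in self.decisions
            ]
        )


def flag_ambiguous_markers(
    gm: GenotypeMatrix,
    marker_map: MarkerMap,
    r2_low: float = 0.5,
    r2_high: float = 0.5,
    local_window_mb: float = 10.0,
    min_obs: int = 20,
) -> list[AnomalyFlag]:
    """Flag markers with low local but high non-local LD.

    One flag per mapped, anchored marker, in genotype-matrix column order.
    Flagged iff max_local_r2 <= r2_low AND max_nonlocal_r2 > r2_high, where
    "local" means same chromosome within ``local_window_mb`` of the recorded
    position. The candidate region is the tightest interval covering the
    non-local partners (r^2 > r2_high) on their modal chromosome; a tie in
    partner counts between chromosomes marks the flag multi-region.
    Unanchored markers (chromosome "UN") are excluded from the LD
    neighborhood and are never flagged.
    """
    mt = marker_map.table.set_index("marker_id")
    absent = [m for m in gm.marker_ids if m not in mt.index]
    if absent:
        raise KeyError(f"markers absent from map (first: {absent[0]!r})")
    chroms = mt.reindex(gm.marker_ids)["chromosome"].to_numpy()
    positions = mt.reindex(gm.marker_ids)["position_bp"].to_numpy(dtype=float)
    names = np.asarray(gm.marker_ids)

    r2, _ = r2_matrix(gm.dosage, min_obs=min_obs)
    anchored = chroms != "UN"
    window_bp = local_window_mb * 1e6
    flags: list[AnomalyFlag] = []
    for j in range(gm.n_markers):
        if not anchored[j]:
            flags.append(AnomalyFlag(names[j], 0.0, 0.0, flagged=False))
            continue
        same = anchored & (chroms == chroms[j])
        local = same & (np.abs(positions - positions[j]) <= window_bp)
        nonlocal_ = anchored & ~local
        local[j] = nonlocal_[j] = False

        row = r2[j]
        loc_vals = row[local]
        loc_vals = loc_vals[~np.isnan(loc_vals)]
        nl_vals = row[nonlocal_]
        max_local = float(loc_vals.max()) if loc_vals.size else 0.0
        nl_clean = nl_vals[~np.isnan(nl_vals)]
        max_nonlocal = float(nl_clean.max()) if nl_clean.size else 0.0

        flagged = (max_local <= r2_low) and (max_nonlocal > r2_high)
        flag = AnomalyFlag(names[j], max_local, max_nonlocal, flagged)
        if flagged:
            pmask = nonlocal_ & (np.nan_to_num(row, nan=-1.0) > r2_high)
            pchroms = chroms[pmask]
            counts = pd.Series(pchroms).value_counts()
            top = counts.max()
            modal = sorted(counts[counts == top].index)
            if len(modal) > 1:
                flag.multi_region = True
            else:
                cchrom = modal[0]
                on_modal = pmask & (chroms == cchrom)
                ppos = positions[on_modal].astype(int)
                order = np.argsort(names[on_modal], kind="mergesort")
                flag.candidate_chromosome = cchrom
                flag.candidate_interval = (int(ppos.min()), int(ppos.max()))
                flag.partner_ids = list(names[on_modal][order])
                flag.partner_positions = list(ppos[order])
        flags.append(flag)
    return flags


def correct_positions(
    flags: list[AnomalyFlag],
    hits: AlignmentHitTable,
    marker_map: MarkerMap,
    confirm_window_mb: float = 10.0,
    min_partners: int = 1,
) -> CorrectedMap:
    """Resolve each flag into keep / relocate / remove.

    A flagged marker relocates to its rank-2 alignment hit iff that hit
    exists, lies on the candidate-region chromosome, and is within
    ``confirm_window_mb`` of at least ``min_partners`` high-LD partners.
    Otherwise it is removed with reason no_second_hit,
    second_hit_unconfirmed or multi_region_ambiguity. Unflagged markers are
    kept unchanged. The output map contains no removed markers and
    n_kept + n_relocated + n_removed equals the input count.
    """
    window_bp = confirm_window_mb * 1e6
    decisions: list[CorrectionDecision] = []
    out_rows: list[dict] = []
    mt = marker_map.table.set_index("marker_id")

    for flag in flags:
        row = mt.loc[flag.marker_id]
        old_chrom, old_pos = str(row["chromosome"]), int(row["position_bp"])
        source = row["source_array"]
        common = dict(
            marker_id=flag.marker_id,
            old_chromosome=old_chrom,
            old_position_bp=old_pos,
            max_local_r2=flag.max_local_r2,
            max_nonlocal_r2=flag.max_nonlocal_r2,
        )
        if not flag.flagged:
            decisions.append(
                CorrectionDecision(
                    action="keep",
                    new_chromosome=None,
                    new_position_bp=None,
                    n_supporting_partners=0,
                    reason="unflagged",
                    **common,
                )
            )
            out_rows.append(
                dict(
                    marker_id=flag.marker_id,
                    chromosome=old_chrom,
                    position_bp=old_pos,
                    source_array=source,
                )
            )
            continue
        if flag.multi_region:
            decisions.append(
                CorrectionDecision(
                    action="remove",
                    new_chromosome=None,
                    new_position_bp=None,
                    n_supporting_partners=0,
                    reason="multi_region_ambiguity",
                    **common,
                )
            )
            continue
        second = hits.hit(flag.marker_id, 2)
        if second is None:
            decisions.append(
                CorrectionDecision(
                    action="remove",
                    new_chromosome=None,
                    new_position_bp=None,
                    n_supporting_partners=0,
                    reason="no_second_hit",
                    **common,
                )
            )
            continue
        new_chrom = str(second["chromosome"])
        new_pos = int(second["position_bp"])
        support = 0
        if new_chrom == flag.candidate_chromosome:
            support = int(
                sum(abs(p - new_pos) <= window_bp for p in flag.partner_positions)
            )
        if support >= min_partners:
            decisions.append(
                CorrectionDecision(
                    action="relocate",
                    new_chromosome=new_chrom,
                    new_position_bp=new_pos,
                    n_supporting_partners=support,
                    reason="second_hit_confirmed",
                    **common,
                )
            )
            out_rows.append(
                dict(
                    marker_id=flag.marker_id,
                    chromosome=new_chrom,
                    position_bp=new_pos,
                    source_array=source,
                )
            )
        else:
            decisions.append(
                CorrectionDecision(
                    action="remove",
                    new_chromosome=None,
                    new_position_bp=None,
                    n_supporting_partners=support,
                    reason="second_hit_unconfirmed",
                    **common,
                )
            )
    out_map = MarkerMap(
        pd.DataFrame(
            out_rows,
            columns=["marker_id", "chromosome", "position_bp", "source_array"],
        )
    )
    return CorrectedMap(out_map, decisions)


def correct_map(
    gm: GenotypeMatrix,
    marker_map: MarkerMap,
    hits: AlignmentHitTable,
    r2_low: float = 0.5,
    r2_high: float = 0.5,
    local_window_mb: float = 10.0,
    confirm_window_mb: float = 10.0,
    min_partners: int = 1,
    min_obs: int = 20,
    max_rounds: int = 1,
) -> CorrectedMap:
    """Flag + correct in one call; ``max_rounds`` > 1 iterates to a fixpoint."""
    current = marker_map
    result: CorrectedMap | None = None
    for _ in range(max_rounds):
        sub = gm.subset_markers(
            [m for m in gm.marker_ids if m in set(current.table["marker_id"])]
        )
        flags = flag_ambiguous_markers(
            sub, current, r2_low, r2_high, local_window_mb, min_obs
        )
        result = correct_positions(flags, hits, current, confirm_window_mb, min_partners)
        if result.n_relocated == 0 and result.n_removed == 0:
            break
        current = result.marker_map
    assert result is not None
    return result


def association_scan(
    gm: GenotypeMatrix,
    marker_map: MarkerMap,
    trait_values: np.ndarray,
) -> pd.DataFrame:
    """Single-marker regression scan for demonstration purposes.

    Per marker, simple linear regression of the trait on dosage over
    pairwise-complete individuals; two-sided p from the slope t-statistic,
    reported as -log10 p. This is a demonstration harness for the effect of
    map correction on apparent QTL position, not a production GWAS (no
    kinship or structure correction).
    """
    y = np.asarray(trait_values, dtype=float)
    if y.shape[0] != gm.n_individuals:
        raise ValueError("one trait value per individual required")
    mt = marker_map.table.set_index("marker_id")
    rows = []
    for j, marker in enumerate(gm.marker_ids):
        if marker not in mt.index:
            continue  # e.g. removed by map correction
        x = gm.dosage[:, j]
        ok = ~np.isnan(x) & ~np.isnan(y)
        n = int(ok.sum())
        if n < 3:
            continue
        xv, yv = x[ok], y[ok]
        if np.all(xv == xv[0]):
            continue  # monomorphic: no score
        sx, sy = xv.std(), yv.std()
        if sy == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(xv, yv)[0, 1])
        # slope t-test is equivalent to the correlation t-test; cap |r| just
        # below 1 so perfect association maps to a huge finite statistic
        r = float(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        p = max(p, np.finfo(float).tiny)
        chrom, pos = str(mt.loc[marker, "chromosome"]), int(mt.loc[marker, "position_bp"])
        rows.append((marker, chrom, pos, -np.log10(p)))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp", "neglog10_p"])
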