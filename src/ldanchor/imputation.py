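"""LD-informed k-nearest-neighbour genotype imputation (LD-kNNI).

For each missing call at marker m, the l markers in highest LD (r^2) with m
define the context in which individuals are compared. The distance between
two individuals is the mean absolute dosage difference over context markers
non-missing in both, plus a small epsilon; the k nearest individuals that
are genotyped at m vote for a dosage with weight 1/distance. Cells with no
eligible neighbour fall back to the marker's modal dosage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ld_engine import r2_profile
from .panel_io import GenotypeMatrix

# a neighbour must share at least this many context markers to be eligible;
# prevents zero-information matches at tiny overlap
MIN_SHARED_CONTEXT = 5


@dataclass
class KnniParams:
    l: int = 30
    k: int = 5
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.l < 1 or self.k < 1 or self.epsilon <= 0:
            raise ValueError("require l >= 1, k >= 1, epsilon > 0")


def _modal_dosage(col: np.ndarray) -> float:
    vals = col[~np.isnan(col)]
    if vals.size == 0:
        return 0.0
    counts = {d: int((vals == d).sum()) for d in (0.0, 1.0, 2.0)}
    # ties -> lower dosage (deterministic)
    return max(sorted(counts), key=lambda d: counts[d])


def impute_ld_knni(
    gm: GenotypeMatrix, params: KnniParams | None = None, min_obs: int = 20
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Fill missing dosage calls; returns (completed matrix, per-cell log).

    Non-missing cells are never altered. The log has one row per imputed
    cell: individual_id, marker_id, imputed dosage, method
    {ld_knni, fallback_modal}, n_neighbours.
    """
    if params is None:
        params = KnniParams()
    X = gm.dosage.copy()
    miss_i, miss_j = np.where(np.isnan(X))
    log_rows: list[tuple] = []
    names = np.asarray(gm.marker_ids)
    inds = np.asarray(gm.individual_ids)

    for j in np.unique(miss_j):
        col = gm.dosage[:, j]
        rows_here = miss_i[miss_j == j]
        genotyped = ~np.isnan(col)
        modal = _modal_dosage(col)

        r2, _ = r2_profile(gm.dosage, int(j), min_obs=min_obs)
        r2[j] = np.nan
        order = np.argsort(np.nan_to_num(r2, nan=-1.0), kind="mergesort")[::-1]
        context = order[: params.l]
        context = context[~np.isnan(r2[context])]
        if context.size == 0:
            for i in rows_here:
                X[i, j] = modal
                log_rows.append((inds[i], names[j], modal, "fallback_modal", 0))
            continue

        C = gm.dosage[:, context]  # individuals x context
        C_obs = ~np.isnan(C)
        C0 = np.nan_to_num(C, nan=0.0)
        for i in rows_here:
            shared = C_obs & C_obs[i]  # (n, l_eff)
            n_shared = shared.sum(axis=1)
            diff = np.abs(C0 - C0[i])
            diff[~shared] = 0.0
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = diff.sum(axis=1) / n_shared + params.epsilon
            eligible = genotyped & (n_shared >= MIN_SHARED_CONTEXT)
            eligible[i] = False
            idx = np.where(eligible)[0]
            if idx.size == 0:
                X[i, j] = modal
                log_rows.append((inds[i], names[j], modal, "fallback_modal", 0))
                continue
            nearest = idx[np.argsort(dist[idx], kind="mergesort")[: params.k]]
            votes = {0.0: 0.0, 1.0: 0.0, 2.0: 0.0}
            for nb in nearest:
                votes[col[nb]] += 1.0 / dist[nb]
            best = max(sorted(votes), key=lambda d: votes[d])  # ties -> lower dosage
            X[i, j] = best
            log_rows.append((inds[i], names[j], best, "ld_knni", int(nearest.size)))

    log = pd.DataFrame(
        log_rows,
        columns=["individual_id", "marker_id", "imputed_dosage", "method", "n_neighbours"],
    )
    return GenotypeMatrix(list(gm.individual_ids), list(gm.marker_ids), X), log


def imputation_accuracy(
    truth: GenotypeMatrix,
    imputed: GenotypeMatrix,
    cells: list[tuple[int, int]],
) -> float:
    """Fraction of masked cells recovered exactly (by (row, col) index)."""
    if not cells:
        raise ValueError("no cells to score")
    hits = sum(
        float(truth.dosage[i, j] == imputed.dosage[i, j]) for i, j in cells
    )
    return hits / len(cells)
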