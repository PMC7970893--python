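"""Pairwise linkage disequilibrium (r^2) on dosage matrices.

r^2 is the squared Pearson correlation of allele dosages over
pairwise-complete individuals (composite LD). For fully inbred lines this
coincides with the haplotype-frequency r^2; for heterozygous material it is
the standard composite approximation and we document the divergence rather
than estimate phase. An r^2 is reported only when at least ``min_obs``
individuals are non-missing at both markers and both markers are
polymorphic over that shared set — below that LD is treated as unknown,
never as zero, since small-n r^2 is upward-biased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import GenotypeMatrix, MarkerMap

_VAR_TOL = 1e-12


@dataclass
class LDResult:
    marker_a: str
    marker_b: str
    r2: float
    n_obs: int


def r2_matrix(
    dosage: np.ndarray, min_obs: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r^2 with pairwise-complete observations.

    Returns (r2, n_obs) both (m, m); r2 is nan where undefined (too few
    shared observations, or either marker monomorphic over the shared set).
    Diagonal is 1 for polymorphic markers.
    """
    X = np.asarray(dosage, dtype=float)
    obs = ~np.isnan(X)
    X0 = np.where(obs, X, 0.0)
    O = obs.astype(float)
    n = O.T @ O
    sx = X0.T @ O          # sum of a over individuals observed at both
    sxx = (X0 * X0).T @ O
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_a = sxx - sx**2 / n
        var_b = var_a.T
        r2 = cov**2 / (var_a * var_b)
    bad = (n < min_obs) | (var_a <= _VAR_TOL) | (var_b <= _VAR_TOL)
    r2[bad] = np.nan
    np.clip(r2, 0.0, 1.0, out=r2)
    return r2, n.astype(int)


def r2_profile(
    dosage: np.ndarray, j: int, min_obs: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """r^2 of marker column ``j`` against every marker (vector form)."""
    X = np.asarray(dosage, dtype=float)
    y = X[:, j]
    obs = ~np.isnan(X)
    oy = ~np.isnan(y)
    joint = obs & oy[:, None]
    Xj = np.where(joint, X, 0.0)
    Yj = np.where(joint, y[:, None], 0.0)
    n = joint.sum(axis=0)
    sx = Xj.sum(axis=0)
    sy = Yj.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (Xj * Yj).sum(axis=0) - sx * sy / n
        var_x = (Xj * Xj).sum(axis=0) - sx**2 / n
        var_y = (Yj * Yj).sum(axis=0) - sy**2 / n
        r2 = cov**2 / (var_x * var_y)
    r2[(n < min_obs) | (var_x <= _VAR_TOL) | (var_y <= _VAR_TOL)] = np.nan
    np.clip(r2, 0.0, 1.0, out=r2)
    return r2, n.astype(int)


def pairwise_r2(
    gm: GenotypeMatrix,
    markers: list[str] | None = None,
    min_obs: int = 20,
) -> pd.DataFrame:
    """Pairwise r^2 over a marker subset (default: all markers).

    Returns a long DataFrame (marker_a, marker_b, r2, n_obs) with one row
    per unordered pair for which r^2 is defined; pairs with a monomorphic
    member or fewer than ``min_obs`` shared observations are omitted.
    """
    sub = gm if markers is None else gm.subset_markers(markers)
    r2, n = r2_matrix(sub.dosage, min_obs=min_obs)
    ia, ib = np.triu_indices(sub.n_markers, k=1)
    ok = ~np.isnan(r2[ia, ib])
    names = np.asarray(sub.marker_ids)
    return pd.DataFrame(
        {
            "marker_a": names[ia[ok]],
            "marker_b": names[ib[ok]],
            "r2": r2[ia[ok], ib[ok]],
            "n_obs": n[ia[ok], ib[ok]],
        }
    )


def ld_profile(
    gm: GenotypeMatrix,
    marker_map: MarkerMap,
    marker: str,
    local_window_mb: float = 10.0,
    partner_threshold: float = 0.5,
    min_obs: int = 20,
) -> dict:
    """LD neighborhood summary for one marker.

    "Local" partners share the marker's chromosome within
    ``local_window_mb``; everything else (other chromosome, or same
    chromosome beyond the window) is "non-local". Markers on chromosome
    "UN" (unanchored) are excluded from the neighborhood entirely.

    Returns a dict with max_local_r2, max_nonlocal_r2 (0.0 when the class
    is empty or all r^2 undefined) and a partners DataFrame of all markers
    with r^2 > partner_threshold.
    """
    j = gm.marker_index(marker)
    col = gm.dosage[:, j]
    vals = col[~np.isnan(col)]
    if vals.size == 0 or np.all(vals == vals[0]):
        raise ValueError(f"marker {marker!r} is monomorphic; LD profile undefined")
    chrom, pos = marker_map.lookup(marker)
    r2, n = r2_profile(gm.dosage, j, min_obs=min_obs)

    mt = marker_map.table.set_index("marker_id")
    chroms = mt.reindex(gm.marker_ids)["chromosome"].to_numpy()
    positions = mt.reindex(gm.marker_ids)["position_bp"].to_numpy(dtype=float)

    window_bp = local_window_mb * 1e6
    same_chrom = chroms == chrom
    local = same_chrom & (np.abs(positions - pos) <= window_bp)
    known = ~pd.isna(chroms) & (chroms != "UN")
    local &= known
    nonlocal_ = known & ~local
    local[j] = nonlocal_[j] = False

    def _max(mask: np.ndarray) -> float:
        vals = r2[mask]
        vals = vals[~np.isnan(vals)]
        return float(vals.max()) if vals.size else 0.0

    partner_mask = known & (np.nan_to_num(r2, nan=-1.0) > partner_threshold)
    partner_mask[j] = False
    partners = pd.DataFrame(
        {
            "marker_id": np.asarray(gm.marker_ids)[partner_mask],
            "chromosome": chroms[partner_mask],
            "position_bp": positions[partner_mask].astype(int),
            "r2": r2[partner_mask],
            "n_obs": n[partner_mask],
            "local": local[partner_mask],
        }
    ).sort_values("marker_id", kind="mergesort").reset_index(drop=True)
    return {
        "marker_id": marker,
        "max_local_r2": _max(local),
        "max_nonlocal_r2": _max(nonlocal_),
        "partners": partners,
    }


def prune_by_ld(
    gm: GenotypeMatrix,
    marker_map: MarkerMap,
    r2_threshold: float = 0.7,
    min_obs: int = 20,
) -> list[str]:
    """Greedy left-to-right LD pruning within chromosomes.

    Scanning markers in (chromosome, position) order, a marker is dropped
    iff its r^2 with any already-kept marker on the same chromosome is
    strictly above ``r2_threshold``. The kept set therefore has all
    same-chromosome pairwise r^2 <= threshold.
    """
    ordered = marker_map.sorted().table
    ordered = ordered[ordered["marker_id"].isin(gm.marker_ids)]
    kept: list[str] = []
    for chrom, grp in ordered.groupby("chromosome", sort=False):
        ids = list(grp["marker_id"])
        if len(ids) == 1:
            kept.extend(ids)
            continue
        sub = gm.subset_markers(ids)
        r2, _ = r2_matrix(sub.dosage, min_obs=min_obs)
        kept_idx: list[int] = []
        for j in range(len(ids)):
            vals = r2[j, kept_idx] if kept_idx else np.array([])
            if vals.size and np.nanmax(np.append(vals, 0.0)) > r2_threshold:
                continue
            kept_idx.append(j)
        kept.extend(ids[j] for j in kept_idx)
    return kept
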