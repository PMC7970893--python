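"""Temporal breeding-signature analyses.

Decade cohorts, allele-frequency trajectories and their annual rate of
change, Nei's F_ST (pairwise ratio-of-sums and per-locus), a permutation
per-locus F_ST outlier scan with Benjamini-Hochberg FDR, and
reference-phased graphical genotypes for tracing introgression carriers.

Nei's estimator works from expected heterozygosities: with p_g the tracked-
allele frequency in group g and n_g the genotyped count, Hs is the size-
weighted mean of 2 p_g (1 - p_g), Ht = 2 p_bar (1 - p_bar) at the size-
weighted mean frequency, and F_ST = (Ht - Hs) / Ht. The pairwise statistic
sums Ht - Hs and Ht over loci before taking the ratio; the per-locus
statistic takes the ratio within each locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .panel_io import GenotypeMatrix, MarkerMap, PanelMetadata

DECADE_LABELS = ("1960s", "1970s", "1980s", "1990s", "2000s", "2010-2020")
DECADE_MIDPOINTS = {
    "1960s": 1965,
    "1970s": 1975,
    "1980s": 1985,
    "1990s": 1995,
    "2000s": 2005,
    "2010-2020": 2015,
}


@dataclass
class DecadeGroups:
    """Assignment of year-annotated individuals to six decade cohorts."""

    assignment: dict[str, str]  # individual_id -> group label
    excluded: list[str] = field(default_factory=list)

    @property
    def labels(self) -> tuple[str, ...]:
        return DECADE_LABELS

    def members(self, label: str) -> list[str]:
        return [g for g, lab in self.assignment.items() if lab == label]

    def sizes(self) -> dict[str, int]:
        return {lab: len(self.members(lab)) for lab in DECADE_LABELS}


def group_by_decade(meta: PanelMetadata) -> DecadeGroups:
    """Assign individuals to decade-of-registration cohorts.

    1960-1969 -> 1960s, ..., 2000-2009 -> 2000s, 2010-2020 -> 2010-2020.
    Individuals without a year or outside 1960-2020 are excluded and
    listed.
    """
    assignment: dict[str, str] = {}
    excluded: list[str] = []
    for _, row in meta.table.iterrows():
        gid = row["individual_id"]
        year = row["registration_year"]
        if pd.isna(year) or year < 1960 or year > 2020:
            excluded.append(gid)
            continue
        year = int(year)
        label = "2010-2020" if year >= 2010 else f"{(year // 10) * 10}s"
        assignment[gid] = label
    return DecadeGroups(assignment, excluded)


def _group_freqs(
    gm: GenotypeMatrix, groups: DecadeGroups, tracked_alt: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(group, marker) tracked-allele frequency and genotyped count.

    tracked_alt is a boolean vector: True where the tracked allele is the
    alternate (dosage-counted) allele, False where it is the reference.
    Returns (freq, n) each of shape (n_groups, n_markers); freq is nan
    where a group has no genotyped individual at a marker.
    """
    freq = np.full((len(DECADE_LABELS), gm.n_markers), np.nan)
    n = np.zeros((len(DECADE_LABELS), gm.n_markers), dtype=int)
    idx = {g: i for i, g in enumerate(gm.individual_ids)}
    for gi, label in enumerate(DECADE_LABELS):
        members = [idx[m] for m in groups.members(label) if m in idx]
        if not members:
            continue
        sub = gm.dosage[members, :]
        n[gi] = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_alt = np.nanmean(sub, axis=0) / 2.0
        freq[gi] = np.where(tracked_alt, p_alt, 1.0 - p_alt)
    return freq, n


def _panel_minor_mask(gm: GenotypeMatrix) -> np.ndarray:
    """True where the panel-wide minor allele is the alternate allele.

    Ties (frequency exactly 0.5) track the alternate allele.
    """
    p_alt = gm.allele_frequency()
    return np.where(np.isnan(p_alt), True, p_alt <= 0.5)


@dataclass
class FreqTrajectory:
    marker_id: str
    groups: tuple[str, ...]
    frequency: np.ndarray  # tracked-allele frequency per group, nan where absent
    n: np.ndarray  # genotyped individuals per group
    allele_rule: str = "panel_minor"


def allele_freq_trajectory(
    gm: GenotypeMatrix,
    groups: DecadeGroups,
    allele_rule: str = "panel_minor",
) -> dict[str, FreqTrajectory]:
    """Tracked-allele frequency per decade cohort, per marker.

    allele_rule 'panel_minor' tracks the panel-wide minor allele (fixed
    once per marker); 'alt' tracks the alternate (dosage) allele.
    """
    if allele_rule == "panel_minor":
        tracked_alt = _panel_minor_mask(gm)
    elif allele_rule == "alt":
        tracked_alt = np.ones(gm.n_markers, dtype=bool)
    else:
        raise ValueError(f"unknown allele rule {allele_rule!r}")
    freq, n = _group_freqs(gm, groups, tracked_alt)
    return {
        marker: FreqTrajectory(marker, DECADE_LABELS, freq[:, j], n[:, j], allele_rule)
        for j, marker in enumerate(gm.marker_ids)
    }


def annual_allele_change(traj: FreqTrajectory) -> float | None:
    """Weighted OLS slope of cohort frequency (in %) on cohort midpoint year.

    Weights are the per-cohort genotyped counts; returns % per year, or
    None with fewer than two defined points.
    """
    years = np.array([DECADE_MIDPOINTS[g] for g in traj.groups], dtype=float)
    y = traj.frequency * 100.0
    w = traj.n.astype(float)
    ok = ~np.isnan(y) & (w > 0)
    if ok.sum() < 2:
        return None
    x, y, w = years[ok], y[ok], w[ok]
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    denom = np.sum(w * (x - xbar) ** 2)
    if denom == 0:
        return None
    return float(np.sum(w * (x - xbar) * (y - ybar)) / denom)


@dataclass
class FstResult:
    scope: str  # pairwise_groups | per_locus
    hs: float
    ht: float
    fst: float | None


def _freq_and_n_for(
    gm: GenotypeMatrix, members_a: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    idx = {g: i for i, g in enumerate(gm.individual_ids)}
    rows = [idx[m] for m in members_a if m in idx]
    sub = gm.dosage[rows, :]
    n = (~np.isnan(sub)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(sub, axis=0) / 2.0
    return p, n


def nei_fst_pair(
    gm: GenotypeMatrix, members_a: list[str], members_b: list[str]
) -> FstResult:
    """Nei F_ST for one pair of groups, ratio of sums over loci."""
    pa, na = _freq_and_n_for(gm, members_a)
    pb, nb = _freq_and_n_for(gm, members_b)
    ok = (na > 0) & (nb > 0)
    pa, pb = pa[ok], pb[ok]
    wa = na[ok] / (na[ok] + nb[ok])
    pbar = wa * pa + (1 - wa) * pb
    ht = 2 * pbar * (1 - pbar)
    hs = wa * 2 * pa * (1 - pa) + (1 - wa) * 2 * pb * (1 - pb)
    sum_ht = float(ht.sum())
    sum_hs = float(hs.sum())
    if sum_ht == 0:
        return FstResult("pairwise_groups", sum_hs, sum_ht, None)
    return FstResult("pairwise_groups", sum_hs, sum_ht, (sum_ht - sum_hs) / sum_ht)


def nei_fst_pairwise(gm: GenotypeMatrix, groups: DecadeGroups) -> pd.DataFrame:
    """Matrix of pairwise Nei F_ST over all decade-cohort pairs."""
    labels = [lab for lab in DECADE_LABELS if groups.members(lab)]
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        out.loc[a, a] = 0.0
        for b in labels[i + 1 :]:
            res = nei_fst_pair(gm, groups.members(a), groups.members(b))
            val = np.nan if res.fst is None else res.fst
            out.loc[a, b] = out.loc[b, a] = val
    return out


def _per_locus_fst_from_freqs(freq: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized within-locus Nei F_ST across groups.

    freq, n: (n_groups, n_markers). nan where undefined (monomorphic across
    groups, or fewer than two genotyped groups).
    """
    w = np.where(np.isnan(freq), 0.0, n.astype(float))
    wsum = w.sum(axis=0)
    f0 = np.nan_to_num(freq, nan=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (w * f0).sum(axis=0) / wsum
        ht = 2 * pbar * (1 - pbar)
        hs = (w * 2 * f0 * (1 - f0)).sum(axis=0) / wsum
        fst = (ht - hs) / ht
    n_groups = (w > 0).sum(axis=0)
    fst[(n_groups < 2) | (ht <= 0)] = np.nan
    return fst


def per_locus_fst(gm: GenotypeMatrix, groups: DecadeGroups) -> pd.Series:
    """Per-locus Nei F_ST across all decade cohorts (nan where undefined)."""
    tracked_alt = np.ones(gm.n_markers, dtype=bool)  # label-invariant
    freq, n = _group_freqs(gm, groups, tracked_alt)
    fst = _per_locus_fst_from_freqs(freq, n)
    return pd.Series(fst, index=gm.marker_ids, name="fst")


def fst_outlier_scan(
    gm: GenotypeMatrix,
    groups: DecadeGroups,
    n_perm: int = 1000,
    q_threshold: float = 0.001,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation per-locus F_ST outlier scan with BH FDR control.

    The null distribution is generated by permuting cohort labels across
    the grouped individuals n_perm times and recomputing every per-locus
    F_ST; p = (1 + #{perm >= observed}) / (1 + n_perm), pooled over loci
    within each permutation scan. Monomorphic loci are absent from the
    output. This keeps the decision surface of an F_ST outlier scan
    (per-locus F_ST ranked, FDR threshold) with a permutation null in
    place of a Bayesian model.
    """
    import warnings

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse")
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(gm.individual_ids)}
    grouped = [(idx[g], lab) for g, lab in groups.assignment.items() if g in idx]
    rows = np.array([r for r, _ in grouped])
    labels = np.array([lab for _, lab in grouped])

    X = gm.dosage[rows, :]
    obs_mask = ~np.isnan(X)
    X0 = np.nan_to_num(X, nan=0.0)

    def fst_for(lab_vec: np.ndarray) -> np.ndarray:
        G = np.stack([(lab_vec == lab) for lab in DECADE_LABELS]).astype(float)
        n = G @ obs_mask  # genotyped count per (group, marker)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = (G @ X0) / (2.0 * n)
        freq[n == 0] = np.nan
        return _per_locus_fst_from_freqs(freq, n)

    observed = fst_for(labels)
    tested = ~np.isnan(observed)
    obs_vals = observed[tested]

    exceed = np.zeros(obs_vals.size, dtype=int)
    for _ in range(n_perm):
        perm = fst_for(rng.permutation(labels))
        exceed += np.nan_to_num(perm[tested], nan=-np.inf) >= obs_vals
    p = (1.0 + exceed) / (1.0 + n_perm)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "marker_id": np.asarray(gm.marker_ids)[tested],
            "fst": obs_vals,
            "p_value": p,
            "q_value": q,
            "outlier": q < q_threshold,
        }
    )
    return out


@dataclass
class GraphicalGenotypes:
    """Region genotypes coded against a reference carrier haplotype."""

    chromosome: str
    start_bp: int
    end_bp: int
    reference_individual: str
    codes: pd.DataFrame  # individuals x region markers; {match,mismatch,het,missing}
    match_fraction: pd.Series  # per individual, over non-missing codes


def phase_to_reference(
    gm: GenotypeMatrix,
    marker_map: MarkerMap,
    region: tuple[str, int, int],
    reference_individual: str,
) -> GraphicalGenotypes:
    """Code each individual against a reference individual over a region.

    A cell is 'match' iff both calls are homozygous and equal, 'het' when
    either call is heterozygous (conservative: never counted as a match),
    'missing' when either is missing. The match fraction is matches over
    non-missing codes.
    """
    chrom, start, end = region
    mt = marker_map.table
    sel = mt[
        (mt["chromosome"] == chrom)
        & (mt["position_bp"] >= start)
        & (mt["position_bp"] <= end)
        & (mt["marker_id"].isin(gm.marker_ids))
    ].sort_values("position_bp", kind="mergesort")
    if sel.empty:
        raise ValueError(f"no markers in region {chrom}:{start}-{end}")
    marker_ids = list(sel["marker_id"])
    sub = gm.subset_markers(marker_ids)
    try:
        ref_row = sub.individual_ids.index(reference_individual)
    except ValueError:
        raise KeyError(f"reference individual {reference_individual!r} not in panel")
    ref = sub.dosage[ref_row]
    if np.isnan(ref).all():
        raise ValueError("reference individual missing at every region marker")

    D = sub.dosage
    codes = np.full(D.shape, "mismatch", dtype=object)
    codes[(D == ref[None, :]) & (D != 1)] = "match"
    codes[(D == 1) | (ref[None, :] == 1)] = "het"
    codes[np.isnan(D) | np.isnan(ref)[None, :]] = "missing"
    frame = pd.DataFrame(codes, index=sub.individual_ids, columns=marker_ids)
    informative = (frame != "missing").sum(axis=1)
    matches = (frame == "match").sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = matches / informative.replace(0, np.nan)
    return GraphicalGenotypes(
        chrom, start, end, reference_individual, frame, frac.rename("match_fraction")
    )


def call_introgression_carriers(
    gg: GraphicalGenotypes,
    meta: PanelMetadata,
    match_threshold: float = 0.9,
) -> pd.DataFrame:
    """Carriers = individuals matching the reference haplotype at >= threshold.

    Returns carriers sorted by registration year (unknown years last), with
    a boolean first_carrier column marking the minimum-year carrier(s).
    """
    years = meta.table.set_index("individual_id")["registration_year"]
    rows = []
    for gid, frac in gg.match_fraction.items():
        if pd.isna(frac) or frac < match_threshold:
            continue
        year = years.get(gid, np.nan)
        rows.append((gid, year, float(frac)))
    out = pd.DataFrame(rows, columns=["individual_id", "registration_year", "match_fraction"])
    out = out.sort_values(
        ["registration_year", "individual_id"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    known = out["registration_year"].dropna()
    first_year = known.min() if not known.empty else np.nan
    out["first_carrier"] = out["registration_year"] == first_year
    return out
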