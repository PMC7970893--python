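"""Marker retention rules with per-marker audit ledgers.

Three independent filters: alignment-hit uniqueness/mismatch, genotype
MAF/missingness/monomorphism, and Axiom cluster-QC. Each returns a
:class:`FilterReport` so a chained run reproduces a "retained N markers"
style audit. Chaining order in the CLI: axiom_qc -> alignment_hits ->
genotype_markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import AlignmentHitTable, AxiomQCTable, GenotypeMatrix, MarkerMap


@dataclass
class FilterReport:
    """Kept/removed decision with reason for every input marker of one rule."""

    rule_name: str
    decisions: pd.DataFrame  # columns: marker_id, decision {kept,removed}, reason

    def __post_init__(self) -> None:
        if self.decisions["marker_id"].duplicated().any():
            raise ValueError("marker appears twice in filter report")

    @property
    def n_in(self) -> int:
        return len(self.decisions)

    @property
    def n_kept(self) -> int:
        return int((self.decisions["decision"] == "kept").sum())

    def kept_ids(self) -> list[str]:
        return list(
            self.decisions.loc[self.decisions["decision"] == "kept", "marker_id"]
        )

    def to_tsv(self, path: str) -> None:
        self.decisions.to_csv(path, sep="\t", index=False)


def filter_alignment_hits(
    hits: AlignmentHitTable,
    max_mismatch: int = 1,
    min_separation: int = 3,
) -> tuple[MarkerMap, FilterReport]:
    """Keep markers whose best alignment is unique and near-perfect.

    A marker is kept with its rank-1 placement iff the rank-1 hit has at
    most ``max_mismatch`` mismatches AND either no rank-2 hit exists or the
    rank-2 hit is at least ``min_separation`` mismatches worse. Rank-2 hits
    of kept markers remain available downstream as relocation candidates.
    """
    rows = []
    decisions = []
    for marker, grp in hits.table.groupby("marker_id", sort=True):
        grp = grp.sort_values("hit_rank")
        best = grp.iloc[0]
        if int(best["mismatches"]) > max_mismatch:
            decisions.append(
                (marker, "removed", f"best_hit_mismatches>{max_mismatch}")
            )
            continue
        if len(grp) > 1:
            second = grp.iloc[1]
            sep = int(second["mismatches"]) - int(best["mismatches"])
            if sep < min_separation:
                decisions.append(
                    (marker, "removed", f"second_hit_separation<{min_separation}")
                )
                continue
        decisions.append((marker, "kept", "unique_best_hit"))
        rows.append(
            (marker, str(best["chromosome"]), int(best["position_bp"]), "other")
        )
    best_map = MarkerMap(
        pd.DataFrame(
            rows, columns=["marker_id", "chromosome", "position_bp", "source_array"]
        )
    )
    report = FilterReport(
        "alignment_hits",
        pd.DataFrame(decisions, columns=["marker_id", "decision", "reason"]),
    )
    return best_map, report


def filter_genotype_markers(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove monomorphic, rare (MAF < maf_min) and gappy (missing > miss_max)
    markers.

    Both thresholds are strict: MAF exactly maf_min and missing fraction
    exactly miss_max are kept. MAF uses the allele count over 2 x non-missing
    individuals; heterozygotes contribute one copy of each allele.
    """
    if gm.n_markers == 0 or gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    maf = gm.maf()
    missing = gm.missing_fraction()
    n_nonmiss = (~np.isnan(gm.dosage)).sum(axis=0)
    decisions = []
    for j, marker in enumerate(gm.marker_ids):
        if n_nonmiss[j] == 0:
            decisions.append((marker, "removed", "all_missing"))
        elif maf[j] == 0.0:
            decisions.append((marker, "removed", "monomorphic"))
        elif missing[j] > miss_max:
            decisions.append((marker, "removed", f"missing>{miss_max}"))
        elif maf[j] < maf_min:
            decisions.append((marker, "removed", f"maf<{maf_min}"))
        else:
            decisions.append((marker, "kept", "pass"))
    report = FilterReport(
        "genotype_markers",
        pd.DataFrame(decisions, columns=["marker_id", "decision", "reason"]),
    )
    kept = report.kept_ids()
    return gm.subset_markers(kept), report


def filter_axiom_qc(
    qc: AxiomQCTable,
    fld_min: float = 4.0,
    homfld_min: float = 8.0,
) -> FilterReport:
    """Array cluster-quality filter.

    Kept iff class is PolyHighResolution or OffTargetVariant, FLD >= fld_min
    (inclusive) and HomFLD, when present, >= homfld_min. An absent HomFLD
    (no homozygote clusters formed) does not by itself remove a marker.
    """
    decisions = []
    for _, row in qc.table.iterrows():
        marker = row["marker_id"]
        if row["class_label"] not in ("PolyHighResolution", "OffTargetVariant"):
            decisions.append((marker, "removed", "class_not_phr_or_otv"))
        elif not pd.isna(row["fld"]) and row["fld"] < fld_min:
            decisions.append((marker, "removed", f"fld<{fld_min}"))
        elif pd.isna(row["fld"]):
            decisions.append((marker, "removed", "fld_absent"))
        elif not pd.isna(row["homfld"]) and row["homfld"] < homfld_min:
            decisions.append((marker, "removed", f"homfld<{homfld_min}"))
        else:
            decisions.append((marker, "kept", "pass"))
    return FilterReport(
        "axiom_qc",
        pd.DataFrame(decisions, columns=["marker_id", "decision", "reason"]),
    )
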