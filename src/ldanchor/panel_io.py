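"""Readers, writers and validated containers for panel data.

All tabular dialects are UTF-8, tab-separated, single header line.
Physical positions are 1-based inclusive bp throughout the package;
``bed_interval``/``from_bed_interval`` convert at the I/O boundary only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKENS = {"NA", "-9", ""}

SOURCE_ARRAYS = ("15K", "135K", "other")


class PanelIOError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers biallelic dosage calls.

    ``dosage`` is a float array with values in {0, 1, 2, nan}; nan encodes a
    missing call. Row order follows ``individual_ids``, column order
    ``marker_ids``.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.individual_ids) or m != len(self.marker_ids):
            raise PanelIOError("dosage shape does not match id lists")
        if len(set(self.individual_ids)) != n:
            raise PanelIOError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise PanelIOError("duplicate marker ids")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise PanelIOError(f"dosage value {bad!r} outside {{0,1,2,NA}}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in matrix") from None

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.dosage).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over non-missing calls.

        Denominator is 2 x (non-missing individuals); heterozygotes
        contribute one copy of each allele. nan where all calls missing.
        """
        counts = (~np.isnan(self.dosage)).sum(axis=0)
        sums = np.nansum(self.dosage, axis=0)
        return np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, marker_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in marker_ids]
        return GenotypeMatrix(
            list(self.individual_ids), list(marker_ids), self.dosage[:, idx]
        )

    def subset_individuals(self, individual_ids: list[str]) -> "GenotypeMatrix":
        lookup = {g: i for i, g in enumerate(self.individual_ids)}
        idx = [lookup[g] for g in individual_ids]
        return GenotypeMatrix(
            list(individual_ids), list(self.marker_ids), self.dosage[idx, :]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.individual_ids, columns=self.marker_ids
        )


@dataclass
class MarkerMap:
    """Per-marker chromosome and 1-based bp position.

    Wraps a DataFrame with columns marker_id, chromosome, position_bp,
    source_array; marker_id unique, positions strictly positive.
    """

    table: pd.DataFrame

    REQUIRED = ("marker_id", "chromosome", "position_bp", "source_array")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise PanelIOError(f"marker map missing columns {missing}")
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise PanelIOError(f"duplicate marker id {dup!r} in map")
        if len(df) == 0:
            df = df.assign(position_bp=df["position_bp"].astype(int))
        pos = df["position_bp"]
        if not np.issubdtype(pos.dtype, np.integer):
            raise PanelIOError("position_bp must be integer")
        if (pos <= 0).any():
            bad = df.loc[pos <= 0, "marker_id"].iloc[0]
            raise PanelIOError(f"non-positive position for marker {bad!r}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, marker_id: str) -> tuple[str, int]:
        row = self.table.loc[self.table["marker_id"] == marker_id]
        if row.empty:
            raise KeyError(f"marker {marker_id!r} not in map")
        return str(row["chromosome"].iloc[0]), int(row["position_bp"].iloc[0])

    def sorted(self) -> "MarkerMap":
        return MarkerMap(
            self.table.sort_values(
                ["chromosome", "position_bp", "marker_id"], kind="mergesort"
            ).reset_index(drop=True)
        )


def subgenome(chromosome: str) -> str:
    """Wheat subgenome letter (A/B/D) for names like '1A'..'7D', else 'other'."""
    if (
        len(chromosome) == 2
        and chromosome[0] in "1234567"
        and chromosome[1] in "ABD"
    ):
        return chromosome[1]
    return "other"


def bed_interval(position_bp: int, length: int = 1) -> tuple[int, int]:
    """1-based inclusive bp -> 0-based half-open BED interval."""
    return position_bp - 1, position_bp - 1 + length


def from_bed_interval(start: int) -> int:
    """0-based half-open BED start -> 1-based bp."""
    return start + 1


@dataclass
class AlignmentHitTable:
    """Ranked candidate placements per marker with mismatch counts.

    Within a marker, hit_rank runs 1, 2, ... consecutively and mismatches
    are non-decreasing with rank.
    """

    table: pd.DataFrame

    REQUIRED = ("marker_id", "hit_rank", "chromosome", "position_bp", "mismatches")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise PanelIOError(f"hit table missing columns {missing}")
        df = df.sort_values(["marker_id", "hit_rank"], kind="mergesort").reset_index(
            drop=True
        )
        for marker, grp in df.groupby("marker_id", sort=False):
            ranks = grp["hit_rank"].to_numpy()
            if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
                raise PanelIOError(
                    f"marker {marker!r}: hit ranks {list(ranks)} not consecutive from 1"
                )
            mm = grp["mismatches"].to_numpy()
            if (np.diff(mm) < 0).any():
                raise PanelIOError(
                    f"marker {marker!r}: mismatches decrease with rank"
                )
            if (mm < 0).any():
                raise PanelIOError(f"marker {marker!r}: negative mismatch count")
        self.table = df

    def hit(self, marker_id: str, rank: int) -> pd.Series | None:
        sel = self.table[
            (self.table["marker_id"] == marker_id) & (self.table["hit_rank"] == rank)
        ]
        return None if sel.empty else sel.iloc[0]

    def marker_ids(self) -> list[str]:
        return list(self.table["marker_id"].unique())


@dataclass
class PanelMetadata:
    """Cultivar identity, registration year and origin per individual."""

    table: pd.DataFrame

    REQUIRED = ("individual_id", "cultivar_name", "registration_year", "origin")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise PanelIOError(f"metadata missing columns {missing}")
        if df["individual_id"].duplicated().any():
            raise PanelIOError("duplicate individual id in metadata")
        years = df["registration_year"].dropna()
        if ((years < 1900) | (years > 2100)).any():
            raise PanelIOError("registration year outside [1900, 2100]")
        self.table = df.reset_index(drop=True)

    def year_of(self, individual_id: str) -> float:
        row = self.table.loc[self.table["individual_id"] == individual_id]
        if row.empty:
            raise KeyError(individual_id)
        return row["registration_year"].iloc[0]


@dataclass
class AxiomQCTable:
    """Array cluster-QC metrics: class label, FLD and HomFLD per marker."""

    table: pd.DataFrame

    REQUIRED = ("marker_id", "class_label", "fld", "homfld")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise PanelIOError(f"QC table missing columns {missing}")
        for col in ("fld", "homfld"):
            vals = df[col].dropna()
            if not np.isfinite(vals).all():
                raise PanelIOError(f"non-finite {col} value")
        self.table = df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# genotype I/O


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):  # pandas would silently mangle these
        dup = pd.Index(header)[pd.Index(header).duplicated()][0]
        raise PanelIOError(f"duplicate marker id {dup!r} in genotype header")
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, index_col=0
    )
    markers = list(df.columns)
    raw = df.to_numpy()
    out = np.empty(raw.shape, dtype=float)
    for tok, val in (("0", 0.0), ("1", 1.0), ("2", 2.0)):
        out[raw == tok] = val
    miss = np.isin(raw, list(MISSING_TOKENS))
    out[miss] = np.nan
    bad = ~miss & ~np.isin(raw, ("0", "1", "2"))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PanelIOError(
            f"invalid dosage {raw[i, j]!r} for individual "
            f"{df.index[i]!r} marker {markers[j]!r}"
        )
    return GenotypeMatrix(list(df.index.astype(str)), markers, out)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise PanelIOError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT) or '.'}) — biallelic SNPs only"
            )
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if mid in seen:
            raise PanelIOError(f"duplicate marker id {mid!r} in VCF")
        seen.add(mid)
        marker_ids.append(mid)
        # allele pairs with -1 for a missing allele; a half-missing call
        # ("0/.") has no defined dosage and is treated as missing
        dos = np.empty(len(individuals), dtype=float)
        for i, alleles in enumerate(rec.genotypes):
            a1, a2 = alleles[0], alleles[1]
            dos[i] = np.nan if (a1 < 0 or a2 < 0) else float(a1 + a2)
        rows.append(dos)
    vcf.close()
    dosage = (
        np.column_stack(rows)
        if rows
        else np.empty((len(individuals), 0), dtype=float)
    )
    return GenotypeMatrix(individuals, marker_ids, dosage)


def read_genotypes(path: str, format_hint: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF (v4.2, GT field) or dosage TSV.

    Format is taken from ``format_hint`` ('vcf' or 'tsv') or inferred from
    the file extension. Heterozygous VCF genotypes become dosage 1;
    half-missing genotypes become missing.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_dosage_tsv(path)
    raise PanelIOError(f"unknown genotype format {fmt!r}")


def write_genotypes(gm: GenotypeMatrix, path: str) -> None:
    """Write the dosage TSV dialect (missing written as NA)."""
    df = gm.to_dataframe()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "individual_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# marker map I/O


def read_marker_map(path: str) -> MarkerMap:
    """Read a marker map: native 4-column TSV or PLINK-style .map.

    A PLINK .map line is ``chrom marker cM bp`` (whitespace separated, no
    header); the cM column is ignored and source_array set to 'other'.
    """
    if str(path).endswith(".map"):
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["chromosome", "marker_id", "cm", "position_bp"],
            dtype={"chromosome": str, "marker_id": str},
        )
        df = df[["marker_id", "chromosome", "position_bp"]]
        df["source_array"] = "other"
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "marker_id": str})
    pos = pd.to_numeric(df["position_bp"], errors="coerce")
    if pos.isna().any() or (pos != pos.astype("Int64").astype(float)).any():
        bad = df.loc[pos.isna() | (pos % 1 != 0), "marker_id"].iloc[0]
        raise PanelIOError(f"non-integer position for marker {bad!r}")
    df["position_bp"] = pos.astype(int)
    return MarkerMap(df)


def write_marker_map(marker_map: MarkerMap, path: str) -> None:
    marker_map.table[list(MarkerMap.REQUIRED)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hits / metadata / QC I/O


def read_hits(path: str) -> AlignmentHitTable:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    return AlignmentHitTable(df)


def write_hits(hits: AlignmentHitTable, path: str) -> None:
    hits.table.to_csv(path, sep="\t", index=False)


def read_metadata(path: str) -> PanelMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "origin": str})
    df["registration_year"] = pd.to_numeric(
        df["registration_year"], errors="coerce"
    )
    return PanelMetadata(df)


def write_metadata(meta: PanelMetadata, path: str) -> None:
    out = meta.table.copy()
    out["registration_year"] = out["registration_year"].map(
        lambda y: "" if pd.isna(y) else str(int(y))
    )
    out.to_csv(path, sep="\t", index=False)


def read_axiom_qc(path: str) -> AxiomQCTable:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "class_label": str})
    return AxiomQCTable(df)


def write_axiom_qc(qc: AxiomQCTable, path: str) -> None:
    qc.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SAM convenience converter (optional path into the hits dialect)


def sam_to_hits(path: str) -> AlignmentHitTable:
    """Convert a SAM file of marker-sequence alignments to the hits dialect.

    Alignments are grouped per query name, ranked by NM tag (edit distance,
    ascending; ties by alignment score AS descending, then coordinate), and
    emitted as hit_rank 1, 2, ... with mismatches = NM. Unmapped reads are
    skipped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            score = aln.get_tag("AS") if aln.has_tag("AS") else 0
            rows.append(
                (
                    aln.query_name,
                    nm,
                    -score,
                    aln.reference_name,
                    aln.reference_start + 1,  # SAM is 1-based in text, pysam 0-based
                )
            )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3], r[4]))
    out = []
    prev = None
    rank = 0
    for name, nm, _negscore, chrom, pos in rows:
        rank = rank + 1 if name == prev else 1
        prev = name
        out.append((name, rank, chrom, pos, nm))
    df = pd.DataFrame(
        out, columns=["marker_id", "hit_rank", "chromosome", "position_bp", "mismatches"]
    )
    return AlignmentHitTable(df)


def validate_panel(
    gm: GenotypeMatrix,
    marker_map: MarkerMap | None = None,
    meta: PanelMetadata | None = None,
) -> list[str]:
    """Cross-link checks; returns a list of human-readable problems (empty = ok)."""
    problems = []
    if marker_map is not None:
        mapped = set(marker_map.table["marker_id"])
        missing = [m for m in gm.marker_ids if m not in mapped]
        if missing:
            problems.append(
                f"{len(missing)} genotyped markers absent from map "
                f"(first: {missing[0]!r})"
            )
    if meta is not None:
        known = set(meta.table["individual_id"])
        missing = [g for g in gm.individual_ids if g not in known]
        if missing:
            problems.append(
                f"{len(missing)} individuals absent from metadata "
                f"(first: {missing[0]!r})"
            )
    return problems
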