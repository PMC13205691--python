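"""Readers, writers and validation for every table the pipeline touches.

All tables are UTF-8, tab-separated, with a mandatory header row. Missing
values are forbidden in abundance matrices (absence is encoded as 0), and
sample identifiers join across tables by exact string match.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ParseError",
    "UnitError",
    "ABUNDANCE_UNITS",
    "AbundanceMatrix",
    "read_abundance",
    "write_abundance",
    "filter_taxa",
    "read_sample_info",
    "validate_sample_info",
    "read_annotations",
    "validate_annotations",
    "read_hgt_events",
    "write_hgt_events",
    "AlignmentHit",
    "read_alignment_hits",
    "write_alignment_hits",
    "read_gene_abundance",
    "validate_gene_abundance",
]


class SchemaError(ValueError):
    """A table violates a declared invariant (duplicates, negatives, bad unit)."""


class ParseError(ValueError):
    """A file cannot be parsed into the expected shape."""


class UnitError(ValueError):
    """An operation received a matrix in an incompatible unit."""


#: Recognised abundance units. ``normalized_1e10`` is the coverage-style
#: normalization mapped_reads / (L * N) * 1e10; the two relative units differ
#: only in scale (fractions sum to <=1 per sample, percents to <=100).
ABUNDANCE_UNITS = ("read_count", "relative_fraction", "relative_percent", "normalized_1e10")

_RELATIVE_UNITS = ("relative_fraction", "relative_percent")


@dataclass
class AbundanceMatrix:
    """Nonnegative taxa x samples abundance matrix with a declared unit.

    ``data`` is indexed by taxon id with sample ids as columns. The unit is
    carried as explicit metadata so downstream thresholds (e.g. the retention
    filter) are always interpreted on a known scale.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.unit not in ABUNDANCE_UNITS:
            raise SchemaError(f"unknown abundance unit {self.unit!r}; expected one of {ABUNDANCE_UNITS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate taxon ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups}")
        if self.data.isna().any().any():
            raise SchemaError("missing values are forbidden in abundance matrices; encode absence as 0")
        vals = self.data.to_numpy(dtype=float)
        if (vals < 0).any():
            raise SchemaError("negative abundance value")
        if self.unit == "relative_fraction":
            colsums = vals.sum(axis=0)
            if (colsums > 1 + 1e-9).any():
                raise SchemaError("relative_fraction column sums exceed 1")
        elif self.unit == "relative_percent":
            colsums = vals.sum(axis=0)
            if (colsums > 100 + 1e-6).any():
                raise SchemaError("relative_percent column sums exceed 100")

    # -- convenience ------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise SchemaError(f"sample ids not in matrix: {missing}")
        return AbundanceMatrix(self.data.loc[:, list(sample_ids)].copy(), self.unit)


def read_abundance(path: str | Path | io.TextIOBase, unit: str) -> AbundanceMatrix:
    """Read a taxa x samples TSV (first column taxon ids, header sample ids)."""
    if unit not in ABUNDANCE_UNITS:
        raise SchemaError(f"unknown abundance unit {unit!r}")
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    header = text.splitlines()[0].split("\t") if text else []
    sample_header = header[1:]
    if len(set(sample_header)) != len(sample_header):
        # checked on the raw header because DataFrame readers rename duplicates
        raise SchemaError("duplicate sample ids in header")
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype={0: str})
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(str(exc)) from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        raise ParseError("missing or short row in abundance table")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric abundance value: {exc}") from exc
    return AbundanceMatrix(df, unit)


def write_abundance(m: AbundanceMatrix, path: str | Path) -> None:
    out = m.data.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t", float_format="%.17g")  # full precision: read∘write = id


def filter_taxa(
    m: AbundanceMatrix,
    relab_threshold: float = 0.2,
    prevalence_fraction: float = 0.01,
) -> AbundanceMatrix:
    """Retention filter: keep a taxon if its maximum relative abundance across
    samples exceeds ``relab_threshold`` OR it is detected (value > 0) in at
    least ``prevalence_fraction`` of samples.

    The threshold is interpreted in the matrix's declared relative unit; count
    matrices must be converted to relative abundance first.
    """
    if m.unit not in _RELATIVE_UNITS:
        raise UnitError(f"filter_taxa requires a relative unit, got {m.unit!r}")
    vals = m.values
    n_samples = vals.shape[1]
    if n_samples == 0:
        raise SchemaError("matrix has no samples")
    max_relab = vals.max(axis=1)
    prevalence = (vals > 0).sum(axis=1) / n_samples
    keep = (max_relab > relab_threshold) | (prevalence >= prevalence_fraction)
    return AbundanceMatrix(m.data.loc[keep].copy(), m.unit)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

SAMPLE_INFO_COLUMNS = ["sample_id", "subject_id", "group", "day", "project_id"]


def validate_sample_info(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_INFO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample metadata missing columns: {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["day"] = df["day"].astype(int)
    if df["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_id in metadata")
    dup = df.duplicated(subset=["project_id", "subject_id", "day"])
    if dup.any():
        raise SchemaError("(subject_id, day) not unique within a project")
    return df


def read_sample_info(path: str | Path) -> pd.DataFrame:
    return validate_sample_info(pd.read_csv(path, sep="\t"))


def check_samples_covered(m: AbundanceMatrix, sample_info: pd.DataFrame) -> None:
    """Every sample id in the matrix must appear in the metadata."""
    known = set(sample_info["sample_id"])
    unknown = [s for s in m.sample_ids if s not in known]
    if unknown:
        raise SchemaError(f"matrix samples missing from metadata: {unknown}")


# ---------------------------------------------------------------------------
# Taxon annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "taxon_id",
    "species_name",
    "kingdom",
    "lifestyle",
    "host_genus",
    "host_phylum",
    "host_link_method",
]

_KINGDOMS = {"virus", "bacterium"}
_LIFESTYLES = {"virulent", "temperate", "unknown"}
_LINK_METHODS = {"nomenclature", "crassphage_override", "provided", "none"}


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table missing columns: {missing}")
    df = df.copy()
    for col in ("host_genus", "host_phylum"):
        df[col] = df[col].where(df[col].notna(), None)
        df[col] = df[col].replace({"": None})
    if df["taxon_id"].duplicated().any():
        raise SchemaError("duplicate taxon_id in annotations")
    bad_kingdom = set(df["kingdom"]) - _KINGDOMS
    if bad_kingdom:
        raise SchemaError(f"unknown kingdom values: {bad_kingdom}")
    bad_ls = set(df["lifestyle"]) - _LIFESTYLES
    if bad_ls:
        raise SchemaError(f"unknown lifestyle values: {bad_ls}")
    bad_m = set(df["host_link_method"]) - _LINK_METHODS
    if bad_m:
        raise SchemaError(f"unknown host_link_method values: {bad_m}")
    linked = df["host_link_method"] != "none"
    if (linked & df["host_genus"].isna()).any():
        raise SchemaError("linked taxa must carry a host_genus")
    if (~linked & df["host_genus"].notna()).any():
        raise SchemaError("host fields must be empty when host_link_method is 'none'")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    return validate_annotations(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# HGT events
# ---------------------------------------------------------------------------

HGT_COLUMNS = [
    "event_id",
    "donor_taxon",
    "recipient_taxon",
    "gene_id",
    "amino_acid_identity",
    "gene_cluster_coverage",
    "alignment_length_bp",
    "group",
    "phage_contig_id",
    "phage_nt_identity",
    "phage_e_value",
    "phage_mediated",
]


def validate_hgt_events(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HGT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"HGT table missing columns: {missing}")
    df = df.copy()
    if df["event_id"].duplicated().any():
        raise SchemaError("duplicate event_id in HGT table")
    df["phage_mediated"] = df["phage_mediated"].astype(bool)
    flagged = df["phage_mediated"]
    if (flagged & df["phage_contig_id"].isna()).any():
        raise SchemaError("phage_mediated=True requires a phage hit")
    return df


def read_hgt_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"event_id": str, "donor_taxon": str, "recipient_taxon": str, "gene_id": str},
    )
    return validate_hgt_events(df)


def write_hgt_events(df: pd.DataFrame, path: str | Path) -> None:
    validate_hgt_events(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment hits (12-column tabular alignment convention, BLAST outfmt 6)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise SchemaError(f"identity {self.identity} outside [0, 100]")
        if self.e_value < 0:
            raise SchemaError(f"negative e_value {self.e_value}")

    def to_row(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.identity:.3f}",
                str(self.alignment_length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                f"{self.e_value:.17g}",
                f"{self.bit_score:.10g}",
            ]
        )


def read_alignment_hits(path: str | Path | io.TextIOBase) -> list[AlignmentHit]:
    """Parse 12-column tab-separated alignment rows (the outfmt-6 convention)."""
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 12:
            raise ParseError(f"line {lineno}: expected 12 tab-separated columns, got {len(parts)}")
        try:
            hits.append(
                AlignmentHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    e_value=float(parts[10]),
                    bit_score=float(parts[11]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return hits


def write_alignment_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    Path(path).write_text("\n".join(h.to_row() for h in hits) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Gene-level abundance (HGT enzyme classes and KOs), long format
# ---------------------------------------------------------------------------

GENE_ABUNDANCE_COLUMNS = ["gene_key", "pathway", "sample_id", "value"]


def validate_gene_abundance(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_ABUNDANCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"gene abundance table missing columns: {missing}")
    df = df.copy()
    if df["gene_key"].isna().any() or (df["gene_key"].astype(str).str.len() == 0).any():
        raise SchemaError("empty gene_key")
    df["value"] = df["value"].astype(float)
    if (df["value"] < 0).any():
        raise SchemaError("negative gene abundance value")
    return df


def read_gene_abundance(path: str | Path) -> pd.DataFrame:
    return validate_gene_abundance(pd.read_csv(path, sep="\t", dtype={"gene_key": str, "sample_id": str}))
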