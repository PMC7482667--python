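"""Readers and writers for every format the pipeline touches.

Abundance tables travel as CSV (first column protein IDs, header row sample
IDs, empty cell = missing value), networks as SIF plus a tab-separated edge
attribute table, sequences as 60-column-wrapped FASTA, and SRM transitions
as a fixed-schema CSV.  Phosphosite annotation strings of the form
``Phospho [S832; S834; S857]`` are parsed into (residue, position) site
lists with 1-based protein coordinates.

No reader silently drops input: malformed rows raise, and skipped blank
lines are reported through the module logger.
"""

from __future__ import annotations

import csv
import io as _stdio
import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Sample groups of the study design: non-tumor dura and arachnoid
#: controls and the three WHO meningioma grades.
CANONICAL_GROUPS = ("DURA", "ARACH", "MGI", "MGII", "MGIII")

#: Cell contents treated as a missing abundance by default.  Exports from
#: quantification software use blank cells and NA spellings interchangeably.
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan"})

TRANSITION_COLUMNS = (
    "protein",
    "peptide",
    "modified_sequence",
    "precursor_mz",
    "precursor_z",
    "fragment",
    "fragment_z",
    "fragment_mz",
    "library_intensity",
)


# ---------------------------------------------------------------------------
# Abundance matrix container
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Protein-by-sample intensity table.

    Parameters
    ----------
    values
        DataFrame with protein IDs as index and sample IDs as columns.
        ``NaN`` marks a missing observation (the missing mask).
    scale
        ``"linear"`` for raw intensities (strictly positive where observed)
        or ``"log2"`` for log2-transformed values.
    unique_peptide_counts
        Optional per-protein count of unique identifying peptides, used by
        the >=2-unique-peptide confidence filter.
    """

    values: pd.DataFrame
    scale: str = "linear"
    unique_peptide_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein IDs: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        self.values = self.values.astype(float)
        if self.scale == "linear":
            observed = self.values.to_numpy()
            if np.any(observed[np.isfinite(observed)] <= 0):
                raise ValueError("linear-scale abundances must be strictly positive")
        if self.unique_peptide_counts is not None:
            missing = self.values.index.difference(self.unique_peptide_counts.index)
            if len(missing):
                raise ValueError(
                    f"unique_peptide_counts lacks entries for proteins: {missing.tolist()}"
                )
            self.unique_peptide_counts = self.unique_peptide_counts.reindex(
                self.values.index
            ).astype(int)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean grid, True where the value is absent."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def is_complete(self) -> bool:
        return not bool(self.values.isna().to_numpy().any())

    def copy_with(self, values: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(
            values=values,
            scale=self.scale if scale is None else scale,
            unique_peptide_counts=None
            if self.unique_peptide_counts is None
            else self.unique_peptide_counts.reindex(values.index),
        )


def read_abundance_csv(
    text: str,
    missing_tokens: frozenset[str] | set[str] = DEFAULT_MISSING_TOKENS,
    scale: str = "linear",
    unique_peptide_counts: pd.Series | None = None,
) -> AbundanceMatrix:
    """Parse an abundance CSV into an :class:`AbundanceMatrix`.

    The table must be rectangular with a header row of sample IDs and
    protein IDs in the first column.  Cells matching ``missing_tokens``
    become masked entries.  Ragged rows and duplicate IDs raise.
    """
    reader = csv.reader(_stdio.StringIO(text))
    rows = list(reader)
    # drop trailing fully blank lines (a final newline yields none with csv)
    while rows and all(cell.strip() == "" for cell in rows[-1]):
        logger.info("read_abundance_csv: skipped blank trailing line")
        rows.pop()
    if not rows:
        raise ValueError("empty abundance table")
    header = rows[0]
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ValueError(f"duplicate sample ID in header: {sid!r}")
        seen.add(sid)
    n_fields = len(header)
    protein_ids: list[str] = []
    data: list[list[float]] = []
    seen_prot: set[str] = set()
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != n_fields:
            raise ValueError(
                f"row {i}: expected {n_fields} fields, got {len(row)}"
            )
        pid = row[0]
        if pid in seen_prot:
            raise ValueError(f"duplicate protein ID: {pid!r}")
        seen_prot.add(pid)
        protein_ids.append(pid)
        vals = []
        for j, cell in enumerate(row[1:]):
            token = cell.strip()
            if token in missing_tokens:
                vals.append(math.nan)
            else:
                try:
                    vals.append(float(token))
                except ValueError as exc:
                    raise ValueError(
                        f"row {i}, sample {sample_ids[j]!r}: "
                        f"non-numeric value {cell!r}"
                    ) from exc
        data.append(vals)
    df = pd.DataFrame(data, index=protein_ids, columns=sample_ids, dtype=float)
    return AbundanceMatrix(df, scale=scale, unique_peptide_counts=unique_peptide_counts)


def write_abundance_csv(matrix: AbundanceMatrix) -> str:
    """Serialize to the canonical CSV dialect (blank cell = missing)."""
    df = matrix.values.copy()
    df.index.name = "protein"
    return df.to_csv(na_rep="")


def read_metadata_csv(text: str) -> pd.Series:
    """Read sample->group metadata from a CSV with columns sample,group[,note]."""
    df = pd.read_csv(_stdio.StringIO(text), dtype=str)
    if "sample" not in df.columns or "group" not in df.columns:
        raise ValueError("metadata CSV requires 'sample' and 'group' columns")
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample IDs in metadata: {dupes}")
    return pd.Series(df["group"].to_numpy(), index=df["sample"].to_numpy(), name="group")


def write_metadata_csv(metadata: pd.Series) -> str:
    df = pd.DataFrame({"sample": metadata.index, "group": metadata.to_numpy()})
    return df.to_csv(index=False)


def check_metadata(matrix: AbundanceMatrix, metadata: pd.Series) -> None:
    """Every sample in the matrix must carry a group label."""
    missing = [s for s in matrix.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")


# ---------------------------------------------------------------------------
# Phosphosite annotations
# ---------------------------------------------------------------------------

_ANNOT_RE = re.compile(r"Phospho \[(?P<body>[^\]]*)\]")
_SITE_RE = re.compile(r"(?P<res>[A-Za-z])(?P<pos>\d+)")


def parse_phospho_annotation(text: str | None) -> list[tuple[str, int]]:
    """Parse ``Phospho [S832; S834; S857]`` into [("S", 832), ...].

    ``NA``, ``None`` and empty/whitespace text mean "no sites" and yield an
    empty list.  Residues outside S/T/Y and non-positive or non-numeric
    positions raise ``ValueError``.  Positions are 1-based coordinates in
    the protein sequence.
    """
    if text is None:
        return []
    stripped = text.strip()
    if stripped in ("", "NA"):
        return []
    m = _ANNOT_RE.fullmatch(stripped)
    if m is None:
        raise ValueError(f"unrecognized phosphosite annotation: {text!r}")
    sites: list[tuple[str, int]] = []
    for token in m.group("body").split(";"):
        token = token.strip()
        sm = _SITE_RE.fullmatch(token)
        if sm is None:
            raise ValueError(f"malformed phosphosite token {token!r} in {text!r}")
        res = sm.group("res").upper()
        if res not in "STY":
            raise ValueError(
                f"phosphosite residue must be S, T or Y; got {res!r} in {token!r}"
            )
        pos = int(sm.group("pos"))
        if pos < 1:
            raise ValueError(f"phosphosite position must be >= 1, got {pos}")
        sites.append((res, pos))
    return sites


def format_phospho_annotation(sites: list[tuple[str, int]]) -> str:
    """Inverse of :func:`parse_phospho_annotation` (empty list -> "NA")."""
    if not sites:
        return "NA"
    return "Phospho [" + "; ".join(f"{res}{pos}" for res, pos in sites) + "]"


# ---------------------------------------------------------------------------
# Network edge lists (SIF + attributes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edge:
    """One directed interaction: source -> target with a signed ANN score
    and, when available, the Pearson r of the underlying abundance pair."""

    source: str
    target: str
    score: float
    r: float = math.nan
    relation: str = "int"


def sort_edges(edges: list[Edge]) -> list[Edge]:
    """Deterministic export order: |score| descending, ties lexicographic."""
    return sorted(edges, key=lambda e: (-abs(e.score), e.source, e.target))


def write_sif(edges: list[Edge]) -> str:
    """Simple interaction format: one ``source<TAB>relation<TAB>target`` line
    per edge, in the deterministic export order."""
    lines = [f"{e.source}\t{e.relation}\t{e.target}" for e in sort_edges(edges)]
    return "".join(line + "\n" for line in lines)


def write_edge_attributes(edges: list[Edge]) -> str:
    """Tab-separated attribute table parallel to the SIF export."""
    out = ["source\trelation\ttarget\tscore\tr"]
    for e in sort_edges(edges):
        r_txt = "" if math.isnan(e.r) else repr(e.r)
        out.append(f"{e.source}\t{e.relation}\t{e.target}\t{e.score!r}\t{r_txt}")
    return "".join(line + "\n" for line in out)


def read_sif(text: str) -> list[tuple[str, str, str]]:
    """Parse a SIF file back into (source, relation, target) triples."""
    triples = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            logger.info("read_sif: skipped blank line %d", lineno)
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"SIF line {lineno}: expected 3 fields, got {len(parts)}")
        triples.append((parts[0], parts[1], parts[2]))
    return triples


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text into (id, sequence) pairs.

    Sequences are upper-cased and must contain only the 20 standard residue
    letters.
    """
    records = []
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"record {rec.id!r}: non-standard residue letters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], descriptions: dict[str, str] | None = None) -> str:
    """Write (id, sequence) pairs as FASTA wrapped at 60 columns."""
    descriptions = descriptions or {}
    seqrecords = [
        SeqRecord(Seq(seq), id=pid, description=descriptions.get(pid, ""))
        for pid, seq in records
    ]
    buf = _stdio.StringIO()
    SeqIO.write(seqrecords, buf, "fasta")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# SRM transition CSV and spectral-library table
# ---------------------------------------------------------------------------

def write_transition_csv(rows: list) -> str:
    """Serialize TransitionRow objects with the fixed column schema."""
    out = [",".join(TRANSITION_COLUMNS)]
    for row in rows:
        out.append(
            ",".join(
                [
                    row.protein,
                    row.peptide,
                    row.modified_sequence,
                    f"{row.precursor_mz:.6f}",
                    str(row.precursor_z),
                    row.fragment,
                    str(row.fragment_z),
                    f"{row.fragment_mz:.6f}",
                    f"{row.library_intensity:.6g}",
                ]
            )
        )
    return "".join(line + "\n" for line in out)


def read_transition_csv(text: str) -> pd.DataFrame:
    df = pd.read_csv(_stdio.StringIO(text))
    missing = set(TRANSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transition CSV missing columns: {sorted(missing)}")
    return df


LibraryType = dict[str, dict[tuple[str, int], float]]


def read_library_csv(text: str) -> LibraryType:
    """Read a spectral-library-like table (peptide,fragment,fragment_z,intensity)
    into a nested dict: peptide -> (fragment label, charge) -> intensity."""
    df = pd.read_csv(_stdio.StringIO(text))
    required = {"peptide", "fragment", "fragment_z", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library CSV missing columns: {sorted(missing)}")
    library: LibraryType = {}
    for rec in df.itertuples(index=False):
        library.setdefault(rec.peptide, {})[(rec.fragment, int(rec.fragment_z))] = float(
            rec.intensity
        )
    return library


def write_library_csv(library: LibraryType) -> str:
    out = ["peptide,fragment,fragment_z,intensity"]
    for peptide in sorted(library):
        for (fragment, z), intensity in sorted(library[peptide].items()):
            out.append(f"{peptide},{fragment},{z},{intensity:.6g}")
    return "".join(line + "\n" for line in out)
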