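"""Reading, writing, and coordinate bookkeeping for aligned protein families.

This module holds the plumbing shared by the whole pipeline: aligned-FASTA
input/output, Newick tree input/output (thin wrappers over dendropy), a
metadata table (id, species, clade), mapping between 1-based reference
residue numbers and 1-based alignment columns, domain sub-alignment
extraction, and gap-threshold column trimming.

Conventions
-----------
* Residues and alignment columns are both 1-based; ranges are inclusive.
* The only gap character is ``'-'``; ``'.'`` is normalised to ``'-'`` on read.
* Sequences are uppercase strings over the 20 amino-acid letters plus ``'X'``
  for ambiguous/unknown residues. Other IUPAC ambiguity letters (B, Z, J, U,
  O) and ``'*'`` are normalised to ``'X'`` on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

GAP = "-"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACIDS: frozenset[str] = frozenset(AA20)
VALID_RESIDUES: frozenset[str] = frozenset(AA20 + "X")

# residues normalised to 'X' rather than rejected
_AMBIGUOUS = frozenset("BZJUO*")


class FamilyError(ValueError):
    """Raised for malformed families, alignments, or coordinate requests."""


@dataclass(frozen=True)
class SequenceRecord:
    """One ungapped protein sequence with optional provenance metadata."""

    id: str
    residues: str
    species: str = ""
    clade: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FamilyError("sequence record has an empty id")
        if not self.residues:
            raise FamilyError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise FamilyError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainSpec:
    """A named residue range on the reference sequence (1-based, inclusive)."""

    name: str
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.ref_start <= self.ref_end):
            raise FamilyError(
                f"domain {self.name!r}: need 1 <= ref_start <= ref_end, "
                f"got {self.ref_start}..{self.ref_end}"
            )

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1


class AlignedFamily:
    """An ordered protein multiple alignment keyed by sequence id.

    Every aligned row has identical length ``n_columns``; removing gaps from
    a row recovers the underlying :class:`SequenceRecord` residues. Rows that
    are entirely gaps are rejected.
    """

    def __init__(
        self,
        rows: Iterable[tuple[str, str]],
        metadata: pd.DataFrame | None = None,
    ) -> None:
        self._ids: list[str] = []
        self._aligned: dict[str, str] = {}
        for seq_id, aligned in rows:
            if seq_id in self._aligned:
                raise FamilyError(f"duplicate sequence id {seq_id!r}")
            self._ids.append(seq_id)
            self._aligned[seq_id] = aligned
        if not self._ids:
            raise FamilyError("alignment has no rows")
        lengths = {len(s) for s in self._aligned.values()}
        if len(lengths) != 1:
            ragged = [i for i in self._ids
                      if len(self._aligned[i]) != len(self._aligned[self._ids[0]])]
            raise FamilyError(
                f"ragged alignment: rows {ragged} differ in length from {self._ids[0]!r}"
            )
        # zero columns is a permitted degenerate case (e.g. trimming removed
        # everything); such a family carries ids only
        self._n_columns = lengths.pop()
        for seq_id in () if self._n_columns == 0 else self._ids:
            row = self._aligned[seq_id]
            if set(row) <= {GAP}:
                raise FamilyError(f"row {seq_id!r} is all gaps")
            bad = set(row) - VALID_RESIDUES - {GAP}
            if bad:
                raise FamilyError(
                    f"row {seq_id!r} contains invalid characters {sorted(bad)}"
                )
        self.metadata = metadata

    # -- container protocol -------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    @property
    def n_columns(self) -> int:
        return self._n_columns

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._aligned

    def __getitem__(self, seq_id: str) -> str:
        try:
            return self._aligned[seq_id]
        except KeyError:
            raise FamilyError(
                f"sequence id {seq_id!r} not in family; available: {self._ids}"
            ) from None

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return ((i, self._aligned[i]) for i in self._ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignedFamily):
            return NotImplemented
        return self._ids == other._ids and self._aligned == other._aligned

    def ungapped(self, seq_id: str) -> str:
        return self[seq_id].replace(GAP, "")

    def record(self, seq_id: str) -> SequenceRecord:
        species, clade = "", None
        if self.metadata is not None and seq_id in set(self.metadata["id"]):
            row = self.metadata.loc[self.metadata["id"] == seq_id].iloc[0]
            species = str(row.get("species", "") or "")
            clade = row.get("clade")
            clade = None if pd.isna(clade) else str(clade)
        return SequenceRecord(seq_id, self.ungapped(seq_id), species, clade)

    def subset_columns(self, columns: Sequence[int]) -> "AlignedFamily":
        """New family keeping the given 1-based columns, in the given order."""
        for c in columns:
            if not 1 <= c <= self._n_columns:
                raise FamilyError(f"column {c} outside 1..{self._n_columns}")
        idx = [c - 1 for c in columns]
        rows = []
        for seq_id in self._ids:
            row = self._aligned[seq_id]
            rows.append((seq_id, "".join(row[i] for i in idx)))
        return AlignedFamily(rows, metadata=self.metadata)


@dataclass
class ColumnMap:
    """Bidirectional map between reference residue numbers and columns.

    ``residue_to_column[i]`` is the 1-based alignment column that holds the
    i-th non-gap character of the reference row. The inverse map is partial:
    columns where the reference is gapped have no residue.
    """

    ref_id: str
    residue_to_column: dict[int, int]
    column_to_residue: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.column_to_residue:
            self.column_to_residue = {c: r for r, c in self.residue_to_column.items()}

    @property
    def ref_length(self) -> int:
        return len(self.residue_to_column)

    def column(self, residue: int) -> int:
        try:
            return self.residue_to_column[residue]
        except KeyError:
            raise FamilyError(
                f"residue {residue} outside reference {self.ref_id!r} "
                f"(length {self.ref_length})"
            ) from None

    def columns_for(self, spec: DomainSpec) -> list[int]:
        """All alignment columns spanned by a domain, interior gaps included."""
        if spec.ref_end > self.ref_length:
            raise FamilyError(
                f"domain {spec.name!r} ({spec.ref_start}..{spec.ref_end}) exceeds "
                f"reference {self.ref_id!r} length {self.ref_length}"
            )
        return list(range(self.column(spec.ref_start), self.column(spec.ref_end) + 1))


# ---------------------------------------------------------------------------
# Alignment I/O
# ---------------------------------------------------------------------------

def _normalise(seq: str) -> str:
    seq = seq.upper().replace(".", GAP)
    return "".join("X" if c in _AMBIGUOUS else c for c in seq)


def read_alignment(path: str | Path, metadata: pd.DataFrame | None = None) -> AlignedFamily:
    """Read an aligned FASTA file, preserving row order.

    Raises :class:`FamilyError` naming the offending id on duplicate ids or
    ragged (unequal-length) rows.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append((rec.id, _normalise(str(rec.seq))))
    if not rows:
        raise FamilyError(f"no FASTA records found in {path}")
    return AlignedFamily(rows, metadata=metadata)


def write_alignment(fam: AlignedFamily, path: str | Path, wrap: int = 60) -> None:
    """Write an aligned FASTA file (fixed line wrapping)."""
    path = Path(path)
    with path.open("w") as fh:
        for seq_id, aligned in fam:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(aligned), wrap):
                fh.write(aligned[i:i + wrap] + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the id/species/clade metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "id" not in df.columns:
        raise FamilyError(f"metadata {path} lacks an 'id' column")
    if df["id"].duplicated().any():
        dups = df["id"][df["id"].duplicated()].tolist()
        raise FamilyError(f"metadata {path} has duplicate ids {dups}")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tree I/O (shared Newick parser; reconstruction lives in loss_reconstruction)
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree, keeping underscores in labels verbatim."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path, annotations: bool = False) -> None:
    Path(path).write_text(
        tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_annotations=not annotations,
        )
    )


# ---------------------------------------------------------------------------
# Coordinate mapping, domain extraction, trimming
# ---------------------------------------------------------------------------

def build_column_map(fam: AlignedFamily, ref_id: str) -> ColumnMap:
    """Map reference residue numbers to alignment columns by gap skipping."""
    row = fam[ref_id]  # raises with available ids if absent
    mapping: dict[int, int] = {}
    residue = 0
    for col, char in enumerate(row, start=1):
        if char != GAP:
            residue += 1
            mapping[residue] = col
    return ColumnMap(ref_id=ref_id, residue_to_column=mapping)


def extract_domain(fam: AlignedFamily, cmap: ColumnMap, spec: DomainSpec) -> AlignedFamily:
    """Slice out the alignment columns spanned by a reference domain.

    Interior gap columns are retained; the reference row of the output,
    ungapped, equals reference residues ``ref_start..ref_end``.
    """
    return fam.subset_columns(cmap.columns_for(spec))


def trim_columns(
    fam: AlignedFamily, gap_threshold: float
) -> tuple[AlignedFamily, list[int]]:
    """Drop gappy columns, trimAl-style.

    Keeps exactly the columns whose non-gap fraction is >= ``gap_threshold``
    (inclusive boundary). Returns the trimmed family and the kept 1-based
    column indices, which translate trimmed coordinates back to the input.
    """
    if not 0.0 <= gap_threshold <= 1.0:
        raise FamilyError(f"gap_threshold must be in [0, 1], got {gap_threshold}")
    n_rows = len(fam)
    kept: list[int] = []
    rows = [fam[i] for i in fam.ids]
    for col in range(fam.n_columns):
        non_gap = sum(1 for row in rows if row[col] != GAP)
        if non_gap / n_rows >= gap_threshold:
            kept.append(col + 1)
    if not kept:
        warnings.warn(
            f"trim_columns: no column reaches non-gap fraction {gap_threshold}; "
            "result is empty", stacklevel=2
        )
    return fam.subset_columns(kept), kept


def write_kept_columns(kept: list[int], path: str | Path) -> None:
    """One-based kept-column list, one per line."""
    Path(path).write_text("\n".join(str(c) for c in kept) + "\n")
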