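"""Sequence, alignment and panel-metadata I/O.

An :class:`AlignedPanel` is the central container: a small-subunit (SSU)
rDNA multiple alignment in which every sequence carries a taxon name and a
group label (``target`` / ``non_target`` / ``outgroup``), plus one record
designated as the ungapped coordinate reference.  All probe coordinates in
this package are 1-based closed intervals on that ungapped reference.

The panel is consumed pre-aligned (aligned FASTA); this package never
re-aligns.  RNA input is accepted and normalized to the DNA alphabet at
ingestion (probes are synthesized as DNA), with a flag recording the
original alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AlignmentShapeError, CoordinateError, InputError, MetadataError

logger = logging.getLogger("probespectrum")

GAP = "-"

#: IUPAC nucleotide ambiguity codes mapped to the set of bases they stand for.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

VALID_RESIDUES = frozenset(IUPAC_SETS) | {GAP}


class Group(str, Enum):
    """Role of a panel sequence in probe design."""

    TARGET = "target"
    NON_TARGET = "non_target"
    OUTGROUP = "outgroup"
    UNASSIGNED = "unassigned"


#: Groups counted as "off-target" when computing specificity floors.
OFFTARGET_GROUPS = (Group.NON_TARGET, Group.OUTGROUP)


@dataclass
class SequenceRecord:
    """One gapped sequence of a panel with its taxon/group metadata."""

    id: str
    residues: str
    taxon: str = ""
    group: Group = Group.UNASSIGNED
    accession: str | None = None
    rna_input: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record with empty id")
        self.group = Group(self.group)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


def _normalize_residues(raw: str, record_id: str) -> tuple[str, bool]:
    """Uppercase, map U->T, validate the alphabet; returns (residues, was_rna)."""
    seq = raw.upper()
    was_rna = "U" in seq
    if was_rna:
        seq = seq.replace("U", "T")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise InputError(
            f"sequence {record_id!r} contains invalid residues: {sorted(bad)}"
        )
    return seq, was_rna


@dataclass
class AlignedPanel:
    """A multiple alignment with per-sequence metadata and a coordinate reference.

    Invariants: all records share one gapped length; ids are unique;
    ``reference_id`` names a member record.
    """

    records: list[SequenceRecord]
    reference_id: str | None = None
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("empty panel")
        length = len(self.records[0])
        for rec in self.records[1:]:
            if len(rec) != length:
                raise AlignmentShapeError(
                    f"sequence {rec.id!r} has gapped length {len(rec)}, "
                    f"expected {length}"
                )
        self.length = length
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids in panel: {dupes}")
        if self.reference_id is None:
            targets = [r for r in self.records if r.group is Group.TARGET]
            self.reference_id = (targets[0] if targets else self.records[0]).id
        elif self.reference_id not in set(ids):
            raise InputError(f"reference_id {self.reference_id!r} not in panel")

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    @property
    def reference(self) -> SequenceRecord:
        return self.get(self.reference_id)

    def by_group(self, group: Group) -> list[SequenceRecord]:
        return [r for r in self.records if r.group is group]

    @property
    def target_records(self) -> list[SequenceRecord]:
        return self.by_group(Group.TARGET)

    @property
    def offtarget_records(self) -> list[SequenceRecord]:
        return [r for r in self.records if r.group in OFFTARGET_GROUPS]

    def with_reference(self, record_id: str) -> "AlignedPanel":
        self.get(record_id)  # raises KeyError if absent
        return AlignedPanel(records=self.records, reference_id=record_id)


@dataclass(frozen=True)
class CoordinateMap:
    """Bijective map between alignment columns and ungapped reference positions.

    Both coordinate systems are 1-based.  Built from one gapped record; the
    map covers exactly its non-gap columns.
    """

    record_id: str
    columns: tuple[int, ...]  # columns[i] is the alignment column of position i+1

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.columns, self.columns[1:])):
            raise CoordinateError("alignment columns must be strictly increasing")

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """(alignment column, ungapped position) pairs."""
        return [(c, i + 1) for i, c in enumerate(self.columns)]

    def ref_to_col(self, position: int) -> int:
        """Alignment column of an ungapped reference position."""
        if not 1 <= position <= len(self.columns):
            raise CoordinateError(
                f"position {position} outside ungapped range 1..{len(self.columns)} "
                f"of {self.record_id!r}"
            )
        return self.columns[position - 1]

    def col_to_ref(self, column: int) -> int:
        """Ungapped reference position at an alignment column (gap columns error)."""
        from bisect import bisect_left

        i = bisect_left(self.columns, column)
        if i == len(self.columns) or self.columns[i] != column:
            raise CoordinateError(
                f"column {column} is a gap in (or outside) {self.record_id!r}"
            )
        return i + 1


def build_coordinate_map(panel: AlignedPanel, record_id: str) -> CoordinateMap:
    """Coordinate map of one panel record; all-gap records yield an empty map."""
    rec = panel.get(record_id)
    cols = tuple(i + 1 for i, base in enumerate(rec.residues) if base != GAP)
    if not cols:
        logger.warning("record %r is all-gap; empty coordinate map", record_id)
    return CoordinateMap(record_id=record_id, columns=cols)


def read_alignment(path: str | Path, reference_id: str | None = None) -> AlignedPanel:
    """Read an aligned FASTA into an :class:`AlignedPanel` (groups unassigned)."""
    path = Path(path)
    records: list[SequenceRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        residues, was_rna = _normalize_residues(str(seqrec.seq), seqrec.id)
        records.append(SequenceRecord(id=seqrec.id, residues=residues, rna_input=was_rna))
    if not records:
        raise InputError(f"no sequences found in {path}")
    return AlignedPanel(records=records, reference_id=reference_id)


def write_alignment(panel: AlignedPanel, path: str | Path, width: int = 70) -> None:
    """Write the panel as aligned FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for rec in panel:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


PANEL_COLUMNS = ["id", "taxon", "group", "accession"]


def read_panel_table(path: str | Path) -> pd.DataFrame:
    """Read a 4-column panel metadata TSV (header: id taxon group accession)."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = [c for c in PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise MetadataError(f"panel table missing columns: {missing}")
    return table[PANEL_COLUMNS]


def attach_panel_metadata(
    panel: AlignedPanel, table: pd.DataFrame | str | Path
) -> AlignedPanel:
    """Assign taxon/group/accession from a metadata table to panel records.

    Every table id must exist in the panel; panel ids absent from the table
    keep ``unassigned`` with a logged warning.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_panel_table(table)
    if table["id"].duplicated().any():
        dupes = sorted(table.loc[table["id"].duplicated(), "id"])
        raise MetadataError(f"duplicate ids in panel table: {dupes}")
    panel_ids = {r.id for r in panel.records}
    unknown = sorted(set(table["id"]) - panel_ids)
    if unknown:
        raise MetadataError(f"panel table ids not in alignment: {unknown}")
    meta = table.set_index("id")
    new_records = []
    for rec in panel.records:
        if rec.id in meta.index:
            row = meta.loc[rec.id]
            try:
                group = Group(row["group"])
            except ValueError as exc:
                raise MetadataError(
                    f"unknown group {row['group']!r} for id {rec.id!r}"
                ) from exc
            new_records.append(
                replace(rec, taxon=row["taxon"], group=group,
                        accession=row["accession"] or None)
            )
        else:
            logger.warning("panel id %r missing from metadata table; left unassigned",
                           rec.id)
            new_records.append(rec)
    return AlignedPanel(records=new_records, reference_id=panel.reference_id)


def write_panel_table(panel: AlignedPanel, path: str | Path) -> None:
    rows = [
        {"id": r.id, "taxon": r.taxon, "group": r.group.value,
         "accession": r.accession or ""}
        for r in panel
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fasta_collection(path: str | Path) -> list[tuple[str, str]]:
    """Read a plain (unaligned) FASTA into (id, sequence) pairs, normalized."""
    out = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        residues, _ = _normalize_residues(str(seqrec.seq), seqrec.id)
        out.append((seqrec.id, residues.replace(GAP, "")))
    if not out:
        raise InputError(f"no sequences found in {path}")
    return out


def reverse_complement(sequence: str) -> str:
    """DNA reverse complement (delegates to Biopython; supports IUPAC codes)."""
    return str(Seq(sequence).reverse_complement())


def base_matches(expected: str, observed: str) -> bool:
    """Does an observed panel residue satisfy an expected (probe-site) base?

    Ambiguity codes in the panel match only if the expected base is inside
    the ambiguity set (conservative); gaps never match.
    """
    if observed == GAP:
        return False
    return expected in IUPAC_SETS.get(observed, "")
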