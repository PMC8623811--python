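"""Sequence, domain-annotation and tree I/O plus the core data model.

Protein sequences travel as :class:`ProteinRecord` (one protein x one
species), domain coordinates as :class:`DomainAnnotation` (1-based inclusive,
UniProt convention), and gapped sequence sets as :class:`Alignment`, which
keeps a per-row column map back to ungapped residue numbering so that any
alignment column can be translated to a human residue index and back.

File formats are delegated to Biopython (FASTA, aligned-FASTA, Clustal) and
dendropy (Newick); this module only adds the header dialect and the
validation the rest of the pipeline relies on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ParseError, ValidationError

#: The 20 standard one-letter amino-acid codes plus X (unknown residue).
#: X never matches any residue in downstream comparisons.
RESIDUE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GAP = "-"

#: Canonical CHD paralogue groups: I (CHD1-2), II (CHD3-5), III (CHD6-9).
CHD_GROUPS = {
    "CHD1": "I", "CHD2": "I",
    "CHD3": "II", "CHD4": "II", "CHD5": "II",
    "CHD6": "III", "CHD7": "III", "CHD8": "III", "CHD9": "III",
}

#: Domain categories used for aggregation; BRK and BRK2 share one category.
DOMAIN_CATEGORIES = ("Chromodomains", "Helicases", "SANT", "DUF", "BRK", "PHD")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence labelled with its paralogue family and species."""

    id: str
    family: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if GAP in self.sequence:
            raise ValidationError(f"record {self.id!r}: gap characters not allowed")
        bad = sorted(set(self.sequence) - RESIDUE_ALPHABET)
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal residue symbol(s) {''.join(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """A named functional domain on one family's reference (human) sequence.

    Coordinates are 1-based and inclusive, so the domain length is
    ``end - start + 1``.
    """

    family: str
    domain_name: str
    category: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"{self.family}/{self.domain_name}: invalid coordinates "
                f"{self.start}-{self.end} (need 1 <= start <= end)"
            )
        if self.category not in DOMAIN_CATEGORIES:
            raise ValidationError(
                f"{self.family}/{self.domain_name}: unknown category {self.category!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


class Alignment:
    """A rectangular gapped residue matrix with labelled rows.

    ``column_map[r][c]`` gives the 1-based residue index in row *r*'s
    ungapped sequence at alignment column *c* (0-based), or ``None`` when
    that cell is a gap.  Ungapping any row reproduces its input sequence.
    """

    def __init__(self, labels: Sequence[str], seqs: Sequence[str]):
        labels = list(labels)
        seqs = [str(s).upper() for s in seqs]
        if len(labels) != len(seqs):
            raise FormatError("label/sequence count mismatch")
        if not seqs:
            raise FormatError("alignment needs at least one row")
        width = len(seqs[0])
        for lab, s in zip(labels, seqs):
            if len(s) != width:
                raise FormatError(
                    f"ragged alignment: row {labels[0]!r} has length {width}, "
                    f"row {lab!r} has length {len(s)}"
                )
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate row labels in alignment")
        self.labels = labels
        self.seqs = seqs
        self._index = {lab: i for i, lab in enumerate(labels)}
        self.column_map: list[list[int | None]] = []
        for s in seqs:
            cm: list[int | None] = []
            k = 0
            for ch in s:
                if ch == GAP:
                    cm.append(None)
                else:
                    k += 1
                    cm.append(k)
            self.column_map.append(cm)

    @property
    def n_rows(self) -> int:
        return len(self.seqs)

    @property
    def width(self) -> int:
        return len(self.seqs[0])

    def row(self, label: str) -> str:
        try:
            return self.seqs[self._index[label]]
        except KeyError:
            raise KeyError(f"no alignment row labelled {label!r}") from None

    def row_index(self, label: str) -> int:
        if label not in self._index:
            raise KeyError(f"no alignment row labelled {label!r}")
        return self._index[label]

    def ungapped(self, label: str) -> str:
        return self.row(label).replace(GAP, "")

    def residue_index(self, label: str, col: int) -> int | None:
        """1-based ungapped residue index of ``label`` at column ``col`` (0-based)."""
        return self.column_map[self._index[label]][col]

    def column_of(self, label: str, residue_index: int) -> int:
        """Alignment column (0-based) holding ``label``'s 1-based residue ``residue_index``."""
        if not hasattr(self, "_rev"):
            self._rev: dict[int, dict[int, int]] = {}
        r = self._index[label]
        rev = self._rev.get(r)
        if rev is None:
            rev = {v: c for c, v in enumerate(self.column_map[r]) if v is not None}
            self._rev[r] = rev
        try:
            return rev[residue_index]
        except KeyError:
            raise IndexError(
                f"residue {residue_index} of {label!r} not present in alignment"
            ) from None

    def column(self, col: int) -> str:
        return "".join(s[col] for s in self.seqs)

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment(
            list(self.labels), ["".join(s[c] for c in cols) for s in self.seqs]
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.labels == other.labels
            and self.seqs == other.seqs
        )

    def __repr__(self) -> str:
        return f"<Alignment {self.n_rows} rows x {self.width} cols>"


# ---------------------------------------------------------------------------
# FASTA

def _parse_header(header: str, delimiter: str, lineno: int | None = None) -> tuple[str, str, str]:
    parts = header.split(delimiter)
    if len(parts) != 3 or not all(p.strip() for p in parts):
        where = f" (line {lineno})" if lineno is not None else ""
        raise ParseError(
            f"malformed FASTA header {header!r}{where}: "
            f"expected id{delimiter}family{delimiter}species"
        )
    return parts[0].strip(), parts[1].strip(), parts[2].strip()


def read_fasta(path: str | os.PathLike, delimiter: str = "|") -> list[ProteinRecord]:
    """Read protein records from FASTA with ``id|family|species`` headers.

    Sequences are upper-cased and a single trailing ``*`` (stop) is
    stripped.  Raises :class:`ParseError` on malformed headers and
    :class:`ValidationError` on illegal residue symbols or duplicate
    (family, species) pairs.
    """
    records: list[ProteinRecord] = []
    lineno = {}
    # track header line numbers for error messages
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                lineno[line[1:].strip()] = i
    seen: set[tuple[str, str]] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description.strip()
        rid, family, species = _parse_header(header, delimiter, lineno.get(header))
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        record = ProteinRecord(rid, family, species, seq)
        key = (family, species)
        if key in seen:
            raise ValidationError(f"duplicate (family, species) pair {key}")
        seen.add(key)
        records.append(record)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike,
                delimiter: str = "|") -> None:
    seqs = [
        SeqRecord(Seq(r.sequence),
                  id=f"{r.id}{delimiter}{r.family}{delimiter}{r.species}",
                  description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Alignments

_ALN_FORMATS = {"fasta": "fasta", "aligned-fasta": "fasta", "clustal": "clustal"}


def read_alignment(path: str | os.PathLike, dialect: str = "fasta") -> Alignment:
    """Read an alignment from aligned-FASTA or Clustal format."""
    fmt = _ALN_FORMATS.get(dialect.lower())
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    return Alignment([r.description or r.id for r in msa], [str(r.seq) for r in msa])


def write_alignment(a: Alignment, path: str | os.PathLike, dialect: str = "fasta") -> None:
    fmt = _ALN_FORMATS.get(dialect.lower())
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    recs = [SeqRecord(Seq(s), id=lab, description="") for lab, s in zip(a.labels, a.seqs)]
    with open(path, "w") as fh:
        AlignIO.write(AlignIO.MultipleSeqAlignment(recs), fh, fmt)


# ---------------------------------------------------------------------------
# Domain tables

DOMAIN_TABLE_COLUMNS = ("family", "domain_name", "category", "start", "end")


def load_domain_table(path: str | os.PathLike) -> list[DomainAnnotation]:
    """Load a TSV of domain annotations and validate per-family non-overlap."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(DOMAIN_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"domain table missing column(s): {sorted(missing)}")
    annotations = []
    for _, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise ParseError(f"non-integer coordinate in row {dict(row)}") from exc
        annotations.append(
            DomainAnnotation(row["family"], row["domain_name"], row["category"], start, end)
        )
    validate_domain_annotations(annotations)
    return annotations


def validate_domain_annotations(annotations: Sequence[DomainAnnotation]) -> None:
    by_family: dict[str, list[DomainAnnotation]] = {}
    for a in annotations:
        by_family.setdefault(a.family, []).append(a)
    for family, anns in by_family.items():
        anns = sorted(anns, key=lambda a: a.start)
        for prev, cur in zip(anns, anns[1:]):
            if cur.start <= prev.end:
                raise ValidationError(
                    f"overlapping domains on {family}: "
                    f"{prev.domain_name} ({prev.start}-{prev.end}) and "
                    f"{cur.domain_name} ({cur.start}-{cur.end})"
                )


def write_domain_table(annotations: Iterable[DomainAnnotation],
                       path: str | os.PathLike) -> None:
    import pandas as pd

    pd.DataFrame(
        [(a.family, a.domain_name, a.category, a.start, a.end) for a in annotations],
        columns=list(DOMAIN_TABLE_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees (dendropy-backed)

def tree_from_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def newick_string(tree: dendropy.Tree) -> str:
    # 6 significant digits keeps round-trips stable without bloating files
    return tree.as_string(schema="newick", unquoted_underscores=True,
                          real_value_format_specifier=".6g",
                          suppress_rooting=True).strip()


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    """Write a tree as Newick; duplicate leaf labels are rejected before writing."""
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate leaf label(s): {dupes}")
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")
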