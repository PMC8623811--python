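"""Domain extraction and orthologue variability profiling.

A *variable position* is an alignment column of a domain where at least
one non-reference orthologue differs from the reference (human) residue —
by mismatch, gap, or an X ambiguity.  Positions, not substitution events,
are counted: a column where several species differ contributes one
variable position.  Summaries aggregate counts per protein (percent of the
family's total domain residues) and per domain category (share of the
grand total).

Chromodomains additionally carry a 21-residue conserved core (the
"chromobox") whose aromatic-cage positions 5, 8 and 12 are checked
separately: variable positions are partitioned into inside/outside the
core, and a reference sequence lacking an aromatic residue (F/W/Y) at core
position 5 is surfaced as a validation warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .seqio import GAP, Alignment, DomainAnnotation, ProteinRecord


@dataclass(frozen=True)
class ChromoboxSpec:
    """Location and aromatic-cage rules of the chromobox core.

    ``offset`` is the 1-based start of the 21-residue core within its
    chromodomain; ``aromatic_positions`` are core-relative (1-based).
    """

    offset: int = 1
    length: int = 21
    aromatic_positions: frozenset[int] = frozenset({5, 8, 12})
    aromatic_set: frozenset[str] = frozenset("FWY")

    def __post_init__(self) -> None:
        if self.length != 21:
            raise ValidationError("chromobox core length is fixed at 21")
        if not set(self.aromatic_positions) <= set(range(1, 22)):
            raise ValidationError("aromatic positions must lie in [1, 21]")


@dataclass
class ConservationProfile:
    """Per-domain orthologue variability relative to a reference row."""

    annotation: DomainAnnotation
    reference_row: str
    n_columns: int
    variable_columns: list[int]
    per_species_diffs: dict[str, list[tuple[int, str, str]]]

    @property
    def family(self) -> str:
        return self.annotation.family

    @property
    def domain_name(self) -> str:
        return self.annotation.domain_name

    @property
    def category(self) -> str:
        return self.annotation.category

    @property
    def n_variable(self) -> int:
        return len(self.variable_columns)


def domain_columns(a: Alignment, reference: str, d: DomainAnnotation) -> list[int]:
    """Alignment columns spanned by a domain on the reference row.

    Includes insertion columns (reference gap) that fall strictly inside
    the domain's span.
    """
    first = a.column_of(reference, d.start)
    last = a.column_of(reference, d.end)
    return list(range(first, last + 1))


def extract_domain(r: ProteinRecord, d: DomainAnnotation,
                   orthologue_alignment: Alignment | None = None,
                   reference_label: str | None = None) -> str:
    """Domain subsequence of ``r``.

    For the reference protein the annotation coordinates are sliced
    directly.  For another species the coordinates are transferred through
    the orthologue alignment: the segment aligned to the reference domain
    columns is returned, ungapped.
    """
    if r.family != d.family:
        raise ValidationError(
            f"annotation is for {d.family}, record is {r.family}"
        )
    if orthologue_alignment is None:
        if d.end > len(r.sequence):
            raise ValidationError(
                f"{d.family}/{d.domain_name}: end {d.end} exceeds sequence "
                f"length {len(r.sequence)}"
            )
        return r.sequence[d.start - 1:d.end]
    if reference_label is None:
        raise ValidationError("reference_label required with an alignment")
    cols = domain_columns(orthologue_alignment, reference_label, d)
    row = orthologue_alignment.row(r.id)
    return "".join(row[c] for c in cols).replace(GAP, "")


def variability_profile(domain_alignment: Alignment, reference: str,
                        d: DomainAnnotation) -> ConservationProfile:
    """Flag every domain column where any non-reference row differs from
    the reference.  Residue indices are reference (human) coordinates."""
    if reference not in domain_alignment.labels:
        raise ValidationError(f"reference row {reference!r} absent from alignment")
    cols = domain_columns(domain_alignment, reference, d)
    ref_row = domain_alignment.row(reference)
    variable: list[int] = []
    diffs: dict[str, list[tuple[int, str, str]]] = {
        lab: [] for lab in domain_alignment.labels if lab != reference
    }
    last_index = d.start - 1
    for c in cols:
        ref_char = ref_row[c]
        idx = domain_alignment.residue_index(reference, c)
        if idx is not None:
            last_index = idx
        human_index = idx if idx is not None else last_index
        col_variable = False
        for lab in diffs:
            ch = domain_alignment.row(lab)[c]
            if ch != ref_char or ch == "X" or ch == GAP:
                col_variable = True
                diffs[lab].append((human_index, ref_char, ch))
        if col_variable and (not variable or variable[-1] != human_index):
            variable.append(human_index)
    return ConservationProfile(
        annotation=d,
        reference_row=reference,
        n_columns=len(cols),
        variable_columns=variable,
        per_species_diffs={k: v for k, v in diffs.items() if v},
    )


def profile_family(orthologue_alignment: Alignment, reference: str,
                   annotations: list[DomainAnnotation]) -> list[ConservationProfile]:
    """Variability profiles for every domain of one family."""
    return [variability_profile(orthologue_alignment, reference, d)
            for d in sorted(annotations, key=lambda x: x.start)]


def summarize_by_protein(profiles: list[ConservationProfile]) -> pd.DataFrame:
    """Per-family variable-position counts and percentages.

    ``percent`` is 100 x variable positions / total reference residues
    across the family's domains, rounded to one decimal for reporting.
    """
    rows: dict[str, dict[str, float]] = {}
    for p in profiles:
        r = rows.setdefault(p.family, {"variable_count": 0, "domain_residue_total": 0})
        r["variable_count"] += p.n_variable
        r["domain_residue_total"] += p.annotation.length
    out = pd.DataFrame(
        [
            (fam, int(r["variable_count"]), int(r["domain_residue_total"]),
             round(100.0 * r["variable_count"] / r["domain_residue_total"], 1)
             if r["domain_residue_total"] else 0.0)
            for fam, r in sorted(rows.items())
        ],
        columns=["family", "variable_count", "domain_residue_total", "percent"],
    )
    return out


def summarize_by_category(profiles: list[ConservationProfile]) -> pd.DataFrame:
    """Variable-position counts per domain category and their share of the
    grand total (percent, one decimal)."""
    import logging

    counts: dict[str, int] = {}
    for p in profiles:
        counts[p.category] = counts.get(p.category, 0) + p.n_variable
    grand = sum(counts.values())
    if grand == 0:
        logging.getLogger(__name__).warning(
            "no variable positions found; all category shares reported as 0"
        )
    rows = [
        (cat, n, round(100.0 * n / grand, 1) if grand else 0.0)
        for cat, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["category", "variable_count", "share_percent"])


@dataclass
class ChromoboxReport:
    """Partition of a chromodomain's variable positions around the core."""

    inside: list[tuple[int, int, bool]]  # (human_index, core_pos, aromatic_position)
    outside: list[int]
    position5_aromatic: bool
    warnings: list[str] = field(default_factory=list)


def chromobox_check(profile: ConservationProfile, box: ChromoboxSpec,
                    domain_alignment: Alignment) -> ChromoboxReport:
    """Check a chromodomain profile against the chromobox core rules."""
    d = profile.annotation
    core_start = d.start + box.offset - 1
    core_end = core_start + box.length - 1
    if box.offset < 1 or core_end > d.end:
        raise ValidationError(
            f"chromobox window {core_start}-{core_end} outside domain "
            f"{d.start}-{d.end}"
        )
    inside: list[tuple[int, int, bool]] = []
    outside: list[int] = []
    for idx in profile.variable_columns:
        if core_start <= idx <= core_end:
            rel = idx - core_start + 1
            inside.append((idx, rel, rel in box.aromatic_positions))
        else:
            outside.append(idx)
    pos5 = core_start + 4
    col = domain_alignment.column_of(profile.reference_row, pos5)
    ref_char = domain_alignment.row(profile.reference_row)[col]
    pos5_ok = ref_char in box.aromatic_set
    warnings = []
    if not pos5_ok:
        warnings.append(
            f"{d.family}/{d.domain_name}: reference residue {ref_char!r} at "
            f"chromobox position 5 (residue {pos5}) is not aromatic"
        )
    return ChromoboxReport(inside, outside, pos5_ok, warnings)


def profile_report(profiles: list[ConservationProfile]) -> pd.DataFrame:
    """Long-format per-difference table (one row per species difference)."""
    rows = []
    for p in profiles:
        for species, dlist in sorted(p.per_species_diffs.items()):
            for idx, ref_char, ch in dlist:
                rows.append((p.family, p.domain_name, p.category, idx,
                             ref_char, species, ch))
    return pd.DataFrame(
        rows,
        columns=["family", "domain", "category", "human_pos", "human_aa",
                 "species", "species_aa"],
    )
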