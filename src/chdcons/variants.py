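"""Pathogenic missense variants: parsing, domain mapping and
orthologue/paralogue conservation classification.

Variants arrive as HGVS protein strings (e.g. ``p.Arg618Gln``) in a TSV
with columns ``family, hgvs_p, phenotype, inheritance``.  Each variant is
mapped to the functional domain containing its residue, then classified:

* ``ortho_variable`` — the position varies among the family's orthologues;
* ``para_variable_group`` — some same-group human paralogue differs at the
  homologous alignment column;
* ``para_variable_all`` — some human paralogue (any of the nine) differs.

A paralogue with a gap at the homologous column counts as differing.
Group scope is a subset of all-paralogue scope, so
``para_variable_group`` implies ``para_variable_all``.  Variants whose
stated reference residue disagrees with the supplied human sequence are
flagged (``concordant = No``) but kept in the report, making isoform
mismatches visible rather than silent.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .domains import ConservationProfile
from .errors import ParseError, ValidationError
from .seqio import GAP, Alignment, DomainAnnotation, CHD_GROUPS

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Xaa": "X",
}

_HGVS_P = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def parse_hgvs_p(s: str) -> tuple[str, int, str]:
    """Parse ``p.<Ref3><pos><Alt3>`` into one-letter codes and position."""
    m = _HGVS_P.match(s.strip())
    if not m:
        raise ParseError(f"malformed HGVS p. string: {s!r}")
    ref3, pos, alt3 = m.groups()
    for code in (ref3, alt3):
        if code not in _THREE_TO_ONE:
            raise ParseError(f"unknown amino-acid code {code!r} in {s!r}")
    position = int(pos)
    if position < 1:
        raise ParseError(f"non-positive residue position in {s!r}")
    return _THREE_TO_ONE[ref3], position, _THREE_TO_ONE[alt3]


@dataclass
class VariantRecord:
    """A parsed missense variant with its classification flags."""

    family: str
    hgvs_p: str
    position: int
    ref_aa: str
    alt_aa: str
    phenotype: str = ""
    inheritance: str = ""
    domain_name: str | None = None
    concordant: bool | None = None
    ortho_variable: bool | None = None
    para_variable_group: bool | None = None
    para_variable_all: bool | None = None
    paralogue_gaps: list[str] = field(default_factory=list)

    @classmethod
    def from_strings(cls, family: str, hgvs_p: str, phenotype: str = "",
                     inheritance: str = "") -> "VariantRecord":
        ref, pos, alt = parse_hgvs_p(hgvs_p)
        return cls(family=family, hgvs_p=hgvs_p.strip(), position=pos,
                   ref_aa=ref, alt_aa=alt, phenotype=phenotype,
                   inheritance=inheritance)


def load_variant_table(path: str | os.PathLike) -> list[VariantRecord]:
    """Read a variant TSV (columns family, hgvs_p, phenotype, inheritance)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"family", "hgvs_p"} - set(df.columns)
    if missing:
        raise ParseError(f"variant table missing column(s): {sorted(missing)}")
    return [
        VariantRecord.from_strings(
            row["family"], row["hgvs_p"],
            row.get("phenotype", ""), row.get("inheritance", ""),
        )
        for _, row in df.iterrows()
    ]


def check_reference_concordance(v: VariantRecord, human_sequence: str) -> bool:
    """True iff the human sequence carries ``ref_aa`` at the variant position."""
    if v.position > len(human_sequence):
        raise ValidationError(
            f"{v.family} {v.hgvs_p}: position {v.position} beyond sequence "
            f"length {len(human_sequence)}"
        )
    return human_sequence[v.position - 1] == v.ref_aa


def map_variant_to_domain(v: VariantRecord,
                          annotations: Sequence[DomainAnnotation]) -> str | None:
    """Name of the unique domain containing the variant position, or None."""
    hits = [d for d in annotations
            if d.family == v.family and d.contains(v.position)]
    if len(hits) > 1:
        raise ValidationError(
            f"{v.family} position {v.position} falls in overlapping domains "
            f"{[d.domain_name for d in hits]}"
        )
    return hits[0].domain_name if hits else None


def classify_variant_conservation(
    v: VariantRecord,
    ortho_profile: ConservationProfile,
    paralogue_alignment: Alignment,
    group_map: dict[str, str] | None = None,
) -> VariantRecord:
    """Fill the three conservation flags of a mapped variant.

    ``paralogue_alignment`` holds the human sequences of all families
    (rows labelled by family); the homologous column is the one carrying
    the variant family's residue at ``position`` through the alignment's
    column map.
    """
    group_map = group_map or CHD_GROUPS
    if v.domain_name is None:
        raise ValidationError(f"{v.family} {v.hgvs_p}: variant not mapped to a domain")
    v.ortho_variable = v.position in set(ortho_profile.variable_columns)
    try:
        col = paralogue_alignment.column_of(v.family, v.position)
    except (IndexError, KeyError) as exc:
        raise ValidationError(
            f"{v.family} {v.hgvs_p}: cannot resolve position "
            f"{v.position} in the paralogue alignment"
        ) from exc
    own = paralogue_alignment.row(v.family)[col]
    group = group_map.get(v.family)
    para_all = False
    para_group = False
    gaps = []
    for fam in paralogue_alignment.labels:
        if fam == v.family:
            continue
        ch = paralogue_alignment.row(fam)[col]
        differs = ch != own or ch == "X" or ch == GAP
        if ch == GAP:
            gaps.append(fam)
        if differs:
            para_all = True
            if group_map.get(fam) == group:
                para_group = True
    v.para_variable_all = para_all
    v.para_variable_group = para_group
    v.paralogue_gaps = gaps
    return v


def curated_human_tables() -> tuple[list[DomainAnnotation], pd.DataFrame]:
    """Bundled example data for the human CHD proteins.

    Returns the functional-domain coordinates (UniProt/CDD) for the
    domains harbouring reported pathogenic variants, and the ClinVar
    pathogenic missense variants affecting them, with their published
    orthologue/paralogue conservation annotations.
    """
    from importlib.resources import files

    from .seqio import load_domain_table

    data = files("chdcons") / "data"
    anns = load_domain_table(str(data / "chd_human_domains.tsv"))
    table = pd.read_csv(str(data / "chd_pathogenic_variants.tsv"), sep="\t")
    return anns, table


def _yesno(flag: bool | None) -> str:
    if flag is None:
        return "NA"
    return "Yes" if flag else "No"


REPORT_COLUMNS = [
    "family", "hgvs_p", "domain", "phenotype", "inheritance",
    "reference_concordant", "orthologue_variable",
    "paralogue_variable_group", "paralogue_variable_all",
]


def build_report(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    """One row per classified variant, ordered by family then position."""
    rows = [
        (v.family, v.hgvs_p, v.domain_name or "none", v.phenotype,
         v.inheritance, _yesno(v.concordant), _yesno(v.ortho_variable),
         _yesno(v.para_variable_group), _yesno(v.para_variable_all))
        for v in sorted(variants, key=lambda v: (v.family, v.position))
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
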