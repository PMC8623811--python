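"""Synthetic CHD-like protein families with planted, machine-checkable truth.

The generator emulates the structure of the real CHD system: nine
paralogous families in three groups (I: 2 members, II: 3, III: 4), each
observed in six mammalian species of which two primates are identical to
human.  All families share one coordinate scaffold (alternating linkers
and domains) so that paralogue-homologous positions coincide; divergence
is hierarchical — deep between groups, moderate within groups, shallow
(default 2% per non-primate species) among orthologues.  Domains evolve at
a reduced rate on paralogue branches, mirroring the real proteins, whose
functional domains stay alignable across all nine members while linkers
drift.  Within each group the basal family (e.g. CHD6 in group III)
receives extra divergence on its terminal branch so distance trees should
place it basally within its clade.

Substitutions are drawn uniformly over the 19 alternative residues; since
downstream variability counting is residue-identity based, the choice of
substitution model does not affect truth recovery.  Chromobox aromatic
positions (core-relative 5, 8, 12) are seeded with F/W/Y and excluded from
all mutation, matching the observed invariance of the aromatic cage.

Planted pathogenic variants rewrite their column across all 54 sequences
to realise a requested conservation class (orthologue-variable yes/no,
paralogue-variable within group / across all nine), and the emitted truth
table records the exact per-domain variable positions recomputed from the
final sequences, so every pipeline stage can be scored against it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .seqio import (
    DomainAnnotation,
    ProteinRecord,
    write_domain_table,
    write_fasta,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AROMATIC = "FWY"

#: Shared scaffold: every family uses these coordinates; a family only
#: *annotates* the domains its group carries, the rest of the scaffold is
#: plain sequence.  (domain_name, category, length)
DEFAULT_BLUEPRINT: tuple[tuple[str, str, int], ...] = (
    ("PHD I", "PHD", 28),
    ("PHD II", "PHD", 28),
    ("Chromo 1", "Chromodomains", 68),
    ("Chromo 2", "Chromodomains", 60),
    ("Helicase ATP-binding", "Helicases", 171),
    ("Helicase C-terminal", "Helicases", 150),
    ("SANT", "SANT", 59),
    ("DUF", "DUF", 70),
    ("BRK", "BRK", 46),
    ("BRK2", "BRK", 35),
)

#: Which scaffold domains each group annotates: PHDs only in group II,
#: SANT in I and III, DUF in I and II, BRK domains in III; chromodomains
#: and helicases everywhere.
DEFAULT_GROUP_DOMAINS: dict[str, tuple[str, ...]] = {
    "I": ("Chromo 1", "Chromo 2", "Helicase ATP-binding",
          "Helicase C-terminal", "SANT", "DUF"),
    "II": ("PHD I", "PHD II", "Chromo 1", "Chromo 2",
           "Helicase ATP-binding", "Helicase C-terminal", "DUF"),
    "III": ("Chromo 1", "Chromo 2", "Helicase ATP-binding",
            "Helicase C-terminal", "SANT", "BRK", "BRK2"),
}

DEFAULT_SPECIES = (
    "Homo_sapiens", "Pan_troglodytes", "Macaca_mulatta",
    "Felis_catus", "Rattus_norvegicus", "Mus_musculus",
)
DEFAULT_PRIMATES = ("Pan_troglodytes", "Macaca_mulatta")

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

#: The six admissible conservation classes for a planted variant:
#: (ortho_variable, para_variable_group, para_variable_all); group scope
#: implies all-paralogue scope.
VARIANT_CLASSES: tuple[tuple[bool, bool, bool], ...] = (
    (False, False, False),
    (False, False, True),
    (False, True, True),
    (True, False, False),
    (True, False, True),
    (True, True, True),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic family generator.

    Divergences are per-site substitution probabilities; paralogue values
    are applied per tree edge at half the quoted pairwise rate, and
    ``domain_conservation_factor`` scales them down inside domains.
    """

    seed: int
    n_groups: int = 3
    families_per_group: dict[str, int] = field(
        default_factory=lambda: {"I": 2, "II": 3, "III": 4})
    species: tuple[str, ...] = DEFAULT_SPECIES
    primates: tuple[str, ...] = DEFAULT_PRIMATES
    reference_species: str = "Homo_sapiens"
    domain_blueprint: tuple[tuple[str, str, int], ...] = DEFAULT_BLUEPRINT
    group_domains: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_DOMAINS))
    linker_length: int = 15
    lead_length: int = 30
    tail_length: int = 20
    ortho_divergence: float = 0.02
    primate_divergence: float = 0.0
    para_divergence_within_group: float = 0.25
    para_divergence_between_group: float = 0.5
    domain_conservation_factor: float = 0.3
    basal_extra_divergence: float = 1.5
    chromobox_offset: int = 20
    indel_rate: float = 0.0
    n_planted_variants: int = 19

    def __post_init__(self) -> None:
        for name in ("ortho_divergence", "primate_divergence",
                     "para_divergence_within_group",
                     "para_divergence_between_group", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if any(length < 1 for _, _, length in self.domain_blueprint):
            raise ValidationError("domain lengths must be positive")

    @property
    def family_labels(self) -> list[str]:
        labels = []
        i = 1
        for g in sorted(self.families_per_group):
            for _ in range(self.families_per_group[g]):
                labels.append(f"CHD{i}")
                i += 1
        return labels

    @property
    def group_map(self) -> dict[str, str]:
        out = {}
        i = 1
        for g in sorted(self.families_per_group):
            for _ in range(self.families_per_group[g]):
                out[f"CHD{i}"] = g
                i += 1
        return out


@dataclass
class TruthTable:
    """Ground truth emitted alongside a synthetic dataset."""

    variable_positions: dict[str, dict[str, list[int]]]  # family -> domain -> [pos]
    variant_classes: list[dict]
    group_map: dict[str, str]
    tree: str  # family-level generating topology, Newick
    indels: list[dict] = field(default_factory=list)
    protected_positions: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


#: A reduced scaffold (~40% of the default residue count) for quick runs;
#: chromodomains stay long enough to hold the 21-residue chromobox core.
SMALL_BLUEPRINT: tuple[tuple[str, str, int], ...] = (
    ("PHD I", "PHD", 12),
    ("PHD II", "PHD", 12),
    ("Chromo 1", "Chromodomains", 45),
    ("Chromo 2", "Chromodomains", 45),
    ("Helicase ATP-binding", "Helicases", 60),
    ("Helicase C-terminal", "Helicases", 50),
    ("SANT", "SANT", 25),
    ("DUF", "DUF", 28),
    ("BRK", "BRK", 20),
    ("BRK2", "BRK", 16),
)


def small_config(seed: int, **overrides) -> SimConfig:
    """A :class:`SimConfig` with the reduced scaffold for fast pipelines."""
    defaults = dict(domain_blueprint=SMALL_BLUEPRINT, linker_length=8,
                    lead_length=12, tail_length=8)
    defaults.update(overrides)
    return SimConfig(seed=seed, **defaults)


def _scaffold_layout(c: SimConfig) -> tuple[int, list[tuple[str, str, int, int]]]:
    """Total length and (name, category, start, end) for every scaffold domain."""
    pos = c.lead_length
    coords = []
    for name, cat, length in c.domain_blueprint:
        start = pos + 1
        end = pos + length
        coords.append((name, cat, start, end))
        pos = end + c.linker_length
    total = pos - c.linker_length + c.tail_length
    return total, coords


def _mutate(seq: np.ndarray, p_linker: float, p_domain: float,
            domain_mask: np.ndarray, protected: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Substitute residues site-wise; protected sites never change."""
    p = np.where(domain_mask, p_domain, p_linker)
    hit = (rng.random(seq.size) < p) & ~protected
    out = seq.copy()
    if hit.any():
        shift = rng.integers(1, 20, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 20
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in seq)


def _family_tree_newick(c: SimConfig) -> str:
    parts = []
    idx = 1
    for g in sorted(c.families_per_group):
        fams = [f"CHD{idx + k}" for k in range(c.families_per_group[g])]
        idx += len(fams)
        clade = fams[-1]
        for fam in reversed(fams[:-1]):
            clade = f"({fam},{clade})"
        parts.append(clade)
    return "(" + ",".join(parts) + ");"


def plant_variant(
    human: dict[str, np.ndarray],
    orthologues: dict[tuple[str, str], np.ndarray],
    family: str,
    position: int,
    class_spec: tuple[bool, bool, bool],
    group_map: dict[str, str],
    primates: tuple[str, ...],
    reference_species: str,
    rng: np.random.Generator,
) -> dict:
    """Rewrite one scaffold column so the classifier's truth is known.

    ``position`` is 1-based.  Returns the truth entry; mutates the
    sequence arrays in place.
    """
    ortho, para_group, para_all = class_spec
    if para_group and not para_all:
        raise ValidationError("group-scope variability implies all-paralogue scope")
    i = position - 1
    r0 = int(rng.integers(0, 20))
    r1 = (r0 + int(rng.integers(1, 20))) % 20   # orthologue deviation
    r2 = (r0 + int(rng.integers(1, 20))) % 20   # paralogue deviation
    used = {r0, r1, r2}
    alt = next(a for a in rng.permutation(20) if int(a) not in used)
    group = group_map[family]

    deviant_para = None
    if para_all:
        pool = [f for f in human
                if f != family and (group_map[f] == group) == para_group]
        deviant_para = pool[int(rng.integers(0, len(pool)))]
    deviant_species = None
    non_primates = [s for (f, s) in orthologues
                    if f == family and s not in primates and s != reference_species]
    if ortho:
        # distinct species only
        non_primates = sorted(set(non_primates))
        deviant_species = non_primates[int(rng.integers(0, len(non_primates)))]

    for fam in human:
        residue = r2 if fam == deviant_para else r0
        human[fam][i] = residue
        for (f, s), arr in orthologues.items():
            if f != fam:
                continue
            if fam == family and s == deviant_species:
                arr[i] = r1
            else:
                arr[i] = residue

    ref3 = _ONE_TO_THREE[AMINO_ACIDS[r0]]
    alt3 = _ONE_TO_THREE[AMINO_ACIDS[int(alt)]]
    return {
        "family": family,
        "hgvs_p": f"p.{ref3}{position}{alt3}",
        "position": position,
        "ortho_variable": ortho,
        "para_variable_group": para_group,
        "para_variable_all": para_all,
    }


def simulate_family(c: SimConfig) -> tuple[list[ProteinRecord],
                                           list[DomainAnnotation], TruthTable]:
    """Generate the full synthetic dataset: records, annotations, truth."""
    rng = np.random.default_rng(c.seed)
    total, coords = _scaffold_layout(c)
    group_map = c.group_map
    families = c.family_labels

    domain_mask = np.zeros(total, dtype=bool)
    for _, _, start, end in coords:
        domain_mask[start - 1:end] = True

    # chromobox aromatic-cage sites: seeded aromatic, never mutated
    protected = np.zeros(total, dtype=bool)
    protected_positions: dict[str, list[int]] = {}
    for name, cat, start, end in coords:
        if cat != "Chromodomains":
            continue
        core_start = start + c.chromobox_offset - 1
        sites = [core_start + r - 1 for r in (5, 8, 12)]
        if sites[-1] > end:
            raise ValidationError(f"chromobox core does not fit in {name}")
        protected_positions[name] = sites
        for s in sites:
            protected[s - 1] = True

    root = rng.integers(0, 20, size=total)
    for sites in protected_positions.values():
        for s in sites:
            root[s - 1] = AMINO_ACIDS.index(AROMATIC[int(rng.integers(0, 3))])

    factor = c.domain_conservation_factor
    p_between = c.para_divergence_between_group / 2.0
    p_within = c.para_divergence_within_group / 2.0

    def evolve(seq: np.ndarray, p: float) -> np.ndarray:
        return _mutate(seq, p, p * factor, domain_mask, protected, rng)

    # group ancestors, then a caterpillar within each group; the basal
    # family's terminal branch carries extra substitutions
    human: dict[str, np.ndarray] = {}
    idx = 0
    for g in sorted(c.families_per_group):
        anc = evolve(root, p_between)
        fams = families[idx:idx + c.families_per_group[g]]
        idx += len(fams)
        current = anc
        for k, fam in enumerate(fams):
            if k < len(fams) - 1:
                current = evolve(current, p_within / 2.0)
                branch = p_within / 2.0
                if k == 0:
                    branch *= c.basal_extra_divergence
                human[fam] = evolve(current, branch)
            else:
                human[fam] = evolve(current, p_within / 2.0)

    orthologues: dict[tuple[str, str], np.ndarray] = {}
    for fam in families:
        for sp in c.species:
            if sp == c.reference_species:
                orthologues[(fam, sp)] = human[fam]  # same array: shared identity
            elif sp in c.primates:
                orthologues[(fam, sp)] = evolve(human[fam], c.primate_divergence) \
                    if c.primate_divergence > 0 else human[fam].copy()
            else:
                orthologues[(fam, sp)] = _mutate(
                    human[fam], c.ortho_divergence, c.ortho_divergence,
                    domain_mask, protected, rng)
    for fam in families:  # decouple reference arrays before planting
        orthologues[(fam, c.reference_species)] = human[fam]

    # annotations per family (only the group's domains)
    annotations: list[DomainAnnotation] = []
    for fam in families:
        wanted = set(c.group_domains[group_map[fam]])
        for name, cat, start, end in coords:
            if name in wanted:
                annotations.append(DomainAnnotation(fam, name, cat, start, end))

    # plant variants inside annotated domains, one column each
    anns_by_family: dict[str, list[DomainAnnotation]] = {}
    for a in annotations:
        anns_by_family.setdefault(a.family, []).append(a)
    used_columns: set[int] = set()
    variant_truth: list[dict] = []
    for k in range(c.n_planted_variants):
        class_spec = VARIANT_CLASSES[k % len(VARIANT_CLASSES)]
        fam = families[int(rng.integers(0, len(families)))]
        anns = anns_by_family[fam]
        for _attempt in range(200):
            ann = anns[int(rng.integers(0, len(anns)))]
            position = int(rng.integers(ann.start, ann.end + 1))
            if position not in used_columns and not protected[position - 1]:
                break
        else:
            raise ValidationError("could not place a planted variant")
        used_columns.add(position)
        entry = plant_variant(human, orthologues, fam, position, class_spec,
                              group_map, c.primates, c.reference_species, rng)
        entry["domain_name"] = ann.domain_name
        variant_truth.append(entry)

    # ground-truth variable positions, recomputed from the final arrays
    non_primates = [s for s in c.species
                    if s != c.reference_species and s not in c.primates]
    variable_positions: dict[str, dict[str, list[int]]] = {}
    for fam in families:
        per_domain: dict[str, list[int]] = {}
        diff = np.zeros(total, dtype=bool)
        for sp in non_primates:
            diff |= orthologues[(fam, sp)] != human[fam]
        for ann in anns_by_family[fam]:
            hits = np.nonzero(diff[ann.start - 1:ann.end])[0] + ann.start
            per_domain[ann.domain_name] = [int(h) for h in hits]
        variable_positions[fam] = per_domain

    # optional linker-only deletions in non-primate orthologues
    indels: list[dict] = []
    final: dict[tuple[str, str], np.ndarray | str] = dict(orthologues)
    if c.indel_rate > 0:
        linker_runs = _linker_runs(total, coords)
        for fam in families:
            for sp in non_primates:
                if rng.random() >= c.indel_rate:
                    continue
                run = linker_runs[int(rng.integers(0, len(linker_runs)))]
                length = int(rng.integers(1, 4))
                start = int(rng.integers(run[0], max(run[0], run[1] - length) + 1))
                arr = orthologues[(fam, sp)]
                final[(fam, sp)] = np.concatenate(
                    [arr[:start - 1], arr[start - 1 + length:]])
                indels.append({"family": fam, "species": sp,
                               "start": start, "length": length})

    records = [
        ProteinRecord(f"{fam}_{sp}", fam, sp, _decode(np.asarray(final[(fam, sp)])))
        for fam in families for sp in c.species
    ]
    truth = TruthTable(
        variable_positions=variable_positions,
        variant_classes=variant_truth,
        group_map=group_map,
        tree=_family_tree_newick(c),
        indels=indels,
        protected_positions=protected_positions,
    )
    return records, annotations, truth


def _linker_runs(total: int, coords) -> list[tuple[int, int]]:
    """1-based inclusive (start, end) runs of non-domain scaffold."""
    mask = np.ones(total, dtype=bool)
    for _, _, start, end in coords:
        mask[start - 1:end] = False
    runs = []
    start = None
    for i, free in enumerate(mask, start=1):
        if free and start is None:
            start = i
        elif not free and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, total))
    return [r for r in runs if r[1] - r[0] >= 4]


def write_dataset(records, annotations, truth: TruthTable,
                  outdir: str | os.PathLike) -> dict[str, Path]:
    """Emit FASTA, domain TSV, variant TSV and truth JSON to a directory."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "domains": outdir / "domains.tsv",
        "variants": outdir / "variants.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(records, paths["fasta"])
    write_domain_table(annotations, paths["domains"])
    pd.DataFrame(
        [(v["family"], v["hgvs_p"], "synthetic phenotype", "Autosomal Dominant")
         for v in truth.variant_classes],
        columns=["family", "hgvs_p", "phenotype", "inheritance"],
    ).to_csv(paths["variants"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
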