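# Methods

This note records the models, parameter choices and numerical conventions
behind `chdcons`, and what the synthetic benchmarks do and do not
demonstrate.

## Data model and coordinates

All domain coordinates are 1-based and inclusive (the UniProt convention),
so a domain spanning 493–663 has length 171. Sequences use the 20 standard
one-letter codes plus `X`; `X` never matches any residue in a comparison,
including another `X` — a deliberately conservative rule so that ambiguity
inflates, never hides, variability. Alignments carry a per-row column map
back to ungapped residue numbering; every coordinate transfer (domain
extraction in a non-reference species, homologous-column lookup for a
variant) goes through this map rather than through independent arithmetic,
so off-by-one drift between stages is structurally impossible.

## Alignment

Pairwise alignment is global Needleman–Wunsch with affine gaps in Gotoh's
three-state formulation. Defaults: BLOSUM62, gap open −10, gap extend −1
(a gap of length L costs `open + (L−1)·extend`). The DP is filled row-wise
with a max-plus prefix scan for the horizontal state, and traceback
tie-breaks are fixed (diagonal > up > left; state precedence M > Ix > Iy)
so identical inputs give byte-identical output.

Multiple alignment is progressive: UPGMA on pairwise p-distances supplies
the guide tree (distance ties broken by lexicographically smallest cluster
label pair), and profiles are merged with the same affine DP, scoring a
column pair as the mean substitution score over all residue–residue pairs
drawn from the two columns (gap cells excluded; all-gap pairings score 0).
This targets the regime the analysis lives in — orthologues at 95–100%
identity, paralogue domains at roughly 50–90% — where any reasonable
global aligner agrees; it does not attempt Clustal Omega's HMM iterations,
and externally computed alignments can be supplied at every CLI boundary
instead.

## Trimming

A column is kept iff its entropy score ≤ `entropy_threshold` (0.5) **and**
its gap rate ≤ `gap_rate_cutoff` (0.5); maximal kept runs shorter than
`min_block_size` (5) are then discarded. The entropy score is this
package's own formulation (equivalence with BMGE's internals is not
claimed): BLOSUM62 similarities are min–max normalised to [0, 1]; each
residue type in a column gets a dissimilarity weight `1 − mean
normalised similarity to the other residues of the column`
(occurrence-weighted, self-pairs included); type counts are multiplied by
these weights and renormalised; and the Shannon entropy of the result is
divided by `log(min(n, 20))`, the maximum entropy achievable with `n`
non-gap residues. Consequences that the tests pin down:

* a single-residue column scores 0, an all-gap column 1;
* a two-row column of maximally dissimilar residues scores exactly 1
  (the normalisation limit);
* at equal multiplicities, biochemically dissimilar columns (`AAAW`)
  outscore interchangeable ones (`LLLV`) — the weighting, not the counts,
  separates them.

The capacity normalisation `log(min(n, 20))` rather than the entropy of
the observed types is what keeps deep alignments usable: in a 54-row
alignment a clean two-clade split scores ≈ 0.2 and survives the 0.5
threshold, whereas normalising by observed-type entropy would push every
balanced split to ≈ 1 and strip exactly the phylogenetically informative
columns. Trimming is idempotent and monotone in both thresholds (with
block size 1), and these invariants are property-tested.

## Tree inference

Distances are the proportion of differing residues over mutually ungapped
columns, Poisson-corrected as d = −ln(1 − p) (an error is raised at
saturation, p ≥ 1). Trees come from canonical neighbor-joining with the Q
criterion; ties take the smallest working-list index pair, and a negative
branch length is clamped to zero with the deficit moved to its sister so
the joined pair's path length is preserved. Midpoint rooting walks the
longest leaf-to-leaf path (ties broken by the lexicographically smallest
end-label pair); a tree with all-zero branch lengths is rooted at the
first internal node with a logged warning. Monophyly is an edge-bipartition
test, so a label set is monophyletic whenever its complement is a clade.
Maximum-likelihood inference and branch supports are out of scope: the
contract is topology-level (the three CHD groups must come out as clades),
which NJ on these deeply separated groups resolves without ambiguity.

## Variability and variant classification

A domain position is **variable** when at least one non-reference
orthologue differs from the reference (human) residue — by mismatch, gap
or `X`. Positions are counted, not substitution events: two species
differing at one column contribute one variable position. Percentages per
protein divide by the family's total annotated domain residues and are
rounded to one decimal for reporting (full precision is kept internally);
category shares divide by the grand total of variable positions across
all six categories (BRK and BRK2 aggregate into one BRK category).

Chromodomains carry a 21-residue chromobox core at a configurable offset;
the check partitions variable positions into inside/outside the core,
reports core-relative coordinates, and verifies the aromatic cage: the
reference residue at core position 5 must be aromatic, with F/W/Y as the
aromatic set (histidine deliberately excluded from the methyllysine cage;
the set is a parameter of `ChromoboxSpec`).

Variants are parsed from HGVS `p.` three-letter strings. Classification
uses two alignments: the family's orthologue alignment (for the
orthologue flag) and an alignment of the nine human paralogue sequences
with rows labelled by family (for the paralogue flags). The homologous
column is found through the variant family's column map; any paralogue
differing there — including by a gap — sets the all-paralogue flag, and a
same-group paralogue differing sets the group flag, so group scope implies
all-paralogue scope by construction. The published single
"paralogue variability" annotation corresponds to the all-nine scope; the
report emits both scopes plus a reference-concordance column so isoform
mismatches are visible rather than silently dropped.

## Synthetic data generator

The generator emulates the real CHD family design: 9 families in groups of 2/3/4,
observed in human, chimpanzee, macaque (primates, divergence 0 by
default), cat, rat and mouse. All families share one coordinate scaffold
(lead, alternating domains and linkers, tail) so paralogue-homologous
positions coincide; each family annotates only its group's domains (PHDs
in II, SANT in I and III, DUF in I and II, BRK/BRK2 in III, chromodomains
and helicases everywhere). Default sizes give a 900-residue scaffold; the
reduced scaffold (`small_config`, 405 residues) is used by the pytest
suite to keep the default run fast, while `scripts/acceptance.py` uses the
full size.

Divergence is hierarchical. Quoted pairwise rates are applied per tree
edge at half value: root→group edges use `between_group/2 = 0.25` per
linker site, within-group caterpillar edges `within_group/4 = 0.0625`
each; inside domains, paralogue-branch rates are scaled by
`domain_conservation_factor = 0.3`, reflecting that real CHD functional
domains stay alignable across all nine members while linkers drift.
Orthologue branches apply 2% per site per non-primate species uniformly.
Each group is generated as a caterpillar whose basal family (CHD6-like in
group III) receives 1.5× substitutions on its terminal branch, so distance
trees should both keep groups monophyletic and attach the basal family
basally. Substitutions are uniform over the 19 alternative residues — the
downstream counting is identity-based, so a rate matrix would not change
what truth recovery measures. Chromobox cage sites (core-relative 5/8/12)
are seeded with F/W/Y and excluded from all mutation. Optional indels are
deletions of 1–3 residues confined to linkers of non-primate orthologues,
recorded in the truth table; the exact-recovery guarantees are stated for
`indel_rate = 0`.

Planted variants rewrite one scaffold column across all 54 sequences to
realise a requested class — orthologue-variable (one non-primate species
deviates), group-paralogue-variable (a same-group family deviates), or
all-paralogue-variable (a cross-group family deviates) — and the alternate
allele is chosen so it never occurs in any emitted sequence. The truth
table's variable positions are recomputed from the final arrays, so
engineering never desynchronises truth from data.

### What the synthetic benchmarks show — and what they do not

Exact truth recovery (precision = recall = 1 for variable positions and
variant flags) demonstrates that the alignment, coordinate transfer,
profiling and classification machinery is internally consistent under
substitution-only evolution at realistic divergences. It does not
exercise: alignment ambiguity around real indels, isoform/coordinate
mismatches between databases, compositional biases, or rate heterogeneity
across sites. The bundled curated tables (published domain coordinates and
the 19 ClinVar pathogenic missense variants) cover the coordinate-mapping
part of the real analysis; reproducing the real variability counts would
require the orthologue sequence set, which is not redistributed.

## Numerical conventions and degenerate inputs

* Traceback equality uses a 1e-9 tolerance (profile scores are means and
  not exactly representable); scores themselves are exact for integer
  matrices.
* UPGMA and NJ tie-breaks, and the midpoint path tie-break, are fixed as
  described above; all pipeline stages are deterministic functions of
  their inputs, and the end-to-end rerun test asserts identical output
  checksums.
* Empty trimmed alignments are representable (width 0) rather than an
  error; an all-gap column scores entropy 1 and gap rate 1 and is always
  removed.
* A variant whose stated reference residue disagrees with the supplied
  human sequence is reported with `reference_concordant = No`, not
  dropped.
* The acceptance script derives all randomness from `--seed`; dataset
  seeds are `seed + 1000 + k`, kept well below 2^31.
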