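"""Shared fixtures: one small synthetic dataset, analysed once per session."""

from __future__ import annotations

import pytest

from chdcons.cli import classify_variants, conserve, paralogue_alignment
from chdcons.synthdata import simulate_family, small_config
from chdcons.variants import VariantRecord


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-scaffold 9-family x 6-species dataset with planted truth."""
    cfg = small_config(seed=11)
    records, annotations, truth = simulate_family(cfg)
    return cfg, records, annotations, truth


@pytest.fixture(scope="session")
def analysed(small_dataset):
    """Profiles, per-family orthologue alignments, paralogue alignment and
    classified planted variants for the session dataset."""
    cfg, records, annotations, truth = small_dataset
    profiles, alignments = conserve(records, annotations, cfg.reference_species)
    paln = paralogue_alignment(records, cfg.reference_species)
    variants = [VariantRecord.from_strings(v["family"], v["hgvs_p"])
                for v in truth.variant_classes]
    classified = classify_variants(variants, records, annotations, profiles,
                                   cfg.reference_species, group_map=truth.group_map,
                                   paralogue_aln=paln)
    return {
        "profiles": profiles,
        "alignments": alignments,
        "paralogue_alignment": paln,
        "classified": classified,
    }
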