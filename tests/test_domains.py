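"""Domain extraction, variability profiling, summaries and chromobox checks."""

import pytest

from chdcons import Alignment, DomainAnnotation, ProteinRecord, ValidationError
from chdcons.domains import (
    ChromoboxSpec,
    chromobox_check,
    extract_domain,
    profile_family,
    summarize_by_category,
    summarize_by_protein,
    variability_profile,
)


def make_record(seq, family="CHD7", species="Homo_sapiens"):
    return ProteinRecord(f"{family}_{species}", family, species, seq)


class TestExtractDomain:
    def test_reference_slice_length(self):
        seq = "M" * 1000
        d = DomainAnnotation("CHD7", "Chromo 1", "Chromodomains", 800, 867)
        assert len(extract_domain(make_record(seq), d)) == 68

    def test_single_residue_domain(self):
        d = DomainAnnotation("CHD7", "DUF", "DUF", 3, 3)
        assert extract_domain(make_record("MKLVA"), d) == "L"

    def test_planted_domain_recovered(self, small_dataset):
        _, records, annotations, _ = small_dataset
        rec = next(r for r in records
                   if r.family == "CHD3" and r.species == "Homo_sapiens")
        ann = next(a for a in annotations
                   if a.family == "CHD3" and a.domain_name == "Chromo 1")
        assert extract_domain(rec, ann) == rec.sequence[ann.start - 1:ann.end]

    def test_out_of_range_rejected(self):
        d = DomainAnnotation("CHD7", "DUF", "DUF", 3, 10)
        with pytest.raises(ValidationError):
            extract_domain(make_record("MKLVA"), d)

    def test_family_mismatch_rejected(self):
        d = DomainAnnotation("CHD1", "DUF", "DUF", 1, 2)
        with pytest.raises(ValidationError):
            extract_domain(make_record("MKLVA"), d)

    def test_transfer_through_alignment_for_other_species(self):
        # cat has a one-residue deletion inside the domain
        aln = Alignment(
            ["CHD7_Homo_sapiens", "CHD7_Felis_catus"],
            ["MKLVAEDE", "MKL-AEDE"],
        )
        d = DomainAnnotation("CHD7", "DUF", "DUF", 2, 6)
        cat = make_record("MKLAEDE", species="Felis_catus")
        assert extract_domain(cat, d, aln, "CHD7_Homo_sapiens") == "KLAE"


def make_aln(rows):
    return Alignment(list(rows), list(rows.values()))


DOM = DomainAnnotation("CHD7", "DUF", "DUF", 1, 8)


class TestVariabilityProfile:
    def test_identical_rows_have_no_variable_columns(self):
        aln = make_aln({"hum": "MKLVAEDE", "cat": "MKLVAEDE", "rat": "MKLVAEDE"})
        p = variability_profile(aln, "hum", DOM)
        assert p.variable_columns == []
        assert p.n_columns == 8

    def test_planted_substitutions_flagged_exactly(self):
        aln = make_aln({"hum": "MKLVAEDE", "cat": "MALVAEDW", "rat": "MKLVAEDE"})
        p = variability_profile(aln, "hum", DOM)
        assert p.variable_columns == [2, 8]
        assert p.per_species_diffs == {"cat": [(2, "K", "A"), (8, "E", "W")]}

    def test_positions_not_events_counted(self):
        # two species differing at the same column -> one variable position
        aln = make_aln({"hum": "MKLVAEDE", "cat": "MALVAEDE", "rat": "MGLVAEDE"})
        p = variability_profile(aln, "hum", DOM)
        assert p.variable_columns == [2]
        assert set(p.per_species_diffs) == {"cat", "rat"}

    @pytest.mark.parametrize("other", ["MK-VAEDE", "MKXVAEDE"])
    def test_gap_or_x_counts_as_variable(self, other):
        aln = make_aln({"hum": "MKLVAEDE", "cat": other})
        p = variability_profile(aln, "hum", DOM)
        assert p.variable_columns == [3]

    def test_invariant_to_row_order(self):
        rows = {"hum": "MKLVAEDE", "cat": "MALVAEDW", "rat": "MKLVAEDD"}
        p1 = variability_profile(make_aln(rows), "hum", DOM)
        reordered = {"rat": rows["rat"], "hum": rows["hum"], "cat": rows["cat"]}
        p2 = variability_profile(make_aln(reordered), "hum", DOM)
        assert p1.variable_columns == p2.variable_columns
        assert p1.per_species_diffs == p2.per_species_diffs

    def test_duplicated_identical_species_changes_nothing(self):
        rows = {"hum": "MKLVAEDE", "cat": "MALVAEDW"}
        p1 = variability_profile(make_aln(rows), "hum", DOM)
        rows["cat2"] = rows["hum"]
        p2 = variability_profile(make_aln(rows), "hum", DOM)
        assert p1.variable_columns == p2.variable_columns

    def test_missing_reference_rejected(self):
        aln = make_aln({"cat": "MKLVAEDE", "rat": "MKLVAEDE"})
        with pytest.raises(ValidationError):
            variability_profile(aln, "hum", DOM)

    def test_recovers_planted_truth(self, small_dataset, analysed):
        _, _, _, truth = small_dataset
        recovered = {}
        for p in analysed["profiles"]:
            recovered.setdefault(p.family, {})[p.domain_name] = p.variable_columns
        assert recovered == {
            fam: {dom: positions for dom, positions in domains.items()}
            for fam, domains in truth.variable_positions.items()
        }


class TestSummaries:
    def _profiles(self):
        d1 = DomainAnnotation("CHD1", "Chromo 1", "Chromodomains", 1, 100)
        d2 = DomainAnnotation("CHD1", "DUF", "DUF", 101, 250)
        d3 = DomainAnnotation("CHD2", "Chromo 1", "Chromodomains", 1, 100)
        mk = lambda d, cols: variability_profile(
            make_aln({"hum": "A" * 250, "cat": _mutated("A" * 250, cols)}),
            "hum", d)
        return [mk(d1, [5, 10]), mk(d2, [120, 130, 140]), mk(d3, [])]

    def test_per_protein_percentages(self):
        table = summarize_by_protein(self._profiles())
        chd1 = table[table.family == "CHD1"].iloc[0]
        assert chd1.variable_count == 5
        assert chd1.domain_residue_total == 250
        assert chd1.percent == 2.0
        chd2 = table[table.family == "CHD2"].iloc[0]
        assert chd2.percent == 0.0

    def test_category_shares(self):
        table = summarize_by_category(self._profiles())
        shares = dict(zip(table.category, table.share_percent))
        assert shares == {"Chromodomains": 40.0, "DUF": 60.0}
        counts = dict(zip(table.category, table.variable_count))
        assert sum(counts.values()) == 5

    def test_zero_variability_shares_are_zero(self):
        d = DomainAnnotation("CHD4", "PHD I", "PHD", 1, 10)
        p = variability_profile(
            make_aln({"hum": "A" * 10, "cat": "A" * 10}), "hum", d)
        table = summarize_by_category([p])
        assert table.share_percent.tolist() == [0.0]

    def test_counts_conserved_between_summaries(self, analysed):
        profiles = analysed["profiles"]
        per_protein = summarize_by_protein(profiles)
        per_category = summarize_by_category(profiles)
        assert per_protein.variable_count.sum() == per_category.variable_count.sum()
        assert per_category.share_percent.sum() == pytest.approx(100.0, abs=0.3)


def _mutated(seq, positions):
    out = list(seq)
    for pos in positions:
        out[pos - 1] = "W"
    return "".join(out)


class TestChromobox:
    DOMAIN = DomainAnnotation("CHD7", "Chromo 1", "Chromodomains", 1, 30)
    BOX = ChromoboxSpec(offset=5)  # core = residues 5..25

    def _profile(self, variable):
        ref = list("AAAA" + "QF" + "A" * 19 + "AAAAA")  # F at core position 2?
        # build reference with aromatic at core position 5 (residue 9)
        ref = ["A"] * 30
        ref[8] = "F"  # core position 5
        hum = "".join(ref)
        cat = _mutated(hum, variable)
        aln = make_aln({"hum": hum, "cat": cat})
        return variability_profile(aln, "hum", self.DOMAIN), aln

    def test_outside_core_classified_outside(self):
        profile, aln = self._profile([2])
        report = chromobox_check(profile, self.BOX, aln)
        assert report.outside == [2]
        assert report.inside == []

    def test_inside_core_relative_position(self):
        # residue 11 -> core-relative position 7, not an aromatic position
        profile, aln = self._profile([11])
        report = chromobox_check(profile, self.BOX, aln)
        assert report.inside == [(11, 7, False)]
        assert report.position5_aromatic

    def test_aromatic_position_flagged(self):
        # residue 12 -> core-relative 8, one of the cage positions
        profile, aln = self._profile([12])
        report = chromobox_check(profile, self.BOX, aln)
        assert report.inside == [(12, 8, True)]

    def test_non_aromatic_position5_warns(self):
        hum = "A" * 30  # no aromatic at core position 5
        aln = make_aln({"hum": hum, "cat": hum})
        profile = variability_profile(aln, "hum", self.DOMAIN)
        report = chromobox_check(profile, self.BOX, aln)
        assert not report.position5_aromatic
        assert report.warnings

    def test_window_out_of_range_rejected(self):
        profile, aln = self._profile([])
        with pytest.raises(ValidationError):
            chromobox_check(profile, ChromoboxSpec(offset=15), aln)

    def test_planted_cage_positions_never_vary(self, small_dataset, analysed):
        _, _, _, truth = small_dataset
        protected = {pos for sites in truth.protected_positions.values()
                     for pos in sites}
        for p in analysed["profiles"]:
            if p.category == "Chromodomains":
                assert not (set(p.variable_columns) & protected)
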