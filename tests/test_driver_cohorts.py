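import random

import pytest
import yaml

from evotriage.driver_cohorts import (
    DEFAULT_DRIVER_RULES,
    DriverRule,
    assign_cohorts,
    load_driver_rules,
    match_rule,
    parse_site,
)
from evotriage.errors import ConfigError
from evotriage.hgvs import normalize_protein_change, parse_protein_change

from conftest import make_record, sample_for

KRAS_RULE = next(r for r in DEFAULT_DRIVER_RULES if r.gene_symbol == "KRAS")
EGFR_RULE = next(r for r in DEFAULT_DRIVER_RULES if r.gene_symbol == "EGFR")
BRAF_RULE = next(r for r in DEFAULT_DRIVER_RULES if r.gene_symbol == "BRAF")


class TestHgvsParsing:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("p.Gln61His", "p.Q61H"),
            ("p.Val600Glu", "p.V600E"),
            ("p.G12D", "p.G12D"),
            ("p.Ter500Ter", "p.*500*"),
        ],
    )
    def test_three_letter_normalization(self, raw, expected):
        assert normalize_protein_change(raw) == expected

    def test_substitution_fields(self):
        pc = parse_protein_change("p.G12D")
        assert (pc.ref, pc.position, pc.alt) == ("G", 12, "D")
        assert pc.is_substitution and not pc.is_synonymous

    def test_synonymous_detected(self):
        assert parse_protein_change("p.G12G").is_synonymous

    def test_range_events_take_first_position(self):
        pc = parse_protein_change("p.E746_A750del")
        assert pc.position == 746 and not pc.is_substitution

    def test_garbage_parses_to_none(self):
        assert parse_protein_change("not-hgvs") is None
        assert parse_protein_change("") is None


class TestMatchRule:
    def test_kras_g12c_matches_kras_rule(self):
        assert match_rule(make_record("KRAS", hgvsp="p.G12C"), KRAS_RULE)

    def test_alternate_residue_irrelevant(self):
        # the rule names the reference site G12; any substitution matches
        for alt in "DCVA":
            assert match_rule(make_record("KRAS", hgvsp=f"p.G12{alt}"), KRAS_RULE)

    def test_gene_mismatch(self):
        assert not match_rule(make_record("KRAS", hgvsp="p.G12C"), EGFR_RULE)

    def test_synonymous_at_hotspot_does_not_match(self):
        assert not match_rule(make_record("KRAS", hgvsp="p.G12G", classification="Silent"), KRAS_RULE)

    def test_non_hotspot_position_does_not_match(self):
        assert not match_rule(make_record("KRAS", hgvsp="p.A59T"), KRAS_RULE)

    def test_three_letter_hgvsp_matches(self):
        assert match_rule(make_record("KRAS", hgvsp="p.Gln61His"), KRAS_RULE)

    def test_egfr_exon19_inframe_del_matches(self):
        record = make_record("EGFR", classification="In_Frame_Del", hgvsp="p.E746_A750del", exon=19)
        assert match_rule(record, EGFR_RULE)

    def test_egfr_indel_outside_exon_range(self):
        record = make_record("EGFR", classification="In_Frame_Del", hgvsp="p.E746_A750del", exon=25)
        assert not match_rule(record, EGFR_RULE)

    def test_egfr_indel_residue_fallback_when_exon_missing(self):
        inside = make_record("EGFR", classification="In_Frame_Del", hgvsp="p.E746_A750del")
        outside = make_record("EGFR", classification="In_Frame_Del", hgvsp="p.E1000_A1004del")
        assert match_rule(inside, EGFR_RULE)
        assert not match_rule(outside, EGFR_RULE)

    def test_braf_v600e(self):
        assert match_rule(make_record("BRAF", hgvsp="p.V600E"), BRAF_RULE)

    def test_unparseable_change_on_rule_gene_is_non_match(self, caplog):
        record = make_record("KRAS", hgvsp="p.?")
        with caplog.at_level("WARNING"):
            assert not match_rule(record, KRAS_RULE)
        assert "unparseable" in caplog.text

    def test_case_insensitive_gene_match(self):
        assert match_rule(make_record("Kras", hgvsp="p.G13D"), KRAS_RULE)


class TestAssignCohorts:
    def _records(self):
        return [
            make_record("KRAS", sample=sample_for(1), hgvsp="p.G13D"),
            make_record("TP53", sample=sample_for(1), hgvsp="p.R175H"),
            make_record("KRAS", sample=sample_for(2), hgvsp="p.G12V"),
            make_record("EGFR", sample=sample_for(2), hgvsp="p.L858R"),
            make_record("TP53", sample=sample_for(3), hgvsp="p.R175H"),
            make_record("BRAF", sample=sample_for(4), hgvsp="p.V600E"),
        ]

    def test_example_assignments(self):
        by_patient = {a.patient_id: a for a in assign_cohorts(self._records())}
        assert by_patient["TCGA-AA-0001"].label == "mKRAS"
        assert by_patient["TCGA-AA-0002"].label == "excluded"
        assert by_patient["TCGA-AA-0002"].matched_rules == ("EGFR", "KRAS")
        assert by_patient["TCGA-AA-0003"].label == "WT"
        assert by_patient["TCGA-AA-0004"].label == "mBRAF"

    def test_partition_covers_all_patients(self):
        assignments = assign_cohorts(self._records(), patients=[f"TCGA-AA-{i:04d}" for i in range(1, 8)])
        assert len(assignments) == 7
        counts = {}
        for a in assignments:
            counts[a.label] = counts.get(a.label, 0) + 1
        assert sum(counts.values()) == 7
        assert counts["WT"] == 4  # patients 3, 5, 6, 7

    def test_order_invariance(self):
        records = self._records()
        baseline = {a.patient_id: a.label for a in assign_cohorts(records)}
        rng = random.Random(0)
        for _ in range(5):
            shuffled = records[:]
            rng.shuffle(shuffled)
            assert {a.patient_id: a.label for a in assign_cohorts(shuffled)} == baseline

    def test_empty_rules_is_config_error(self):
        with pytest.raises(ConfigError):
            assign_cohorts(self._records(), rules=[])

    def test_excluded_iff_multiple_rules(self):
        for a in assign_cohorts(self._records()):
            assert (a.label == "excluded") == (len(a.matched_rules) > 1)
            assert (a.label == "WT") == (len(a.matched_rules) == 0)


class TestRuleConfig:
    def test_rule_requires_sites_or_exons(self):
        with pytest.raises(ConfigError):
            DriverRule("GENE")

    def test_parse_site(self):
        assert parse_site("G12") == ("G", 12)
        with pytest.raises(ConfigError):
            parse_site("12G")

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text(
            yaml.safe_dump(
                {
                    "KRAS": {"sites": ["G12", "G13", "Q61", "A146"]},
                    "EGFR": {"sites": ["L858"], "indel_exons": [18, 21], "indel_residues": [688, 875]},
                }
            )
        )
        rules = load_driver_rules(path)
        kras = next(r for r in rules if r.gene_symbol == "KRAS")
        egfr = next(r for r in rules if r.gene_symbol == "EGFR")
        assert ("G", 12) in kras.residue_sites
        assert egfr.indel_exon_range == (18, 21)
        assert match_rule(make_record("KRAS", hgvsp="p.A146T"), kras)
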