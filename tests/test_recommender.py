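"""Rulebook loading/validation and drug recommendation logic."""

import pandas as pd
import pytest

from tumorboard.pilot import encode_evidence_row, load_pilot_evidence
from tumorboard.recommend import Recommendation, cohort_drug_counts, recommend
from tumorboard.rulebook import DnaRule, DrugRulebook, dump_rulebook, load_rulebook
from tumorboard.variants import ActionableEvent, classify_actionable


def scores_frame(over_genes: dict[str, float], other: dict[str, float] | None = None):
    genes = dict(over_genes)
    flags = {g: True for g in over_genes}
    for g, z in (other or {}).items():
        genes[g] = z
        flags[g] = False
    return pd.DataFrame(
        {"nrz": pd.Series(genes), "over_flag": pd.Series(flags)}
    ).rename_axis("gene")


# --- rulebook -------------------------------------------------------------

def test_default_rulebook_has_the_six_agent_panel(default_rulebook):
    assert set(default_rulebook.panel) == {
        "bortezomib", "crizotinib", "dasatinib", "lapatinib", "sorafenib", "vorinostat",
    }
    assert default_rulebook.expression_rules["vorinostat"] == [
        "HDAC2", "HDAC4", "HDAC8", "HDAC9", "CTBP2", "RAD23",
    ]
    # drugs without published expression rules carry none (never auto-selected)
    assert "bortezomib" not in default_rulebook.expression_rules
    assert "lapatinib" not in default_rulebook.expression_rules


def test_rule_referencing_unknown_drug_rejected():
    with pytest.raises(ValueError, match="unknown drug"):
        DrugRulebook(
            panel={"vorinostat": ""},
            dna_rules=[DnaRule("imatinib", "KIT", "SNV")],
            expression_rules={},
        )
    with pytest.raises(ValueError, match="unknown drug"):
        DrugRulebook(panel={"vorinostat": ""}, dna_rules=[],
                     expression_rules={"imatinib": ["KIT"]})
    with pytest.raises(ValueError, match="empty"):
        DrugRulebook(panel={}, dna_rules=[], expression_rules={})
    with pytest.raises(ValueError, match="empty gene list"):
        DrugRulebook(panel={"vorinostat": ""}, dna_rules=[],
                     expression_rules={"vorinostat": []})


def test_rulebook_round_trip(tmp_path, default_rulebook):
    path = tmp_path / "rules.yaml"
    dump_rulebook(default_rulebook, path)
    again = load_rulebook(path)
    assert again == default_rulebook


# --- recommend ------------------------------------------------------------

def test_dna_priority_selects_crizotinib_over_expression(default_rulebook):
    scores = scores_frame({"ALK": 3.5, "HDAC2": 4.0, "HDAC9": 3.0})
    events = [ActionableEvent("ALK", "SNV", ("crizotinib",), "ALK SNV F1174L", 2)]
    rec = recommend("pt", scores, events, default_rulebook)
    assert rec.drug == "crizotinib" and rec.status == "dna"
    assert any(e.kind == "DNA" and e.gene == "ALK" for e in rec.evidence)
    assert any(e.kind == "expression" and e.gene == "ALK" for e in rec.evidence)


@pytest.mark.parametrize(
    "over,expected",
    [
        ({"HDAC2": 3.0, "HDAC4": 2.5, "HDAC9": 2.8}, "vorinostat"),
        ({"RET": 2.7}, "sorafenib"),
        ({"PDGFRB": 3.2, "DDR2": 2.4}, "dasatinib"),
        ({"HDAC2": 2.1}, "vorinostat"),
    ],
)
def test_expression_rules_reproduce_board_selections(default_rulebook, over, expected):
    rec = recommend("pt", scores_frame(over), [], default_rulebook)
    assert rec.drug == expected and rec.status == "expression"
    assert {e.gene for e in rec.evidence} == set(over)


def test_no_evidence_gives_no_match(default_rulebook):
    rec = recommend("pt", scores_frame({}, {"HDAC2": 1.0}), [], default_rulebook)
    assert rec.drug is None and rec.status == "no_match" and rec.evidence == []


def test_more_supporting_genes_beat_higher_single_nrz(default_rulebook):
    # two flagged dasatinib targets outrank one very high sorafenib target
    scores = scores_frame({"PDGFRB": 2.1, "DDR2": 2.2, "RET": 9.0})
    rec = recommend("pt", scores, [], default_rulebook)
    assert rec.drug == "dasatinib"
    assert ("sorafenib", 1, 9.0) in rec.runners_up


def test_equal_count_breaks_tie_by_max_nrz_then_alphabetical(default_rulebook):
    scores = scores_frame({"RET": 5.0, "PDGFRB": 3.0})
    assert recommend("pt", scores, [], default_rulebook).drug == "sorafenib"
    # exact tie on (count, max nrz): alphabetical, and the tie is recorded
    tied = scores_frame({"RET": 3.0, "PDGFRB": 3.0})
    rec = recommend("pt", tied, [], default_rulebook)
    assert rec.drug == "dasatinib" and rec.tie_broken


def test_dna_conflict_resolved_by_rule_specificity(default_rulebook):
    events = [
        ActionableEvent("KIT", "SNV", ("sorafenib",), "KIT SNV", 1),
        ActionableEvent("ALK", "SNV", ("crizotinib",), "ALK SNV F1174L", 2),
    ]
    rec = recommend("pt", scores_frame({}), events, default_rulebook)
    assert rec.drug == "crizotinib"


def test_adding_matching_dna_event_never_changes_away_from_its_drug(default_rulebook):
    """DNA priority invariant over a spread of expression profiles."""
    profiles = [
        {"HDAC2": 5.0, "HDAC9": 4.0, "HDAC4": 3.0},
        {"RET": 8.0},
        {"PDGFRB": 3.0, "DDR2": 3.0, "SRC": 3.0, "LCK": 3.0},
        {},
    ]
    event = ActionableEvent("ALK", "CN-gain", ("crizotinib",), "ALK CN gain", 1)
    for over in profiles:
        rec = recommend("pt", scores_frame(over), [event], default_rulebook)
        assert rec.drug == "crizotinib"


def test_raising_target_nrz_never_lowers_drug_rank(default_rulebook):
    base = scores_frame({"RET": 2.5, "HDAC2": 3.0, "HDAC9": 3.0})
    boosted = scores_frame({"RET": 7.5, "HDAC2": 3.0, "HDAC9": 3.0})

    def rank(rec: Recommendation, drug: str) -> int:
        order = [rec.drug] + [d for d, _, _ in rec.runners_up]
        return order.index(drug)

    r0 = recommend("pt", base, [], default_rulebook)
    r1 = recommend("pt", boosted, [], default_rulebook)
    assert rank(r1, "sorafenib") <= rank(r0, "sorafenib")


def test_recommendation_requires_evidence_unless_no_match():
    with pytest.raises(ValueError, match="evidence"):
        Recommendation("pt", "vorinostat", "expression", evidence=[])


def test_evidence_order_independence(default_rulebook):
    scores = scores_frame({"HDAC2": 3.0, "HDAC9": 2.5})
    events = [
        ActionableEvent("ALK", "SNV", ("crizotinib",), "a", 1),
        ActionableEvent("ALK", "CN-gain", ("crizotinib",), "b", 1),
    ]
    assert recommend("pt", scores, events, default_rulebook) == recommend(
        "pt", scores.iloc[::-1], events[::-1], default_rulebook
    )


# --- cohort tallies -------------------------------------------------------

def test_cohort_counts_conservation(default_rulebook):
    recs = [
        recommend("a", scores_frame({"HDAC2": 3.0}), [], default_rulebook),
        recommend("b", scores_frame({"RET": 3.0}), [], default_rulebook),
        recommend("c", scores_frame({}), [], default_rulebook),  # no match
    ]
    counts = cohort_drug_counts(recs)
    assert counts == {"sorafenib": (1, 0.5), "vorinostat": (1, 0.5)}
    assert sum(c for c, _ in counts.values()) == 2
    single = cohort_drug_counts(recs[:1])
    assert single == {"vorinostat": (1, 1.0)}
    with pytest.raises(ValueError):
        cohort_drug_counts([])


# --- published evidence-table reproduction --------------------------------

EXPECTED_DRUGS = {
    "SL00402": "vorinostat", "SL00393": "vorinostat", "SL00477": "vorinostat",
    "SL00522": "crizotinib", "SL00511": "sorafenib", "SL00535": "dasatinib",
    "SL00545": "vorinostat", "SL00558": "vorinostat", "SL00575": "vorinostat",
    "SL00581": "vorinostat", "SL00586": "vorinostat", "SL00587": "vorinostat",
    "SL00589": "vorinostat", "SL00605": "crizotinib", "SL00608": "vorinostat",
    "SL00625": "vorinostat", "SL00650": "vorinostat", "SL00653": "vorinostat",
    "SL00680": "vorinostat", "SL00720": "vorinostat",
}


def test_pilot_evidence_rows_reproduce_published_selections(default_rulebook):
    table = load_pilot_evidence()
    assert len(table) == 20
    for _, row in table.iterrows():
        pid, scores, variants, segments, fusions = encode_evidence_row(row)
        events = classify_actionable(variants, segments, fusions, default_rulebook)
        rec = recommend(pid, scores, events, default_rulebook)
        assert rec.drug == EXPECTED_DRUGS[pid], pid
        if pid in ("SL00522", "SL00605"):
            assert rec.status == "dna"
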