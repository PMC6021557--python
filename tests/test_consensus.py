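"""Item summaries and the round-1/round-2 retention rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from delphiset import (
    ItemSummary,
    Thresholds,
    build_round2_itemset,
    classify_round1,
    classify_round2,
    fixture_decisions,
    fixture_summaries,
    flag_near_miss,
    new_item_candidates,
    load_fixture,
    round1_summaries,
    summarize_item,
    top10_pct,
)

THR = Thresholds()

score_lists = st.lists(st.integers(min_value=1, max_value=9), min_size=1, max_size=60)


# ---------------------------------------------------------------------------
# summarize_item
# ---------------------------------------------------------------------------

def test_degenerate_distribution_summary():
    s = summarize_item([9, 9, 9, 9])
    assert s.pct_7to9 == 100.0
    assert s.pct_1to3 == 0.0
    assert s.median == 9
    assert s.sd == 0.0
    assert s.iqr == (9, 9)


def test_panel_of_45_with_43_high_scores_matches_printed_percentage():
    # 43 of 45 in the 7-9 band, none low: the top item of the study's round 1
    scores = [9] * 43 + [5, 6]
    s = summarize_item(scores)
    assert round(s.pct_7to9, 2) == 95.56
    assert s.pct_1to3 == 0.0


def test_empty_scores_rejected():
    with pytest.raises(ValueError):
        summarize_item([])


@given(score_lists)
def test_summary_percentages_equal_counting_oracle(scores):
    s = summarize_item(scores)
    n = len(scores)
    assert s.pct_7to9 == pytest.approx(100 * sum(1 for x in scores if 7 <= x <= 9) / n)
    assert s.pct_1to3 == pytest.approx(100 * sum(1 for x in scores if 1 <= x <= 3) / n)
    assert s.pct_8or9 == pytest.approx(100 * sum(1 for x in scores if x >= 8) / n)
    assert s.pct_8or9 <= s.pct_7to9 + 1e-12
    assert s.pct_7to9 + s.pct_1to3 <= 100 + 1e-9
    assert s.median == np.median(scores)


# ---------------------------------------------------------------------------
# classify_round1
# ---------------------------------------------------------------------------

def _summary(pct_high, pct_low, item_id="x", n=45):
    return ItemSummary(item_id=item_id, n=n, pct_7to9=pct_high, pct_1to3=pct_low)


@pytest.mark.parametrize(
    "pct_high,pct_low,top10,retained,reason",
    [
        (95.56, 0.00, None, True, "consensus_overall"),  # hospital admissions
        (35.56, 20.00, 10.0, False, "dropped"),  # number of other procedures
        (50.00, 14.99, None, False, "dropped"),  # strict > boundary
        (42.22, 13.33, 15.56, True, "top10"),  # imaging scans
        (50.01, 15.00, None, False, "dropped"),  # strict < boundary on low band
    ],
)
def test_round1_overall_and_top10_rules(pct_high, pct_low, top10, retained, reason):
    d = classify_round1(_summary(pct_high, pct_low), {}, top10, THR)
    assert d.retained is retained
    assert d.reason == reason


def test_two_qualifying_subgroups_retain_an_item():
    overall = _summary(46.67, 6.67)
    subgroups = {
        "primary_care": _summary(60.0, 10.0),
        "public_health": _summary(55.0, 0.0),
        "mental": _summary(40.0, 10.0),
    }
    d = classify_round1(overall, subgroups, 5.0, THR)
    assert d.retained and d.reason == "subgroup"
    assert set(d.qualifying_subgroups) == {"primary_care", "public_health"}


def test_one_qualifying_subgroup_is_not_enough():
    d = classify_round1(_summary(46.67, 6.67), {"mental": _summary(60.0, 0.0)}, None, THR)
    assert not d.retained


def test_reason_priority_overall_beats_subgroup_and_top10():
    subgroups = {"mental": _summary(80.0, 0.0), "physical": _summary(80.0, 0.0)}
    d = classify_round1(_summary(95.0, 0.0), subgroups, 50.0, THR)
    assert d.reason == "consensus_overall"


# ---------------------------------------------------------------------------
# top-10 and new-item arithmetic
# ---------------------------------------------------------------------------

def test_top10_threshold_arithmetic_at_panel_size_45():
    sel = {f"p{i}": ["a"] for i in range(7)} | {f"q{i}": ["b"] for i in range(10)}
    pct = top10_pct(sel, "a", n_raters=45)
    assert round(pct, 2) == 15.56 and pct >= THR.top10_min
    pct6 = top10_pct({k: v for k, v in list(sel.items())[:6]}, "a", n_raters=45)
    assert round(pct6, 2) == 13.33 and pct6 < THR.top10_min


@given(
    st.dictionaries(
        st.text(alphabet="abcdef", min_size=1, max_size=3),
        st.lists(st.sampled_from(["i1", "i2", "i3"]), unique=True, max_size=3),
        max_size=20,
    ),
    st.sampled_from(["i1", "i2", "i3"]),
)
def test_top10_pct_equals_counting_oracle(selections, item):
    count = sum(1 for items in selections.values() if item in items)
    assert top10_pct(selections, item, n_raters=45) == pytest.approx(100 * count / 45)


def test_top10_completers_denominator_policy():
    sel = {"a": ["i1"], "b": ["i1"], "c": [], "d": ["i2"]}
    assert top10_pct(sel, "i1", n_raters=10, denominator_policy="completers") == pytest.approx(
        100 * 2 / 3
    )
    with pytest.raises(ZeroDivisionError):
        top10_pct({"a": []}, "i1", n_raters=0)


def test_new_item_candidates_strict_10pct_rule():
    counts = {"carer time": 5, "travel costs": 4, "otc medication": 0}
    assert new_item_candidates(counts, 45) == ["carer time"]  # 11.11% in, 8.89% out
    assert new_item_candidates({}, 45) == []


# ---------------------------------------------------------------------------
# near-miss review
# ---------------------------------------------------------------------------

def test_equipment_like_near_miss_is_flagged_not_retained():
    s = _summary(44.44, 13.33, item_id="equipment")
    decisions = {"equipment": classify_round1(s, {}, 13.5, THR)}
    flagged = flag_near_miss(decisions, {"equipment": s}, THR, margin=10.0)
    assert flagged["equipment"].reason == "near_miss_review"
    assert not flagged["equipment"].retained


def test_far_miss_is_not_flagged():
    s = _summary(20.0, 40.0, item_id="y")
    decisions = {"y": classify_round1(s, {}, 2.0, THR)}
    assert flag_near_miss(decisions, {"y": s}, THR, margin=10.0)["y"].reason == "dropped"


def test_zero_margin_flags_nothing_on_printed_fixtures():
    summaries = round1_summaries()
    decisions = {
        iid: classify_round1(s, {}, None, THR) for iid, s in summaries.items()
    }
    flagged = flag_near_miss(decisions, summaries, THR, margin=0.0, top10_margin=0.0)
    assert all(d.reason != "near_miss_review" for d in flagged.values())


# ---------------------------------------------------------------------------
# classify_round2
# ---------------------------------------------------------------------------

def _r2summary(p79, p13, p89, item_id="x"):
    return ItemSummary(item_id=item_id, n=42, pct_7to9=p79, pct_1to3=p13, pct_8or9=p89)


@pytest.mark.parametrize(
    "p79,p13,p89,pre,strict",
    [
        (78.57, 0.00, 61.90, True, False),  # operation/procedure
        (97.62, 2.38, 90.48, True, True),  # hospital admissions
        (64.29, 14.29, 47.62, False, False),  # prescribed medication
        (70.00, 0.00, 70.00, False, False),  # strict > boundary
    ],
)
def test_round2_rule_examples(p79, p13, p89, pre, strict):
    o = classify_round2(_r2summary(p79, p13, p89), THR)
    assert o.preagreed is pre and o.stringent is strict


def test_round2_requires_pct_8or9():
    with pytest.raises(ValueError):
        classify_round2(ItemSummary(item_id="x", n=42, pct_7to9=80.0, pct_1to3=0.0), THR)


@given(
    st.floats(0, 100),
    st.floats(0, 100),
)
def test_stringent_is_subset_of_preagreed_on_random_summaries(p79, p13):
    # the 8-9 band can never exceed the 7-9 band
    p89 = p79 * 0.9
    o = classify_round2(_r2summary(p79, p13, p89), THR)
    assert not (o.stringent and not o.preagreed)


def test_all_34_printed_round2_rows_reproduce():
    table5 = load_fixture("table5")
    summaries = fixture_summaries("table5")
    for _, row in table5.iterrows():
        o = classify_round2(summaries[row["item_id"]], THR)
        assert o.preagreed == (row["preagreed"] == "Include"), row["item_id"]
        assert o.stringent == (row["stringent"] == "Include"), row["item_id"]


# ---------------------------------------------------------------------------
# round-2 item set bookkeeping
# ---------------------------------------------------------------------------

def test_fixture_decisions_build_the_34_item_round2_set():
    itemset = build_round2_itemset(fixture_decisions())
    assert len(itemset) == 34
    assert itemset["equipment"] == "manual_override"
    assert itemset["hospital_admissions"] == "consensus_overall"


def test_empty_decisions_give_empty_itemset():
    assert build_round2_itemset({}) == {}


def test_itemset_equals_union_oracle():
    decisions = fixture_decisions()
    itemset = build_round2_itemset(decisions)
    oracle = {
        iid for iid, d in decisions.items() if d.retained or d.manual_override
    }
    assert set(itemset) == oracle


def test_override_for_unknown_item_rejected():
    with pytest.raises(KeyError):
        build_round2_itemset(fixture_decisions(), manual_overrides=["no_such_item"])


# ---------------------------------------------------------------------------
# rounding and ordering invariances
# ---------------------------------------------------------------------------

def test_two_decimal_rounding_never_flips_a_verdict_at_panel_sizes_45_and_42():
    # achievable percentages are multiples of 100/45 and 100/42, none of
    # which sits within rounding distance of a threshold
    for n in (45, 42):
        for count in range(n + 1):
            exact = 100 * count / n
            rounded = round(exact, 2)
            for cut in (THR.r1_high, THR.r1_low, THR.r2_high, THR.top10_min):
                assert (exact > cut) == (rounded > cut)
                assert (exact < cut) == (rounded < cut)
                assert (exact >= cut) == (rounded >= cut)


def test_decisions_invariant_to_rater_and_item_ordering(tiny_panel):
    from delphiset import summarize_panel

    shuffled = tiny_panel.scores.sample(frac=1.0, random_state=3).reset_index(drop=True)
    from delphiset import RatingsPanel

    panel2 = RatingsPanel(round_label="round1", scores=shuffled)
    assert summarize_panel(tiny_panel) == summarize_panel(panel2)
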