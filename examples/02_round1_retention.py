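"""Apply the round-1 retention rules to the published per-item summaries.

The packaged fixtures transcribe the study's printed round-1 tables
(60 candidate resource-use items, % rating 7-9 and % rating 1-3).
An item is kept when >50% of the panel scored it 7-9 and <15% scored
it 1-3; the printed tables also record which items were instead kept by
subgroup consensus, top-10 prioritization, or near-miss review.
"""

from collections import Counter

from delphiset import Thresholds, build_round2_itemset, fixture_decisions, round1_summaries

thr = Thresholds()
summaries = round1_summaries()
overall_pass = [
    iid for iid, s in summaries.items()
    if s.pct_7to9 > thr.r1_high and s.pct_1to3 < thr.r1_low
]
print(f"{len(overall_pass)} of {len(summaries)} items pass the overall consensus test")
# -> 27 of 60, exactly the items the study labelled "Consensus"

decisions = fixture_decisions()
print("retention reasons:", dict(Counter(d.reason for d in decisions.values())))
itemset = build_round2_itemset(decisions)
print(f"round-2 item set: {len(itemset)} items")  # -> 34, as published
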