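"""Round-2 verdicts: pre-agreed vs stringent consensus rules.

After the second rating round an item is retained when >70% of the
panel scored it 7-9 (and <15% scored 1-3); the stringent variant
requires >70% scoring 8 or 9 and identifies the most crucial items for
the final selection meeting.  The stringent set is always a subset of
the pre-agreed set.
"""

from delphiset import Thresholds, classify_round2, fixture_summaries

summaries = fixture_summaries("table5")
outcomes = {iid: classify_round2(s, Thresholds()) for iid, s in summaries.items()}

n_pre = sum(o.preagreed for o in outcomes.values())
n_strict = sum(o.stringent for o in outcomes.values())
print(f"pre-agreed includes: {n_pre} of {len(outcomes)}")   # -> 19 of 34
print(f"stringent includes:  {n_strict} of {len(outcomes)}")  # -> 10 of 34

print("\nitems meeting the stringent rule:")
for iid, o in sorted(outcomes.items()):
    if o.stringent:
        print(f"  {iid}")
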