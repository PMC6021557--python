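"""Build the feedback a panelist sees at the start of round 2.

For every retained item the packet pairs the panel's round-1 median
with a reminder of the participant's own round-1 score; a skipped item
carries an explicit missing marker instead of an invented score.
"""

from delphiset import SimConfig, generate_feedback, simulate_round1

sim = simulate_round1(SimConfig(n_raters=12, n_items=8, seed=3))
retained = sim.panel.item_ids[:5]
pid = sim.panel.rater_ids[0]

packet = generate_feedback(sim.panel, retained, pid)
print(f"feedback packet for {pid} ({len(packet.entries)} items):")
for iid in packet.item_ids:
    e = packet.entries[iid]
    own = "--" if e.own_score is None else f"{e.own_score:.0f}"
    print(f"  {iid}: panel median {e.group_median:.1f}, your score {own}")
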