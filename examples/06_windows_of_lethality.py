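"""Windows of lethality from embryonic heartbeat screens.

Lethal lines are re-screened as embryos at E9.5, E12.5, E14.5/15.5 and
E18.5; the window is the interval between the last stage with live
homozygotes and the first with none, collapsed to early / mid / late
gestation.
"""

from fusil.viability import EmbryoRecord, assign_lethality_window

cases = {
    "dead at E9.5 (0/30 live)": [("E9.5", 30, 0)],
    "alive E9.5, dead E12.5": [("E9.5", 30, 8), ("E12.5", 30, 0)],
    "alive through E14.5, dead E18.5": [
        ("E9.5", 30, 8), ("E12.5", 30, 7), ("E14.5_15.5", 30, 6), ("E18.5", 30, 0)
    ],
    "alive at E18.5 (preweaning lethal)": [("E18.5", 30, 6)],
    "only E14.5 scored, dead": [("E14.5_15.5", 30, 0)],
}
for label, recs in cases.items():
    records = [EmbryoRecord("G", s, n, k) for s, n, k in recs]
    print(f"{label:38s} -> {assign_lethality_window(records)}")

print("\nA gene scored dead only at E14.5 is unassigned: the data cannot "
      "distinguish an early from a mid-gestation death.")
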