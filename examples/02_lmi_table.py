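"""Print the localized-mismatch-index product table for 3-stage devices.

Encodes Wake=1, Light=2, Deep=4 and evaluates the LMI (the product of the
two scorers' stage first-differences) for every ordered pair of the six
legal transitions. The diagonal {1, 4, 9} marks agreement; off-diagonal
values are disagreements, split into wake-related and sleep-depth-related
classes.
"""

from hypnoval import AlignedPair, Hypnogram, StageEncoding, lmi_sequence

TRANSITIONS = [
    ("Wake", "Light"),
    ("Wake", "Deep"),
    ("Light", "Deep"),
    ("Light", "Wake"),
    ("Deep", "Light"),
    ("Deep", "Wake"),
]
enc = StageEncoding.default()

names = [f"{a[0]}-{b[0]}" for a, b in TRANSITIONS]
print("PSG \\ device " + "".join(f"{n:>6}" for n in names))
classes = {}
for (pa, pb), row_name in zip(TRANSITIONS, names):
    cells = []
    for da, db in TRANSITIONS:
        pair = AlignedPair(
            psg=Hypnogram(stages=(pa, pb), alphabet="DEV3", source="PSG"),
            device=Hypnogram(stages=(da, db), alphabet="DEV3", source="device"),
        )
        res = lmi_sequence(pair, enc)
        v = int(res.lmi_values[0])
        cells.append(v)
        classes.setdefault(res.classes[0], set()).add(v)
    print(f"{row_name:>12} " + "".join(f"{c:>6}" for c in cells))

print("\nclass grouping (by product value):")
for cls in ("correct_wake", "correct_sleep", "incorrect_wake", "incorrect_sleep"):
    print(f"  {cls:>15}: {sorted(classes[cls])}")
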