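"""Score one recording and compute its per-day sleep variables.

The scorer classifies each worn minute from windowed activity-count
features, forces high-activity minutes (>= mean x 0.72) to wake, and
smooths short islands; non-wear minutes fall back to the parent diary.
"""

from infantsleep.pipeline import process_recording
from infantsleep.synth import GeneratorConfig, generate_cohort

cohort = generate_cohort(GeneratorConfig(n_participants=2, seed=11))
rec = cohort.recordings[(0, 6)]

daily, info = process_recording(rec)
cols = {17: "TST", 21: "WASO", 19: "efficiency%", 34: "naps",
        40: "day sleep", 42: "night sleep"}
print(daily[list(cols)].rename(columns=cols).round(1).to_string())
print(f"\nsleep regularity (whole day): {info['sri'][46]:.3f}")
print("TST = minutes asleep in the sleep period; WASO its wake "
      "complement; naps = daytime sleep bouts exceeding 20 min.")
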