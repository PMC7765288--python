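"""Generate a small synthetic infant cohort and look at its anatomy.

The generator draws five correlated latent sleep factors per infant and
timepoint and realizes them into minute-resolution sleep/wake states,
activity counts and 24-h diaries over ~11 recording days.
"""

import numpy as np

from infantsleep.synth import GeneratorConfig, generate_cohort

cfg = GeneratorConfig(n_participants=20, seed=7)
cohort = generate_cohort(cfg)

print(f"cohort: {cfg.n_participants} infants x {len(cfg.timepoints)} "
      f"timepoints -> {len(cohort.recordings)} recordings")
rec = cohort.recordings[(0, 3)]
print(f"first recording: {rec.n_days} nights, "
      f"{len(rec.minutes)} minutes on the grid")

asleep = (rec.true_states == 1).sum()
print(f"minutes asleep (truth): {asleep} "
      f"({asleep / (rec.true_states != -1).sum():.0%} of worn time)")

lengths = [r.n_days for r in cohort.recordings.values()]
print(f"mean recording length: {np.mean(lengths):.2f} days "
      "(field protocols target ~11 to keep >=3-5 usable days per infant)")
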