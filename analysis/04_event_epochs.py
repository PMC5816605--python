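#!/usr/bin/env python
"""Event-locked SCR epochs and equal-weight condition grand averages.

Pools run/test events, drops events within 10 s of the previously retained
one, extracts -10..+10 s epochs on the z-scored SCR track, and averages
them per participant per role x outcome condition before the equal-weight
grand average.
"""

import pandas as pd

from common_config import CONFIG, OUT_DIR
from dyadsync.pipeline import run_pipeline

counts = run_pipeline(CONFIG, "events", OUT_DIR)
print(f"events: {counts['events_retained']}/{counts['events_total']} retained "
      f"after the 10 s separation filter; {counts['epochs']} epochs "
      f"({counts['epochs_dropped']} dropped at recording edges)")

grand = pd.read_csv(OUT_DIR / "grand_averages.csv")
peaks = (grand.loc[grand.groupby("condition")["value"].idxmax()]
         [["condition", "t_rel_s", "value"]])
print("\ngrand-average peaks per condition (t relative to event):")
print(peaks.round(3).to_string(index=False))
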