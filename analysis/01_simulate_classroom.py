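#!/usr/bin/env python
"""Simulate the synthetic classroom and materialise it on disk.

Writes raw beat series and EDA traces per participant plus the session
structure (dyad map, event log, role schedule, task changes) in the same
CSV formats the import readers accept.
"""

from common_config import CONFIG, OUT_DIR
from dyadsync.pipeline import run_pipeline

counts = run_pipeline(CONFIG, "simulate", OUT_DIR)
print(f"simulated {counts['participants']} participants in "
      f"{counts['dyads']} dyads; {counts['events']} run/test events")
print(f"artifacts in {OUT_DIR}")
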