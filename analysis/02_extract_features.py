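#!/usr/bin/env python
"""Extract per-second feature tracks from the raw signals.

ECG: windowed mean HR and SDNN in 60 s and 300 s windows (one-third
overlap), step-hold upsampled to 1 Hz, plus per-second HR1.
EDA: artifact correction, tonic/phasic decomposition, 1 Hz aggregation,
and within-session z-scoring into SCR and SCL tracks.
"""

from common_config import CONFIG, OUT_DIR
from dyadsync.pipeline import run_pipeline

c1 = run_pipeline(CONFIG, "features", OUT_DIR)
print(f"cardiac tracks: {c1['participants']} participants, "
      f"{c1['features_per_participant']} features each")
c2 = run_pipeline(CONFIG, "decompose", OUT_DIR)
print(f"EDA tracks: {c2['participants']} participants decomposed, "
      f"{len(c2['excluded'])} excluded on quality")
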