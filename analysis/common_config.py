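"""Shared configuration for the numbered analysis drivers.

One classroom at a demonstrative desk scale: 2 rooms of 4 dyads over a
20-minute session with dyad-specific coupling 0.3 above a room-level
confound of 0.1.  All drivers read and write ``results/analysis/``; rerun
with the same config reproduces every table byte for byte.
"""

from pathlib import Path

from dyadsync.io import PipelineConfig
from dyadsync.simulate import SimConfig

OUT_DIR = Path(__file__).resolve().parents[1] / "results" / "analysis"

CONFIG = PipelineConfig(
    sim=SimConfig(n_rooms=2, dyads_per_room=4, session_len=1200,
                  dyad_coupling=0.3, room_coupling=0.1,
                  event_rate=1.0, seed=42),
    n_boot=2000,
    n_perm=1000,
)
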