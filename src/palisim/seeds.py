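"""Counter-based expansion of one master seed into per-stage seeds.

Each named pipeline stage gets a fixed counter so stages can be rerun
independently and reproducibly: ``stage_seed(master, stage, index)`` is a
pure function of its arguments.
"""
from __future__ import annotations

import numpy as np

_STAGE_COUNTERS = {
    "pump_mc": 0,
    "probe_mc": 1,
    "noise": 2,
    "energy": 3,
    "replicate": 4,
    "sweep": 5,
    "misc": 6,
}


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Derive a 31-bit seed for ``stage`` (occurrence ``index``) from the
    master seed."""
    try:
        counter = _STAGE_COUNTERS[stage]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}") from None
    ss = np.random.SeedSequence(
        entropy=int(master), spawn_key=(counter, int(index))
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
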