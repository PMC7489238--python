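"""Shared helpers for building in-memory window sets in tests."""

import numpy as np

from promin.motifs import WindowSet


def window_set(strings, center, width=None):
    width = width or len(strings[0])
    codes = np.array([np.frombuffer(w.encode(), dtype=np.uint8) for w in strings])
    return WindowSet(
        codes=codes,
        source_ids=[f"s{i}" for i in range(len(strings))],
        source_index=np.arange(len(strings)),
        center_pos=np.ones(len(strings), dtype=np.int64),
        center=center,
        width=width,
    )
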