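"""Named, splittable random-number streams.

A single integer seed plus a short text label yields an independent
:class:`numpy.random.Generator`, so e.g. the pool draw and the placement
draw of one simulation can be varied independently while staying fully
reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator determined by ``(seed, label)``.

    Streams with different labels are statistically independent (distinct
    spawn keys of one :class:`numpy.random.SeedSequence`).
    """
    key = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
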