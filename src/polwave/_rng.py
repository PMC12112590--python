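"""Deterministic random-stream forking.

A single user-facing seed is forked into independent child streams keyed by
stable string labels, so adding a pipeline stage (or reordering stages) never
perturbs the draws of another stage.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MASK64 = (1 << 64) - 1


def child_rng(seed: int, *labels) -> np.random.Generator:
    """Return a Generator derived from ``seed`` and a stable label path.

    The same (seed, labels) pair always yields an identical stream; distinct
    label paths yield statistically independent streams.
    """
    tag = "/".join(str(lab) for lab in labels)
    digest = hashlib.sha256(tag.encode("utf-8")).digest()
    words = [int.from_bytes(digest[i : i + 8], "little") for i in range(0, 32, 8)]
    entropy = [int(seed) & _MASK64, *words]
    return np.random.default_rng(np.random.SeedSequence(entropy))
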