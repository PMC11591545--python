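"""Small shared helpers: deterministic random substreams and hashing."""

from __future__ import annotations

import hashlib
import json
import zlib
from typing import Any

import numpy as np


def substream(seed: int, *tags: str) -> np.random.Generator:
    """A reproducible random generator keyed by a master seed and string tags.

    Distinct tags yield statistically independent streams, so adding one
    simulation task never perturbs the draws of another.  The same
    ``(seed, tags)`` pair always yields the same stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(t.encode("utf-8")) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def config_hash(obj: Any) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:12]
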