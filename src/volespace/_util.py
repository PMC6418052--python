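"""Shared helpers: deterministic child RNG streams."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng"]


def child_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Return a Generator for an independent, reproducible child stream.

    One root seed drives the whole pipeline; each sub-generator (site,
    movement, signals, ...) draws from its own stream keyed by a label, so
    adding draws in one component never perturbs another.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(entropy))
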