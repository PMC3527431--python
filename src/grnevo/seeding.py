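"""Deterministic derivation of independent per-component random streams.

One master seed per run is split into labelled child streams (founder, noise,
evolution, assay, ...) so that components draw from independent generators:
changing how often assays run cannot perturb the evolutionary trajectory, and
a run is reproducible from (config, master seed) alone.
"""

from __future__ import annotations

import zlib

import numpy as np

_MAX_SEED = 2**31  # keep derived seeds comfortably in int32 range


def spawn_seeds(master: int | None, labels: list[str]) -> dict[str, int]:
    """Derive one integer seed per label from a master seed.

    Derivation goes through :class:`numpy.random.SeedSequence` keyed by a
    CRC32 of the label, so the mapping is stable across sessions and
    platforms and streams for distinct labels are independent.
    """
    out: dict[str, int] = {}
    for label in labels:
        key = zlib.crc32(label.encode("utf-8"))
        entropy = 0 if master is None else int(master)
        ss = np.random.SeedSequence(entropy=entropy, spawn_key=(key,))
        out[label] = int(ss.generate_state(1, dtype=np.uint64)[0] % _MAX_SEED)
    return out


def spawn_rngs(master: int | None, labels: list[str]) -> dict[str, np.random.Generator]:
    """Labelled independent generators derived from one master seed.

    With ``master=None`` the generators are seeded from OS entropy
    (non-reproducible), mirroring numpy's default behaviour.
    """
    if master is None:
        return {label: np.random.default_rng() for label in labels}
    seeds = spawn_seeds(master, labels)
    return {label: np.random.default_rng(seed) for label, seed in seeds.items()}
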