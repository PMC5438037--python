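"""Deterministic seed derivation.

Every stochastic step in the pipeline draws from a generator derived from the
master seed through a documented spawn-key path, so results are reproducible
and invariant to the order in which pathways are processed:

    SeedSequence(master_seed, spawn_key=(crc32(pathway_id), iteration, stage))

Stage codes are small integers declared in :data:`STAGE`.  Pathway identity
enters through a CRC32 of the pathway ID string rather than a list index, so
running a subset of pathways (or running them in parallel) reproduces the
same per-pathway streams.
"""

from __future__ import annotations

import zlib

import numpy as np

#: stage codes used in spawn keys
STAGE = {
    "split": 0,
    "subsample": 1,  # + subsample run index in the next key slot
    "undersample": 2,
    "forest": 3,
    "permute_test": 4,
    "permute_validation": 5,
}


def path_key(pathway_id: str) -> int:
    """Stable 32-bit key for a pathway ID."""
    return zlib.crc32(pathway_id.encode("utf-8"))


def derive_rng(master_seed: int, *path: int) -> np.random.Generator:
    """Generator for the stream identified by ``path`` under ``master_seed``."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(p) for p in path))
    return np.random.default_rng(ss)


def derive_int_seed(master_seed: int, *path: int) -> int:
    """A 31-bit integer seed (for libraries that want a plain int)."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(p) for p in path))
    return int(ss.generate_state(1)[0] % (2**31))
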