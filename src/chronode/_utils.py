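"""Small shared helpers: deterministic seed derivation and validation."""

from __future__ import annotations

import numpy as np

# Keep derived seeds comfortably below 2**31 so they survive any int32 cast.
_SEED_MOD = 2**31 - 1


def derive_seed(master_seed: int, *tokens) -> int:
    """Derive a reproducible sub-seed from a master seed and a stage label.

    Uses numpy's SeedSequence entropy pooling so that different (stage, index)
    tokens give statistically independent streams while the whole pipeline
    remains a pure function of the master seed.
    """
    keys = [abs(hash(str(t))) % _SEED_MOD for t in tokens]
    ss = np.random.SeedSequence(entropy=int(master_seed) % _SEED_MOD, spawn_key=tuple(keys))
    return int(ss.generate_state(1)[0] % _SEED_MOD)


def rng_for(master_seed: int, *tokens) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *tokens))


def check_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
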