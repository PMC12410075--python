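"""Seed handling.

A single user-facing seed is expanded into independent per-stage child seeds
through :class:`numpy.random.SeedSequence` spawn keys, so rerunning one stage
never perturbs the stream of another. Stage names are mapped to fixed spawn
indices; adding a stage never renumbers existing ones.
"""

from __future__ import annotations

import numpy as np

# Fixed stage registry: append-only.
_STAGES = {
    "covariates": 0,
    "outcome": 1,
    "split": 2,
    "cv": 3,
    "xgb": 4,
    "rf": 5,
    "bootstrap": 6,
    "simulation": 7,
}


def child_seed(seed: int, stage: str) -> int:
    """Derive the 31-bit child seed for a named pipeline stage."""
    try:
        key = _STAGES[stage]
    except KeyError:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(_STAGES)}") from None
    ss = np.random.SeedSequence(int(seed), spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator seeded with the stage's child seed."""
    return np.random.default_rng(child_seed(seed, stage))
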