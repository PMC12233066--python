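"""Shared configuration plumbing: strict pydantic base, hashing, seed derivation."""

from __future__ import annotations

import hashlib
import json

import numpy as np
from pydantic import BaseModel, ConfigDict


class StrictModel(BaseModel):
    """Pydantic base for all stage configurations.

    Unknown keys are rejected at construction time so that typos in YAML
    configs fail loudly instead of silently falling back to defaults.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)


def config_hash(model: BaseModel) -> str:
    """Stable SHA-256 hex digest of a configuration model.

    The digest is computed over the canonical JSON serialization with sorted
    keys, so two configs that compare equal hash equal regardless of field
    declaration order.
    """
    payload = json.dumps(model.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def derive_seed(global_seed: int, label: str) -> int:
    """Derive a per-stage seed from a global seed and a stage label.

    Deterministic: the same (global_seed, label) pair always yields the same
    child seed, and distinct labels yield (with overwhelming probability)
    distinct streams.
    """
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    ss = np.random.SeedSequence([int(global_seed) & 0xFFFFFFFFFFFFFFFF, key])
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed) & 0xFFFFFFFFFFFFFFFF)
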