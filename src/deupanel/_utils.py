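"""Shared helpers: seed derivation and table validation."""

from __future__ import annotations

import numpy as np
import pandas as pd

COUNT_COLUMNS = ("gene_id", "ppm", "rep1", "rep2")


def derive_seed(master: int, *key: int) -> int:
    """Derive a child seed (< 2**31) deterministically from a master seed and a key.

    One master seed expands to per-restart / per-refit seeds so every report
    can record exactly which stream produced it.
    """
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def check_counts_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a duplicate-count table (gene_id, ppm, rep1, rep2)."""
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    if (counts[["rep1", "rep2"]].to_numpy() < 0).any():
        raise ValueError("negative replicate counts")
    return counts
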