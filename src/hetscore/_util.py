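"""Shared helpers: well-id handling and deterministic random substreams."""

from __future__ import annotations

import hashlib
import re

import numpy as np

_WELL_RE = re.compile(r"^([A-Za-z])0*([0-9]+)$")

# 16 rows x 24 columns: standard 384-well geometry
PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLS = 24


def normalize_well_id(well: str) -> str:
    """Normalize a well id to letter + zero-padded two-digit column (B2 -> B02)."""
    m = _WELL_RE.match(str(well).strip())
    if m is None:
        raise ValueError(f"malformed well id: {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col < 1:
        raise ValueError(f"malformed well id: {well!r}")
    return f"{row}{col:02d}"


def well_position(well_id: str) -> tuple[int, int]:
    """Return 0-based (row, column) plate indices for a normalized well id."""
    w = normalize_well_id(well_id)
    row = PLATE_ROWS.index(w[0])
    return row, int(w[1:]) - 1


def _key_hash(*keys: object) -> int:
    h = hashlib.blake2s("|".join(str(k) for k in keys).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big")


def substream_rng(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic per-key random generator.

    The stream depends only on (seed, keys), so e.g. adding wells to a
    simulated screen never perturbs the draws of existing wells.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, _key_hash(*keys)])


def substream_seed(seed: int, *keys: object) -> int:
    """A stable derived integer seed below 2**31 for the given key tuple."""
    return int(substream_rng(seed, *keys).integers(2**31))
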