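"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float) -> int:
    """Round to the nearest integer, with .5 always rounding away from zero.

    Python's built-in ``round`` uses banker's rounding; reported percentages
    here follow the half-up convention instead (83.5 -> 84).
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def child_seed(seed: int, stream: str) -> int:
    """Derive a deterministic per-stream child seed from one global seed.

    Keeps independent sub-generators (counts, truth labels, target table,
    permutation null) reproducible in isolation: rerunning a single stage
    with the same global seed regenerates the same stream.
    """
    ss = np.random.SeedSequence([seed, abs(hash_stable(stream)) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def hash_stable(s: str) -> int:
    """Order-independent stable string hash (Python's ``hash`` is salted)."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**61 - 1)
    return h


def normalize_mirna_id(mirna_id: str) -> str:
    """Canonical matching key for a mature miRNA name.

    Strips surrounding whitespace and lowercases, so ``hsa-miR-21-5p`` and
    ``HSA-MIR-21-5P`` collide. Arm suffixes (-5p/-3p) are left intact;
    mature-vs-precursor mapping is deliberately not attempted.
    """
    return mirna_id.strip().lower()
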