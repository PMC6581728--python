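"""Small shared helpers: sequence arithmetic and seeded RNG derivation."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: fixed per-stage offsets so every stage-local generator derives from one seed
STAGE_OFFSETS = {
    "genome": 101,
    "events": 211,
    "counts": 307,
    "divergence": 401,
    "decoys": 503,
    "background": 601,
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Fraction of G/C bases; 0.0 for empty sequences."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def derived_rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    """A generator for one pipeline stage, derived from the global seed.

    All randomness in the package flows through here so that a single
    integer seed fixes every output.
    """
    return np.random.default_rng(np.random.SeedSequence((seed, STAGE_OFFSETS[stage], extra)))
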