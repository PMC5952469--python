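"""Small shared helpers: logging, RNG handling, sequence encoding."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("hybscan")

#: canonical nucleotide alphabet; N is "unknown" and never matches anything
ALPHABET = "ACGTN"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_BYTE_LUT = np.full(256, 4, dtype=np.uint8)
for _c, _i in _CODE.items():
    _BYTE_LUT[ord(_c)] = _i
    _BYTE_LUT[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as uint8 codes 0..4 (4 = N)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BYTE_LUT[raw]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def rng_from(seed) -> np.random.Generator:
    """Generator from an int seed or pass through an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is required for stochastic operations")
    logger.debug("seeding RNG with %r", seed)
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]
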