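"""Small shared helpers: sequence codecs, seeding, hashing."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


class SnrcmError(Exception):
    """Base class for all errors raised by this package."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """ACGT -> uint8 codes 0..3. Any other character raises."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = chr(int(np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[int(np.argmax(arr > 3))]))
        raise SnrcmError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes) if codes.size < 64 else (
        np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
    )


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def derive_seed(seed: int, label: str) -> int:
    """Fan a global seed out to an independent per-stage seed (< 2**31)."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def random_dna(rng: np.random.Generator, length: int, gc_frac: float = 0.5) -> str:
    p_gc = gc_frac / 2.0
    p_at = (1.0 - gc_frac) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)
    return decode(codes)
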