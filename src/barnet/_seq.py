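"""Low-level nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_DECODE = np.array(list(ALPHABET))


def encode(barcodes: Iterable[str]) -> np.ndarray:
    """Encode equal-length ACGT strings as a 2-D uint8 array (one row per
    sequence, values 0..3)."""
    barcodes = list(barcodes)
    if not barcodes:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(barcodes[0])
    out = np.empty((len(barcodes), length), dtype=np.uint8)
    for i, bc in enumerate(barcodes):
        if len(bc) != length:
            raise ValueError(
                f"mixed sequence lengths: expected {length}, got {len(bc)} ({bc!r})"
            )
        try:
            out[i] = [_CODE[c] for c in bc]
        except KeyError as exc:
            raise ValueError(f"non-ACGT character in {bc!r}") from exc
    return out


def decode(codes: np.ndarray) -> list[str]:
    """Inverse of :func:`encode`."""
    return ["".join(row) for row in _DECODE[codes]]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def min_hamming_to_set(queries: Sequence[str], targets: Sequence[str]) -> np.ndarray:
    """Minimum Hamming distance from each query to any target.

    Queries and targets must share a common length (truncate beforehand).
    Vectorised; memory is kept bounded by chunking over queries.
    """
    if len(targets) == 0:
        raise ValueError("target set is empty")
    q = encode(queries)
    t = encode(targets)
    if q.shape[1] != t.shape[1]:
        raise ValueError("queries and targets must have the same length")
    out = np.empty(len(queries), dtype=np.int64)
    chunk = max(1, 2_000_000 // max(1, t.shape[0] * t.shape[1]))
    for start in range(0, len(queries), chunk):
        block = q[start : start + chunk]
        # (nq, nt) mismatch counts via broadcasting
        d = (block[:, None, :] != t[None, :, :]).sum(axis=2)
        out[start : start + chunk] = d.min(axis=1)
    return out


def random_barcodes(
    n: int, length: int, rng: np.random.Generator, *, unique: bool = True
) -> list[str]:
    """Draw ``n`` random barcodes of the given length, unique by default."""
    if unique and n > 4**length:
        raise ValueError(f"cannot draw {n} unique {length}-mers (only {4**length} exist)")
    if not unique:
        return decode(rng.integers(0, 4, size=(n, length), dtype=np.uint8))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = decode(rng.integers(0, 4, size=(n - len(out) + 16, length), dtype=np.uint8))
        for bc in batch:
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                if len(out) == n:
                    break
    return out


def mutate_bases(
    codes: np.ndarray, per_base_error: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each base independently with probability ``per_base_error``,
    uniformly to one of the three other bases. Returns a new array."""
    if not 0.0 <= per_base_error <= 1.0:
        raise ValueError("per_base_error must be in [0, 1]")
    out = codes.copy()
    if per_base_error == 0.0 or codes.size == 0:
        return out
    mask = rng.random(codes.shape) < per_base_error
    # adding 1..3 mod 4 guarantees a different base
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    out[mask] = (codes[mask] + shift[mask]) % 4
    return out
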