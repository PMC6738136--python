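"""Two-bit k-mer encoding helpers shared by the simulator and the smudge module.

k-mers are packed into int64 (2 bits/base, first base most significant), so k
must be at most 31. Canonical form is the lexicographic minimum of a k-mer and
its reverse complement, computed on the packed representation (A<C<G<T matches
the 0<1<2<3 code order, so integer min equals string min).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def encode_bases(seq: str) -> np.ndarray:
    """Sequence string -> uint8 code array (255 for non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode_bases(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def kmer_array(seq: str, k: int) -> np.ndarray:
    """All packed k-mers of ``seq`` (windows containing non-ACGT are dropped)."""
    if not 1 <= k <= 31:
        raise ValueError("k must be in 1..31")
    codes = encode_bases(seq)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    length = n - k + 1
    out = np.zeros(length, dtype=np.int64)
    for i in range(k):
        out = (out << 2) | codes[i : i + length].astype(np.int64)
    bad = codes > 3
    if bad.any():
        bad_window = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64))[
            k - 1 : n
        ]
        out = out[bad_window == 0]
    return out


def encode_kmer(kmer: str) -> int:
    arr = kmer_array(kmer, len(kmer))
    if arr.size != 1:
        raise ValueError(f"invalid k-mer {kmer!r}")
    return int(arr[0])


def revcomp_kmers(kmers: np.ndarray, k: int) -> np.ndarray:
    """Packed reverse complements."""
    rc = np.zeros_like(kmers)
    tmp = kmers.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


def canonical_kmers(kmers: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(kmers, revcomp_kmers(kmers, k))


def decode_kmers(kmers: np.ndarray, k: int) -> list[str]:
    """Packed k-mers -> strings (vectorized; used when writing TSV output)."""
    n = kmers.size
    if n == 0:
        return []
    mat = np.empty((n, k), dtype=np.uint8)
    tmp = kmers.copy()
    for j in range(k - 1, -1, -1):
        mat[:, j] = tmp & 3
        tmp >>= 2
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    flat = lut[mat].tobytes()
    return [flat[i * k : (i + 1) * k].decode("ascii") for i in range(n)]


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]
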