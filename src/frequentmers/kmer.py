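"""2-bit k-mer encoding and per-sample k-mer set extraction.

A k-mer over {A,C,G,T} is packed into an unsigned integer, two bits per
base (A=0, C=1, G=2, T=3), leftmost base most significant, so codes lie
in [0, 4**k).  The default length is k=16, which fits a 32-bit word; all
in-memory arrays use uint64 so any k up to 32 works.

Extraction slides a window of length k over every read (step 1), skips
windows containing N, counts total occurrences across all reads of a
sample, and keeps the distinct k-mers seen at least ``min_count`` times
(default 2: singletons are treated as probable sequencing errors and
discarded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

# byte -> 2-bit code; 4 marks anything that is not A/C/G/T (N, separators)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_BASES = "ACGT"


@dataclass(frozen=True)
class KmerCodec:
    """Fixed-length 2-bit nucleotide codec."""

    k: int = 16

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 32:
            raise ValueError(f"k must be in [1, 32], got {self.k}")

    @property
    def n_codes(self) -> int:
        return 4**self.k

    def encode(self, seq: str) -> int:
        """Pack a length-k ACGT string into an integer.

        Raises ValueError on wrong length or any non-ACGT character.
        """
        if len(seq) != self.k:
            raise ValueError(f"expected length {self.k}, got {len(seq)}")
        code = 0
        for ch in seq.upper():
            try:
                code = (code << 2) | _BASES.index(ch)
            except ValueError:
                raise ValueError(f"non-ACGT character {ch!r} in {seq!r}") from None
        return code

    def decode(self, code: int) -> str:
        if not 0 <= code < self.n_codes:
            raise ValueError(f"code {code} out of range for k={self.k}")
        out = []
        for shift in range(2 * (self.k - 1), -1, -2):
            out.append(_BASES[(code >> shift) & 3])
        return "".join(out)

    def revcomp(self, code: int) -> int:
        """Code of the reverse complement of the k-mer behind ``code``."""
        rc = 0
        for _ in range(self.k):
            rc = (rc << 2) | (3 - (code & 3))
            code >>= 2
        return rc


@dataclass
class KmerSet:
    """Distinct k-mers retained for one sample, as sorted encoded integers."""

    sample_id: str
    k: int
    kmers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))

    def __post_init__(self) -> None:
        self.kmers = np.asarray(self.kmers, dtype=np.uint64)

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, code: int) -> bool:
        i = np.searchsorted(self.kmers, np.uint64(code))
        return bool(i < len(self.kmers) and self.kmers[i] == np.uint64(code))

    def decode_all(self) -> list[str]:
        codec = KmerCodec(self.k)
        return [codec.decode(int(c)) for c in self.kmers]


def _reads_to_u8(reads: Iterable[str]) -> np.ndarray:
    """Concatenate reads into one uint8 code array with a separator (4)
    between reads so windows never span read boundaries."""
    chunks: list[np.ndarray] = []
    sep = np.array([4], dtype=np.uint8)
    for read in reads:
        chunks.append(_CODE[np.frombuffer(read.encode("ascii"), dtype=np.uint8)])
        chunks.append(sep)
    if not chunks:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(chunks)


def window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All sliding-window codes over a uint8 code array.

    Returns (codes, valid): one entry per window position; ``valid`` is
    False wherever the window contains a non-ACGT symbol.
    """
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        b = arr[j : j + n]
        codes = (codes << np.uint64(2)) | b.astype(np.uint64)
        valid &= b < 4
    return codes, valid


def sequence_codes(seq: str, k: int) -> np.ndarray:
    """Valid (N-free) window codes of a single sequence, in order."""
    arr = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    codes, valid = window_codes(arr, k)
    return codes[valid]


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Map each code to min(code, revcomp(code)) — vectorised."""
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << np.uint64(2)) | (np.uint64(3) - (tmp & np.uint64(3)))
        tmp >>= np.uint64(2)
    return np.minimum(codes, rc)


def extract_kmerset(
    sample,
    codec: KmerCodec,
    min_count: int = 2,
    canonical: bool = False,
    reads: Sequence[str] | None = None,
) -> KmerSet:
    """Extract the retained k-mer set of one sample.

    ``sample`` is either a SampleReads-like object (with ``sample_id``
    and ``reads`` attributes) or a bare sample id, in which case the
    read strings are passed via ``reads``.

    Counts are totals over all reads of the (run-merged) sample; a k-mer
    is kept iff its total count is >= min_count.  With ``canonical`` each
    window contributes min(code, revcomp) instead of the forward code.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if reads is None:
        sample_id, reads = sample.sample_id, sample.reads
    else:
        sample_id = sample
    arr = _reads_to_u8(reads)
    codes, valid = window_codes(arr, codec.k)
    codes = codes[valid]
    if canonical:
        codes = canonical_codes(codes, codec.k)
    if len(codes) == 0:
        return KmerSet(sample_id, codec.k)
    uniq, counts = np.unique(codes, return_counts=True)
    return KmerSet(sample_id, codec.k, uniq[counts >= min_count])
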