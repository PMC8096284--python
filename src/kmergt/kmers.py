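"""Integer-packed k-mer codes and neighbor-verified counting in raw reads.

A k-mer is packed into an unsigned integer at 2 bits per base (A=0, C=1,
G=2, T=3, most-significant bits first), so k up to 32 fits one 64-bit
word and all string comparisons reduce to integer comparisons.  Counting
is *canonical*: a k-mer and its reverse complement are the same key,
because the reads being counted are unmapped and of unknown strand.

Counting optionally applies a neighbor-verification rule: an occurrence
of an indexed k-mer in a read is accepted only if at least one of the
immediately adjacent windows (one base to the left or right) matches a
neighbor stored with the k-mer at extraction time.  This suppresses
spurious matches from sequencing errors that happen to recreate a target
k-mer in an unrelated context.  Occurrences at read boundaries, where no
adjacent window can be checked, are accepted.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

#: sentinel code for bases other than A/C/G/T
INVALID_BASE = 4

_BASE_CODE = np.full(256, INVALID_BASE, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_CODE_BASE = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

MAX_K = 32


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_kmer(seq: str) -> Optional[int]:
    """Pack a DNA string into its 2-bit integer code.

    Returns ``None`` when the sequence contains a base outside A/C/G/T
    (case-insensitive), so callers can skip windows covering ambiguous
    bases.  Length must be between 1 and 32.
    """
    if not 1 <= len(seq) <= MAX_K:
        raise ValueError(f"k-mer length must be in [1, {MAX_K}], got {len(seq)}")
    code = 0
    for ch in seq:
        b = int(_BASE_CODE[ord(ch)])
        if b == INVALID_BASE:
            return None
        code = (code << 2) | b
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer` for a code of known length ``k``."""
    if not 0 <= code < (1 << (2 * k)):
        raise ValueError("code out of range for k")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_CODE_BASE[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Reverse complement of a packed k-mer, in code space."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | ((code & 3) ^ 3)
        code >>= 2
    return rc


def canonical(code: int, k: int) -> int:
    """The smaller of a code and its reverse complement; strand-invariant."""
    return min(code, revcomp_code(code, k))


def window_canonical_codes(seq: str, k: int) -> list[Optional[int]]:
    """Canonical code of every k-window of ``seq``, rolling incrementally.

    Windows covering an ambiguous base are ``None``.  Length of the
    result is ``max(0, len(seq) - k + 1)``.
    """
    n = len(seq)
    nwin = n - k + 1
    if nwin <= 0:
        return []
    out: list[Optional[int]] = [None] * nwin
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = 0
    rc = 0
    run = 0
    for j in range(n):
        b = int(_BASE_CODE[ord(seq[j])])
        if b == INVALID_BASE:
            run = 0
            fwd = (fwd << 2) & mask
            rc = rc >> 2
        else:
            run += 1
            fwd = ((fwd << 2) | b) & mask
            rc = (rc >> 2) | ((b ^ 3) << shift)
        w = j - k + 1
        if w >= 0 and run >= k:
            out[w] = min(fwd, rc)
    return out


class KmerIndex:
    """The set of k-mers to count, with their stored neighbors.

    Maps each canonical code to the union of canonical neighbor codes
    recorded for it during extraction (left and right adjacent windows in
    the source haplotype).  All k-mers in one index share a single ``k``.
    """

    def __init__(self, k: int):
        if not 1 <= k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}]")
        self.k = k
        self.neighbors: dict[int, frozenset[int]] = {}

    def add(self, code: int, neighbors: Iterable[int] = ()) -> None:
        code = canonical(code, self.k)
        nb = frozenset(canonical(x, self.k) for x in neighbors if x is not None)
        if code in self.neighbors:
            nb = self.neighbors[code] | nb
        self.neighbors[code] = nb

    def __contains__(self, code: int) -> bool:
        return code in self.neighbors

    def __len__(self) -> int:
        return len(self.neighbors)

    @property
    def codes(self) -> list[int]:
        return list(self.neighbors)


class CountTable(Mapping):
    """Occurrence counts per canonical k-mer, plus reads processed."""

    def __init__(self, codes: Iterable[int], k: int):
        self.k = k
        self._codes = np.unique(np.fromiter(codes, dtype=np.uint64))
        self._counts = np.zeros(len(self._codes), dtype=np.int64)
        self.reads_processed = 0

    def __getitem__(self, code: int) -> int:
        i = int(np.searchsorted(self._codes, np.uint64(code)))
        if i >= len(self._codes) or int(self._codes[i]) != code:
            raise KeyError(code)
        return int(self._counts[i])

    def __iter__(self) -> Iterator[int]:
        return (int(c) for c in self._codes)

    def __len__(self) -> int:
        return len(self._codes)

    def as_dict(self) -> dict[int, int]:
        return {int(c): int(n) for c, n in zip(self._codes, self._counts)}


def seqs_to_matrix(seqs: list[str]) -> np.ndarray:
    """Pack a batch of reads into a 2D base-code matrix, padded with 4."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    width = max(len(s) for s in seqs)
    mat = np.full((len(seqs), width), INVALID_BASE, dtype=np.uint8)
    for i, s in enumerate(seqs):
        if s:
            mat[i, : len(s)] = _BASE_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    return mat


def window_codes_matrix(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical window codes for a batch of reads.

    Returns ``(canon, valid)`` of shape (n_reads, n_windows); ``valid`` is
    False for windows covering a padded or ambiguous base.
    """
    n_reads, width = mat.shape
    nwin = width - k + 1
    if nwin <= 0 or n_reads == 0:
        return (np.empty((n_reads, 0), np.uint64), np.empty((n_reads, 0), bool))
    mask = np.uint64((1 << (2 * k)) - 1)
    shift = np.uint64(2 * (k - 1))
    two = np.uint64(2)
    three = np.uint64(3)
    fwd = np.zeros(n_reads, np.uint64)
    rc = np.zeros(n_reads, np.uint64)
    run = np.zeros(n_reads, np.int32)
    canon = np.empty((n_reads, nwin), np.uint64)
    valid = np.empty((n_reads, nwin), bool)
    for j in range(width):
        b = mat[:, j]
        ok = b < INVALID_BASE
        bb = np.where(ok, b, 0).astype(np.uint64)
        fwd = ((fwd << two) | bb) & mask
        rc = (rc >> two) | ((bb ^ three) << shift)
        run = np.where(ok, run + 1, 0)
        w = j - k + 1
        if w >= 0:
            canon[:, w] = np.minimum(fwd, rc)
            valid[:, w] = run >= k
    return canon, valid


def scan_read(
    seq: str, index: KmerIndex, verify_neighbors: bool = True
) -> list[tuple[int, int]]:
    """Accepted occurrences of indexed k-mers in one read.

    Returns ``(canonical_code, window_start)`` pairs.  With verification
    on, an occurrence is accepted when any *checkable* adjacent window
    (exists within the read, free of ambiguous bases) matches a stored
    neighbor, or when no adjacent window is checkable at all.
    """
    codes = window_canonical_codes(seq, index.k)
    hits: list[tuple[int, int]] = []
    for i, c in enumerate(codes):
        if c is None or c not in index.neighbors:
            continue
        if verify_neighbors and index.neighbors[c]:
            nb = index.neighbors[c]
            checkable = []
            if i > 0 and codes[i - 1] is not None:
                checkable.append(codes[i - 1])
            if i + 1 < len(codes) and codes[i + 1] is not None:
                checkable.append(codes[i + 1])
            if checkable and not any(x in nb for x in checkable):
                continue
        hits.append((c, i))
    return hits


def _iter_matrices(reads) -> Iterator[np.ndarray]:
    """Normalize a read source into base-code matrices.

    Accepts an ndarray, an object exposing ``.chunks()`` (the read
    simulator), or an iterable of strings / ndarrays.
    """
    if isinstance(reads, np.ndarray):
        yield reads
        return
    if hasattr(reads, "chunks"):
        for chunk in reads.chunks():
            if isinstance(chunk, tuple):
                for part in chunk:
                    yield part
            else:
                yield chunk
        return
    batch: list[str] = []
    for item in reads:
        if isinstance(item, np.ndarray):
            if batch:
                yield seqs_to_matrix(batch)
                batch = []
            yield item
        else:
            batch.append(item)
            if len(batch) >= 20000:
                yield seqs_to_matrix(batch)
                batch = []
    if batch:
        yield seqs_to_matrix(batch)


def count_reads(reads, index: KmerIndex, verify_neighbors: bool = True) -> CountTable:
    """Count accepted occurrences of every indexed k-mer over a read stream.

    ``reads`` may be an iterable of sequences, a packed base-code matrix,
    or any object with a ``.chunks()`` method yielding matrices.  Both
    FASTQ mates and any other read stream count identically; strand is
    irrelevant (canonical matching).
    """
    if len(index) == 0:
        raise ValueError("empty k-mer index")
    table = CountTable(index.neighbors.keys(), index.k)
    sorted_codes = table._codes
    counts = table._counts
    nb_map = index.neighbors
    k = index.k
    for mat in _iter_matrices(reads):
        table.reads_processed += mat.shape[0]
        canon, valid = window_codes_matrix(mat, k)
        nwin = canon.shape[1]
        if nwin == 0:
            continue
        flat = canon.ravel()
        idx = np.searchsorted(sorted_codes, flat)
        idx = np.minimum(idx, len(sorted_codes) - 1)
        hit = valid.ravel() & (sorted_codes[idx] == flat)
        if not verify_neighbors:
            np.add.at(counts, idx[hit], 1)
            continue
        for h in np.nonzero(hit)[0]:
            r, c = divmod(int(h), nwin)
            nb = nb_map[int(canon[r, c])]
            if not nb:  # nothing stored to verify against
                counts[idx[h]] += 1
                continue
            checkable = []
            if c > 0 and valid[r, c - 1]:
                checkable.append(int(canon[r, c - 1]))
            if c + 1 < nwin and valid[r, c + 1]:
                checkable.append(int(canon[r, c + 1]))
            if not checkable or any(x in nb for x in checkable):
                counts[idx[h]] += 1
    return table


def scan_positions(seq: str, codes: Iterable[int], k: int) -> dict[int, list[int]]:
    """Start positions of every occurrence of the given canonical codes in
    a long sequence (e.g. a reference contig), both strands merged.
    """
    target = np.unique(np.fromiter(codes, dtype=np.uint64))
    out: dict[int, list[int]] = {int(c): [] for c in target}
    n = len(seq)
    if n < k or len(target) == 0:
        return out
    stride = 1024
    width = stride + k - 1
    starts = list(range(0, n - k + 1, stride))
    mat = np.full((len(starts), width), INVALID_BASE, dtype=np.uint8)
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    for r, s in enumerate(starts):
        piece = arr[s : s + width]
        mat[r, : len(piece)] = piece
    canon, valid = window_codes_matrix(mat, k)
    nwin = canon.shape[1]
    flat = canon.ravel()
    idx = np.searchsorted(target, flat)
    idx = np.minimum(idx, len(target) - 1)
    hit = valid.ravel() & (target[idx] == flat)
    for h in np.nonzero(hit)[0]:
        r, c = divmod(int(h), nwin)
        pos = starts[r] + c
        if c < stride and pos <= n - k:
            out[int(canon[r, c])].append(pos)
    return out
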