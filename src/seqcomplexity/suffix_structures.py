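"""Suffix array and LCP array construction.

All four complexity measures are functions of two arrays: the suffix array
S (suffix start positions in lexicographic order of the suffixes) and the
LCP array (LCP[i] is the length of the longest common prefix of the
suffixes ranked i and i-1; LCP[1] = 0).  Positions and ranks are 1-based in
the public data model, mirroring the convention in which the measures are
stated; 0-based arrays are used internally and converted at the boundary.

The suffix array is built by prefix doubling over numpy argsorts
(O(n log^2 n), fully vectorised), which profiles 10 Mbp genomes in well
under a minute; the LCP array uses Kasai's O(n) algorithm compiled with
numba.  Any correct construction would do — correctness is fixed by the
invariants, not the algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

from seqcomplexity.errors import ConsistencyError, EmptyInputError

__all__ = ["SuffixArray", "LCPArray", "build_suffix_array", "build_lcp"]


@dataclass(frozen=True)
class SuffixArray:
    """Lexicographic order of all suffixes of a string.

    ``order[r]`` is the 1-based start position of the rank-(r+1) suffix;
    ``order`` is a permutation of 1..n.  A shorter suffix that is a prefix
    of a longer one sorts first (plain lexicographic order, no sentinel).
    """

    n: int
    order: np.ndarray

    def __post_init__(self) -> None:
        if self.order.shape != (self.n,):
            raise ConsistencyError(
                f"suffix array length {self.order.shape} != n={self.n}"
            )


@dataclass(frozen=True)
class LCPArray:
    """Adjacent-rank longest-common-prefix lengths.

    ``values[r]`` is the LCP of the suffixes ranked r+1 and r (1-based
    ranks); ``values[0] == 0`` by definition.
    """

    values: np.ndarray

    @property
    def n(self) -> int:
        return int(self.values.shape[0])


def _encode(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)


def _suffix_array_doubling(codes: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix array over integer codes; returns 0-based."""
    n = codes.shape[0]
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    k = 1
    while True:
        # sort by (rank[i], rank[i+k]), missing second key = -1 (shorter
        # suffix that is a prefix sorts first)
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.cumsum(bump)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = new_rank
        if new_rank[-1] == n - 1:
            return order
        k *= 2


@njit(nogil=True)
def _kasai(codes: np.ndarray, sa0: np.ndarray) -> np.ndarray:  # pragma: no cover
    n = codes.shape[0]
    rank = np.empty(n, dtype=np.int64)
    for i in range(n):
        rank[sa0[i]] = i
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa0[r - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def build_suffix_array(sequence: str) -> SuffixArray:
    """Build the suffix array of ``sequence`` (non-empty, typically ACGT).

    Deterministic: the suffix array of a string is unique.
    """
    if not sequence:
        raise EmptyInputError("cannot build a suffix array of an empty sequence")
    order0 = _suffix_array_doubling(_encode(sequence))
    return SuffixArray(n=len(sequence), order=order0 + 1)


def build_lcp(sequence: str, sa: SuffixArray) -> LCPArray:
    """Build the LCP array of ``sequence`` given its suffix array."""
    if sa.n != len(sequence):
        raise ConsistencyError(
            f"suffix array built for n={sa.n} but sequence has length {len(sequence)}"
        )
    values = _kasai(_encode(sequence), np.ascontiguousarray(sa.order - 1))
    return LCPArray(values=values)


def dump_tsv(sa: SuffixArray, lcp: LCPArray, path: str | Path) -> None:
    """Write ranks, suffix positions and LCP values as a three-column TSV."""
    with open(path, "w") as handle:
        handle.write("rank\tsuffix_start\tlcp\n")
        for r in range(sa.n):
            handle.write(f"{r + 1}\t{sa.order[r]}\t{lcp.values[r]}\n")
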