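"""Complexity measures of a genome computed from its suffix structures.

Four measures are provided, all linear-time given the suffix array S and
LCP array of the sequence g (n = |g|):

- ``I(g) = sum_i log4(LCP[i]+2) - log4(LCP[i]+1)`` — a smooth proxy for the
  number of distinct substrings (log base 4 for the DNA alphabet).
- ``D(g) = 2 * #distinct substrings / (n (n+1))`` — the rate of distinct
  substrings among all n(n+1)/2 substrings, in (0, 1].
- ``D_k(g) = #distinct k-mers / (n - k + 1)`` — the rate of distinct
  substrings of one fixed length k.
- ``R_k(g) = sum_{f(x)>1, |x|=k} f(x) / (n - k + 1)`` — the fraction of
  k-mer positions occupied by repeated k-mers.

The identities that make these linear-time:

- the number of distinct substrings is ``n(n+1)/2 - sum(LCP)`` (every LCP
  unit accounts for exactly one repeat occurrence of some substring);
- the number of distinct k-mers is ``|{j : S[j] <= n-k+1 and LCP[j] < k}|``;
- the total occurrences of repeated k-mers is ``sum (j - i + 2)`` over the
  maximal intervals [i, j] of suffix-array ranks with LCP >= k, each such
  interval corresponding to exactly one repeated k-mer.

``oracle_kmer_spectrum`` is an exhaustive hash-based k-mer counter kept as
an independent cross-check of the suffix-array routes on small inputs.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from seqcomplexity.errors import ConsistencyError, ParameterError, UndefinedStatisticError
from seqcomplexity.sequence_io import Genome
from seqcomplexity.suffix_structures import (
    LCPArray,
    SuffixArray,
    build_lcp,
    build_suffix_array,
)

logger = logging.getLogger(__name__)

DEFAULT_K = (12, 25, 50, 100)

_LN4 = math.log(4.0)


@dataclass(frozen=True)
class RepeatIntervalSet:
    """Maximal suffix-array rank intervals with adjacent LCP >= k.

    Each interval [i, j] (1-based ranks, 2 <= i <= j <= n) covers one
    distinct repeated k-mer occurring exactly j - i + 2 times (the ranks
    i-1 .. j share the same k-prefix).  Intervals are sorted, disjoint and
    non-adjacent.  The i = 1 boundary never occurs because LCP[1] = 0 < k
    for every k >= 1.
    """

    k: int
    intervals: tuple[tuple[int, int], ...]

    @property
    def total_occurrences(self) -> int:
        """Total occurrences of all repeated k-mers: sum of (j - i + 2)."""
        return sum(j - i + 2 for i, j in self.intervals)


@dataclass(frozen=True)
class ComplexityProfile:
    """All four measures of one genome, with D_k/R_k over a list of k."""

    genome_id: str
    length: int
    I: float
    D: float
    per_k: Mapping[int, tuple[float, float]] = field(default_factory=dict)


def _check_consistent(sa: SuffixArray, lcp: LCPArray) -> int:
    if sa.n != lcp.n:
        raise ConsistencyError(f"suffix array n={sa.n} but LCP array n={lcp.n}")
    return sa.n


def _check_k(k: int, n: int) -> None:
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} out of range [1, {n}]")


def count_distinct_substrings(sa: SuffixArray, lcp: LCPArray) -> int:
    """Number of distinct non-empty substrings: n(n+1)/2 - sum(LCP)."""
    n = _check_consistent(sa, lcp)
    return n * (n + 1) // 2 - int(lcp.values.sum())


def i_complexity(lcp: LCPArray) -> float:
    """I-complexity: sum of log4(LCP[i]+2) - log4(LCP[i]+1).

    Each term is computed as a single log of a ratio and accumulated with
    numpy's pairwise summation, which keeps rounding error negligible even
    for n in the tens of millions.
    """
    v = lcp.values.astype(np.float64)
    return float(np.sum(np.log((v + 2.0) / (v + 1.0))) / _LN4)


def d_complexity(length: int, distinct_count: int) -> float:
    """D-complexity: distinct substrings over all n(n+1)/2 substrings."""
    if length <= 0:
        raise UndefinedStatisticError("D is undefined for an empty sequence")
    total = length * (length + 1) // 2
    if not 1 <= distinct_count <= total:
        raise ParameterError(
            f"distinct_count={distinct_count} outside [1, {total}] for n={length}"
        )
    return 2.0 * distinct_count / (length * (length + 1.0))


def count_distinct_kmers(sa: SuffixArray, lcp: LCPArray, k: int) -> int:
    """Number of distinct k-mers: ranks j with S[j] <= n-k+1 and LCP[j] < k."""
    n = _check_consistent(sa, lcp)
    _check_k(k, n)
    return int(np.count_nonzero((sa.order <= n - k + 1) & (lcp.values < k)))


def k_repeat_intervals(lcp: LCPArray, k: int) -> RepeatIntervalSet:
    """Maximal runs of ranks u (u >= 2) with LCP[u] >= k, one linear scan."""
    n = lcp.n
    _check_k(k, n)
    mask = lcp.values >= k
    assert not mask[0], "LCP[1] = 0 must be < k for k >= 1"
    step = np.diff(mask.astype(np.int8))
    starts = np.nonzero(step == 1)[0] + 1  # 0-based indices into values
    ends = np.nonzero(step == -1)[0]
    if mask[-1]:
        ends = np.append(ends, n - 1)
    intervals = tuple(
        (int(s) + 1, int(e) + 1) for s, e in zip(starts, ends)
    )  # to 1-based ranks
    return RepeatIntervalSet(k=k, intervals=intervals)


def _structures(genome: Genome | str) -> tuple[str, SuffixArray, LCPArray]:
    seq = genome.sequence if isinstance(genome, Genome) else genome
    if not seq:
        raise UndefinedStatisticError("complexity is undefined for an empty genome")
    sa = build_suffix_array(seq)
    return seq, sa, build_lcp(seq, sa)


def d_k(genome: Genome | str, k: int) -> float:
    """Rate of distinct k-mers among the |g| - k + 1 k-mer positions."""
    seq, sa, lcp = _structures(genome)
    return count_distinct_kmers(sa, lcp, k) / (len(seq) - k + 1)


def r_k(genome: Genome | str, k: int) -> float:
    """Fraction of k-mer positions carrying k-mers that occur more than once."""
    seq, sa, lcp = _structures(genome)
    _check_k(k, len(seq))
    return k_repeat_intervals(lcp, k).total_occurrences / (len(seq) - k + 1)


def complexity_profile(
    genome: Genome | str, k_list: Iterable[int] = DEFAULT_K
) -> ComplexityProfile:
    """Compute I, D and per-k (D_k, R_k) in one pass over one index build.

    k values outside [1, |g|] are dropped with a warning rather than
    reported as zero: a silent zero would corrupt downstream correlations.
    """
    seq, sa, lcp = _structures(genome)
    n = len(seq)
    distinct = count_distinct_substrings(sa, lcp)
    per_k: dict[int, tuple[float, float]] = {}
    for k in k_list:
        if not 1 <= k <= n:
            logger.warning("dropping k=%d outside [1, %d]", k, n)
            continue
        dk = count_distinct_kmers(sa, lcp, k) / (n - k + 1)
        rk = k_repeat_intervals(lcp, k).total_occurrences / (n - k + 1)
        per_k[k] = (dk, rk)
    return ComplexityProfile(
        genome_id=genome.id if isinstance(genome, Genome) else "",
        length=n,
        I=i_complexity(lcp),
        D=d_complexity(n, distinct),
        per_k=per_k,
    )


def oracle_kmer_spectrum(sequence: str, k: int) -> dict[int, int]:
    """Exhaustive k-mer spectrum: occurrence count r -> number of distinct
    k-mers occurring exactly r times (C(k, r)).

    Hash-based and independent of the suffix-array routes; quadratic in
    memory over the distinct k-mers, intended for validation-scale inputs.
    """
    _check_k(k, len(sequence))
    counts = Counter(sequence[i : i + k] for i in range(len(sequence) - k + 1))
    spectrum: dict[int, int] = {}
    for r in counts.values():
        spectrum[r] = spectrum.get(r, 0) + 1
    return spectrum


def profiles_to_frame(profiles: Sequence[ComplexityProfile]) -> pd.DataFrame:
    """Tabulate profiles: one row per genome, D_k/R_k spread into columns."""
    k_all = sorted({k for p in profiles for k in p.per_k})
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "genome_id": p.genome_id,
            "length": p.length,
            "I": p.I,
            "D": p.D,
        }
        for k in k_all:
            dk_rk = p.per_k.get(k)
            row[f"D_{k}"] = dk_rk[0] if dk_rk else np.nan
            row[f"R_{k}"] = dk_rk[1] if dk_rk else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
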