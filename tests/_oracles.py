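"""Brute-force reference implementations used only by the tests.

These deliberately avoid suffix arrays and any code path from the package:
suffixes are sorted as plain strings, substrings are enumerated into sets,
and prefixes are compared character by character.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def brute_suffix_array(s: str) -> list[int]:
    """1-based suffix start positions in lexicographic suffix order."""
    return sorted(range(1, len(s) + 1), key=lambda i: s[i - 1 :])


def brute_lcp(s: str, order: list[int]) -> list[int]:
    """LCP of adjacent suffixes in ``order`` by direct character comparison."""
    values = [0]
    for prev, cur in zip(order, order[1:]):
        a, b = s[prev - 1 :], s[cur - 1 :]
        h = 0
        while h < min(len(a), len(b)) and a[h] == b[h]:
            h += 1
        values.append(h)
    return values


def brute_distinct_substrings(s: str) -> int:
    return len({s[i:j] for i in range(len(s)) for j in range(i + 1, len(s) + 1)})


def brute_distinct_kmers(s: str, k: int) -> int:
    return len({s[i : i + k] for i in range(len(s) - k + 1)})


def brute_repeat_occupancy(s: str, k: int) -> int:
    """Total occurrences of k-mers occurring more than once."""
    counts: dict[str, int] = {}
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return sum(c for c in counts.values() if c > 1)
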