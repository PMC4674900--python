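"""A deliberately simple exact-match aligner used for validation.

Real aligners are out of scope here; this stub exists so the evaluator and
the complexity-vs-accuracy correlation stage can be exercised end to end.
It reports, for each read, one exact occurrence of the read (or its
reverse complement) in the reference, chosen uniformly at random among all
occurrences.  On a repeat-free genome with error-free reads it is a
perfect aligner; on repetitive genomes it misplaces reads in proportion to
the ambiguity of their k-mer content — exactly the effect the
length-sensitive complexity measures quantify.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from seqcomplexity.read_simulation import SimulatedReadSet, revcomp
from seqcomplexity.sequence_io import Genome


def find_occurrences(haystack: str, needle: str) -> list[int]:
    """All 0-based occurrence positions (overlapping) of needle."""
    hits = []
    start = haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def align_exact(
    reads: SimulatedReadSet,
    genome: Genome,
    sam_path: str | Path,
    seed: int = 0,
) -> None:
    """Write a SAM file placing each read at a random exact occurrence.

    Reads with no exact occurrence on either strand are emitted unmapped
    (flag 4).  Mapping quality is a flat 60 and the CIGAR a full match —
    the stub models placement ambiguity only, not alignment scoring.
    """
    rng = np.random.default_rng(seed)
    ref = genome.sequence
    with open(sam_path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unknown\n")
        out.write(f"@SQ\tSN:{genome.id}\tLN:{len(ref)}\n")
        for read in reads.reads:
            candidates = [(pos, 0) for pos in find_occurrences(ref, read.bases)]
            candidates += [
                (pos, 16) for pos in find_occurrences(ref, revcomp(read.bases))
            ]
            if not candidates:
                out.write(
                    f"{read.name}\t4\t*\t0\t0\t*\t*\t0\t0\t"
                    f"{read.bases}\t{read.qualities}\n"
                )
                continue
            pos, flag = candidates[rng.integers(len(candidates))]
            seq = read.bases if flag == 0 else revcomp(read.bases)
            out.write(
                f"{read.name}\t{flag}\t{genome.id}\t{pos + 1}\t60\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t{read.qualities}\n"
            )
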