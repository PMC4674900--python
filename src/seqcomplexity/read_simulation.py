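"""Read simulation with mutation and sequencing-error models.

The simulator mimics the classic wgsim workflow: first mutate the reference
(substitutions plus indels, so the "donor" genome differs from the
reference the way a resequenced individual would), then sample reads
uniformly from the mutated sequence on both strands and add per-base
sequencing errors.  Truth coordinates — the read's span mapped back to
*reference* coordinates via the indel bookkeeping — are encoded in the read
name, which is what makes downstream precision/recall evaluation against
the reference meaningful.

Read names use ``<genome_id>|<start>|<end>|<strand>|<serial>`` with 1-based
inclusive reference coordinates and start <= end regardless of strand.
The pipe separator keeps parsing unambiguous for ids containing
underscores (wgsim's own underscore-delimited names are ambiguous there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from seqcomplexity.errors import ParameterError
from seqcomplexity.sequence_io import Genome

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: indel length model: geometric with this continuation probability, capped
_INDEL_CONTINUATION = 0.3
_INDEL_CAP = 10


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    Defaults follow the evaluation protocol this package emulates:
    2x coverage, read lengths from {50, 75, 100}, sequencing error rates
    from {0.005, 0.01, 0.02}, mutation rates in [0.001, 0.01] of which 15%
    are indels.
    """

    read_length: int = 100
    coverage: float = 2.0
    error_rate: float = 0.01
    mutation_rate: float = 0.001
    indel_fraction: float = 0.15
    seed: int = 1

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ParameterError(f"read_length must be >= 1, got {self.read_length}")
        if self.coverage <= 0:
            raise ParameterError(f"coverage must be > 0, got {self.coverage}")
        for name in ("error_rate", "mutation_rate"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ParameterError(f"{name} must be in [0, 1), got {rate}")
        if not 0 <= self.indel_fraction <= 1:
            raise ParameterError(
                f"indel_fraction must be in [0, 1], got {self.indel_fraction}"
            )


@dataclass(frozen=True)
class Mutation:
    """One applied variant, in 1-based reference coordinates."""

    position: int
    ref: str
    alt: str
    type: Literal["SUB", "INS", "DEL"]


@dataclass(frozen=True)
class MutatedGenome:
    """A mutated copy of a reference with per-base reference coordinates.

    ``ref_positions[i]`` is the 0-based reference coordinate that mutated
    base i derives from (inserted bases inherit the coordinate of the base
    they were inserted after), giving a monotone map used to express read
    spans in reference coordinates.
    """

    sequence: str
    ref_positions: np.ndarray
    mutation_log: tuple[Mutation, ...]


@dataclass(frozen=True)
class SimulatedRead:
    name: str
    bases: str
    qualities: str


@dataclass(frozen=True)
class ReadTruth:
    genome_id: str
    start: int  # 1-based, leftmost
    end: int  # 1-based, inclusive
    strand: Literal["+", "-"]
    serial: int


@dataclass(frozen=True)
class SimulatedReadSet:
    reads: tuple[SimulatedRead, ...]
    mutation_log: tuple[Mutation, ...] = field(default_factory=tuple)

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for read in self.reads:
                handle.write(f"@{read.name}\n{read.bases}\n+\n{read.qualities}\n")

    def write_mutation_log(self, path: str | Path, chrom: str = ".") -> None:
        """Write applied variants as a minimal VCF-like TSV."""
        with open(path, "w") as handle:
            handle.write("CHROM\tPOS\tREF\tALT\tTYPE\n")
            for m in self.mutation_log:
                handle.write(f"{chrom}\t{m.position}\t{m.ref}\t{m.alt or '.'}\t{m.type}\n")


def encode_read_name(truth: ReadTruth) -> str:
    return "|".join(
        (truth.genome_id, str(truth.start), str(truth.end), truth.strand, str(truth.serial))
    )


def parse_read_name(name: str) -> ReadTruth:
    """Invert :func:`encode_read_name`; tolerates '|' inside the genome id."""
    parts = name.rsplit("|", 4)
    if len(parts) != 5 or parts[3] not in ("+", "-"):
        raise ValueError(f"read name {name!r} does not encode a truth tuple")
    return ReadTruth(
        genome_id=parts[0],
        start=int(parts[1]),
        end=int(parts[2]),
        strand=parts[3],  # type: ignore[arg-type]
        serial=int(parts[4]),
    )


def _indel_length(rng: np.random.Generator) -> int:
    # geometric over {1, 2, ...} with success prob 1 - continuation
    return min(int(rng.geometric(1.0 - _INDEL_CONTINUATION)), _INDEL_CAP)


def mutate_genome(
    genome: Genome, config: SimulationConfig, rng: np.random.Generator
) -> MutatedGenome:
    """Apply substitutions and indels to the reference.

    Each reference position is independently selected with probability
    ``mutation_rate``; a selected position becomes an indel with
    probability ``indel_fraction`` (insertion or deletion equiprobable,
    geometric length, capped) and otherwise a substitution to a uniformly
    chosen different base.  Positions consumed by a deletion cannot host a
    second event.
    """
    seq = genome.sequence
    n = len(seq)
    if n == 0:
        raise ParameterError("cannot mutate an empty genome")
    if config.mutation_rate == 0:
        return MutatedGenome(
            sequence=seq,
            ref_positions=np.arange(n, dtype=np.int64),
            mutation_log=(),
        )
    hits = np.nonzero(rng.random(n) < config.mutation_rate)[0]
    parts: list[str] = []
    ref_parts: list[np.ndarray] = []
    log: list[Mutation] = []
    prev = 0
    for p in hits:
        p = int(p)
        if p < prev:  # swallowed by a preceding deletion
            continue
        parts.append(seq[prev:p])
        ref_parts.append(np.arange(prev, p, dtype=np.int64))
        if rng.random() < config.indel_fraction:
            length = _indel_length(rng)
            if rng.random() < 0.5:  # insertion after base p
                inserted = "".join(rng.choice(list(_BASES), size=length))
                parts.append(seq[p] + inserted)
                ref_parts.append(np.full(length + 1, p, dtype=np.int64))
                log.append(Mutation(p + 1, seq[p], seq[p] + inserted, "INS"))
                prev = p + 1
            else:  # deletion of bases p .. p+length-1
                length = min(length, n - p)
                log.append(Mutation(p + 1, seq[p : p + length], "", "DEL"))
                prev = p + length
        else:
            alt = _OTHER[seq[p]][rng.integers(3)]
            parts.append(alt)
            ref_parts.append(np.array([p], dtype=np.int64))
            log.append(Mutation(p + 1, seq[p], alt, "SUB"))
            prev = p + 1
    parts.append(seq[prev:])
    ref_parts.append(np.arange(prev, n, dtype=np.int64))
    return MutatedGenome(
        sequence="".join(parts),
        ref_positions=np.concatenate(ref_parts),
        mutation_log=tuple(log),
    )


def _apply_sequencing_errors(
    bases: str, error_rate: float, rng: np.random.Generator
) -> str:
    if error_rate == 0:
        return bases
    errs = np.nonzero(rng.random(len(bases)) < error_rate)[0]
    if errs.size == 0:
        return bases
    out = list(bases)
    for i in errs:
        out[i] = _OTHER[out[i]][rng.integers(3)]
    return "".join(out)


def simulate_reads(genome: Genome, config: SimulationConfig) -> SimulatedReadSet:
    """Simulate single-end reads from a mutated copy of ``genome``.

    Read count is floor(coverage * |g| / read_length); start positions are
    uniform over the mutated sequence, strands uniform, reverse-strand
    reads emitted as reverse complements.  Deterministic given
    ``config.seed``.  Quality strings are constant ('I') since no
    downstream stage consumes them.
    """
    rng = np.random.default_rng(config.seed)
    mut = mutate_genome(genome, config, rng)
    m = len(mut.sequence)
    L = config.read_length
    if L > m:
        raise ParameterError(
            f"read_length {L} exceeds mutated genome length {m}"
        )
    n_reads = int(config.coverage * len(genome.sequence) // L)
    starts = rng.integers(0, m - L + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    qual = "I" * L
    reads = []
    for serial, (s0, neg) in enumerate(zip(starts, strands), start=1):
        s0 = int(s0)
        fragment = mut.sequence[s0 : s0 + L]
        strand: Literal["+", "-"] = "-" if neg else "+"
        if neg:
            fragment = revcomp(fragment)
        bases = _apply_sequencing_errors(fragment, config.error_rate, rng)
        truth = ReadTruth(
            genome_id=genome.id,
            start=int(mut.ref_positions[s0]) + 1,
            end=int(mut.ref_positions[s0 + L - 1]) + 1,
            strand=strand,
            serial=serial,
        )
        reads.append(SimulatedRead(encode_read_name(truth), bases, qual))
    return SimulatedReadSet(reads=tuple(reads), mutation_log=mut.mutation_log)
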