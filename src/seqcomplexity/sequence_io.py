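"""FASTA input and genome preprocessing.

Genomic sequences frequently carry runs of N (assembly gaps) and lowercase
soft-masked regions.  N runs are not real sequence content and would show up
as enormous artificial repeats in any substring-based complexity measure, so
they are stripped before analysis; case is normalised because masking is an
annotation, not a change of nucleotide.  The :class:`Genome` record keeps
enough provenance (original length, number of stripped bases) to audit the
preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from Bio import SeqIO

from seqcomplexity.errors import FastaFormatError, ValidationError

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")

AmbiguousPolicy = Literal["strip", "error"]


@dataclass(frozen=True)
class Genome:
    """A preprocessed DNA sequence over the four-letter alphabet.

    Attributes
    ----------
    id:
        FASTA header token (first whitespace-delimited word).
    sequence:
        Uppercase sequence containing only A, C, G, T.
    original_length:
        Number of bases before preprocessing.
    removed_bases:
        Number of characters stripped (N's plus any other non-ACGT codes).
    """

    id: str
    sequence: str
    original_length: int
    removed_bases: int

    def __post_init__(self) -> None:
        if len(self.sequence) + self.removed_bases != self.original_length:
            raise ValueError(
                "inconsistent Genome provenance: "
                f"{len(self.sequence)} + {self.removed_bases} != {self.original_length}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def preprocess(
    raw: str, *, on_ambiguous: AmbiguousPolicy = "strip"
) -> tuple[str, int]:
    """Normalise case and strip non-ACGT characters from ``raw``.

    N/n characters are always removed and counted.  Other non-ACGT
    characters (IUPAC ambiguity codes, stray symbols) are removed and
    counted under the default ``strip`` policy — they are no more real
    content than N — or rejected with the offending position under
    ``error``.

    Returns
    -------
    (sequence, removed_bases)
        The cleaned uppercase sequence and the count of stripped characters.
    """
    upper = raw.upper()
    if set(upper) <= _VALID:  # fast path: nothing to strip
        return upper, 0
    if on_ambiguous == "error":
        for pos, ch in enumerate(upper):
            if ch not in _VALID and ch != "N":
                raise ValidationError(
                    f"non-IUPAC-ACGTN character {ch!r} at position {pos + 1}"
                )
    kept = [ch for ch in upper if ch in _VALID]
    removed = len(upper) - len(kept)
    n_count = upper.count("N")
    if removed > n_count:
        logger.warning(
            "stripped %d non-N ambiguous characters in addition to %d N's",
            removed - n_count,
            n_count,
        )
    return "".join(kept), removed


def _preprocess_record(
    record_id: str, raw: str, on_ambiguous: AmbiguousPolicy
) -> Genome:
    sequence, removed = preprocess(raw, on_ambiguous=on_ambiguous)
    return Genome(
        id=record_id,
        sequence=sequence,
        original_length=len(raw),
        removed_bases=removed,
    )


def read_fasta(
    path: str | Path, *, on_ambiguous: AmbiguousPolicy = "strip"
) -> list[Genome]:
    """Read a (multi-record) FASTA file and return preprocessed genomes.

    Records are returned in file order.  A record whose sequence is empty
    after preprocessing is retained (its zero length flags it downstream).

    Raises
    ------
    FastaFormatError
        If the file is empty or does not start with a ``>`` header; the
        message names the offending line.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno} is not a FASTA header "
                        "(expected '>')"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: empty FASTA file")
    genomes = [
        _preprocess_record(record.id, str(record.seq), on_ambiguous)
        for record in SeqIO.parse(str(path), "fasta")
    ]
    if not genomes:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return genomes


def write_fasta(genomes: list[Genome], path: str | Path, width: int = 70) -> None:
    """Write genomes as wrapped FASTA (convenience for fixtures and CLIs)."""
    with open(path, "w") as handle:
        for g in genomes:
            handle.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                handle.write(g.sequence[i : i + width] + "\n")
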