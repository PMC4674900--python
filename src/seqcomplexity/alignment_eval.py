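"""Precision/recall evaluation of SAM alignments against simulated truth.

A mapped record is *correct* when it is placed on the right reference and
its leftmost 1-based coordinate lies within a gap tolerance (default 20)
of the truth position encoded in the read name — either the truth's
leftmost coordinate directly, or the start derived from the truth's right
endpoint and the record's read span (indels can shift one end more than
the other).  Precision is correct / aligned; recall is correct / total
reads.  With ``count_secondary`` every mapped record contributes, which
reproduces the multi-mapping regime in which recall can exceed 1 because
one read may be counted correct at several locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pysam

from seqcomplexity.errors import EmptyInputError, EvaluationError
from seqcomplexity.read_simulation import ReadTruth, parse_read_name

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalConfig:
    gap: int = 20
    count_secondary: bool = False

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError(f"gap must be >= 0, got {self.gap}")


@dataclass(frozen=True)
class EvalResult:
    total_reads: int
    aligned: int
    correct: int

    @property
    def precision(self) -> float | None:
        """correct / aligned; None (undefined) when nothing aligned."""
        return self.correct / self.aligned if self.aligned else None

    @property
    def recall(self) -> float:
        """correct / total reads; may exceed 1 when secondaries are counted."""
        return self.correct / self.total_reads


def is_correct(truth: ReadTruth, record: pysam.AlignedSegment, gap: int) -> bool:
    """Positional correctness of one mapped record under the gap tolerance."""
    if record.reference_name != truth.genome_id:
        return False
    pos = record.reference_start + 1  # SAM leftmost, to 1-based
    span = record.query_length or record.infer_query_length() or (
        truth.end - truth.start + 1
    )
    start_from_left = truth.start
    start_from_right = truth.end - span + 1
    return (
        abs(pos - start_from_left) <= gap or abs(pos - start_from_right) <= gap
    )


def _count_fastq_reads(path: str | Path) -> tuple[int, set[str]]:
    names: set[str] = set()
    with open(path) as handle:
        for i, line in enumerate(handle):
            if i % 4 == 0:
                names.add(line[1:].split()[0])
    return len(names), names


def evaluate(
    sam_path: str | Path,
    fastq_path: str | Path | None = None,
    config: EvalConfig = EvalConfig(),
) -> EvalResult:
    """Evaluate a SAM file whose read names encode simulation truth.

    ``total_reads`` comes from the FASTQ when given (the denominator must
    include reads the aligner dropped entirely), otherwise from the
    distinct read names in the SAM, unmapped records included.

    With ``count_secondary`` false (default) exactly one record per read
    contributes: the primary, or the first mapped record encountered; a
    second primary for the same name is ignored with a warning.
    """
    fastq_names: set[str] | None = None
    total_from_fastq = 0
    if fastq_path is not None:
        total_from_fastq, fastq_names = _count_fastq_reads(fastq_path)

    seen_names: set[str] = set()
    counted_names: set[str] = set()
    aligned = 0
    correct = 0
    n_records = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for record in sam:
            n_records += 1
            name = record.query_name
            if name is None:
                raise EvaluationError("SAM record without a read name")
            seen_names.add(name)
            if fastq_names is not None and name not in fastq_names:
                logger.warning("read %s in SAM but not in FASTQ", name)
            if record.is_unmapped:
                continue
            if not config.count_secondary:
                if record.is_secondary or record.is_supplementary:
                    continue
                if name in counted_names:
                    logger.warning("multiple primary records for read %s; first wins", name)
                    continue
                counted_names.add(name)
            try:
                truth = parse_read_name(name)
            except ValueError as exc:
                raise EvaluationError(str(exc)) from exc
            aligned += 1
            if is_correct(truth, record, config.gap):
                correct += 1
    if n_records == 0:
        raise EmptyInputError(f"{sam_path}: SAM file contains no records")
    total = total_from_fastq if fastq_names is not None else len(seen_names)
    return EvalResult(total_reads=total, aligned=aligned, correct=correct)


def write_eval_tsv(
    result: EvalResult, genome_id: str, path: str | Path
) -> None:
    precision = "" if result.precision is None else f"{result.precision:.6g}"
    with open(path, "w") as handle:
        handle.write("genome_id\ttotal\taligned\tcorrect\tprecision\trecall\n")
        handle.write(
            f"{genome_id}\t{result.total_reads}\t{result.aligned}\t"
            f"{result.correct}\t{precision}\t{result.recall:.6g}\n"
        )
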