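import pysam
import pytest

from conftest import make_genome
from _oracles import random_dna
from seqcomplexity import (
    EvalConfig,
    SimulationConfig,
    evaluate,
    is_correct,
    simulate_reads,
)
from seqcomplexity.errors import EmptyInputError, EvaluationError
from seqcomplexity.read_simulation import ReadTruth
from seqcomplexity.toy_aligner import align_exact


def write_sam(path, records, ref="ref", ln=100000):
    lines = ["@HD\tVN:1.6\tSO:unknown", f"@SQ\tSN:{ref}\tLN:{ln}"]
    for name, flag, pos in records:
        seq = "A" * 50
        lines.append(
            f"{name}\t{flag}\t{'*' if flag & 4 else ref}\t{0 if flag & 4 else pos}"
            f"\t60\t{'*' if flag & 4 else '50M'}\t*\t0\t0\t{seq}\t{'I' * 50}"
        )
    path.write_text("\n".join(lines) + "\n")


def name(i, start=100, end=149, strand="+"):
    return f"ref|{start}|{end}|{strand}|{i}"


def read_one_record(path):
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        return next(iter(sam))


@pytest.mark.parametrize(
    "mapped_pos, gap, expected",
    [
        (115, 20, True),
        (130, 20, False),
        (100, 0, True),
        (120, 20, True),  # exactly at the gap boundary
        (121, 20, False),  # one past the boundary
        (80, 20, True),
        (79, 20, False),
    ],
)
def test_is_correct_gap_window(tmp_path, mapped_pos, gap, expected):
    sam = tmp_path / "one.sam"
    write_sam(sam, [(name(1), 0, mapped_pos)])
    record = read_one_record(sam)
    truth = ReadTruth("ref", 100, 149, "+", 1)
    assert is_correct(truth, record, gap) is expected


def test_is_correct_requires_matching_reference(tmp_path):
    sam = tmp_path / "one.sam"
    write_sam(sam, [(name(1), 0, 100)], ref="other")
    record = read_one_record(sam)
    assert not is_correct(ReadTruth("ref", 100, 149, "+", 1), record, 20)


def test_is_correct_accepts_right_endpoint_derived_start(tmp_path):
    # indel shifted the left end; right-end-derived start still matches
    sam = tmp_path / "one.sam"
    write_sam(sam, [(name(1, start=100, end=179), 0, 130)])
    record = read_one_record(sam)  # span 50, right-derived start = 179-50+1 = 130
    assert is_correct(ReadTruth("ref", 100, 179, "+", 1), record, 0)


def test_evaluate_counts_and_metrics(tmp_path):
    """10 reads: 8 aligned of which 6 within gap -> precision .75, recall .6."""
    records = []
    for i in range(1, 7):
        records.append((name(i), 0, 100 + i))  # correct
    for i in range(7, 9):
        records.append((name(i), 0, 5000))  # aligned, wrong place
    for i in range(9, 11):
        records.append((name(i), 4, 0))  # unmapped
    sam = tmp_path / "eval.sam"
    write_sam(sam, records)
    result = evaluate(sam, None, EvalConfig(gap=20))
    assert (result.total_reads, result.aligned, result.correct) == (10, 8, 6)
    assert result.precision == pytest.approx(0.75)
    assert result.recall == pytest.approx(0.6)


def test_evaluate_is_order_invariant(tmp_path):
    records = [(name(i), 0, 100 + 10 * i) for i in range(1, 8)]
    sam_a, sam_b = tmp_path / "a.sam", tmp_path / "b.sam"
    write_sam(sam_a, records)
    write_sam(sam_b, records[::-1])
    ra = evaluate(sam_a, None, EvalConfig())
    rb = evaluate(sam_b, None, EvalConfig())
    assert (ra.aligned, ra.correct, ra.total_reads) == (rb.aligned, rb.correct, rb.total_reads)


def test_evaluate_zero_aligned(tmp_path):
    sam = tmp_path / "unmapped.sam"
    write_sam(sam, [(name(i), 4, 0) for i in range(1, 4)])
    result = evaluate(sam, None, EvalConfig())
    assert result.aligned == 0
    assert result.precision is None
    assert result.recall == 0


def test_evaluate_secondary_records(tmp_path):
    """One read at two in-gap locations: recall 2.0 when secondaries count."""
    records = [(name(1), 0, 101), (name(1), 256, 110)]
    sam = tmp_path / "multi.sam"
    write_sam(sam, records)
    primary_only = evaluate(sam, None, EvalConfig(gap=20))
    assert (primary_only.aligned, primary_only.correct) == (1, 1)
    both = evaluate(sam, None, EvalConfig(gap=20, count_secondary=True))
    assert (both.total_reads, both.aligned, both.correct) == (1, 2, 2)
    assert both.recall == pytest.approx(2.0)


def test_evaluate_total_from_fastq(tmp_path):
    fq = tmp_path / "reads.fq"
    fq.write_text(
        "".join(f"@{name(i)}\n{'A' * 50}\n+\n{'I' * 50}\n" for i in range(1, 5))
    )
    sam = tmp_path / "sub.sam"
    write_sam(sam, [(name(1), 0, 100)])
    result = evaluate(sam, fq, EvalConfig())
    assert result.total_reads == 4
    assert result.recall == pytest.approx(0.25)


def test_evaluate_error_cases(tmp_path):
    empty = tmp_path / "empty.sam"
    empty.write_text("@HD\tVN:1.6\n@SQ\tSN:ref\tLN:1000\n")
    with pytest.raises(EmptyInputError):
        evaluate(empty, None, EvalConfig())
    bad = tmp_path / "bad.sam"
    write_sam(bad, [("plainname", 0, 100)])
    with pytest.raises(EvaluationError, match="plainname"):
        evaluate(bad, None, EvalConfig())


def test_perfect_aligner_round_trip(tmp_path, rng):
    """Error-free reads from a repeat-free genome align perfectly."""
    genome = make_genome(random_dna(rng, 20_000), gid="clean")
    cfg = SimulationConfig(
        read_length=75, coverage=2, error_rate=0, mutation_rate=0, seed=8
    )
    reads = simulate_reads(genome, cfg)
    fq, sam = tmp_path / "r.fq", tmp_path / "r.sam"
    reads.write_fastq(fq)
    align_exact(reads, genome, sam, seed=8)
    result = evaluate(sam, fq, EvalConfig(gap=20))
    assert result.precision == 1.0
    assert result.recall == 1.0
    assert result.total_reads == len(reads.reads)
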