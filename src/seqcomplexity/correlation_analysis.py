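"""Correlating genome complexity with alignment accuracy.

The central analysis: given complexity profiles for a panel of genomes and
a table of per-genome alignment performance (precision/recall per aligner
and simulation condition), compute the linear (Pearson) correlation of
each complexity measure with each accuracy metric.  A measure whose value
predicts accuracy across genomes is a useful proxy for alignability, and
the expectation is that the distinct-k-mer rate D_k with k near the read
length correlates best.

Because assembling a large panel of public genomes is an external exercise,
the module also ships a seeded synthetic genome panel generator with
tunable repeat content, used to exercise the full pipeline (complexity ->
simulation -> alignment -> evaluation -> correlation) at desk scale.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from seqcomplexity.alignment_eval import EvalConfig, evaluate
from seqcomplexity.complexity import ComplexityProfile, complexity_profile, profiles_to_frame
from seqcomplexity.errors import InsufficientDataError, UndefinedStatisticError
from seqcomplexity.read_simulation import SimulationConfig, simulate_reads
from seqcomplexity.sequence_io import Genome
from seqcomplexity.toy_aligner import align_exact

logger = logging.getLogger(__name__)

PERFORMANCE_COLUMNS = (
    "genome_id",
    "aligner_id",
    "read_length",
    "error_rate",
    "mutation_rate",
    "precision",
    "recall",
)


@dataclass(frozen=True)
class CorrelationResult:
    measure_id: str  # "I", "D", "D_<k>" or "R_<k>"
    aligner_id: str
    metric: Literal["precision", "recall"]
    r: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient.

    Raises :class:`UndefinedStatisticError` for constant inputs rather
    than returning 0 — an undefined correlation must stay visibly missing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def correlate(
    profiles: Sequence[ComplexityProfile] | pd.DataFrame,
    perf: pd.DataFrame,
    measures: Iterable[str],
) -> list[CorrelationResult]:
    """One correlation per (measure, aligner, metric) cell.

    ``perf`` rows missing a profile (and vice versa) are dropped pairwise
    with a logged count; a cell with a constant metric or measure yields a
    missing entry (logged), never r = 0.  Fewer than 3 shared genomes in a
    cell is an error: a correlation on 2 points is meaningless.
    """
    prof_df = (
        profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    )
    measures = list(measures)
    missing_measures = [m for m in measures if m not in prof_df.columns]
    if missing_measures:
        raise KeyError(f"measures not present in profiles: {missing_measures}")
    merged = perf.merge(prof_df, on="genome_id", how="inner")
    dropped = len(perf) - len(merged)
    if dropped:
        logger.info("dropped %d performance rows without a profile", dropped)
    results: list[CorrelationResult] = []
    for aligner_id, group in merged.groupby("aligner_id", sort=True):
        for measure in measures:
            for metric in ("precision", "recall"):
                pair = group[[measure, metric]].dropna()
                if len(pair) < 3:
                    raise InsufficientDataError(
                        f"cell ({measure}, {aligner_id}, {metric}) has only "
                        f"{len(pair)} shared genomes"
                    )
                try:
                    r = pearson(pair[measure].to_numpy(), pair[metric].to_numpy())
                except UndefinedStatisticError:
                    logger.warning(
                        "constant input in cell (%s, %s, %s); correlation missing",
                        measure,
                        aligner_id,
                        metric,
                    )
                    continue
                results.append(
                    CorrelationResult(
                        measure_id=measure,
                        aligner_id=str(aligner_id),
                        metric=metric,  # type: ignore[arg-type]
                        r=r,
                        n=len(pair),
                    )
                )
    return results


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "measure_id": c.measure_id,
                "aligner_id": c.aligner_id,
                "metric": c.metric,
                "r": c.r,
                "n": c.n,
            }
            for c in results
        ]
    )


def summarize_performance(perf: pd.DataFrame) -> pd.DataFrame:
    """Boxplot-style summary per (aligner, read length) and metric."""
    if perf.empty:
        raise ValueError("performance table is empty")
    rows = []
    for (aligner_id, read_length), group in perf.groupby(
        ["aligner_id", "read_length"], sort=True
    ):
        for metric in ("precision", "recall"):
            values = group[metric].dropna().to_numpy()
            if values.size == 0:
                continue
            rows.append(
                {
                    "aligner_id": aligner_id,
                    "read_length": read_length,
                    "metric": metric,
                    "n": values.size,
                    "mean": float(values.mean()),
                    "median": float(np.median(values)),
                    "q1": float(np.percentile(values, 25)),
                    "q3": float(np.percentile(values, 75)),
                    "min": float(values.min()),
                    "max": float(values.max()),
                }
            )
    return pd.DataFrame(rows)


def ecdf(values: Sequence[float]) -> list[tuple[float, float]]:
    """Right-continuous empirical CDF at the sorted unique values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("ecdf of an empty sample is undefined")
    uniq, counts = np.unique(arr, return_counts=True)
    cum = np.cumsum(counts) / arr.size
    return [(float(v), float(c)) for v, c in zip(uniq, cum)]


def genome_panel(
    n_genomes: int = 20,
    length: int = 50_000,
    repeat_unit_length: int = 500,
    max_repeat_fraction: float = 0.85,
    short_unit_length: int = 20,
    max_short_fraction: float = 0.5,
    seed: int = 0,
) -> list[Genome]:
    """Synthetic genomes spanning low to high repeat content.

    Each genome starts as i.i.d. random sequence and receives two repeat
    processes, mimicking the multi-scale repeat structure of real genomes:

    - copies of a long repeat unit (default 500 bp, i.e. at or above read
      length) pasted at random positions until a target fraction of the
      genome is repeat-derived; that fraction sweeps evenly from 0 to
      ``max_repeat_fraction`` across the panel.  These repeats create
      ambiguous read placements.
    - copies of a short repeat unit (default 20 bp) at a fraction drawn
      uniformly in [0, ``max_short_fraction``] per genome, independent of
      the long-repeat sweep.  These depress short-k complexity (D_12,
      R_12) without making read-length windows ambiguous.

    The result is a panel whose D_k/R_k sweep their ranges and in which
    only complexity at k near the read length tracks alignability.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if repeat_unit_length >= length or short_unit_length >= length:
        raise ValueError("repeat units must be shorter than the genome")
    rng = np.random.default_rng(seed)
    long_fractions = np.linspace(0.0, max_repeat_fraction, n_genomes)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genomes = []
    for i, long_frac in enumerate(long_fractions):
        arr = bases[rng.integers(0, 4, size=length)]
        short_frac = rng.uniform(0.0, max_short_fraction)
        for unit_len, frac in (
            (short_unit_length, short_frac),
            (repeat_unit_length, long_frac),
        ):
            n_copies = int(round(frac * length / unit_len))
            if n_copies:
                unit = bases[rng.integers(0, 4, size=unit_len)]
                starts = rng.integers(0, length - unit_len + 1, size=n_copies)
                for s in starts:
                    arr[s : s + unit_len] = unit
        genomes.append(
            Genome(
                id=f"panel_{i:03d}",
                sequence=arr.tobytes().decode("ascii"),
                original_length=length,
                removed_bases=0,
            )
        )
    return genomes


def run_panel_experiment(
    genomes: Sequence[Genome],
    sim_config: SimulationConfig,
    k_list: Iterable[int] = (12, 25, 50, 100),
    eval_config: EvalConfig = EvalConfig(),
    aligner_id: str = "exact-match",
    workdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pipeline on a genome panel with the built-in aligner.

    For each genome: profile complexity, simulate reads, align with the
    exact-match stub, evaluate.  Returns (profiles table, performance
    table) ready for :func:`correlate`.
    """
    profiles = []
    perf_rows = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp_path = Path(tmp)
        for idx, genome in enumerate(genomes):
            profiles.append(complexity_profile(genome, k_list))
            cfg = SimulationConfig(
                read_length=sim_config.read_length,
                coverage=sim_config.coverage,
                error_rate=sim_config.error_rate,
                mutation_rate=sim_config.mutation_rate,
                indel_fraction=sim_config.indel_fraction,
                seed=sim_config.seed + idx,
            )
            reads = simulate_reads(genome, cfg)
            fq = tmp_path / f"{genome.id}.fq"
            sam = tmp_path / f"{genome.id}.sam"
            reads.write_fastq(fq)
            align_exact(reads, genome, sam, seed=cfg.seed)
            result = evaluate(sam, fq, eval_config)
            perf_rows.append(
                {
                    "genome_id": genome.id,
                    "aligner_id": aligner_id,
                    "read_length": cfg.read_length,
                    "error_rate": cfg.error_rate,
                    "mutation_rate": cfg.mutation_rate,
                    "precision": result.precision,
                    "recall": result.recall,
                }
            )
    return profiles_to_frame(profiles), pd.DataFrame(perf_rows)
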