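# seqcomplexity

Length-sensitive genome complexity measures and their relation to the
difficulty of short-read alignment.

## The problem

Short-read aligners misplace reads when a genome contains repeats close to
the read length: a 100 bp read drawn from a repeated 100-mer has several
equally good homes. A complexity measure that can be computed from the
genome alone — without aligning anything — and that predicts alignment
accuracy is useful for choosing aligners and anticipating their accuracy on
new genomes. This package implements four such measures, all computable in
a single pass over the genome's suffix array `S` and LCP array (`LCP[i]` is
the longest common prefix of the suffixes ranked `i` and `i−1`; `LCP[1] = 0`):

- **I-complexity** — `I(g) = Σᵢ log₄(LCP[i]+2) − log₄(LCP[i]+1)`, a smooth
  proxy for the number of distinct substrings.
- **D-complexity** — the rate of distinct substrings,
  `D(g) = 2·|{x : f(x)>0}| / (|g|(|g|+1))`, where `f(x)` is the occurrence
  count of substring `x`. The numerator is `|g|(|g|+1)/2 − Σ LCP[i]`:
  every unit of LCP accounts for exactly one repeat occurrence.
- **D_k** — the rate of *distinct k-mers*,
  `D_k(g) = |{x : f(x)>0, |x|=k}| / (|g|−k+1)`; the distinct-k-mer count is
  `|{j : S[j] ≤ |g|−k+1 and LCP[j] < k}|`.
- **R_k** — the rate of *k-mer repeat occurrences*,
  `R_k(g) = Σ_{f(x)>1, |x|=k} f(x) / (|g|−k+1)`, computed as `Σ (j−i+2)`
  over the maximal runs `[i, j]` of suffix-array ranks with `LCP ≥ k`.
  Equivalently `R_k·(|g|−k+1) = Σ_{r>1} r·C(k,r)` in terms of the k-mer
  spectrum `C(k,r)`.

`D_k` and `R_k` are *length-sensitive*: only repeats of length `k` matter,
and the empirical finding the package is built to explore is that `D_k`
with `k` near the read length correlates far better with alignment
precision/recall than length-blind measures such as `I` or `D`.

Around the measures sit the pieces needed to test that claim end to end:
FASTA input with N-stripping (assembly-gap N runs would otherwise read as
enormous fake repeats), a wgsim-style read simulator (mutations with a 15%
indel share, per-base sequencing errors, truth coordinates encoded in read
names), a SAM precision/recall evaluator with a positional gap tolerance
(default 20), an intentionally simple exact-match aligner for validation,
and a Pearson-correlation stage over panels of genomes, including a seeded
synthetic-panel generator with tunable repeat content.

## Worked example

```python
from seqcomplexity import (
    Genome, complexity_profile, correlate, genome_panel,
)
from seqcomplexity.correlation_analysis import run_panel_experiment
from seqcomplexity.read_simulation import SimulationConfig

g = Genome(id="toy", sequence="ACA", original_length=3, removed_bases=0)
p = complexity_profile(g, [1])
print(f"I = {p.I:.6f}, D = {p.D:.6f}, D_1 = {p.per_k[1][0]:.6f}, R_1 = {p.per_k[1][1]:.6f}")

panel = genome_panel(n_genomes=16, length=30_000, seed=7)
cfg = SimulationConfig(read_length=50, coverage=2, error_rate=0, mutation_rate=0, seed=8)
profiles, perf = run_panel_experiment(panel, cfg, k_list=[12, 50])
for c in correlate(profiles, perf, ["D_12", "D_50"]):
    print(f"{c.measure_id:5s} {c.metric:9s} r = {c.r:+.3f}  (n = {c.n})")
```

prints

```
I = 1.292481, D = 0.833333, D_1 = 0.666667, R_1 = 0.666667
D_12  precision r = +0.908  (n = 16)
D_12  recall    r = +0.908  (n = 16)
D_50  precision r = +0.998  (n = 16)
D_50  recall    r = +0.998  (n = 16)
```

For `"ACA"`: the distinct substrings are {A, C, AC, CA, ACA}, so
`D = 5/6 ≈ 0.833`; two of the three 1-mer positions carry distinct bases
(`D_1 = 2/3`) and two are occupied by the repeated base A (`R_1 = 2/3`).
On the synthetic panel — 16 genomes of 30 kb whose repeat content sweeps
from none to heavy — the distinct-k-mer rate at `k =` read length (50)
tracks the exact-match aligner's accuracy almost perfectly (r ≈ 0.998),
while `D_12` correlates noticeably less (r ≈ 0.91): alignability is a
length-sensitive property.

## Command line

```sh
seqcomplexity complexity --fasta genome.fa --k 12,25,50,100 --out profile.tsv
seqcomplexity simulate   --fasta genome.fa --read-length 100 --coverage 2 \
                         --error-rate 0.02 --mutation-rate 0.001 --seed 17 --out reads.fq
seqcomplexity evaluate   --sam aligner_output.sam --fastq reads.fq --gap 20 --out eval.tsv
seqcomplexity correlate  --profiles profiles.tsv --performance perf.tsv \
                         --measures I,D,D_50,D_100,R_100 --out corr.tsv
```

The `evaluate` command works on any SAM produced by any aligner run on the
simulated FASTQ — read names carry the truth, so no other bookkeeping is
needed.

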