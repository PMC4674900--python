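# Methods

## Measures and the suffix-array identities

All four complexity measures are functionals of the suffix array `S` and
LCP array of the genome string `g` (`n = |g|`, alphabet {A,C,G,T}, 1-based
indices, `LCP[1] = 0`). The package relies on three counting identities,
each of which is verified exhaustively against brute-force enumeration in
the test suite:

1. **Distinct substrings.** `|{x : f(x) > 0}| = n(n+1)/2 − Σ LCP[i]`.
   Within the block of suffix-array ranks sharing a given prefix, every
   repeat occurrence of every substring is accounted for exactly once by
   the LCP value at its rank, so subtracting `Σ LCP` from the total
   substring count `Σᵢ i = n(n+1)/2` leaves one representative per
   distinct substring. (The total-substring sum is `Σ i`, i.e. there are
   `i` substrings ending at position `i`.)
2. **Distinct k-mers.** `|{x : f(x)>0, |x|=k}| = |{j : S[j] ≤ n−k+1 and
   LCP[j] < k}|` — a rank introduces a new k-mer exactly when its suffix is
   long enough to contain one and its k-prefix differs from the previous
   rank's.
3. **Repeat occupancy.** `Σ_{f(x)>1, |x|=k} f(x) = Σ_{[i,j] ∈ I_k} (j−i+2)`
   over the maximal intervals of ranks with `LCP ≥ k`. Each interval is
   one distinct repeated k-mer; ranks `i−1 … j` all carry it, giving
   `j−i+2` occurrences. Since `LCP[1] = 0 < k` for every `k ≥ 1`, an
   interval can never start at rank 1; the scan starts at rank 2 and this
   is asserted in code.

The identities make `I`, `D`, `D_k` and `R_k` computable in one pass after
index construction. `R_k` equals `Σ_{r>1} r·C(k,r) / (n−k+1)` in terms of
the k-mer spectrum `C(k,r)` (count of k-mers occurring exactly `r` times);
the hash-based spectrum is retained as an independent oracle
(`oracle_kmer_spectrum`) and is never used on the production path.

## Numerical choices

- `I` accumulates `log((LCP+2)/(LCP+1)) / ln 4` — one log per term rather
  than a difference of logs, and numpy's pairwise summation — so rounding
  stays far below 1e−9 even at n in the tens of millions (the homopolymer
  closed form `I(Aⁿ) = log₄(n+1)` is checked to 1e−9 for n ≤ 1000).
- Suffix arrays are built by prefix doubling over `np.lexsort`
  (O(n log² n), fully vectorised); LCP uses Kasai's linear algorithm
  compiled with numba. Construction is a pure function of the input and
  the algorithm is deliberately a contract, not a commitment: correctness
  is pinned by string-sort oracle tests, and practicality by the scale
  test (a 10 Mbp profile with k ∈ {12,25,50,100} completes in roughly a
  minute on one CPU; the test budget allows fifteen).
- Lexicographic order treats a shorter suffix that is a prefix of a longer
  one as smaller; no sentinel character appears in the data model.
- `D_k`/`R_k` for `k > |g|` raises a parameter error; `complexity_profile`
  drops out-of-range k values with a logged warning instead of emitting
  silent zeros that would corrupt downstream correlations.
- TSV output uses 6 significant digits by default (full double precision
  in memory).

## Preprocessing

N runs in public assemblies are gap fill, not sequence, and would register
as enormous artificial repeats, so N/n characters are removed before any
measure is computed; flanking sequence is concatenated (this can create
junction substrings that exist in no real molecule — a documented, minor
artifact). Case is normalised because soft-masking is an annotation. Other
IUPAC ambiguity codes are stripped and counted like N by default (they are
equally not literal sequence); a strict mode rejects them with the
offending position. The `Genome` record keeps the original length and the
number of stripped characters.

## Read simulation

The simulator follows the wgsim recipe: mutate the reference, then sample
reads from the mutated ("donor") sequence.

- **Mutation model.** Each position is independently mutated with
  probability `mutation_rate`; a mutation is an indel with probability
  `indel_fraction` (default 0.15) and otherwise a substitution to a
  uniformly chosen different base. Insertions and deletions are
  equiprobable; indel length is geometric with continuation probability
  0.3 capped at 10 — the share of indels is the externally meaningful
  parameter, the length law is this package's own (documented) choice.
  Positions swallowed by a deletion cannot host a second event.
- **Reads.** Read count is `floor(coverage · |g| / read_length)`
  (single-end; the evaluation is per-read positional, so paired ends add
  nothing here). Start positions are uniform on the mutated sequence,
  strands uniform, reverse-strand reads emitted as reverse complements,
  and per-base sequencing errors applied at `error_rate`. Quality strings
  are constant because no downstream stage consumes them.
- **Truth.** Every mutated-sequence base carries the reference coordinate
  it derives from (inserted bases inherit the coordinate of the base they
  follow), so a read's span maps back to *reference* coordinates, which is
  what evaluation against the reference requires. The name format
  `<genome_id>|<start>|<end>|<strand>|<serial>` (1-based, start ≤ end)
  round-trips exactly and stays parseable for ids containing underscores.
- Identical seeds give byte-identical FASTQ; default parameters mirror the
  protocol the package emulates (coverage 2, read lengths 50/75/100,
  error rates 0.5–2%, mutation rates 0.1–1%).

## Evaluation

A mapped record is correct when its reference name matches the truth and
its leftmost 1-based coordinate is within `gap` (default 20) of the
truth's left endpoint, or of the start derived from the truth's right
endpoint and the record's span (indels can shift one end). Strand is not
compared — position is the criterion. Precision is correct/aligned, recall
correct/total; an empty "aligned" set leaves precision undefined
(reported as missing, never 0). By default one record per read counts
(primary or first mapped; a duplicate primary logs a warning); with
`count_secondary` every mapped record counts, which is how a multi-mapping
aligner can exceed recall 1 while `total_reads` still counts distinct
reads.

## Synthetic panel and the toy aligner

The correlation stage needs genomes of graded repeat content. The panel
generator plants two repeat processes in i.i.d. random sequence:

- a **long unit** (default 500 bp, at or above read length) whose genome
  fraction sweeps linearly from 0 to 0.85 across the panel — these create
  genuinely ambiguous read placements;
- a **short unit** (default 20 bp) at a fraction drawn uniformly in
  [0, 0.5] per genome, independent of the sweep — these depress `D_12`
  and inflate `R_12` without making read-length windows ambiguous.

Real genomes carry repeats at many scales; modelling two of them is the
minimum that lets complexity at short k and at read-length k decouple, so
the panel can show that only the latter tracks alignability. What the
panel does *not* emulate: GC skew, tandem microsatellite structure,
divergent (approximate) repeat copies, and N runs. Passing tests therefore
demonstrate the internal consistency of the measures and the direction and
length-sensitivity of the complexity–accuracy relationship, not its
numerical strength on real genomes.

The built-in aligner places each read at a uniformly random exact
occurrence of the read (or its reverse complement) in the reference, and
leaves reads with no exact occurrence unmapped. It exists because real
aligners are out of scope: with error-free reads it isolates exactly the
placement-ambiguity effect the measures quantify (perfect on repeat-free
genomes — the lossless round-trip test — and increasingly wrong as repeat
content grows).

## Correlation stage

"Linear correlation" is Pearson's product-moment r (scipy). Constant
inputs make r undefined and are reported as missing with a warning — never
as 0. Cells with fewer than three shared genomes raise an error rather
than producing a meaningless coefficient. Genomes present in only one of
the two tables are dropped pairwise with a logged count. Aggregation is
per aligner; the CLI accepts arbitrary performance tables so pooling
across error/mutation grids is the caller's choice of rows.

## Problem sizes used in validation

The oracle-equivalence suites run 1000 random strings of lengths 1–200
(every valid k); simulator calibration uses a 100 kb genome (3-sigma
binomial bands); the panel experiment uses 16 genomes of 30 kb at read
length 50; the scale check profiles a 10 Mbp random genome. These sizes
exercise every code path at full fidelity while keeping the default test
run in the minutes range.

## Known limitations

- The suffix array is O(n log² n), not linear; for chromosome-scale inputs
  (100 Mbp+) an induced-sorting construction would be the next step.
- The mutation log is a flat TSV, not a valid VCF (no header, no anchored
  indel convention).
- The simulator models substitution sequencing errors only — no
  platform-specific quality or indel-error profiles.
- Multi-record FASTA files are profiled per record; there is no
  concatenated or generalized index across records.
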