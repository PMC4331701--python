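# Methods notes

## Trimming model

A read pair (R1, R2) of equal length *N* sequenced from an insert of
length *n* < *N* satisfies two structural identities (barcodes and indels
aside): R2[0..n) is the reverse complement of R1[0..n), and both
R1[n..N) and R2[n..N) are adapter-derived and therefore equally long.
The trimmer searches for *n* using only these identities, which live on
the accurate 5' ends of the reads — it never aligns an adapter sequence
against the error-prone 3' ends, and needs no adapter sequence at all.

**Stage 1.** The reverse complement of the first *L* bases of one mate is
compared at every start position of the other mate; positions with at
most ⌊*L*·*E₁*⌋ mismatches become candidate insert lengths (position *p*
maps to candidate *n* = *p* + *L*). The scan runs in both directions and
only candidates found by both survive (the intersection *I*). Each scan
touches at most (*N* − *L* + 1)·*L* ≤ *L*·*N* characters, so the
per-pair stage-1 work is bounded by 2·*L*·*N*; an instrumentation
counter in `trimmer_core` records the exact count and the test suite
asserts the bound. The production scan is vectorized (a sliding-window
view compared against the query), and counts a full (windows × *L*)
comparison grid even where an early-exit implementation would stop
sooner, so the counter is an upper bound on its own work too.

**Stage 2.** Candidates in *I* are validated in descending order: the DNA
portions must be mutual reverse complements within ⌊*n*·*E₂*⌋
mismatches, and the adapter portions equal within ⌊(*N* − *n*)·*E₃*⌋.
The first passing candidate wins. The candidate *n* = *N* (zero-length
adapter) is representable, validated like any other, and reported as
untrimmed because there is nothing to remove.

### Parameter semantics and defaults

| parameter | default | meaning |
|---|---|---|
| *L* | 30 bases | scan prefix length; also the smallest detectable insert |
| *E₁* | 0.4 | stage-1 max mismatch fraction (budget ⌊*L*·*E₁*⌋ = 12) |
| *E₂* | 0.6 | DNA reverse-complementarity max mismatch fraction |
| *E₃* | 0.4 | adapter-equality max mismatch fraction |

Each *E* is interpreted as a **maximum mismatch fraction** with an
integer budget of ⌊length·*E*⌋, and a value of exactly 1 disables the
corresponding check. The fraction-of-perfect-matches reading sometimes
attached to such thresholds is inconsistent with the turn-off-at-1
behavior and with the explicit budget formula, so the budget reading is
used throughout and stated here prominently.

Decisions the design left open, and what this implementation does:

- **Singleton intersections** are accepted *without* stage-2 validation,
  exactly as the two-stage procedure is stated. This can admit false
  positives (it is the source of the small FP count in the README
  example); `strict_singleton` (CLI `--strict-singleton`) forces
  validation of singletons and is off by default.
- **Coordinates** are 0-based half-open everywhere; "insert length *n*"
  means bases [0, n) are DNA and [n, N) adapter.
- **Degenerate inputs:** pairs with unequal mate lengths or mates
  shorter than *L* violate the equal-adapter-length premise and are
  passed through untrimmed with a warning and a `skipped` tally.
- **N bases** always count as mismatches (even N vs N); quality scores
  and indels are deliberately ignored by the matching.
- **Tie-breaking** is moot: *I* is a set, iterated in fixed descending
  order.
- Mismatch budgets use floor, never rounding.

`brute_force_trim` re-derives every decision by exhaustively testing the
stage-1 criterion at every site in both directions on plain byte strings
(quadratic time, no shared scanning code) followed by the identical
acceptance logic; the suite asserts exact agreement with the fast path
on tens of thousands of simulated pairs across all benchmark variants
plus adversarial random inputs.

## Simulator

The generator reproduces a benchmark design rather than any particular
sequencer: per dataset, *n* pairs of fixed-length 101-nt mates, exactly
`round(n · contaminated_fraction)` of them adapter-appended (an exact
count, not per-pair Bernoulli, so the half/half design and the ratio
diagnostic are sharply testable), shuffled over sequential pair ids.

- **Adapter length** A ~ Gaussian(μ = 20, σ = 5), rounded to the nearest
  integer and clamped to [1, min(read_length − 1, adapter length)]. The
  clamping and rounding rules are this package's own choice (at (20, 5)
  the tails involved are negligible, which the moment-recovery tests
  confirm: mean within ±0.2 of 20, SD within ±0.2 of 5).
- **Contaminated pairs:** an insert of length 101 − A is cut from the
  reference; R1 = insert + forward-adapter prefix, R2 =
  reverse-complement(insert) + reverse-adapter prefix. Two built-in
  adapter sets are provided: a typical Illumina forward/reverse pair
  (which share a common prefix, so the *E₃* check is meaningful) and an
  unrelated pair for distinct-adapter library variants.
- **Clean pairs:** two independent reference windows; in overlap mode,
  the two ends of a single fragment of length 2·101 − 50 = 152, giving a
  50-base mate overlap that deliberately tempts the trimmer with genuine
  internal reverse complementarity.
- **Reference:** a uniform random A/C/G/T sequence (default 500 kb), so
  nothing needs downloading; a user FASTA can be substituted, in which
  case windows containing N are rejected and redrawn. A uniform
  reference lacks the repeats and composition bias of a real genome —
  the specificity numbers here therefore do not bound false-positive
  rates near genomic repeats, though the overlap datasets probe the most
  dangerous structured case directly.
- **Qualities and errors:** each base gets a Phred score drawn from a
  per-position distribution and mutates to a uniformly chosen different
  base with probability min(1, 10^(−Q/10) · error_scale). Scales
  10⁻⁰·⁵ / 1 / 10⁺⁰·⁵ give the low/middle/high-error variants. No indels
  are simulated, matching the substitution-only assumption of the
  trimmer. The default quality model is parametric — mean Phred falling
  linearly from 38 (cycle 1) to 20 (cycle 101), discretized Gaussian
  with SD 3 per position, truncated to [2, 40] — a stand-in for real
  per-cycle profiles that keeps their dominant feature, the 3' error
  ramp. `learn_quality_model` builds an empirical per-position model
  from any constant-length FASTQ when fidelity to a specific instrument
  matters.

Every dataset is a deterministic function of its parameters and seed;
the truth table records contamination, true insert length, and mutation
counts split by DNA/adapter portion per mate.

## Evaluation

Detection and localization are scored separately: TP/FP/TN/FN (hence
sensitivity, specificity, accuracy, MCC) use pair-level contamination
status vs trimmed-at-all, while `exact_site_fraction` reports, among true
positives, the fraction cut at exactly the true insert. Contaminated
pairs with a true insert below *L* are structurally invisible to the
algorithm; when the evaluator is told *L* it excludes them from the
confusion counts and reports them as `n_undetectable` instead of letting
them silently depress sensitivity. MCC follows the standard formula,
with 0 returned only when a denominator factor is actually zero. 0/0
ratios are reported as 0 with a warning.

The label-free diagnostics need no truth table: the trimmed/untrimmed
ratio (expected 1 under the half-contaminated design), the trimmed-length
distribution (mode expected at 101 − 20 = 81 under the default adapter
model), and aTP — the count of trimmed pairs whose trimmed mates are
reverse complements within a mismatch fraction (default 0, i.e. strict;
the tolerance is configurable because real sequencing errors make the
strict count a conservative proxy).

## Problem sizes and reproducibility

The shipped checks run the oracle-equivalence comparison on 10,000
middle-error pairs plus 1,000 pairs of each of the eight benchmark
variants, error-free recovery and specificity on 10,000 pairs each, the
ratio diagnostic on 100,000 pairs, and the adapter-moment recovery on
10,000 contaminated pairs — sizes at which the binomial noise on every
asserted quantity is far inside its tolerance. All randomness flows
through a single integer seed per run; trimming itself is seed-free and
byte-identical across worker counts (chunks are dispatched to a process
pool and collected in submission order).

## Known limitations

- Inserts shorter than *L* cannot be detected; lowering *L* trades this
  floor against stage-1 specificity.
- Substitution-only: indel-bearing reads (e.g. 454-style) break the
  Hamming alignment between mates.
- 5' barcodes are not handled; they destroy the reverse-complement
  register between mates.
- Single-end reads are out of scope: the method is intrinsically paired.
- The default quality model is a coarse stand-in; learn an empirical
  model from a representative FASTQ for instrument-faithful simulation.
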