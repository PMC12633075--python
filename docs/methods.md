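# Methods note

This note records the model, the fixed parameters, the scope of the mock
generator, and the numerical choices made in `pseudomsa`. No empirical claim
here goes beyond what the test suite and `scripts/acceptance.py` compute.

## Model and procedure

A pseudoMSA for a query sequence *q* of length *L* is built in four stages.

**1. Fragment sampling.** For each coverage fraction *c* in the schedule
(default 0.4, 0.6, 0.8, 1.0) a fragment length is set by round-half-up,
*l* = max(1, ⌊*c·L* + 0.5⌋), and the start index is drawn uniformly on
[0, *L − l*]. Each (repeat, coverage, grid point) setting draws its own
fragment.

**2. Structural abstraction.** The fragment is translated AA→3Di with
stochastic beam search. Up to *N* distinct hypotheses (default 4) are kept
after exact-string deduplication, ranked by length-normalized score
Σ log *p* / *l*^α with α = 1.0 by default (α = 0 recovers raw cumulative
log-probability). Ranking uses a stable descending sort, so backend emission
order breaks ties.

**3. Back-translation.** Each hypothesis is translated 3Di→AA by multinomial
sampling, up to *M* sequences per hypothesis (default 3) after deduplication.
Sampling parameters come from a Cartesian grid — temperature {0.9, 1.0, 1.1},
top-k {∅, 40}, top-p {0.9, 0.95} — giving 12 grid points, 48 settings per
repeat under the default schedule, and a ceiling of 48 · *N·M* = 576 candidate
rows. The run is capped at the protocol row budget: **Default** 450 rows,
**Shallow** exactly half (225). Partial backend failures are recorded as
warnings and skipped, not fatal.

**4. Assembly.** Rows are padded with terminal gaps (`-`) back to width *L*
at the fragment's recorded offset — a positional operation, never a sequence
aligner. Filters then run in a fixed order with exact accounting:

- *length*: row width must equal *L* after padding;
- *complexity*: remove rows with a homopolymer run > 6, Shannon entropy
  < 2.0 bits over residues, or a non-overlapping digram frequency > 0.6
  (counted at stride 2 over both phases, so a pure dipeptide repeat scores
  1.0);
- *redundancy*: exact duplicates, then greedy removal of rows ≥ 0.95
  identical to an earlier kept row.

Optional mutagenesis supplements (never replaces) a fraction of rows with
point mutants; substitution *a→b* (*b ≠ a*) is drawn with probability
∝ exp(*S(a,b)*/2) from BLOSUM62 or PAM250, or uniformly over the 19
non-identity residues for the MEGABLAST scheme (interpreted as the flat
match/mismatch model, which induces no residue preference). The number of
mutated rows is ⌊fraction · count⌋. The query is always row one of the final
alignment.

## Divergence score (NAD)

Pairwise identity between aligned rows is matches / *L* over the full
alignment width; a gap never matches anything, including another gap. Row *i*
receives weight *w_i* = 1/(1 + *h_i*) where *h_i* counts rows *j ≠ i* with
identity ≥ 0.5, and

NAD = (Σᵢ *wᵢ*) / √L.

Closed forms used as oracles: *N* identical rows give 1/√L; *N* mutually
dissimilar rows give *N*/√L. A single-row alignment returns 1/√L with a
warning. Lower NAD indicates a more converged alignment.

## Coevolution map

Column-pair mutual information is computed over 21 symbols (20 residues +
gap) with a total pseudocount of 1 spread uniformly over the joint cells, then
corrected by the average-product term APC(i,j) = mean_i · mean_j / mean. The
map is symmetrized with a zero diagonal. The uncorrected MI matrix is also
exposed and checked against an independent loop implementation.

## Structure evaluation

Common Cα atoms are matched by (residue number, insertion code), ordered by
the reference. Superposition is Kabsch via SVD with the determinant sign
correction D = diag(1, 1, sign det), so reflections are never applied; a
centered point set of rank < 2 is flagged degenerate. RMSD is invariant to
rigid motions of either input to numerical precision, verified against both
an Euler-grid + Nelder–Mead rotation search and Biopython's
SVDSuperimposer. Ensemble ssRMSD is Σ RMSD² over models that superpose;
failed models are counted, not summed, and an all-fail ensemble yields NaN.

## Nanobody curation gates

A chain passes if it has 80–140 standard amino-acid residues **inclusive**
(hetero records and residues without a Cα excluded) and contiguous numbering:
residue numbers strictly consecutive integers. Any insertion code fails a
chain under a distinct reason, reflecting strict numbering-scheme reading.
Fail reasons are reported per gate; passing chains are re-emitted as
single-chain PDBs with `<entry>_<chain>` FASTA identifiers.

## The mock backend: what it emulates, and what it does not

The mock translator stands in for a bilingual protein language model so the
pipeline is exercisable and fully deterministic offline. It models the
*interface and the statistics the pipeline relies on*, not structural
biology:

- forward (AA→3Di): a seeded position-dependent substitution cipher with
  Bernoulli noise at rate `forward_noise · temperature` (temperature → 0
  yields the exact cipher), so hypotheses are diverse but reproducible;
- backward (3Di→AA): emits sequences whose identity to a cipher-consistent
  reference is drawn uniformly from a configurable band (default 0.3–0.5),
  realized as exactly ⌊(1 − *t*)·*n* + 0.5⌋ substitutions at seeded
  positions;
- reported token log-probabilities are the logs of the emission
  probabilities actually used, so score-based ranking is internally
  consistent.

It does **not** model fold plausibility, residue contact statistics, or any
learned sequence–structure relationship; absolute alignment-quality numbers
obtained with it characterize the pipeline, not any protein. The
`ProstT5Adapter` (optional `plm` extra) provides the same interface over a
real model and is not imported unless requested.

Because pairwise identity is defined over the full alignment width, a padded
fragment's identity to the query is bounded above by its coverage. The
backend's identity band is therefore measured on full-coverage rows
(coverage schedule fixed to 1.0); partial-coverage rows necessarily score
lower and that is by design, not a band violation.

## Determinism and seeding

All randomness flows from a single integer seed through named substreams:
`SeedSequence([seed mod 2³¹, crc32(name), …])`. Reruns with the same seed and
configuration produce byte-identical output files (verified by SHA-256 in the
run manifest). The acceptance script accepts `--seed` and derives every
stream from it.

## Fixed parameters

| Parameter | Default | Rationale |
|---|---|---|
| Coverage schedule | 0.4, 0.6, 0.8, 1.0 | span fragment to full-length context |
| Hypotheses *N* / translations *M* | 4 / 3 | diversity vs. budget; 12 rows per setting |
| Grid | T {0.9, 1.0, 1.1}; top-k {∅, 40}; top-p {0.9, 0.95} | mild perturbation around greedy-ish decoding |
| Row budget | 450 (Default), 225 (Shallow) | Shallow is exactly half |
| Length-normalization α | 1.0 | per-token average log-likelihood |
| Identity threshold (NAD) | 0.5 | homolog-counting cutoff |
| Redundancy threshold | 0.95 | near-duplicate removal |
| Complexity | run > 6; entropy < 2.0 bits; digram > 0.6 | low-complexity screen |
| Mutagenesis Boltzmann scale | exp(*S*/2) | half-bit softening of matrix scores |
| Subsampling sidecar | max_seq 16 : max_extra_seq 32 | fixed 1:2 ratio |
| Curation length gate | 80–140 inclusive | single-domain chain range |
| Toy trace spacing | 3.8 ± 0.1 Å | Cα–Cα virtual bond length |

Fixture problem sizes (60-residue queries, 50-residue traces, 5-model
ensembles, 200 × 40 planted alignments, 10 curation chains) are this
package's own choices, sized so the full suite runs in seconds on a CPU.

## Limitations

- Alignment-quality values computed with the mock backend have no biological
  meaning; they validate pipeline mechanics and score implementations only.
- Padding is positional; no realignment is attempted, so indel-containing
  back-translations are rejected by the length filter rather than aligned.
- The MI+APC map is a QC diagnostic on toy alignments, not a contact
  predictor; no tertiary-contact benchmark is included.
- Curation reads author residue numbering as-is; renumbered or scheme-mapped
  inputs are out of scope.
- The real-model adapter is interface-complete but unexercised here: it
  requires GPU-scale dependencies excluded from the default install, and no
  quantity in this repository depends on it.
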