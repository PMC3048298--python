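# Methods

## Scope and model

`codonopt` optimizes protein-coding nucleotide sequences under synonymous
substitution only: the translation of the output is always identical to
the input, codon for codon. The optimization criterion is a scalar
quality function combining codon adaptation with penalties for sequence
features known to impair transcript stability, processing or
translation. The search is a unidirectional sliding-window exhaustive
enumeration, chosen because nearly all scored features are local
properties spanning at most a few dozen bases, which makes a windowed
exhaustive search a good surrogate for the (intractable) global one and
lets the algorithm process the sequence 5'→3' the way the cell does.

## Codon adaptation

Relative adaptiveness w(c) = f(c) / max f over the synonymous family;
CAI = geometric mean of w over all codons, terminal stop excluded.
Numerical choices:

- **Zero-frequency floor** (`ZERO_W_FLOOR = 0.01`): codons absent from
  the reference table would otherwise send the geometric mean to zero; a
  fixed small floor keeps CAI finite and monotone in the number of bad
  codons.
- **Stop codons** are trimmed from coding sequences on input and never
  counted: ORF lengths and codon counts refer to amino-acid-coding
  positions only, matching how construct panels tabulate ORF sizes
  (e.g. 948 bp for a 316-residue protein).
- **Single-codon families** (Met, Trp) contribute factors of exactly 1.0
  and are included by default; `exclude_single_codon_families` supports
  the variant definition that drops them.
- Ties for the most frequent codon resolve to the lexicographically
  smallest codon, everywhere (back-translation, search), so all results
  are deterministic.

The bundled reference is a genome-wide human codon usage table
(per-thousand frequencies, standard genetic code). Which reference table
underlies any given published CAI column is generally not recoverable,
so the table is explicit configuration, and cross-study CAI comparisons
should be read with a ±0.02 tolerance.

## Quality function

For a candidate = fixed prefix + variation window, scored on the context
`ctx` = last `lookback_nt` (60) of the prefix + window:

| term | default weight | definition |
|---|---|---|
| codon_usage | 1.0 | mean w of the window codons, ×2 while the window starts inside the first 15 codons |
| gc_deviation | 0.02 | −|GC%(last 60 nt of ctx) − 60| |
| cpg_reward | 0.01 | +count of CG dinucleotides in ctx |
| upa_penalty | 0.02 | −count of TA dinucleotides in ctx |
| motif_penalty | 0.5 | −Σ per-entry penalties of soft motif hits in ctx |
| splice_penalty | 0.25 | −number of donor/acceptor hits in ctx |
| repeat_penalty | 0.25 | −number of maximal direct-repeat occurrences (≥ 8 nt) in ctx |
| hairpin_penalty | 0.25 | −number of inverted-repeat hairpins (stem ≥ 8, loop 3–30) in ctx |

The bounded look-back keeps per-candidate scoring O(window + 60) while
still catching features spanning the prefix/window junction; no scored
feature class is longer than the look-back. Terms with weight 0 are
skipped entirely, so reduced configurations (e.g. codon-usage-only) are
exact, not approximate.

The weights are declared stand-ins: the corresponding production systems
use proprietary term definitions and weightings that are not public. The
defaults were set so that optimizing AT-rich, poorly adapted ORFs lands
in the empirically published bands for optimized human constructs
(CAI ≥ 0.95, GC 55–70%), which the test suite checks on synthetic
panels; they are all exposed in `QualityConfig` / YAML config.

## Search

Window of `window_codons = 5` codons ("several amino acid positions");
per-residue candidate codons are the family members with
w ≥ `min_codon_w = 0.1` (always keeping at least the optimal codon), and
the per-window candidate count is capped at 10⁵ (a configuration error
suggests shrinking the window or raising `min_codon_w`). At each
position the best candidate's **first codon only** is committed and the
window shifts one codon 3'-ward; when the window would overrun the 3'
end it shrinks to fit, and at the final position the entire window is
committed. Equal scores resolve to the lexicographically smallest
window, making runs byte-identical.

**Hard constraints** (default: poly(A) signals AATAAA and ATTAAA on the
sense strand) reject candidates that introduce a *new* occurrence — one
not already wholly contained in the fixed prefix. Pre-existence
awareness prevents deadlock: once a motif has been accepted as
unavoidable, subsequent windows are not forever infeasible. If every
candidate in a window is infeasible, the search takes the best-scoring
candidate (fewest new occurrences first) and the result carries the
`unavoidable` flag with the offending hits; this arises when the
amino-acid sequence itself forces the motif (e.g. Trp-Trp under a
TGGTGG constraint).

`brute_force_optimize` enumerates *all* synonymous encodings of a ≤ 8
residue peptide and scores each complete sequence with the same quality
function; with the window covering the whole peptide the sliding-window
result provably coincides, and the test suite verifies sequence- and
score-identity on 100 random 5-mers under three configurations.

## Feature models

- **Motifs**: IUPAC patterns compiled to overlapping-match regexes;
  default soft set = ARE pentamer ATTTA (penalty 0.5) and A/T runs ≥ 7
  (0.25). UpA is a composition term, not a motif. IRES-like elements
  have no workable published model and are supported only as
  user-supplied motif entries — a documented limitation.
- **Splice donor**: 9-mer consensus MAG|GTRAGT scored with per-position
  weights (1,1,1,3,3,1,1,1,1) — the invariant GT dominates — and hit
  threshold 0.75 of the maximum, so the literal consensus always scores
  1.0 and sites lacking GT can never pass. **Acceptor**: AG preceded by
  a ≥ 10 nt tract with pyrimidine fraction ≥ 0.8. These are simple
  deterministic stand-ins for unpublished proprietary models, chosen for
  testability, not trained predictors.
- **Direct repeats**: maximal exact substrings ≥ 8 nt occurring ≥ 2
  times; "maximal" means not contained in any longer repeated
  substring. The implementation (level-wise k-mer extension) is verified
  against an O(L²) brute-force oracle.
- **Hairpins**: exact inverted repeats with stem ≥ 8 pairs and loop
  3–30 nt, found by seeding on the innermost `min_stem` pairs via a
  reverse-complement k-mer index and extending outward; score = 2 per GC
  pair + 1 per AT pair. This is a deliberate stability *proxy* — no
  minimum-free-energy folding — because published ΔG-based screens do
  not define a reproducible method; the proxy keeps the tool
  dependency-free and exactly testable (also oracle-verified).

Coordinates are 0-based half-open everywhere; BED-like exports follow
the same convention.

## Comparison metrics and ratio summaries

`codons_altered` counts differing codon positions; percentages round
half-up in exact integer arithmetic, which reproduces the printed
percentages of the bundled 50-gene reference panel for every row whose
printed ORF length is divisible by 3 (five rows are not, and one row's
printed percentage is internally inconsistent with its own n and length;
these are treated as typos in the source table and excluded from
consistency checks). Expression-ratio summaries classify a pair as
improved at ratio ≥ 1.10, worse at ≤ 0.90, equal between (the ≥ 10%
margin convention), and substitute ratio 2.0 for "only the optimized
construct expressed" when computing medians, per the published rule.
On the bundled panel this yields 43/50 improved (86%) and 48/50 at
least equal (96%), matching the published headline figures.

## siRNA rescue tools

Divergence is ungapped Hamming distance at aligned offsets —
siRNA/target duplexes tolerate no gaps over 19–23 nt — with the earliest
best offset reported. A pair is rescue-compatible for a guide when the
guide matches the wildtype perfectly and faces ≥ 4 mismatches (default,
configurable) at its best offset in the optimized sequence.
`enumerate_rescue_sites` applies the same rule to every wildtype k-mer
(k = 21 default) of an equal-length synonymous pair. Seed-region
weighting of mismatches is a noted extension point.

## Synthetic data

`generate_fixture_orf` emulates the *composition* of natural ORFs: a
random protein (Met start, uniform residues) encoded by sampling each
codon proportionally to its table frequency tilted by
exp(gc_bias · GC(codon)). `gc_bias = −0.8` produces AT-rich, poorly
adapted sequences resembling the wildtype genes that benefit most from
optimization (CAI ≈ 0.70, GC ≈ 38–45%); `mutate_synonymous` produces
synonymous variants with a controlled substitution density. What the
generator does **not** emulate: real amino-acid composition, codon
autocorrelation, genuine splice/poly(A) site statistics, or any
expression phenotype — so passing tests demonstrate algorithmic
correctness and that composition metrics land in published bands, not
that expression of any real gene would improve. Wet-lab expression
ratios are inputs (the bundled panel), never predictions.

Test and verification problem sizes — 60–80 codon ORFs for
default-config runs, 5-mer peptides for oracle equivalence, 100-peptide
samples — were chosen as the smallest sizes that exercise every code
path (multiple windows, ramp boundary, terminal window shrink) while
keeping the full suite fast.

## Known limitations

- No thermodynamic RNA folding, no trained splice models, no tAI or
  codon-pair statistics (out of scope by design).
- The greedy window commit is not globally optimal for window-spanning
  trade-offs longer than the window; the oracle-equivalence guarantees
  hold when the window covers the region of interest.
- Reproducing published CAI columns exactly requires the same reference
  usage table, which published tables rarely specify.
- The supplementary construct FASTA needed for full per-sequence
  reproduction of the bundled panel's printed metrics is not
  redistributable; the corresponding acceptance check requires the user
  to supply `data/construct_panel.fasta`.
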