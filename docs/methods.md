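# Methods notes

## Profile model

The package treats a query protein's homologs as noisy observations of
its per-residue conformation. A local alignment places hit residues on
query positions; replacing each aligned hit residue by that hit's SSE
code (gaps preserved) turns the alignment stack into a per-position
sample of conformations. Weighted counts (weight = alignment identity
of the hit, W(h) ∈ [0, 1]), normalized per position, give the PPM; the
PSSM is the elementwise log2 odds of the PPM against background code
frequencies computed from the reference structure library. Running the
same machinery with untransformed hit strings over the 20-letter
amino-acid alphabet produces the classic AA-PSSM, so the two feature
sets differ *only* in the alphabet of the profile — which is what makes
their comparison meaningful.

The hit weight is realized as the alignment identity fraction (matched
columns over non-gap aligned columns). "Similarity" under a scoring
matrix would be a defensible alternative; identity was chosen because
it is the scale dataset non-redundancy thresholds are phrased in, and
the weight function is pluggable at the `TransformedAlignment` level
for anyone wanting otherwise.

## Pseudocounts

Columns are smoothed with a Henikoff-style mixture
f' = (N·f + τ·g) / (N + τ), where N is the column's total weighted
count, f the observed frequencies, and g the substitution prior
g(c) = Σ_c' f(c') T(c|c') with T the conditional substitution
probabilities inverted from a BLOSUM-style SSE substitution matrix.
Unlike the amino-acid case, the query's own state at a position is
unknown, so a zero-mass column cannot seed a substitution-row prior:
N = 0 falls back to the background distribution outright, and those
positions are recorded in `pseudocount_positions`. τ defaults to 0.5;
τ = 0 reproduces plain normalization, with zero-probability cells
floored at −10 bits in the PSSM so matrices stay finite and
serializable.

## Substitution-matrix estimation

`build_substitution_matrix` is the standard BLOSUM procedure on aligned
SSE string pairs: gap-containing columns skipped, unordered pair
frequencies q(a,b) pooled over both orders, marginals
p(a) = q(a,a) + Σ_{b≠a} q(a,b)/2, expectation p(a)² on the diagonal and
2·p(a)·p(b) off it, score = log2(q/e), never-observed pairs floored.
No within-corpus sequence clustering or weighting is applied — the
intended input is an already non-redundant set of structure-alignment
pairs.

## SSE assignment by vote

Hits lacking a structure annotation get a synthetic SSE string: a
second-round search of the hit against an annotated reference set, then
per hit residue a weighted vote over the aligned reference codes, with
weights the second-round alignment identities (the same W as the
profile stage, keeping the rounds consistent; an unweighted flag
exists). Ties break by a configured code order, by default descending
background frequency in the reference library then alphabetical —
prefer the a-priori likelier conformation. Residues covered by no
reference homolog receive coil ('C'), the least structurally committed
call.

## Search

The local aligner is Biopython's `PairwiseAligner` (affine gaps, local
mode); a gap of length k costs `gap_open + k·gap_extend`. Defaults
(match +2, mismatch −1, gap open −11, extend −1, min aligned length 10,
max 500 hits) mimic BLAST-like behaviour at toy scale. One best local
alignment per target; no multi-HSP handling, no iterated search, no
E-values. Precomputed alignments in the TSV dialect bypass the aligner
entirely, which is the injection point for real search-tool output.
The test suite checks the aligner's optima against an independent
Gotoh dynamic-programming oracle on small instances.

## Features and classifier

Windowing concatenates each position's profile row with its k
neighbours on both sides (window 5 by default — SOV-optimal in our
sweep range; sizes 1–21 supported), padding with 0 (background
log-odds) outside the chain. The amino-acid-type feature maps the 20
residues onto 1..20 by five side-chain classes ordered by mean
Kyte–Doolittle hydropathy, residues within a class ordered by database
abundance ('X' → 0); the class/hydropathy/abundance tables ship as
data and the encoding is rebuilt from them at import, so the
construction, not a frozen table, is the contract.

The classifier is a seeded bootstrap ensemble: each member trains on a
resampled row set (fraction 0.8 by default; fraction exactly 1.0 means
"all rows once", the degenerate limit in which a single-member
ensemble equals a plain classifier) and a random feature subset
(fraction 0.7). Members are decision trees by default; `mlp` and
`mixed` (alternating trees and one-hidden-layer MLPs, 16 units) are
available, with 20 members as a desk-scale default and larger mixed
layouts reachable via `EnsembleParams`. Class probabilities are exact
vote fractions. Three- and eight-state work uses separately trained
models; reducing eight-state output to three states is supported as an
operation but is a measurably weaker substitute for a native
three-state model, hence not the default path.

## Evaluation suite

* Q accuracy, with macro (mean over queries) and micro (pooled residue
  ratio) averages; micro is what the benchmark helpers report.
* SOV, 1999 revision: per reference segment s1 and each overlapping
  predicted segment s2 of the same state,
  (minov + δ)/maxov · len(s1), δ = min(maxov−minov, minov,
  ⌊len(s1)/2⌋, ⌊len(s2)/2⌋); normalization counts len(s1) once per
  overlapping pair plus once per non-overlapping reference segment.
  This variant reproduces the three frameshift worked examples
  (0.441 / 0.526 / 0.462) exactly, which the acceptance tests pin.
  Pooling over queries aggregates numerators and normalizations
  (residue-weighted), not per-query means.
* Boundary/internal accuracy: a residue is "boundary" iff it is the
  first or last residue of a maximal same-code segment of the
  *reference* string. This is the simplest deterministic reading of a
  boundary-restricted accuracy; other window-based definitions exist and
  cannot be disambiguated from summary tables, so the rule is
  documented here as a package choice. Empty partitions report NaN,
  never a fabricated value.
* Pairwise misclassification rates after 8→3 reduction
  (helices H,G,I; strands E,B; coils C,S,T): rate(X↔Y) counts both
  confusion directions over all residues, so the three rates plus Q3
  sum to exactly 1 — asserted as an invariant.

## Synthetic data

The generator emulates the single premise the method rests on:
homologs conserve structure better than sequence. Queries are sampled
from a segment grammar (helix 4–12, strand 3–8, coil 2–6 residues;
helices/strands always separated by coil with 80% probability) with
per-class residue emissions carrying a deliberately *weak* sequence
signal (A/L/M/E/Q/K enriched 4× in helices, V/I/Y/F/W/T in strands,
G/P/S/N/D in coils). Homologs are substitution-only copies at a
requested identity (default band 0.30–0.50 — remote but alignable at
toy scale), with SSE preserved except segment-end jitter (boundaries
shifted ≤2 residues with probability 0.3). Benchmarks enforce a
cross-set query identity ceiling using best-gapless-overlap identity
relative to the shorter sequence (local per-column identity is
meaningless for unrelated short proteins, which trivially share tiny
perfect-match regions).

What the generator does **not** emulate: indels between homologs, real
PDB segment-length and class statistics, chain breaks, domain
architecture, or genuinely remote homology detectable only through
profiles. Passing tests therefore demonstrate the machinery's
correctness and the method's directional premise (structure-space
profiles beat sequence-space profiles when structure is conserved),
not real-benchmark accuracy magnitudes.

## Problem sizes and determinism

The shipped benchmark preset uses 18 queries (12 train / 6 test) of
80–140 residues with 8 homologs each — small enough that the full
end-to-end comparison runs in seconds, large enough that the
SSE-vs-AA feature comparison is far from ties. Every stochastic step
(generation, bootstrap, member seeds) derives from a single integer
seed; member b of an ensemble uses a congruential mix of (seed, b)
kept below 2^31. Identical seeds give byte-identical generated FASTA
and identical predictions.

## Known limitations

* The aligner is quadratic-time per pair; it is meant for reference
  sets of hundreds, not UniRef-scale millions.
* `identity` as the hit weight saturates for near-duplicate hit sets;
  no within-hit-list redundancy weighting is applied.
* The MLP member is a fixed small architecture (one hidden layer); it
  exists to exercise the mixed-ensemble path, not to compete with
  modern deep sequence models.
* The PSSM TSV serializes scores only; occurrence and PPM matrices are
  recomputable but not round-tripped.
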