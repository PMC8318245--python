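# sse-pssm

Secondary-structure-element position-specific scoring matrices for
protein secondary structure prediction.

## The problem

Classic secondary structure predictors encode a query protein by the
amino-acid PSSM: PSI-BLAST-style alignments of the query's homologs,
summarized per residue as log-odds scores of the 20 amino acids
against background. But homologous proteins conserve their *secondary
structure* far longer than their sequence. This package builds the
profile in structure space instead: each aligned homolog's residues
are rewritten in secondary-structure codes (the DSSP eight-state
alphabet {G, H, I, E, B, T, S, C}, or the reduced three-state
{H, E, C}) before the matrix is computed, so the profile captures the
per-position conservation pattern of conformations rather than of
residues. The resulting SSE-PSSM is a drop-in feature set for
per-residue classifiers, alone or merged with the classic AA-PSSM and
an amino-acid-type encoding.

It is aimed at structural bioinformaticians building or benchmarking
secondary structure predictors, and at anyone needing the standard
evaluation suite (Q3/Q8, SOV3/SOV8, boundary/internal accuracy,
misclassification rates) as a library.

## The method

For a query with hits h = 1..n_h (pairwise local alignments against a
target set), each hit's amino-acid string is replaced residue-by-residue
with its SSE string, preserving gaps: hit `ILGWL` with SSE `CHHEE`
aligned as `IL-GW--L` becomes `CH-HE--E`. Per query position p and
code c, weighted occurrences are

    Occ(c, p) = Σ_h  I(Code_{h,p} = c) · W(h),

with W(h) the hit's alignment identity. Normalizing each position
gives the position propensity matrix (PPM), and log-odds against the
background frequencies B_s of the reference structure library give

    PSSM(s, p) = log2( PPM(s, p) / B_s ).

Positions with no aligned hit residue fall back to the background
distribution; sparse columns can be smoothed with a
substitution-matrix-driven pseudocount mixture (parameter `tau`). The
required SSE substitution matrix is estimated from any corpus of
aligned SSE string pairs by the BLOSUM procedure (observed vs expected
pair frequencies, log2 odds). Hits without a structure annotation get
a synthetic SSE string by position-specific weighted voting over a
second-round search against an annotated reference set.

Feature vectors are windowed profiles (default 5-residue centered
window) optionally merged with a one-integer amino-acid-type encoding,
classified per residue by a seeded bootstrap ensemble (decision trees
and/or small MLPs) whose vote fractions are the class probabilities.

## Worked example

```python
>>> import sse_pssm as sp
>>> actual    = "CHHHHCHHHHCHHHHCHHHHCHHHH"   # all-alpha reference
>>> predicted = "HHCHHHHCHHHHCHHHHCHHHHCHH"   # two-residue frameshift
>>> round(sp.q_accuracy(actual, predicted), 3)
0.6
>>> round(sp.sov(actual, predicted), 3)
0.441
>>> sp.average_q([(50, 0.90), (350, 0.50)])   # (macro, micro)
(0.7, 0.55)
```

The frameshifted prediction has the same segment pattern as the
reference, so the per-residue Q3 (0.600) punishes it much harder than
the segment-overlap SOV3 (0.441); for a 50-residue protein at Q3 0.90
pooled with a 350-residue protein at Q3 0.50, the macro average (mean
over proteins) is 0.70 while the micro average (220 of 400 residues
correct) is 0.55 — the two averaging conventions the evaluation module
implements.

An end-to-end experiment on synthetic families (structure conserved,
sequence diverged):

```python
>>> from sse_pssm.fixtures import benchmark_preset
>>> bench = sp.generate_benchmark(benchmark_preset(seed=1), identity_ceiling=0.25)
>>> sp.run_benchmark(bench, "sse", seed=1).micro_q   # SSE-PSSM features
0.961...
>>> sp.run_benchmark(bench, "aa", seed=1).micro_q    # classic AA-PSSM features
0.698...
```

The same pipeline is scriptable from the shell (`sse-pssm fixtures`,
`search`, `assign-sse`, `build-pssm`, `featurize`, `train`, `predict`,
`evaluate`, `build-submatrix`); see `sse-pssm --help`.

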