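# Methods

## Model and assumptions

regulonkit reconstructs conserved regulons under three assumptions:

1. **Orthology by graph clustering.** Genes descended from a common ancestor
   form dense blocks in the protein-similarity graph once bit scores are
   normalized and rescaled, so Markov clustering of that graph approximates
   an ortholog partition. No tree reconciliation is attempted.
2. **Rare, fixed-width binding sites.** The regulator's site is ungapped and
   of fixed width, and true sites are a small minority of promoters, so the
   per-species distribution of best-window log-odds scores is dominated by
   background and a z-score against it separates sites from noise.
3. **Profile co-evolution.** A conserved target gene's motif-occurrence
   profile across species tracks the presence profile of its controlling
   regulator more closely than that of any other regulator.

## Pipeline stages and key parameters

| parameter | default | meaning |
|---|---|---|
| E-value cutoff | 1e-5 | BLAST hits above this are discarded |
| rescaling percentile | 98 | per-species-pair divisor for normalized scores |
| MCL inflation | 3.0 | production clustering granularity |
| promoter window | 300 bp | upstream sequence scored per gene |
| pseudocount | 0.5 | background-weighted smoothing of the count matrix |
| z threshold | 3.0 | per-species significance of a promoter score |
| operon max gap | 50 bp | fallback co-transcription distance rule |
| assignment cutoff | 0.2 | minimum Jaccard to assign a target group |

All are configurable everywhere (library keyword arguments, CLI flags,
config file); the defaults are the method's standard operating point.

**Similarity normalization.** `norm(x,y) = bit(x,y)/max(bit(x,x), bit(y,y))`
with symmetrization by the maximum of the two directed bit scores — the more
inclusive choice, and the one that keeps `norm(x,x) = 1`. Every node must
have a self hit; a missing one is a hard error rather than a silent skip,
since a wrong denominator would distort the whole row. Per-species-pair
rescaling uses linear interpolation between order statistics (the numpy
default percentile); within-species edges form their own pair. A pair with a
single edge uses that edge's own score as divisor (rescaled to 1.0, warned).
Rescaled scores above 1 are capped at 1.0 at graph construction — the top
~2% of every pair are saturated by design of the rescaling — and the cap is
switchable.

**MCL internals.** Expansion power 2, entrywise inflation followed by column
renormalization, pruning of entries below 1e-5 (each column's maximum is
always retained), convergence when the iterate changes by < 1e-6, at most
200 iterations (non-convergence interprets the current iterate with a
warning). Self-loops are set to each node's maximum incident weight, which
makes the chain aperiodic. Clusters are the connected components of the
converged attractor structure, read from the nonzero pattern of the final
matrix (thresholded at the prune level); this always yields a partition, so
the rare overlapping-attractor case cannot produce ambiguous output. The
inflation-sweep hierarchy re-runs MCL on each cluster's induced subgraph at
the next (strictly larger) inflation, which enforces the refinement
invariant by construction.

**Motif model.** An ungapped log-odds matrix in bits,
`log2(((count + pc·bg) / (n + pc)) / bg)`. A fixed-width gapless site is
exactly the regime where a profile HMM without indel states reduces to a
position weight matrix, so the PWM is used directly. `N` in a scanned
sequence contributes 0 (the background expectation); `N` in an input site
contributes fractional background-weighted counts so columns still sum to
the number of sites. Scores of promoters shorter than the motif are the
`-inf` sentinel; such genes ride through the pipeline with z = `-inf` and
are excluded from each species' mean/sd.

**Scanning.** The promoter score is the maximum over all offsets and both
strands (single-best-site semantics, not a sum). Ties break to the smallest
offset, forward strand first, so outputs are deterministic. Both strands are
always scanned; for the palindromic default model this is provably
irrelevant, and the implementation's strand invariance on palindromic input
is exercised by tests.

**Standardization.** Population standard deviation (denominator n), switchable
via `ddof`. A species with zero score spread gets z = 0 everywhere and no
significant calls, with a warning, rather than a division error.

**Operon propagation.** Transcription units are maximal chains of
rank-adjacent, same-strand pairs with co-transcription probability > 0;
"upstream" is strand-aware. Propagation is a single forward pass
`prop(g_i) = max(z(g_i), prop(g_{i-1})·p)` — idempotent, monotone, and never
flowing upstream. Opposite-strand or non-adjacent pairs in an input table
are ignored with a warning since they cannot share a promoter.

**Empirical FDR.** No estimator is prescribed by the approach itself, so the
package uses a shuffle null: each promoter is mononucleotide-shuffled
(composition-preserving; a dinucleotide option using a random-Eulerian-walk
shuffle exists) and rescanned, with shuffled scores standardized against the
observed distribution so hit counts are comparable. FDR = mean shuffled hit
count / observed hit count; zero observed hits yield an undefined sentinel
rather than a division error. On promoters that are themselves i.i.d.
background the estimate is ~1 by exchangeability, which the tests use as a
calibration check.

**Assignment.** `J(∅,∅)` is defined as 0: an empty occurrence profile
carries no assignable signal. The 20% cutoff is applied to the maximum
Jaccard over regulators, which subsumes the per-regulator reading for
assignment purposes. Exact ties go to the first regulator in the declared
order with an audit flag. The regulon matrix grades cells as
no-ortholog / ortholog-without-motif / moderate / strong; the moderate and
strong bounds default to z = 2.0 and 3.0 on the same scale as the
significance rule and are configurable, since they are display thresholds,
not inference thresholds.

**Promoter extraction.** Coordinates are 1-based inclusive. "Upstream"
means upstream of the annotated gene start; TSS annotations are not
assumed. Windows are not trimmed at upstream gene boundaries — the method
specifies a fixed 300-bp window — and windows running off a replicon end are
truncated and flagged. Ambiguity characters other than N are mapped to N
with a warning.

## What the synthetic generator emulates — and what it does not

The generator plants the exact structure the method assumes: block- or
tree-structured regulator presence profiles with modest pairwise overlap
(pairwise Jaccard ≲ 0.25 for the default 3 regulators over 40 species),
target groups whose promoters carry a site sampled from the motif's count
distribution exactly where the generating regulator is present (flipped at
rate ε = 0.1 at the group × species level, since profiles are species-level
Booleans), operons that share the lead promoter's evidence, per-species GC
content drawn from [0.42, 0.58] (the reason per-species standardization
exists), and bit scores with intra-family range [300, 400], cross-family
noise [40, 60] and self scores [400, 500]. Defaults: 40 species, 3
regulators, 30 target groups, 400 background genes per species — background
genes keep motif hits a rare minority (~5%), standing in for the thousands
of non-target genes of a real genome.

It does **not** emulate realistic sequence evolution: proteins are consensus
strings with i.i.d. mutations, promoters are i.i.d. background, there are no
paralogs, no gene gain/loss within target families by default, and no
correlated base composition. Spurious cross-family similarity edges are
drawn between species only, since with no paralogs a lone within-species
noise edge would meet the degenerate single-edge rescaling divisor and be
boosted to full weight — a pathology of the synthetic design, not of real
data, where within-species score distributions contain genuine paralogous
families. Consequently, green tests demonstrate that the inference machinery
is correct under the model's own assumptions, not that the method is robust
to the heterogeneity of real genomes.

## Problem sizes used by tests and the acceptance script

Small fixed sizes keep everything deterministic and quick: 20 seeded
end-to-end runs at the default conditions for recovery statistics; 100
planted-clique instances (2–6 cliques of 4–10 nodes, inter/intra weight
ratio ≤ 0.1) for clustering accuracy; 200 random (promoter, model) pairs
against a brute-force enumeration oracle for the scanner; 500 planted sites
at a 1% hit fraction for recall; 1000 exchangeable null promoters × 5
shuffles for FDR calibration. The acceptance script defaults to 10
end-to-end simulation runs per invocation.

## Known limitations

- Ortholog groups come from single-linkage-like graph clustering; fused or
  split families propagate directly into the profiles.
- The z ≥ 3.0 rule assumes enough genes per species (hundreds) for stable
  moments; tiny genomes make the standardization noisy, and a high fraction
  of true sites inflates the spread and suppresses z.
- Assignment considers only the declared regulators; a target controlled by
  an undeclared regulator will be forced onto the nearest declared profile
  or left unassigned.
- Motif-occurrence profiles conflate "ortholog absent" with "ortholog
  present but no site"; the distinction is kept only in the regulon matrix.
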