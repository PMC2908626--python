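# regulonkit

Comparative-genomics reconstruction of the conserved ("core") regulons of
bacterial transcription factors that recognize near-identical DNA target
sequences.

## The problem

Members of the CRP/FNR super-family such as FNR, FixK and DNR control
different aspects of anaerobic metabolism, yet bind essentially the same
palindromic DNA site (consensus `TTGAT-N4-ATCAA`). Within a single genome,
finding the motif upstream of a gene therefore cannot tell you *which*
regulator controls it. Across many genomes the ambiguity resolves: a
conserved target gene should co-occur, species by species, with the
regulator that controls it. regulonkit implements this phylogenetic-footprint
strategy for any set of genomes, regulators and binding-site models, and
ships a synthetic-data generator so the whole pipeline is testable without
downloads.

## The method

1. **Ortholog groups.** All-vs-all BLASTP bit scores (E ≤ 1e-5) are
   normalized by `norm(x,y) = bit(x,y) / max(bit(x,x), bit(y,y))`, then each
   unordered species pair's scores are divided by that pair's 98th
   percentile to correct for phylogenetic distance. The resulting graph is
   clustered with a from-scratch Markov Cluster (MCL) implementation
   (inflation 3.0 in production; an inflation sweep yields the sub-family
   hierarchy). A mixed FNR/FixK cluster can be split on the 4 conserved
   iron-sulfur-cluster cysteines.
2. **Promoter scanning.** An ungapped log-odds matrix (bits) built from
   aligned sites scores the 300-bp window upstream of every gene on both
   strands; each promoter keeps its best window. Because background base
   composition varies across organisms, raw scores are standardized per
   species; z ≥ 3.0 is significant. An empirical FDR is available by
   rescanning composition-preserving shuffled promoters.
3. **Operon propagation.** Promoter evidence at the first gene of a
   transcription unit flows downstream:
   `prop(g_i) = max(z(g_i), prop(g_{i-1}) · p(g_{i-1}, g_i))` with
   co-transcription probabilities from a VIMSS-style table or a
   distance-based fallback.
4. **Assignment.** Motif occurrence within each ortholog group and the
   presence of each regulator sub-family form Boolean vectors over the
   species list; each target group goes to the regulator with the highest
   Jaccard coefficient `J(A,B) = |A∩B| / |A∪B|`, provided `J ≥ 0.2`.

## Worked example

```python
from regulonkit import SimConfig, simulate, run_pipeline, score_recovery

sim = simulate(SimConfig(seed=42))          # 40 species, 3 regulators, noise 0.1
seeds = {reg: genes[:1] for reg, genes in sim.truth.regulator_genes.items()}
result = run_pipeline(sim.genome_set, sim.similarity, sim.aligned_sites, seeds,
                      operon_map=sim.operon_map)
metrics = score_recovery(sim.truth, result.clusters, result.scores,
                         result.assignments)
print(f"ortholog groups: {len(result.clusters)}")
print(f"significant promoters (z >= 3): {int(result.scores['significant'].sum())}")
print(f"motif model information: {result.model.information_bits():.1f} bits")
print(f"groups assigned to their generating regulator: {metrics.assignment_fraction:.0%}")
print(metrics.confusion)
```

prints

```
ortholog groups: 16654
significant promoters (z >= 3): 644
motif model information: 18.6 bits
groups assigned to their generating regulator: 100%
assigned  REG1  REG2  REG3
true
REG1        10     0     0
REG2         0    10     0
REG3         0     0    10
```

The 16,654 groups are mostly singleton background genes; the 33 planted
families (3 regulator sub-families + 30 target groups) are recovered
exactly, 644 promoters carry a significant site after operon propagation,
and every target group lands on the regulator that generated it despite the
10% flip noise on its occurrence profile.

The same pipeline runs from the shell on files:

```sh
regulonkit simulate --seed 42 --out sim/
regulonkit run-all --dir sim/ --out run/        # writes groups.tsv, scores.tsv,
                                                # profiles.tsv, assignments.tsv
```

Stage subcommands (`cluster`, `scan`, `propagate`, `profile`, `assign`)
expose the intermediate artifacts; every stage writes a manifest with input
hashes and the resolved configuration.

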