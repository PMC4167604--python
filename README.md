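# edisom

Time-course transcriptome clustering with supra-hexagonal self-organizing
maps (SOMs).

`edisom` is for analysts working with a small-*n* expression time course —
one untreated control plus a handful of treatment stages, such as a CD4⁺
T-cell transcriptome sampled across successive stages of escalating-dose
peptide immunotherapy — who want to ask *which temporal expression patterns
exist, which genes follow each one, and what those gene groups do*, without
pre-assuming any cluster structure.

## Method

Given a genes × (control + *S* stages) table of linear-scale intensities,
the pipeline:

1. **Floors detectability.** Intensities below an empirical floor
   (default 200) are not reliably discriminated and are clamped to the
   floor, so ratios between two undetectable values become log2FC = 0.
2. **Computes fold changes.** For gene *g* and stage *s*,
   `fc(g,s) = log2( I(g,s) / I(g, control) )`.
3. **Applies the regulation filter.** Keep *g* iff `|fc(g,s)| ≥ log2(F)` at
   `≥ m` stages (defaults *F* = 2, *m* = 4) — a ≥2-fold change in either
   direction at ≥4 treatment points.
4. **Trains a SOM.** A hexagon-shaped lattice of hexagonal units (*r* rings,
   `3r(r−1)+1` units, sized to ≈ `5√N`) is trained on the kept log2FC
   profiles with the Gaussian-kernel update
   `m_i ← m_i + α·exp(−d(c,i)²/2σ²)·(x − m_i)` (batch variant by default),
   σ shrinking from the grid radius to 0.5 over a rough and a fine-tune
   phase.
5. **Partitions the map topologically.** Per-unit U-heights (mean codebook
   distance to lattice neighbors) are scanned for local minima — the *seed
   units*; clusters grow outward from seeds over the lattice, each step
   attaching the frontier unit closest in codebook space to its adjacent
   cluster's seed. Genes inherit their best-matching unit's cluster; each
   cluster's representative expression pattern is its seed unit's codebook.
6. **Renders component planes.** Plane *s* recolors the map by codebook
   column *s* (shared symmetric limits, red = induced, blue = repressed),
   exported as TSV and optionally PNG.
7. **Scores term enrichment.** Per cluster × GMT term, the hypergeometric
   upper tail `P(X ≥ k)` on the (cluster ∩ background, term ∩ background)
   overlap, Benjamini–Hochberg adjusted per cluster; reported when the
   overlap is ≥3 transcripts at FDR < 0.05.

A synthetic-data generator plants five canonical temporal archetypes
(repressed from baseline; repressed after initial induction; incrementally
induced; induced then repressed; induced and maintained) with lognormal
baselines, sub-floor values and Gaussian log-scale noise, plus flat nulls —
so every stage of the pipeline can be validated against ground truth
(adjusted Rand index after merging clusters by majority archetype).

## Worked example

```bash
python examples/02_som_clustering.py
```

prints

```
grid: 6 rings, 91 units for 464 profiles
quantization error after training: 0.300
8 clusters from seed units [11, 14, 40, 47, 52, 59, 81, 89]
cluster sizes: {1: 86, 2: 94, 3: 17, 4: 46, 5: 75, 6: 57, 7: 57, 8: 32}
adjusted Rand index vs planted archetypes (majority-merged): 0.948
```

Of 1,000 synthetic genes (500 regulated across five archetypes, 500 flat),
464 pass the 2-fold/4-stage filter; the 91-unit map splits into 8
topological clusters whose majority-archetype merge recovers the planted
groups at ARI 0.95. `examples/04_cluster_enrichment.py` then shows each
cluster reporting exactly its own archetype's gene-set term (e.g. cluster 2
hits `SYN:repressed_from_baseline` with 94/94 member genes,
q ≈ 3 × 10⁻⁸²). The other example scripts walk through filtering,
component planes and the gene-panel report (unclustered genes marked `-`).

The same analysis runs from a shell via the thin CLI:

```bash
edisom simulate --out-dir sim --seed 5
edisom run --config config.yaml        # paths, control label, thresholds, seed
edisom enrich --cluster-table out/cluster_table.tsv --gmt sets.gmt --out enr.tsv
```

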