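# Methods

This note documents the models, numerical choices and validation design
behind `edisom`, in the spirit of a methods appendix: what is computed,
under which assumptions, with which defaults, and what the synthetic tests
do and do not demonstrate.

## Input model and preprocessing

The pipeline consumes an already-normalized genes × (control + *S* stages)
table of **linear-scale** intensities. Log2-stored tables must be declared
(`log2_input`), in which case they are exponentiated on read; this keeps
the detectability floor — which is declared in linear intensity units —
meaningful for all inputs. Missing values are rejected rather than imputed:
the intended inputs are complete summarized expression matrices.

**Detectability floor.** Intensities strictly below the floor (default
200) are clamped *up* to the floor, on control and treatment columns
alike. Consequences worth knowing:

* a gene undetectable in both conditions gets log2FC exactly 0, not an
  unstable ratio of noise;
* flooring can only shrink fold-change magnitudes for genes whose control
  sits at or below the floor — it never manufactures regulation;
* a 2-fold *repression* is expressible only when the control intensity is
  ≥ 2× the floor: below that, the floored stage value cannot fall far
  enough. This censoring is intrinsic to the floor, not an artifact of the
  implementation, and it shapes the synthetic-data defaults below.

The boundary case "exactly at the floor" is kept (only strictly smaller
values are clamped); since clamping maps everything below the floor onto
the floor itself, the distinction has no effect on any ratio.

**Regulation filter.** `|log2FC| ≥ log2(min_fold)` at `≥ min_stages`
stages, inclusive on the boundary (exactly two-fold qualifies) and
two-sided (induction and repression both count, as both directions carry
biology in a tolerization time course). Defaults `min_fold = 2`,
`min_stages = 4` of 6. The filter is a pure per-row scan: monotone under
threshold tightening and invariant to row order.

## The supra-hexagonal SOM

**Lattice.** Units occupy a hexagon-shaped patch of the hexagonal lattice:
*r* rings hold `3r(r−1)+1` units, on axial coordinates
`max(|q|,|row|,|q+row|) ≤ r−1`, converted to Cartesian via
`x = q + row/2`, `y = row·√3/2` so immediate neighbors sit at distance 1.
Units are indexed in (row, q) lexicographic order; every tie-break
downstream (BMU ties, plateau seeds, growth order) resolves to the lowest
index, making the whole pipeline deterministic. This compact lattice, as
opposed to a rectangular sheet or torus, gives the map a center and a
boundary that match how component planes are read.

**Sizing.** With no override, *r* minimizes `|3r(r−1)+1 − 5√N|` (ties to
the smaller *r*). The `5√N` rule is standard map-sizing practice; for
N = 1,893 filtered transcripts it yields r = 9, 217 units — about 9 genes
per unit.

**Initialization.** Codebooks are seeded by linear interpolation over the
plane spanned by the data's first two principal directions: each unit's
normalized lattice position maps to mean ± 2 sd along the corresponding
component (SVD signs fixed by the largest-loading convention, so the
result is deterministic). Rank-deficient data fall back to a seeded
uniform draw inside the per-column data range. Principal-plane
initialization plus batch training makes the default pipeline fully
deterministic — no seed sensitivity at all.

**Training.** Classical Kohonen updates with Gaussian neighborhood
`h(c,i) = exp(−d(c,i)²/2σ²)` on lattice distance. Default schedule: a
rough phase of `max(5, ⌈10·units/N⌉)` epochs with σ shrinking linearly
from the ring count to 1, then a fine-tune phase of 4× as many epochs with
σ: 1 → 0.5. Batch mode (neighborhood-weighted means each epoch) is the
default — sample-order free; sequential mode (learning rate 0.5 → 0.05
rough, 0.05 → 0.01 fine-tune) is available and seed-reproducible. Stopping
σ at 0.5 rather than → 0 keeps neighboring codebooks correlated, which the
topological partition depends on. In the narrow-kernel limit batch epochs
reduce to Lloyd steps, so quantization error is non-increasing there; with
wide kernels early epochs trade quantization for topology, as intended.

Profiles are clustered on raw log2FC values — not row-standardized —
because the component planes encode the *signed magnitude* of regulation
and flat genes have already been filtered out.

## Topological two-phase clustering

Phase 1 computes each unit's **U-height** (mean codebook distance to its
≤ 6 lattice neighbors; boundary units average over the neighbors they
have; a single-unit grid gets 0). Local minima of this surface are **seed
units** — interiors of homogeneous map domains. Plateaus of equal-height
mutually adjacent minima collapse to their lowest-index member, so a
perfectly flat (degenerate) map yields one seed, not one per unit.

Phase 2 grows clusters from the seeds over the lattice: repeatedly attach
the unassigned unit that is lattice-adjacent to an existing cluster and
has minimal codebook distance *to that cluster's seed codebook* (ties:
lower cluster ID, then lower unit index). Comparing to the fixed seed
rather than a running centroid keeps the partition a pure function of the
trained map — no order-dependent drift and no assumed cluster shape. The
cluster count is therefore **emergent**; an optional cap iteratively drops
the higher-index seed of the closest codebook pair before growing.

Genes inherit the cluster of their best-matching unit, and each cluster's
representative expression pattern is its seed unit's codebook, reported
verbatim.

## Enrichment

Per cluster × term: overlap *k*, term-in-background size *K*, annotated
cluster size *n*, background *N*; p = hypergeometric upper tail
`P(X ≥ k)` (SciPy's exact survival function); BH step-up q-values within
each (cluster, namespace) family — per-cluster term lists are the unit of
reporting, and adjusting across clusters would couple unrelated lists.
The default background universe is the annotated portion of the
*pre-filter* gene table (configurable to the filtered set): the filter is
part of the discovery procedure, so the universe should be what could have
been discovered. Reporting flags rows with overlap ≥ 3 and q < 0.05; all
scored rows are retained so the reporting rule can be revisited without
recomputation. Gene matching is exact-string; ID translation is a
data-preparation concern, not this package's.

## Synthetic data: what it emulates, and what it does not

The generator plants the five temporal archetypes as fixed
piecewise-linear unit-amplitude shapes (interpolated from breakpoints, so
any stage count ≥ 3 yields the same qualitative patterns), scaled by a
peak amplitude (default 1.5 log2 ≈ 2.8-fold) and perturbed with additive
Gaussian noise on the log2FC scale (default sd 0.25), i.e. multiplicative
lognormal noise on intensities — matching how the pipeline consumes data.
Null genes carry noise only. Stage intensities are
`control · 2^(amplitude·shape + noise)`; the table is emitted unfloored so
the pipeline's own flooring runs.

Baselines are lognormal with meanlog ln(500) and sdlog 0.10 (mean
intensity ≈ 500), with 5% of controls planted below the floor (uniform on
[80, 195]) to exercise the censoring path. The baseline spread is kept
deliberately tight: with the floor at 200, a 2-fold repression is only
expressible for controls ≥ 400, so a wide baseline distribution would make
floor censoring — not filter behaviour — the dominant determinant of
sensitivity. Real regulated transcripts that passed a 2-fold screen were
by construction comfortably detectable, which is the regime the tight
spread mimics. The generator does **not** simulate probe-level array
physics, batch effects, heteroskedastic low-intensity noise, correlated
genes or normalization itself; recovery results on it therefore validate
the pipeline's logic and robustness to iid log-scale noise, not
performance on raw array data.

Recovery is scored by merging recovered clusters by majority truth
archetype (ties broken alphabetically) and computing the adjusted Rand
index against truth — merging is appropriate because several map domains
legitimately express the same archetype, and the emergent cluster count
(typically 5–8 under defaults) exceeds the five planted patterns. Under
defaults the end-to-end median ARI over 5 seeds is ≈ 0.95, filter
sensitivity ≈ 0.93 and the null pass rate ≈ 0.

A companion GMT emitter writes one term per archetype (true members + 20%
decoys) so enrichment has a known right answer, and a synthetic stand-in
of the deposited regulated-transcript table (1,893 transcripts × 6 stages,
12 cluster labels, cluster 2 = 9 members — values synthetic, shape
documented) exercises the parsing and per-cluster counting paths offline.

## Problem sizes and determinism

Default validation sizes — 1,000 genes (5 × 100 regulated + 500 null), 6
stages, ≈ 91-unit maps, 25 batch epochs — were chosen so a full end-to-end
run completes in well under a second while leaving per-seed sensitivity
estimates with standard errors ≈ 0.01; the acceptance script's 10-seed /
5-seed repetitions then pin the aggregate statistics tightly. All
randomness (generator draws, random fallback init, sequential sample
order) flows from explicit integer seeds; batch runs are bit-reproducible,
and rerunning a pipeline config writes byte-identical TSVs.

## Known limitations

* The emergent cluster count depends on the trained map's U-height
  surface; it is a result, not a parameter, and small data changes can
  merge or split marginal domains (the optional cap bounds but does not
  fix K).
* U-height plateau detection compares floating-point equality; it is meant
  for genuinely degenerate (constant) regions, not near-ties.
* Cluster growth is seed-anchored; long thin domains whose far end drifts
  from the seed codebook can be annexed by a neighboring cluster.
* Enrichment treats terms as flat sets — no ontology-graph propagation,
  no term-redundancy reduction.
* The regulation filter is a hard threshold: genes hovering at the
  boundary flip membership under resampling, which is faithful to the
  original rule but worth remembering when interpreting small clusters.
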