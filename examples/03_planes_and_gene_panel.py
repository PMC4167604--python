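"""Component plane presentations and the gene-panel fold-change report.

Each plane recolors the trained map by one stage's codebook values (shared
symmetric color limits, red = induced / blue = repressed); the panel report
lists chosen genes' stage fold changes with their cluster, or a hyphen for
genes that failed the regulation filter.
"""

from edisom import (
    SyntheticSpec, apply_floor, build_grid, component_planes, find_seeds,
    fold_change, gene_panel_report, generate, map_bmu, neighbor_distance,
    partition, regulation_filter, train,
)

matrix, truth = generate(SyntheticSpec(seed=0))
fc_full = fold_change(apply_floor(matrix))
kept, _ = regulation_filter(fc_full)
grid = train(build_grid(kept, seed=0), kept)
bmu = map_bmu(grid, kept)
part = partition(grid, find_seeds(grid, neighbor_distance(grid)), bmu)

planes = component_planes(grid)
print(f"{len(planes)} planes, shared color limits {planes[0].color_limits[0]:+.2f}"
      f" .. {planes[0].color_limits[1]:+.2f} log2FC")
for plane in planes:
    print(f"  {plane.stage_label}: unit values span "
          f"{plane.unit_values.min():+.2f} .. {plane.unit_values.max():+.2f}")

# a small panel: two clustered genes and one that failed the filter
clustered = list(part.gene_cluster)[:2]
dropped = next(t for t in fc_full.transcript_ids if t not in part.gene_cluster)
panel = clustered + [dropped]
report = gene_panel_report(fc_full, part, panel)
print(report.to_string(index=False, float_format=lambda v: f"{v:+.2f}"))
print("-> the hyphen marks a gene excluded from clustering by the 2-fold/4-stage rule.")
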