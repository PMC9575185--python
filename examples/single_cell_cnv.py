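"""Call large copy-number events in single cells and test their association
with cell-cycle state.

Builds a synthetic 85-cell dataset — 42 "G2-sorted" cells of which 7 carry
a +2-copy, 15-Mb amplification, and 43 flat "G1-sorted" cells — then runs
the full profiling pipeline: 5-Mb windows every 2.5 Mb, aberrant-window
exclusion, log2 median-centring, two-anchor percentile normalization,
threshold-merge event calling, and a Fisher exact test on the resulting
2x2 table of cells with/without events per group.
"""
import dtpescape as d

genome = d.gen_genome(4, 100e6, ploidy=2)
carriers = [f"cell{i:03d}" for i in range(7)]
cnv = d.PlantedCNV("chr2", 40_000_000, 55_000_000, copy_delta=+2,
                   cell_ids=frozenset(carriers))
aberrant = []
for chrom in genome.names:
    hi = 70_000_000 if chrom == "chr2" else 47_500_000
    aberrant.append((chrom, hi, hi + 5_000_000, 5.0))   # repeat-pileup-like
    aberrant.append((chrom, 0, 2_500_000, 0.05))        # unmappable-like

sim = d.gen_sc_coverage(
    genome, [cnv], n_cells=85, mean_reads_per_cell=60_000, dispersion=0.2,
    seed=1, window_efficiency_sd=0.15, aberrant_regions=aberrant,
)
grid = d.make_window_grid(genome)                     # 5 Mb / 2.5 Mb step
counts = d.count_reads_in_windows(sim.reads, grid, cell_ids=sim.cell_ids)
_, mask = d.filter_aberrant_windows(counts)           # drops coverage artefacts
profile = d.normalize_copy_profiles(counts, excluded=mask)
events = d.call_cnv_events(profile, grid, amp_log2=0.5, del_log2=-0.5,
                           min_span=10e6)

groups = {c: ("G2_sorted" if i < 42 else "G1_sorted")
          for i, c in enumerate(sim.cell_ids)}
table = d.event_contingency(events, groups)
p = d.fisher_exact_2x2(table.to_numpy())

print(f"windows: {len(grid)} ({int(mask.sum())} excluded as aberrant)")
print(f"events called:\n{events[['cell_id', 'chrom', 'start', 'end', 'direction', 'span']]}")
print(f"\ncontingency table (cells with / without >=1 large event):\n{table}")
print(f"\nFisher exact p = {p:.4f}")
print("\nEvents cluster in cells that passed through S/G2 (the carriers were")
print("planted among the G2-sorted group); a small p says large CNVs and")
print("cell-cycle progression under drug are associated, not independent.")
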