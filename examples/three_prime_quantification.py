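"""Quantify degraded, directional RNA-seq from transcript 3' ends.

Simulates two libraries of identical expression truth — one intact, one
chemically degraded (exponential 3' survival, 0.01/nt) — counts reads in
the 3'-most 500 nt of each high-confidence transcript on the opposite
strand, and shows that two-anchor (50th/90th percentile) normalization
makes the libraries comparable despite the quality difference.
"""
import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

import dtpescape as d

genome = d.gen_genome(2, 1_000_000, 2)
ann = d.gen_annotation(
    genome, 10,
    exon_structure_rule={"n_exons": (1, 3), "exon_len": (600, 3000),
                         "intron_len": (200, 800)},
    high_conf_fraction=1.0, seed=3,
)
rng = np.random.default_rng(1)
truth = {t.transcript_id: float(a)
         for t, a in zip(ann, np.exp(rng.normal(3, 1.2, len(ann))))}

windows = d.derive_three_prime_windows(ann, length=500)
counts = {}
for tag, rate in (("intact", 0.0), ("degraded", 0.01)):
    reads = d.gen_rnaseq_reads(ann, truth, degradation_rate=rate,
                               directional=True, n_reads=100_000, seed=7)
    kept, discarded = d.filter_exonic_reads(reads, ann)
    counts[tag] = d.quantify_three_prime(kept, windows, strand_rule="opposite")
    print(f"{tag}: kept {len(kept)} reads, discarded {discarded} non-exonic")

matrix = pd.DataFrame(counts)
norm = d.normalize_expression(matrix, mode="three_prime", anchors=(50, 90))
gene_truth = pd.Series({t.gene_id: truth[t.transcript_id] for t in ann})

rho = spearmanr(matrix["degraded"][gene_truth.index], gene_truth)[0]
gap_before = (np.log2(matrix + 1).diff(axis=1).iloc[:, 1]).abs().mean()
gap_after = (norm["intact"] - norm["degraded"]).abs().mean()
r = pearsonr(norm["intact"], norm["degraded"])[0]

print(f"\nSpearman(degraded 3' counts, true abundance) = {rho:.3f}")
print(f"mean |log2 intact - degraded| before normalization: {gap_before:.3f}")
print(f"mean |log2 intact - degraded| after normalization:  {gap_after:.3f}")
print(f"per-gene Pearson r after normalization: {r:.3f}")
print("\n3'-restricted counting preserves abundance ranking in degraded RNA,")
print("and percentile matching removes the global quality-driven offset.")
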