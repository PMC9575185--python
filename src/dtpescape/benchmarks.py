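"""Standard synthetic study conditions and end-to-end recovery benchmarks.

Each benchmark builds the standard synthetic dataset for one pipeline arm,
runs the full analysis on it, and reports recovery metrics against the
generator's ground truth. The fixtures fix the study geometry once:

* CNV arm: 85 cells (42 "positive", the first 7 of which carry one
  +2-copy 15-Mb amplification; 43 flat "negative"), a 4 x 100 Mb diploid
  genome at 60,000 reads per cell (150 reads/Mb), negative-binomial
  dispersion 0.2, 15% log-normal per-tile capture-efficiency variation,
  plus one repeat-pileup-like (5x) and one unmappable-like (0.05x)
  aberrant region per chromosome for the exclusion filter to catch.
  Event *detection* marks windows at half the expected +2-copy amplitude
  (|log2| >= 0.5) — the midpoint decision boundary between baseline (0)
  and the expected event level (1) — and requires a span > 10 Mb.

* 3' RNA arm: 10 single- to few-exon genes on a 2 x 1 Mb genome with
  log-normal abundances; an intact (rate 0) and a degraded
  (0.01 /nt) directional library of 100,000 reads each.

* Behaviour-clustering arm: 300 genes, 100 per behaviour archetype,
  Gaussian profile noise (SD 0.25 by default).

* Survival arm: exponential cohorts with a planted hazard ratio, fitted
  with the in-package Cox model.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from . import (
    EscapeParams,
    PlantedCNV,
    TranscriptAnnotation,
    call_cnv_events,
    cluster_behaviours,
    count_reads_in_windows,
    cox_ph,
    cumulative_label_fraction,
    derive_three_prime_windows,
    event_contingency,
    filter_aberrant_windows,
    filter_exonic_reads,
    fisher_exact_2x2,
    gen_annotation,
    gen_genome,
    gen_resistance_cohort,
    gen_rnaseq_reads,
    gen_sc_coverage,
    make_window_grid,
    normalize_copy_profiles,
    normalize_expression,
    quantify_three_prime,
)

__all__ = [
    "cnv_recovery_benchmark",
    "three_prime_benchmark",
    "clustering_benchmark",
    "cox_recovery_benchmark",
    "hazard_proportionality_benchmark",
    "label_fraction_check",
]

# ---- CNV arm fixture ------------------------------------------------------

CNV_GENOME_CHROMS = 4
CNV_CHROM_LENGTH = 100_000_000
CNV_REGION = ("chr2", 40_000_000, 55_000_000)  # 15 Mb, +2 copies
CNV_N_POSITIVE = 42
CNV_N_NEGATIVE = 43
CNV_N_CARRIERS = 7
CNV_READS_PER_CELL = 60_000
CNV_DISPERSION = 0.2
CNV_EFFICIENCY_SD = 0.15
CNV_DETECT_LOG2 = 0.5  # half the expected +2-copy amplitude


def _cnv_fixture_genome():
    genome = gen_genome(CNV_GENOME_CHROMS, CNV_CHROM_LENGTH, 2)
    aberrant = []
    for chrom in genome.names:
        # keep chr2's repeat-like region clear of the planted CNV
        hi_start = 70_000_000 if chrom == CNV_REGION[0] else 47_500_000
        aberrant.append((chrom, hi_start, hi_start + 5_000_000, 5.0))
        aberrant.append((chrom, 0, 2_500_000, 0.05))
    return genome, aberrant


def cnv_recovery_benchmark(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Run the full single-cell CNV pipeline on the standard fixture.

    Returns per-seed and aggregate recovery metrics: carrier-detection
    sensitivity, false events per flat cell, and the Fisher p of the
    positive-vs-negative contingency table.
    """
    genome, aberrant = _cnv_fixture_genome()
    grid = make_window_grid(genome)
    chrom, cs, ce = CNV_REGION
    n_cells = CNV_N_POSITIVE + CNV_N_NEGATIVE
    carriers = [f"cell{i:03d}" for i in range(CNV_N_CARRIERS)]
    cnv = PlantedCNV(chrom, cs, ce, +2, frozenset(carriers))
    sens, false_rates, fisher_ps = [], [], []
    for s in range(n_seeds):
        sim = gen_sc_coverage(
            genome,
            [cnv],
            n_cells=n_cells,
            mean_reads_per_cell=CNV_READS_PER_CELL,
            dispersion=CNV_DISPERSION,
            seed=base_seed + s,
            window_efficiency_sd=CNV_EFFICIENCY_SD,
            aberrant_regions=aberrant,
        )
        counts = count_reads_in_windows(sim.reads, grid, cell_ids=sim.cell_ids)
        _, mask = filter_aberrant_windows(counts)
        profile = normalize_copy_profiles(counts, excluded=mask)
        events = call_cnv_events(
            profile, grid, amp_log2=CNV_DETECT_LOG2, del_log2=-CNV_DETECT_LOG2
        )
        hits = events[
            (events.direction == "amplification")
            & (events.chrom == chrom)
            & (events.start < ce)
            & (events.end > cs)
        ]
        detected = set(hits.cell_id) & set(carriers)
        flat = [c for c in sim.cell_ids if c not in carriers]
        false_events = events[~events.cell_id.isin(carriers)]
        sens.append(len(detected) / len(carriers))
        false_rates.append(len(false_events) / len(flat))
        groups = {
            c: ("positive" if i < CNV_N_POSITIVE else "negative")
            for i, c in enumerate(sim.cell_ids)
        }
        table = event_contingency(events, groups)
        fisher_ps.append(fisher_exact_2x2(table.to_numpy()))
    return {
        "sensitivity": float(np.mean(sens)),
        "false_events_per_cell": float(np.mean(false_rates)),
        "fisher_p_median": float(np.median(fisher_ps)),
        "fisher_p_max": float(np.max(fisher_ps)),
        "per_seed_sensitivity": sens,
        "per_seed_fisher_p": fisher_ps,
        "n_seeds": n_seeds,
    }


# ---- 3' RNA arm fixture ---------------------------------------------------

RNA_N_GENES = 10
RNA_N_READS = 100_000
RNA_DEGRADATION = 0.01  # per nt


def standard_rna_fixture(seed: int = 0):
    """Annotation plus log-normal per-transcript abundances."""
    genome = gen_genome(2, 1_000_000, 2)
    ann = gen_annotation(
        genome,
        RNA_N_GENES,
        exon_structure_rule={
            "n_exons": (1, 3),
            "exon_len": (600, 3000),
            "intron_len": (200, 800),
        },
        high_conf_fraction=1.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    truth = {
        t.transcript_id: float(a)
        for t, a in zip(ann, np.exp(rng.normal(3.0, 1.2, len(ann))))
    }
    return ann, truth


def three_prime_benchmark(seed: int = 0) -> dict:
    """Quantify an intact and a degraded library of identical truth.

    Reports Spearman correlation of degraded-library counts with true
    abundances, and the per-gene agreement between intact and degraded
    libraries before/after percentile normalization.
    """
    ann, truth = standard_rna_fixture(seed)
    windows = derive_three_prime_windows(ann)
    counts = {}
    for tag, rate in (("intact", 0.0), ("degraded", RNA_DEGRADATION)):
        reads = gen_rnaseq_reads(
            ann, truth, degradation_rate=rate, directional=True,
            n_reads=RNA_N_READS, seed=seed + 10, sample_id=tag,
        )
        kept, _ = filter_exonic_reads(reads, ann)
        counts[tag] = quantify_three_prime(kept, windows)
    matrix = pd.DataFrame(counts)
    gene_truth = pd.Series({t.gene_id: truth[t.transcript_id] for t in ann})
    rho = float(spearmanr(matrix["degraded"][gene_truth.index], gene_truth)[0])
    raw_log = np.log2(matrix + 1)
    norm = normalize_expression(matrix, mode="three_prime")
    before = float((raw_log["intact"] - raw_log["degraded"]).abs().mean())
    after = float((norm["intact"] - norm["degraded"]).abs().mean())
    r_norm = float(pearsonr(norm["intact"], norm["degraded"])[0])
    return {
        "spearman_counts_truth": rho,
        "pearson_intact_degraded_normalized": r_norm,
        "mean_abs_log2_diff_before": before,
        "mean_abs_log2_diff_after": after,
        "n_genes": RNA_N_GENES,
    }


# ---- behaviour-clustering arm ---------------------------------------------

CLUSTER_DESIGN = {
    "untreated_G1": ("untreated", "G1"),
    "untreated_G2M": ("untreated", "G2M"),
    "drug_G1": ("drug", "G1"),
    "drug_G2M": ("drug", "G2M"),
}
CLUSTER_ARCHETYPES = {
    "i": (1.0, 1.0, -1.0, -1.0),
    "ii": (1.0, 1.0, -1.0, 1.0),
    "iii": (-1.0, -1.0, 1.0, 1.0),
}


def planted_behaviour_matrix(
    n_per_cluster: int = 100, noise_sd: float = 0.25, seed: int = 0
):
    """Expression profiles built from the three behaviour archetypes."""
    rng = np.random.default_rng(seed)
    rows, genes, truth = [], [], []
    for lab, base in CLUSTER_ARCHETYPES.items():
        for j in range(n_per_cluster):
            genes.append(f"{lab}_{j:03d}")
            truth.append(lab)
            rows.append(np.asarray(base) + rng.normal(0.0, noise_sd, len(base)))
    matrix = pd.DataFrame(rows, index=genes, columns=list(CLUSTER_DESIGN))
    return matrix, pd.Series(truth, index=genes)


def clustering_benchmark(
    n_seeds: int = 20, noise_sd: float = 0.25, n_per_cluster: int = 100
) -> dict:
    """Planted-archetype recovery of the behaviour clustering."""
    rec = []
    for s in range(n_seeds):
        matrix, truth = planted_behaviour_matrix(n_per_cluster, noise_sd, seed=s)
        assignment = cluster_behaviours(matrix, CLUSTER_DESIGN)
        rec.append(float((assignment["label"] == truth).mean()))
    return {
        "recovery_mean": float(np.mean(rec)),
        "recovery_min": float(np.min(rec)),
        "per_seed": rec,
    }


# ---- survival arm ---------------------------------------------------------

def cox_recovery_benchmark(
    n_cohorts: int = 10,
    hazard_ratio: float = 0.22,
    n_per_group: int = 500,
    base_hazard: float = 0.12,
    max_weeks: float = 52.0,
    base_seed: int = 0,
) -> dict:
    """Recover a planted hazard ratio from simulated cohorts.

    Reports the mean estimated risk reduction (1 - HR) and the fraction
    of cohorts whose 95% Wald CI covers the planted HR.
    """
    rr, cover = [], []
    for s in range(n_cohorts):
        cohort = gen_resistance_cohort(
            {"control": base_hazard, "treated": base_hazard * hazard_ratio},
            n_cultures=n_per_group,
            max_weeks=max_weeks,
            seed=base_seed + s,
        )
        x = (cohort["group"] == "treated").astype(float).to_frame("treated")
        fit = cox_ph(cohort["time_weeks"], cohort["event"], x)
        row = fit.summary.iloc[0]
        rr.append(float(row["risk_reduction"]))
        cover.append(bool(row["ci_low"] <= hazard_ratio <= row["ci_high"]))
    return {
        "mean_risk_reduction": float(np.mean(rr)),
        "ci_coverage": float(np.mean(cover)),
        "planted_risk_reduction": 1.0 - hazard_ratio,
        "n_cohorts": n_cohorts,
        "n_per_group": n_per_group,
    }


def hazard_proportionality_benchmark(
    n_fits: int = 10,
    n_per_group: int = 500,
    factor: float = 0.1,
    base_seed: int = 0,
) -> dict:
    """The escape simulator's resistance hazard scales with the escape rate.

    Two groups differ only in the CDK4/6-inhibitor factor on the escape
    rate; because resistance is acquired per completed S phase, the
    hazard of colony formation is proportional to the escape rate, so the
    fitted HR should be consistent with the factor. Reports the mean
    estimated HR and the fraction of fits whose 95% CI covers the factor.
    """
    base = dict(
        n0=200, lambda_escape=0.02, p_resist=0.02,
        death_rate=0.02, p_death_on_cycle=0.5,
    )
    group_params = {
        "drug": EscapeParams(**base),
        "drug_plus_cdk46i": EscapeParams(**base, cdk46i_factor=factor),
    }
    hrs, cover = [], []
    for s in range(n_fits):
        cohort = gen_resistance_cohort(
            group_params, n_cultures=n_per_group, max_weeks=52, seed=base_seed + s
        )
        x = (cohort["group"] == "drug_plus_cdk46i").astype(float).to_frame("combo")
        fit = cox_ph(cohort["time_weeks"], cohort["event"], x)
        row = fit.summary.iloc[0]
        hrs.append(float(row["hr"]))
        cover.append(bool(row["ci_low"] <= factor <= row["ci_high"]))
    return {
        "mean_hr": float(np.mean(hrs)),
        "ci_coverage": float(np.mean(cover)),
        "factor": factor,
        "n_fits": n_fits,
    }


def label_fraction_check(
    lambda_per_day: float = float(np.log(2) / 11.0),
    t_days: float = 11.0,
    n0: int = 20_000,
    seed: int = 0,
) -> dict:
    """Continuous-labelling fraction: simulation vs the 1 - e^(-lambda t) law."""
    params = EscapeParams(n0=n0, lambda_escape=lambda_per_day)
    analytic, simulated = cumulative_label_fraction(params, t_days, seed=seed)
    se = float(np.sqrt(analytic * (1 - analytic) / n0))
    return {
        "analytic": float(analytic),
        "simulated": float(simulated),
        "mc_se": se,
        "n0": n0,
    }
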