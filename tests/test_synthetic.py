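"""Generators: construction, determinism, and the statistical structure
the downstream analyses rely on."""
import numpy as np
import pandas as pd
import pytest

import dtpescape as d


class TestGenome:
    def test_construction(self):
        g = d.gen_genome(2, 50e6, 2, seed=1)
        assert g.total_length == 100_000_000
        assert g.names == ["chr1", "chr2"]
        assert g.ploidy == (2, 2)

    def test_degenerate_single_base_chromosome_is_legal(self):
        g = d.gen_genome(1, 1, 2, seed=0)
        assert g.total_length == 1

    def test_deterministic(self):
        assert d.gen_genome(3, 30e6, 2, seed=7) == d.gen_genome(3, 30e6, 2, seed=7)

    @pytest.mark.parametrize("args", [(0, 1e6), (1, 0), (2, -5)])
    def test_rejects_non_positive_sizes(self, args):
        with pytest.raises(ValueError):
            d.gen_genome(*args)

    def test_aneuploid_baseline(self):
        g = d.gen_genome(3, 10e6, ploidy=(2, 3, 1))
        assert g.ploidy_of("chr2") == 3


class TestCoverage:
    def test_no_cnv_equal_expected_density_across_cells(self, small_genome):
        sim = d.gen_sc_coverage(
            small_genome, [], n_cells=30, mean_reads_per_cell=3000,
            dispersion=0.0, seed=0,
        )
        grid = d.make_window_grid(small_genome)
        counts = d.count_reads_in_windows(sim.reads, grid, cell_ids=sim.cell_ids)
        # per-window means across cells should be statistically flat
        m = counts.mean(axis=0)
        assert m.std() / m.mean() < 0.1

    def test_planted_cnv_doubles_density(self, small_genome):
        carriers = [f"cell{i:03d}" for i in range(7)]
        cnv = d.PlantedCNV("chr1", 20_000_000, 35_000_000, +2, frozenset(carriers))
        sim = d.gen_sc_coverage(
            small_genome, [cnv], n_cells=42, mean_reads_per_cell=5000,
            dispersion=0.05, seed=1,
        )
        reads = sim.reads
        in_region = (
            (reads.chrom == "chr1")
            & (reads.start >= 20_000_000)
            & (reads.start < 35_000_000)
        )
        dens = reads[in_region].groupby("cell_id").size() / 15e6
        base = reads[~in_region].groupby("cell_id").size() / 85e6
        ratio = (dens[carriers] / base[carriers]).to_numpy()
        # forced by construction: (2 + 2) / 2 = 2, within 3 SE over carriers
        se = ratio.std(ddof=1) / np.sqrt(len(ratio))
        assert abs(ratio.mean() - 2.0) < 3 * se + 1e-9
        nc = [c for c in sim.cell_ids if c not in carriers]
        assert abs((dens[nc] / base[nc]).mean() - 1.0) < 0.05

    def test_truth_table_records_copy_numbers(self, small_genome):
        cnv = d.PlantedCNV("chr1", 1_000_000, 2_000_000, -1, frozenset(["cell000"]))
        sim = d.gen_sc_coverage(small_genome, [cnv], 2, 100, seed=0)
        seg = sim.segments
        row = seg[(seg.cell_id == "cell000") & (seg.start == 1_000_000)]
        assert row.copy_number.item() == 1
        assert sim.carriers.carrier.sum() == 1

    def test_deterministic_for_seed(self, small_genome):
        a = d.gen_sc_coverage(small_genome, [], 5, 500, seed=9).reads
        b = d.gen_sc_coverage(small_genome, [], 5, 500, seed=9).reads
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_cnv_outside_genome(self, small_genome):
        cnv = d.PlantedCNV("chr1", 0, 60_000_000, 2, frozenset())
        with pytest.raises(ValueError, match="outside"):
            d.gen_sc_coverage(small_genome, [cnv], 2, 100, seed=0)

    def test_rejects_negative_copy_total(self, small_genome):
        cnv = d.PlantedCNV("chr1", 0, 1_000_000, -3, frozenset())
        with pytest.raises(ValueError):
            d.gen_sc_coverage(small_genome, [cnv], 2, 100, seed=0)

    def test_window_counts_overdispersed(self, small_genome):
        """Marginal window counts exceed Poisson variance by ~dispersion."""
        sim = d.gen_sc_coverage(
            small_genome, [], n_cells=300, mean_reads_per_cell=5000,
            dispersion=0.2, seed=3,
        )
        grid = d.make_window_grid(small_genome)
        counts = d.count_reads_in_windows(sim.reads, grid, cell_ids=sim.cell_ids)
        c = counts.to_numpy(dtype=float)
        mu = c.mean(axis=0)
        # NB: var = mu + d*mu^2  =>  (var - mu)/mu^2 ~ d
        disp = ((c.var(axis=0, ddof=1) - mu) / mu**2).mean()
        assert 0.1 < disp < 0.3


class TestAnnotation:
    def test_simple_single_exon_annotation(self, small_genome):
        ann = d.gen_annotation(small_genome, 10, high_conf_fraction=1.0, seed=0)
        assert len(ann) == 10
        assert all(t.high_confidence and len(t.exons) == 1 for t in ann)

    def test_multiple_transcripts_share_three_prime_end(self, small_genome):
        ann = d.gen_annotation(
            small_genome, 5, transcripts_per_gene=2,
            exon_structure_rule={"n_exons": (2, 3)}, seed=1,
        )
        for gene, ts in ann.by_gene().items():
            three_prime = {
                (t.exons[-1][1] if t.strand == "+" else t.exons[0][0]) for t in ts
            }
            assert len(three_prime) == 1, gene

    def test_gtf_round_trip(self, small_genome, tmp_path):
        ann = d.gen_annotation(
            small_genome, 8, transcripts_per_gene=2,
            exon_structure_rule={"n_exons": (1, 3)}, high_conf_fraction=0.5, seed=2,
        )
        path = tmp_path / "ann.gtf"
        ann.to_gtf(path)
        back = d.TranscriptAnnotation.from_gtf(path)
        orig = {(t.transcript_id, t.gene_id, t.chrom, t.strand, t.exons,
                 t.high_confidence) for t in ann}
        rt = {(t.transcript_id, t.gene_id, t.chrom, t.strand, t.exons,
               t.high_confidence) for t in back}
        assert orig == rt

    def test_infeasible_packing_rejected(self):
        tiny = d.gen_genome(1, 5000, 2)
        with pytest.raises(ValueError, match="packing"):
            d.gen_annotation(tiny, 50, seed=0)

    def test_genes_do_not_overlap(self, small_genome):
        ann = d.gen_annotation(small_genome, 40, seed=3)
        by_chrom = {}
        for t in ann:
            by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


class TestRnaseqReads:
    def test_zero_degradation_gives_uniform_coverage(self, rna_fixture):
        ann, truth = rna_fixture
        t = ann.transcripts[0]
        reads = d.gen_rnaseq_reads(
            d.TranscriptAnnotation((t,)), {t.transcript_id: 1.0},
            degradation_rate=0.0, n_reads=20_000, seed=0,
        )
        # uniform fragment placement: mean start ~ centre of feasible range
        rel = reads.start - t.start
        lo, hi = rel.min(), rel.max()
        assert abs(rel.mean() - (lo + hi) / 2) < 0.02 * t.spliced_length

    def test_high_degradation_confines_reads_to_three_prime_end(self, rna_fixture):
        ann, truth = rna_fixture
        windows = d.derive_three_prime_windows(ann)
        reads = d.gen_rnaseq_reads(ann, truth, degradation_rate=0.1,
                                   n_reads=5000, seed=1)
        counted = d.quantify_three_prime(reads, windows).sum()
        assert counted / len(reads) > 0.99

    def test_directional_reads_oppose_transcript_strand(self, rna_fixture):
        ann, truth = rna_fixture
        reads = d.gen_rnaseq_reads(ann, truth, directional=True,
                                   n_reads=2000, seed=2)
        strand_of = {t.transcript_id: t.strand for t in ann}
        src = reads["source"].map(strand_of)
        assert (reads["strand"] != src).all()

    def test_three_prime_bias_increases_with_degradation_rate(self, rna_fixture):
        ann, truth = rna_fixture
        windows = d.derive_three_prime_windows(ann)
        fracs = []
        for rate in (0.001, 0.004, 0.02):
            reads = d.gen_rnaseq_reads(ann, truth, degradation_rate=rate,
                                       n_reads=20_000, seed=7)
            fracs.append(d.quantify_three_prime(reads, windows).sum() / len(reads))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_deterministic_for_seed(self, rna_fixture):
        ann, truth = rna_fixture
        a = d.gen_rnaseq_reads(ann, truth, n_reads=500, seed=5)
        b = d.gen_rnaseq_reads(ann, truth, n_reads=500, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_empty_annotation_and_zero_abundance(self, rna_fixture):
        ann, _ = rna_fixture
        with pytest.raises(ValueError):
            d.gen_rnaseq_reads(d.TranscriptAnnotation(()), {}, n_reads=10)
        with pytest.raises(ValueError, match="zero"):
            d.gen_rnaseq_reads(ann, {}, n_reads=10)


class TestCohortGenerator:
    def test_short_horizon_censors_everything(self):
        cohort = d.gen_resistance_cohort({"g": 0.001}, 50, max_weeks=1, seed=0)
        assert (cohort.event == 0).all()
        assert (cohort.time_weeks == 1).all()

    def test_exponential_hazard_ratio_recovered(self):
        cohort = d.gen_resistance_cohort(
            {"A": 0.2, "B": 0.2 * 0.22}, 800, max_weeks=100, seed=1
        )
        x = (cohort.group == "B").astype(float).to_frame("b")
        fit = d.cox_ph(cohort.time_weeks, cohort.event, x)
        row = fit.summary.iloc[0]
        assert row.ci_low <= 0.22 <= row.ci_high
        assert abs(row.hr - 0.22) < 0.05

    def test_mechanistic_group_accepted(self):
        params = d.EscapeParams(n0=50, lambda_escape=0.5, p_resist=0.5)
        cohort = d.gen_resistance_cohort({"m": params}, 5, max_weeks=20, seed=2)
        assert len(cohort) == 5
        assert set(cohort.columns) == {"culture_id", "group", "time_weeks", "event"}
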