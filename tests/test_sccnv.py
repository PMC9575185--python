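"""Window grid, counting, aberrant-window exclusion, normalization and
event calling for the single-cell copy-number pipeline."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dtpescape as d


def reads_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "cell_id"])


class TestWindowGrid:
    def test_20mb_chromosome_gives_seven_windows(self):
        g = d.gen_genome(1, 20e6, 2)
        grid = d.make_window_grid(g)
        assert len(grid) == 7
        assert list(grid.windows.start) == [int(i * 2.5e6) for i in range(7)]
        assert grid.windows.end.iloc[-1] == 20_000_000

    def test_exact_width_chromosome_gives_one_window(self):
        grid = d.make_window_grid(d.gen_genome(1, 5e6, 2))
        assert len(grid) == 1
        assert (grid.windows.start.item(), grid.windows.end.item()) == (0, 5_000_000)

    def test_chromosome_shorter_than_width_gives_zero_windows(self):
        grid = d.make_window_grid(d.gen_genome(1, 4.9e6, 2))
        assert len(grid) == 0

    def test_invalid_geometry_rejected(self, small_genome):
        with pytest.raises(ValueError):
            d.make_window_grid(small_genome, width=0)
        with pytest.raises(ValueError):
            d.make_window_grid(small_genome, width=5e6, step=6e6)


class TestCounting:
    def test_midpoint_counted_in_both_overlapping_windows(self):
        g = d.gen_genome(1, 20e6, 2)
        grid = d.make_window_grid(g)
        reads = reads_frame([("chr1", 2_999_950, 3_000_050, "+", "c1")])
        counts = d.count_reads_in_windows(reads, grid, cell_ids=["c1"])
        assert counts.loc["c1", 0] == 1  # [0, 5 Mb)
        assert counts.loc["c1", 1] == 1  # [2.5, 7.5 Mb)
        assert counts.loc["c1"].sum() == 2

    def test_empty_read_set_gives_zero_matrix(self, small_genome):
        grid = d.make_window_grid(small_genome)
        counts = d.count_reads_in_windows(
            reads_frame([]), grid, cell_ids=["a", "b"]
        )
        assert counts.shape == (2, len(grid))
        assert (counts.to_numpy() == 0).all()

    def test_midpoint_on_window_start_included_half_open(self):
        grid = d.make_window_grid(d.gen_genome(1, 20e6, 2))
        # midpoint exactly 2.5 Mb: start of window 1, interior of window 0
        reads = reads_frame([("chr1", 2_499_963, 2_500_037, "+", "c1")])
        counts = d.count_reads_in_windows(reads, grid, cell_ids=["c1"])
        assert counts.loc["c1", 1] == 1
        assert counts.loc["c1", 0] == 1

    def test_unknown_chromosome_skipped(self, small_genome, caplog):
        grid = d.make_window_grid(small_genome)
        reads = reads_frame(
            [("chrUn", 100, 175, "+", "c1"), ("chr1", 100, 175, "+", "c1")]
        )
        counts = d.count_reads_in_windows(reads, grid, cell_ids=["c1"])
        assert counts.loc["c1"].sum() == 1

    def test_unknown_cell_rejected(self, small_genome):
        grid = d.make_window_grid(small_genome)
        reads = reads_frame([("chr1", 100, 175, "+", "mystery")])
        with pytest.raises(ValueError, match="roster"):
            d.count_reads_in_windows(reads, grid, cell_ids=["c1"])


class TestAberrantWindowFilter:
    def test_zero_window_among_uniform_is_masked(self):
        m = pd.DataFrame(np.full((4, 40), 25), index=list("abcd"))
        m.iloc[:, 17] = 0
        _, mask = d.filter_aberrant_windows(m)
        assert mask[17]
        assert mask.sum() == 1

    def test_full_range_masks_nothing(self, rng):
        m = pd.DataFrame(rng.poisson(50, (5, 30)))
        _, mask = d.filter_aberrant_windows(m, low_quantile=0.0, high_quantile=1.0)
        assert not mask.any()

    def test_matches_quantile_oracle(self, rng):
        m = pd.DataFrame(rng.negative_binomial(10, 0.05, (8, 60)))
        _, mask = d.filter_aberrant_windows(m, 0.1, 0.9)
        totals = m.sum(axis=0).to_numpy()
        lo, hi = np.quantile(totals, [0.1, 0.9])
        expected = (totals < lo) | (totals > hi)
        assert (mask == expected).all()

    @pytest.mark.parametrize("lo,hi", [(-0.1, 0.9), (0.5, 0.5), (0.9, 0.1), (0.0, 1.1)])
    def test_invalid_quantiles_rejected(self, lo, hi):
        m = pd.DataFrame(np.ones((2, 5)))
        with pytest.raises(ValueError):
            d.filter_aberrant_windows(m, lo, hi)


class TestEnrichmentNormalize:
    def test_single_sample_against_itself_unchanged(self, rng):
        x = rng.normal(0, 1, (1, 200))
        out = d.enrichment_normalize(x, anchors=(10, 90))
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_affine_shifted_sample_maps_back_onto_reference(self, rng):
        ref = rng.normal(0, 1, 300)
        shifted = 2.5 * ref + 1.7
        out = d.enrichment_normalize(
            np.stack([ref, shifted]), anchors=(10, 90),
            reference=tuple(np.percentile(ref, [10, 90])),
        )
        np.testing.assert_allclose(out[1], ref, atol=1e-9)
        np.testing.assert_allclose(out[0], ref, atol=1e-9)

    def test_two_small_samples_match_hand_computed_affine_map(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        out = d.enrichment_normalize(np.stack([a, b]), anchors=(50, 90))
        # anchors: a -> (3, 4.6), b -> (30, 46); reference = (16.5, 25.3)
        # hand-solved affine maps
        for row, (s_lo, s_hi) in zip(range(2), [(3.0, 4.6), (30.0, 46.0)]):
            scale = (25.3 - 16.5) / (s_hi - s_lo)
            expected = 16.5 + ([a, b][row] - s_lo) * scale
            np.testing.assert_allclose(out[row], expected, atol=1e-12)
        np.testing.assert_allclose(np.percentile(out, 50, axis=1), 16.5, atol=1e-9)
        np.testing.assert_allclose(np.percentile(out, 90, axis=1), 25.3, atol=1e-9)

    def test_idempotent(self, rng):
        x = rng.normal(0, 2, (6, 150)) + rng.normal(0, 1, (6, 1))
        once = d.enrichment_normalize(x, anchors=(10, 90))
        twice = d.enrichment_normalize(once, anchors=(10, 90))
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_degenerate_sample_rejected_by_name(self):
        x = np.stack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.raises(ValueError, match="flatliner"):
            d.enrichment_normalize(x, sample_names=["ok", "flatliner"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10), st.floats(-5, 5))
    def test_order_preserved_and_anchor_match(self, seed, scale, shift):
        r = np.random.default_rng(seed)
        base = r.normal(0, 1, (3, 80))
        base[1] = base[1] * scale + shift
        out = d.enrichment_normalize(base, anchors=(10, 90))
        lo = np.percentile(out, 10, axis=1)
        hi = np.percentile(out, 90, axis=1)
        assert np.allclose(lo, lo[0], atol=1e-9) and np.allclose(hi, hi[0], atol=1e-9)
        for row in range(3):
            order = np.argsort(base[row], kind="stable")
            assert (np.diff(out[row][order]) >= 0).all()


class TestNormalizeProfiles:
    def test_window_median_exactly_zero_after_centring(self, rng):
        counts = pd.DataFrame(
            rng.poisson(200, (9, 30)), index=[f"c{i}" for i in range(9)]
        )
        prof = d.normalize_copy_profiles(counts, percentile_normalize=False)
        med = np.median(prof.to_numpy(), axis=0)
        np.testing.assert_array_equal(med, np.zeros(30))

    def test_zero_count_cell_dropped_with_warning(self, rng, caplog):
        counts = pd.DataFrame(rng.poisson(100, (4, 20)), index=list("abcd"))
        counts.loc["c"] = 0
        with caplog.at_level("WARNING"):
            prof = d.normalize_copy_profiles(counts)
        assert "c" not in prof.index and len(prof) == 3

    def test_excluded_windows_carry_nan(self, rng):
        counts = pd.DataFrame(rng.poisson(100, (5, 20)))
        mask = np.zeros(20, bool)
        mask[[3, 11]] = True
        prof = d.normalize_copy_profiles(counts, excluded=mask)
        assert prof[3].isna().all() and prof[11].isna().all()
        assert prof.drop(columns=[3, 11]).notna().all().all()

    def test_carrier_mean_near_one_for_doubled_region(self):
        """+2 copies on a diploid baseline -> log2 ratio ~ 1 for carriers."""
        genome = d.gen_genome(4, 100e6, 2)
        carriers = [f"cell{i:03d}" for i in range(7)]
        cnv = d.PlantedCNV("chr2", 40e6, 55e6, +2, frozenset(carriers))
        sim = d.gen_sc_coverage(genome, [cnv], 42, 20_000, dispersion=0.05, seed=4)
        grid = d.make_window_grid(genome)
        counts = d.count_reads_in_windows(sim.reads, grid, cell_ids=sim.cell_ids)
        prof = d.normalize_copy_profiles(counts)
        w = grid.windows
        region = w.index[(w.chrom == "chr2") & (w.start >= 40e6) & (w.end <= 55e6)]
        carrier_mean = prof.loc[carriers, region].mean().mean()
        assert abs(carrier_mean - 1.0) < 0.15
        others = [c for c in sim.cell_ids if c not in carriers]
        assert abs(prof.loc[others, region].mean().mean()) < 0.15


class TestEventCalling:
    @pytest.fixture
    def grid40(self):
        return d.make_window_grid(d.gen_genome(1, 40e6, 2))  # 15 windows

    def test_flat_profile_yields_no_events(self, grid40, rng):
        prof = pd.DataFrame(
            rng.uniform(-0.2, 0.2, (3, len(grid40))), index=list("abc")
        )
        assert len(d.call_cnv_events(prof, grid40)) == 0

    def test_seven_marked_windows_merge_to_20mb_event(self, grid40):
        prof = pd.DataFrame(0.0, index=["c"], columns=range(len(grid40)))
        prof.loc["c", 2:8] = 1.5  # 7 consecutive windows
        ev = d.call_cnv_events(prof, grid40)
        assert len(ev) == 1
        assert ev.span.item() == 20_000_000  # 5 + 6 * 2.5 Mb
        assert ev.direction.item() == "amplification"
        assert ev.n_windows.item() == 7

    def test_three_marked_windows_span_10mb_not_emitted(self, grid40):
        prof = pd.DataFrame(0.0, index=["c"], columns=range(len(grid40)))
        prof.loc["c", 4:6] = 1.5  # span = 5 + 2*2.5 = 10 Mb, strict > required
        assert len(d.call_cnv_events(prof, grid40)) == 0

    def test_masked_windows_bridge_a_run(self, grid40):
        prof = pd.DataFrame(0.0, index=["c"], columns=range(len(grid40)))
        prof.loc["c", [2, 3, 6, 7]] = -1.5
        prof.loc["c", [4, 5]] = np.nan  # excluded windows inside the run
        ev = d.call_cnv_events(prof, grid40)
        assert len(ev) == 1
        assert ev.direction.item() == "deletion"
        assert ev.span.item() == int(7 * 2.5e6 + 5e6 - 2 * 2.5e6)

    def test_infinite_thresholds_give_no_events(self, grid40, rng):
        prof = pd.DataFrame(rng.normal(0, 5, (2, len(grid40))), index=list("ab"))
        ev = d.call_cnv_events(
            prof, grid40, amp_log2=np.inf, del_log2=-np.inf, min_span=0
        )
        assert len(ev) == 0

    def test_zero_thresholds_cover_every_retained_window(self, grid40, rng):
        prof = pd.DataFrame(rng.normal(0, 1, (2, len(grid40))), index=list("ab"))
        ev = d.call_cnv_events(prof, grid40, amp_log2=0.0, del_log2=0.0, min_span=0)
        # every window is in >= 1 event (both directions cover the axis)
        covered = set()
        for row in ev.itertuples():
            w = grid40.windows
            covered |= set(
                w.index[(w.start >= row.start) & (w.end <= row.end)]
            )
        assert covered == set(range(len(grid40)))

    def test_wrong_sign_thresholds_rejected(self, grid40):
        prof = pd.DataFrame(0.0, index=["c"], columns=range(len(grid40)))
        with pytest.raises(ValueError):
            d.call_cnv_events(prof, grid40, amp_log2=-1.0)
        with pytest.raises(ValueError):
            d.call_cnv_events(prof, grid40, del_log2=0.5)


class TestContingency:
    def event_frame(self, cells):
        return pd.DataFrame(
            {"cell_id": cells, "chrom": "chr1", "start": 0, "end": 2,
             "direction": "amplification", "mean_log2": 1.0, "span": 2,
             "n_windows": 1}
        )

    def groups(self, n_pos=42, n_neg=43):
        g = {f"p{i}": "positive" for i in range(n_pos)}
        g.update({f"n{i}": "negative" for i in range(n_neg)})
        return g

    def test_seven_of_42_versus_zero_of_43(self):
        ev = self.event_frame([f"p{i}" for i in range(7)] * 2)  # repeats ignored
        tab = d.event_contingency(ev, self.groups())
        assert tab.to_numpy().tolist() == [[7, 35], [0, 43]]

    def test_no_events(self):
        tab = d.event_contingency(self.event_frame([]), self.groups(5, 4))
        assert tab.to_numpy().tolist() == [[0, 5], [0, 4]]

    def test_every_cell_with_event(self):
        g = self.groups(3, 2)
        tab = d.event_contingency(self.event_frame(list(g)), g)
        assert tab.to_numpy().tolist() == [[3, 0], [2, 0]]

    def test_ungrouped_cell_rejected(self):
        with pytest.raises(ValueError, match="no group"):
            d.event_contingency(self.event_frame(["ghost"]), self.groups(2, 2))
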