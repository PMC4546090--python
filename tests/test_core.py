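import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methstage import core
from conftest import make_table


class TestMergeSymmetricCg:
    def test_dyad_counts_combined(self, tiny_cg_table):
        merged = core.merge_symmetric_cg(tiny_cg_table).data
        dyad = merged[merged["pos"] == 1000].iloc[0]
        assert (dyad["n_meth"], dyad["n_total"]) == (5, 10)
        assert dyad["strand"] == "."

    def test_lone_cg_kept_and_ch_passthrough(self, tiny_cg_table):
        merged = core.merge_symmetric_cg(tiny_cg_table).data
        lone = merged[merged["pos"] == 2000].iloc[0]
        assert (lone["n_meth"], lone["n_total"]) == (4, 6)
        chh = merged[merged["context"] == "CHH"].iloc[0]
        assert (chh["pos"], chh["strand"], chh["n_total"]) == (3000, "+", 8)


class TestCoverageFilter:
    @pytest.mark.parametrize(
        "context,total,kept",
        [
            ("CG", 5, False),   # below the six-read CG floor
            ("CG", 6, True),
            ("CHH", 4, True),   # CH floor is four reads
            ("CHH", 3, False),
            ("CG", 101, False),  # above the 100-read ceiling
            ("CHH", 101, False),
            ("CG", 100, True),
        ],
    )
    def test_thresholds(self, context, total, kept):
        table = make_table([("chr1", 10, ".", context, 0, total)])
        out = core.filter_by_coverage(table)
        assert (len(out) == 1) is kept

    def test_idempotent(self, tiny_cg_table):
        once = core.filter_by_coverage(core.merge_symmetric_cg(tiny_cg_table))
        twice = core.filter_by_coverage(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestNonconversion:
    def test_pooled_estimate(self):
        table = make_table(
            [("lambda", i, "+", "CHH", 1 if i < 5 else 0, 1) for i in range(1000)],
            compartment="spike_in",
        )
        assert core.estimate_nonconversion(table) == pytest.approx(0.005)

    def test_zero_and_empty(self):
        clean = make_table([("lambda", 0, "+", "CHH", 0, 1000)])
        assert core.estimate_nonconversion(clean) == 0.0
        with pytest.raises(ValueError):
            core.estimate_nonconversion(make_table([]))

    def test_binomial_sampling_recovery(self, rng):
        # 1e4 sites at 20x with true failure 0.003: estimate within 3 binomial SE
        failure = 0.003
        depth = 20
        n = 10_000
        meth = rng.binomial(depth, failure, n)
        table = make_table(
            [("lambda", i, "+", "CHH", int(m), depth) for i, m in enumerate(meth)]
        )
        est = core.estimate_nonconversion(table)
        se = np.sqrt(failure * (1 - failure) / (n * depth))
        assert abs(est - failure) < 3 * se

    def test_correction_examples(self):
        assert core.correct_nonconversion(0.10, 0.005) == pytest.approx(0.095 / 0.995)
        assert core.correct_nonconversion(0.005, 0.005) == 0.0
        assert core.correct_nonconversion(0.37, 0.0) == 0.37
        with pytest.raises(ValueError):
            core.correct_nonconversion(0.5, 1.0)

    @given(
        true=st.floats(0, 1, allow_nan=False),
        rate=st.floats(0, 0.99, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=200)
    def test_correction_inverts_mixing_model(self, true, rate):
        observed = true + (1 - true) * rate
        assert core.correct_nonconversion(observed, rate) == pytest.approx(
            true, abs=1e-12
        )


class TestMethylationLevel:
    def test_read_weighted_pooling(self):
        table = make_table(
            [("chr1", 0, ".", "CG", 3, 4), ("chr1", 10, ".", "CG", 10, 100)]
        )
        # pooled-read level, not the mean of per-site fractions
        assert core.methylation_level(table) == pytest.approx(13 / 104)

    def test_region_and_context_subsets(self, tiny_cg_table):
        assert core.methylation_level(tiny_cg_table, context="CG", region=("chr1", 2000, 2001)) == pytest.approx(4 / 6)
        assert np.isnan(core.methylation_level(tiny_cg_table, region=("chr2", 0, 10)))
        assert core.methylation_level(tiny_cg_table, context="CH") == pytest.approx(1 / 8)

    def test_union_bounded_by_parts(self, rng):
        # pooled level of two disjoint regions lies between the parts' levels
        rows = [("chr1", i, ".", "CG", int(rng.integers(0, 11)), 10) for i in range(100)]
        table = make_table(rows)
        left = core.methylation_level(table, region=("chr1", 0, 50))
        right = core.methylation_level(table, region=("chr1", 50, 100))
        whole = core.methylation_level(table, region=("chr1", 0, 100))
        assert min(left, right) <= whole <= max(left, right)


class TestContextBreakdown:
    def test_degenerate_tables(self):
        unmeth = make_table(
            [("chr1", 0, ".", "CG", 0, 10), ("chr1", 5, "+", "CHH", 0, 10)]
        )
        bd = core.context_breakdown(unmeth)
        assert bd["methylated_cg"] == 0 and bd["methylated_ch"] == 0
        assert bd["unmethylated"] == 1.0

        cg_only = make_table([("chr1", 0, ".", "CG", 5, 10)])
        assert core.context_breakdown(cg_only)["methylated_ch"] == 0.0

    def test_fractions_sum_to_one(self, rng):
        rows = [("chr1", i * 3, ".", "CG", int(rng.integers(0, 11)), 10) for i in range(50)]
        rows += [("chr1", i * 3 + 1, "+", "CHH", int(rng.integers(0, 3)), 10) for i in range(200)]
        bd = core.context_breakdown(make_table(rows), nonconversion_rate=0.003)
        assert bd["methylated_cg"] + bd["methylated_ch"] + bd["unmethylated"] == pytest.approx(1.0)
        assert bd["total_methylated"] == pytest.approx(bd["methylated_cg"] + bd["methylated_ch"])


class TestWindowLevels:
    def test_pooled_window_level(self):
        table = make_table(
            [("chr1", 100, ".", "CG", 3, 4), ("chr1", 200, ".", "CG", 5, 6)]
        )
        track = core.window_levels(table, 1000, chrom_sizes={"chr1": 1000})
        assert len(track) == 1
        assert track["level"].iloc[0] == pytest.approx(0.8)
        assert track["n_sites"].iloc[0] == 2

    def test_empty_window_missing_and_tiling_count(self):
        table = make_table([("chr1", 5, ".", "CG", 1, 2)])
        track = core.window_levels(table, 10_000, chrom_sizes={"chr1": 100_000})
        assert len(track) == 10
        assert track["level"].notna().sum() == 1

    def test_min_sites_masks_level(self):
        table = make_table([("chr1", 5, ".", "CG", 1, 2)])
        track = core.window_levels(table, 100, min_sites=2, chrom_sizes={"chr1": 100})
        assert np.isnan(track["level"].iloc[0])

    def test_invalid_geometry(self, tiny_cg_table):
        with pytest.raises(ValueError):
            core.window_levels(tiny_cg_table, 100, step=200)


class TestCorrelateWindows:
    @staticmethod
    def _track(levels):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(levels)) * 10,
                "end": np.arange(1, len(levels) + 1) * 10,
                "level": levels,
            }
        )

    def test_identity_and_reflection(self, rng):
        levels = rng.random(50)
        a = self._track(levels)
        assert core.correlate_windows(a, a) == pytest.approx(1.0)
        assert core.correlate_windows(a, self._track(1 - levels)) == pytest.approx(-1.0)

    def test_independent_tracks_near_zero(self, rng):
        a = self._track(rng.random(1000))
        b = self._track(rng.random(1000))
        assert abs(core.correlate_windows(a, b)) < 0.1

    def test_missing_pairs_dropped(self):
        a = self._track([0.1, 0.2, np.nan, 0.4])
        b = self._track([0.1, np.nan, 0.3, 0.4])
        assert np.isnan(core.correlate_windows(a, b))  # only 2 complete pairs
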