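import numpy as np
import pandas as pd
import pytest

from methstage import dmr
from methstage.io import GeneModel
from conftest import make_table


def _two_stage_tables(positions, frac_a, frac_b, depth=20):
    """Identical site sets in both stages with given per-site fractions."""
    rows_a = [
        ("chr1", p, ".", "CG", int(round(f * depth)), depth)
        for p, f in zip(positions, frac_a)
    ]
    rows_b = [
        ("chr1", p, ".", "CG", int(round(f * depth)), depth)
        for p, f in zip(positions, frac_b)
    ]
    return make_table(rows_a), make_table(rows_b)


class TestWelch:
    def test_identical_vectors_null(self):
        a = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        t, p = dmr.welch_test(a, a)
        assert p == pytest.approx(1.0)

    def test_textbook_formula(self):
        a = np.array([0.9, 0.8, 1.0, 0.85, 0.95])
        b = np.array([0.4, 0.5, 0.45, 0.55, 0.35])
        t, p = dmr.welch_test(a, b)  # t is signed as second group minus first
        # hand computation: means 0.9 / 0.45, both sample variances 0.00625,
        # se = sqrt(2 * 0.00625 / 5) = 0.05, t = -0.45 / 0.05 = -9, df = 8
        assert t == pytest.approx(-9.0)
        assert p == pytest.approx(1.8531e-05, rel=1e-3)

    def test_high_variance_masks_large_delta(self, rng):
        a = 0.8 + rng.normal(0, 0.4, 6).clip(0, 1)
        b = 0.6 + rng.normal(0, 0.4, 6).clip(0, 1)
        _, p = dmr.welch_test(a, b)
        assert p > 0.05

    def test_zero_variance_decisions(self):
        const = np.full(5, 0.8)
        assert dmr.welch_test(const, const.copy())[1] == 1.0
        assert dmr.welch_test(np.full(5, 0.2), const)[1] == 0.0


class TestEnumeration:
    def test_sliding_window_count(self):
        # sites every 100 bp over 2 kb at 20x: windows at starts 0..1500
        positions = np.arange(0, 2000, 100)
        a, b = _two_stage_tables(positions, [0.9] * 20, [0.9] * 20)
        cand = dmr.enumerate_windows(a, b)
        assert len(cand) == 16
        assert list(cand["start"]) == list(range(0, 1600, 100))
        assert (cand["n_sites"] == 5).all()

    def test_site_and_coverage_gates(self):
        positions = np.arange(0, 500, 100)  # five sites in one window
        a, b = _two_stage_tables(positions, [0.9] * 5, [0.4] * 5)
        # drop one site below 10x in stage B only
        b.data.loc[0, "n_total"] = 9
        b.data.loc[0, "n_meth"] = 8
        cand = dmr.enumerate_windows(a, b)
        assert (cand["n_sites"] < 5).all() or cand.empty

        a4, b4 = _two_stage_tables(positions[:4], [0.9] * 4, [0.4] * 4)
        assert dmr.enumerate_windows(a4, b4).empty

    def test_matches_scalar_welch(self):
        rng = np.random.default_rng(7)
        positions = np.arange(0, 500, 100)
        fa, fb = rng.random(5), rng.random(5)
        a, b = _two_stage_tables(positions, fa, fb, depth=100)
        cand = dmr.enumerate_windows(a, b)
        row = cand.iloc[0]
        t_ref, p_ref = dmr.welch_test(
            np.round(fa * 100) / 100, np.round(fb * 100) / 100
        )
        assert row["t"] == pytest.approx(t_ref)
        assert row["p_value"] == pytest.approx(p_ref)


class TestBenjaminiHochberg:
    @staticmethod
    def _oracle(p):
        """Brute-force BH: sort, scale by m/rank, cumulative min from the top."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        scaled = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    def test_worked_example(self):
        q = dmr.adjust_bh([0.001, 0.01, 0.02, 0.5])
        assert q == pytest.approx([0.004, 0.02, 0.0266667, 0.5], rel=1e-5)

    def test_degenerate(self):
        assert dmr.adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])
        assert dmr.adjust_bh([0.123]) == pytest.approx([0.123])

    def test_oracle_equivalence_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 200))
            np.testing.assert_allclose(dmr.adjust_bh(p), self._oracle(p), atol=1e-12)


def _sig_candidates(rows):
    """Candidate frame from (start, end, delta) with overwhelming significance."""
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [r[0] for r in rows],
            "end": [r[1] for r in rows],
            "n_sites": 5,
            "level_a": 0.8,
            "level_b": [0.8 + r[2] / 100 for r in rows],
            "delta": [r[2] for r in rows],
            "t": 50.0,
            "df": 8.0,
            "p_value": 1e-12,
        }
    )


class TestCallDmrs:
    def test_overlapping_windows_merge(self):
        cand = _sig_candidates([(1000, 1500, -40), (1100, 1600, -40), (1400, 1900, -40)])
        out = dmr.call_dmrs(cand)
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (1000, 1900)
        assert out.iloc[0]["n_windows"] == 3
        assert out.iloc[0]["direction"] == "loss"

    def test_isolated_window_has_minimum_length(self):
        out = dmr.call_dmrs(_sig_candidates([(7000, 7500, 35)]))
        assert len(out) == 1
        assert out.iloc[0]["end"] - out.iloc[0]["start"] == 500

    def test_opposite_directions_not_merged(self):
        cand = _sig_candidates([(1000, 1500, 40), (1100, 1600, -40)])
        out = dmr.call_dmrs(cand)
        assert len(out) == 2
        assert set(out["direction"]) == {"gain", "loss"}

    def test_threshold_gates(self):
        cand = _sig_candidates([(0, 500, 25)])  # below the 30-point delta
        assert dmr.call_dmrs(cand).empty
        weak = _sig_candidates([(0, 500, 40)])
        weak["p_value"] = 0.03  # above P < 0.02
        assert dmr.call_dmrs(weak).empty

    def test_lengths_follow_window_arithmetic(self, rng):
        starts = np.sort(rng.choice(np.arange(0, 100_000, 100), 60, replace=False))
        cand = _sig_candidates([(int(s), int(s) + 500, 40) for s in starts])
        out = dmr.call_dmrs(cand)
        lengths = out["end"] - out["start"]
        assert (lengths >= 500).all()
        assert ((lengths - 500) % 100 == 0).all()


class TestLocationAnnotation:
    genes = [GeneModel("G1", "chr1", 10_000, 40_000, "+")]

    def test_promoter_priority_and_intergenic(self):
        dmrs = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1", "chr2"],
                "start": [8_500, 9_900, 20_000, 1_000],
                "end": [9_200, 11_000, 20_500, 1_500],
            }
        )
        loc = dmr.annotate_dmr_location(dmrs, self.genes)
        # promoter is [8000, 10500): fully inside, straddling promoter+body, body-only, off-chrom
        assert list(loc) == ["promoter", "promoter", "intron", "intergenic"]

    def test_exon_annotation_when_available(self):
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [20_000], "end": [20_500]})
        exons = pd.DataFrame({"chrom": ["chr1"], "start": [19_500], "end": [20_200]})
        assert dmr.annotate_dmr_location(dmrs, self.genes, exons=exons).iloc[0] == "exon"

    def test_promoter_subset(self):
        dmrs = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [8_500, 20_000], "end": [9_200, 20_500]}
        )
        assert len(dmr.dmr_promoter_overlap(dmrs, self.genes)) == 1
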