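import numpy as np
import pandas as pd
import pytest

from methstage import core, simulate
from methstage.genes import classify_expression_change


SMALL = dict(chrom_lengths=(200_000,), ch_spacing=None, dmrs_per_archetype=1)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = simulate.simulate_methylome(simulate.SimulationConfig(**SMALL, seed=9))
        b = simulate.simulate_methylome(simulate.SimulationConfig(**SMALL, seed=9))
        for key in a.calls:
            pd.testing.assert_frame_equal(a.calls[key].data, b.calls[key].data)
        pd.testing.assert_frame_equal(a.truth.dmrs, b.truth.dmrs)
        pd.testing.assert_frame_equal(a.truth.pmds, b.truth.pmds)

    def test_different_seeds_differ(self):
        a = simulate.simulate_methylome(simulate.SimulationConfig(**SMALL, seed=1))
        b = simulate.simulate_methylome(simulate.SimulationConfig(**SMALL, seed=2))
        key = next(iter(a.calls))
        assert not a.calls[key].data["n_meth"].equals(b.calls[key].data["n_meth"])


class TestMarginals:
    def test_fully_methylated_without_failures(self):
        config = simulate.SimulationConfig(
            chrom_lengths=(50_000,), ch_spacing=None, pmds_per_chrom=0,
            dmrs_per_archetype=0, cg_background=(1.0, 1.0, 1.0),
            site_concentration=None, hmc_level=0.0,
            conversion_failure_rate=0.0, seed=3,
        )
        sim = simulate.simulate_methylome(config)
        df = sim.calls[("P0.5", 1)].data
        assert (df["n_meth"] == df["n_total"]).all()

    def test_spike_in_recovers_failure_rate(self):
        config = simulate.SimulationConfig(**SMALL, seed=4)
        sim = simulate.simulate_methylome(config)
        pooled = core.pool_tables(list(sim.spike_ins.values()))
        est = core.estimate_nonconversion(pooled)
        n_calls = pooled.data["n_total"].sum()
        se = np.sqrt(0.003 * 0.997 / n_calls)
        assert abs(est - 0.003) < 4 * se

    def test_global_level_matches_planted_mixture(self):
        config = simulate.SimulationConfig(
            chrom_lengths=(2_000_000,), ch_spacing=None, dmrs_per_archetype=0,
            pmds_per_chrom=1, pmd_length_range=(500_000, 500_001),
            conversion_failure_rate=0.0, hmc_level=0.0, depth=15.0, seed=5,
        )
        sim = simulate.simulate_methylome(config)
        table = core.filter_by_coverage(
            core.merge_symmetric_cg(core.pool_tables(sim.stage_tables("P0.5")))
        )
        level = core.methylation_level(table, context="CG")
        pmd_frac = 0.25
        expected = 0.761 * (1 - pmd_frac) + 0.45 * pmd_frac
        assert level == pytest.approx(expected, abs=0.015)

    def test_window_levels_converge_to_truth_at_high_depth(self):
        config = simulate.SimulationConfig(
            chrom_lengths=(500_000,), ch_spacing=None, pmds_per_chrom=0,
            dmrs_per_archetype=0, site_concentration=None, hmc_level=0.0,
            conversion_failure_rate=0.0, depth=100.0, seed=6,
        )
        sim = simulate.simulate_methylome(config)
        table = core.merge_symmetric_cg(core.pool_tables(sim.stage_tables("P0.5")))
        track = core.window_levels(table, 10_000, min_sites=5)
        assert (track["level"] - 0.761).abs().max() < 0.01


class TestOxbsPair:
    def test_expected_bs_oxbs_gap(self):
        config = simulate.SimulationConfig(
            chrom_lengths=(300_000,), ch_spacing=None, pmds_per_chrom=0,
            dmrs_per_archetype=0, depth=30.0, hmc_level=0.10,
            conversion_failure_rate=0.0, seed=7,
        )
        bs, ox, truth = simulate.simulate_oxbs_pair(config)
        bs_level = core.methylation_level(core.pool_tables(bs), context="CG")
        ox_level = core.methylation_level(core.pool_tables(ox), context="CG")
        assert bs_level - ox_level == pytest.approx(0.10, abs=0.01)

    def test_zero_hmc_means_no_gap(self):
        config = simulate.SimulationConfig(
            chrom_lengths=(300_000,), ch_spacing=None, pmds_per_chrom=0,
            dmrs_per_archetype=0, depth=30.0, hmc_level=0.0, seed=8,
        )
        bs, ox, _ = simulate.simulate_oxbs_pair(config)
        gap = core.methylation_level(core.pool_tables(bs)) - core.methylation_level(
            core.pool_tables(ox)
        )
        assert gap == pytest.approx(0.0, abs=0.01)


class TestConfigValidation:
    def test_bad_probability_fatal(self):
        config = simulate.SimulationConfig(cg_background=(1.2, 0.5, 0.5))
        with pytest.raises(ValueError):
            config.validate()

    def test_archetype_arity_fatal(self):
        config = simulate.SimulationConfig(dmr_archetypes={1: (0.5, 0.5)})
        with pytest.raises(ValueError):
            config.validate()


@pytest.fixture(scope="module")
def sim_and_expr():
    config = simulate.SimulationConfig(
        chrom_lengths=(2_000_000, 2_000_000), ch_spacing=None,
        dmrs_per_archetype=5, n_genes=120, seed=10,
    )
    sim = simulate.simulate_methylome(config)
    expr, genes, truth = simulate.simulate_expression(config, sim.truth)
    return config, expr, genes, truth


class TestExpression:

    def test_pmd_genes_silenced(self, sim_and_expr):
        config, expr, genes, truth = sim_and_expr
        log_expr = np.log2(expr + 1)
        pmd_med = log_expr[truth["is_pmd_gene"]].stack().median()
        non_med = log_expr[~truth["is_pmd_gene"]].stack().median()
        assert pmd_med < non_med

    def test_planted_changes_pass_thresholds(self, sim_and_expr):
        config, expr, genes, truth = sim_and_expr
        calls = classify_expression_change(expr, config.stages[0], config.stages[1])
        planted = truth["changed_t1"]
        # every planted change clears the fold/delta thresholds
        assert (calls.loc[planted[planted].index, "call"] != "none").all()

    def test_unchanged_genes_rarely_called(self, sim_and_expr):
        config, expr, genes, truth = sim_and_expr
        calls = classify_expression_change(expr, config.stages[0], config.stages[1])
        quiet = truth[~truth["changed_t1"]].index
        false_rate = (calls.loc[quiet, "call"] != "none").mean()
        assert false_rate < 0.05
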