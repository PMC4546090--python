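"""Recovery scoring of the pipeline against planted simulation truth.

These helpers run the full analysis chain on synthetic data and score it
against the generator's truth tables: false-discovery proportion and
sensitivity of the DMR caller, conversion-rate recovery from the spike-in,
5hmC recovery from a BS/oxBS pair, PMD base-pair Jaccard, and silhouette
selection of the trajectory-cluster count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import TrajectoryClustering, select_k_silhouette
from .core import filter_by_coverage, merge_symmetric_cg, pool_tables
from .core import estimate_nonconversion, window_levels
from .dmr import find_dmrs
from .hydroxy import estimate_5hmc
from .pmd import segment_pmds
from .simulate import (
    TRAJECTORY_ARCHETYPES,
    SimulationConfig,
    simulate_methylome,
    simulate_oxbs_pair,
    two_stage_dmr_config,
)


def _prep(tables):
    return [filter_by_coverage(merge_symmetric_cg(t)) for t in tables]


def _any_overlap(df: pd.DataFrame, chrom: str, start: int, end: int) -> bool:
    sub = df[df["chrom"] == chrom]
    return bool(((sub["start"] < end) & (start < sub["end"])).any())


def dmr_recovery(seed: int, **config_kwargs) -> dict[str, float]:
    """Run the full DMR caller on a two-stage simulation with planted DMRs.

    Returns the false-discovery proportion (called DMRs not overlapping any
    planted region, over all called DMRs; 0 when nothing is called), the
    sensitivity (planted regions overlapped by a call), and the call count.
    """
    config = two_stage_dmr_config(seed=seed, **config_kwargs)
    sim = simulate_methylome(config)
    called = find_dmrs(_prep(sim.stage_tables("A")), _prep(sim.stage_tables("B")))
    truth = sim.truth.dmrs
    if len(called):
        fp = sum(
            not _any_overlap(truth, r.chrom, r.start, r.end) for r in called.itertuples()
        )
        fdp = fp / len(called)
    else:
        fdp = 0.0
    recovered = sum(
        _any_overlap(called, r.chrom, r.start, r.end) for r in truth.itertuples()
    )
    return {
        "fdp": fdp,
        "sensitivity": recovered / len(truth) if len(truth) else float("nan"),
        "n_called": float(len(called)),
    }


def conversion_rate_percent(
    seed: int,
    n_sites: int = 10_000,
    depth: float = 20.0,
    failure_rate: float = 0.003,
) -> float:
    """Estimated bisulfite conversion rate (percent) from a simulated
    fully unmethylated spike-in."""
    config = SimulationConfig(
        chrom_lengths=(10_000,),
        cg_spacing=500.0,
        ch_spacing=None,
        pmds_per_chrom=0,
        dmrs_per_archetype=0,
        replicates=1,
        spike_sites=n_sites,
        spike_depth=depth,
        conversion_failure_rate=failure_rate,
        seed=seed,
    )
    sim = simulate_methylome(config)
    spike = sim.spike_ins[(config.stages[0], 1)]
    return 100.0 * (1.0 - estimate_nonconversion(spike))


def hmc_recovery(
    seed: int,
    genome_length: int = 500_000,
    depth: float = 30.0,
    hmc_level: float = 0.014,
) -> dict[str, float]:
    """Pooled 5hmC estimate from a paired BS/oxBS simulation vs planted truth."""
    config = SimulationConfig(
        chrom_lengths=(genome_length,),
        ch_spacing=None,
        dmrs_per_archetype=2,
        depth=depth,
        hmc_level=hmc_level,
        seed=seed,
    )
    bs, ox, truth = simulate_oxbs_pair(config)
    profile = estimate_5hmc(pool_tables(_prep(bs)), pool_tables(_prep(ox)))
    return {"estimate": profile.pooled_hmc, "truth": truth.hmc_level,
            "n_sites": float(len(profile.sites))}


def pmd_jaccard(seed: int, genome_length: int = 5_000_000, depth: float = 15.0) -> float:
    """Base-pair Jaccard between called and planted PMDs on one simulated
    chromosome."""
    config = SimulationConfig(
        chrom_lengths=(genome_length,),
        ch_spacing=None,
        dmrs_per_archetype=0,
        depth=depth,
        seed=seed,
    )
    sim = simulate_methylome(config)
    pooled = pool_tables(_prep(sim.stage_tables(config.stages[0])))
    track = window_levels(pooled, 10_000, min_sites=5)
    called = segment_pmds(track)
    truth = sim.truth.pmds

    def _mask(df):
        m = np.zeros(genome_length, dtype=bool)
        for r in df.itertuples():
            m[r.start:r.end] = True
        return m

    a, b = _mask(called), _mask(truth)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else float("nan")


def archetype_matrix(
    seed: int, n_per_cluster: int = 100, noise_sd: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Trajectory rows (L0, d1, d2 in points) drawn from the six archetypes
    plus Gaussian noise, with their planted labels."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for label, (l0, l1, l2) in TRAJECTORY_ARCHETYPES.items():
        base = np.array([l0 * 100, (l1 - l0) * 100, (l2 - l1) * 100])
        rows.append(base + rng.normal(0.0, noise_sd, size=(n_per_cluster, 3)))
        labels.extend([label] * n_per_cluster)
    return np.vstack(rows), np.array(labels)


def archetype_purity(seed: int, n_per_cluster: int = 100, noise_sd: float = 5.0) -> float:
    """Cluster/archetype purity of complete-linkage clustering at k = 6."""
    X, truth = archetype_matrix(seed, n_per_cluster, noise_sd)
    pred = TrajectoryClustering(n_clusters=6).fit_predict(X)
    ct = pd.crosstab(pd.Series(truth), pd.Series(pred))
    return float(ct.max(axis=0).sum() / len(truth))


def silhouette_k(seed: int, n_per_cluster: int = 100, noise_sd: float = 5.0) -> int:
    """Silhouette-selected cluster count on six planted archetypes."""
    X, _ = archetype_matrix(seed, n_per_cluster, noise_sd)
    best, _scores = select_k_silhouette(X, range(2, 11))
    return best
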