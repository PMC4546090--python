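"""Synthetic WGBS / RNA-seq data with planted ground truth.

The generator emulates the statistical structure of a stage-resolved WGBS
study of neonatal male germ cells: a mostly highly methylated CG landscape
with megabase-scale partially methylated domains (PMDs), stage-specific
DMRs following six trajectory archetypes, transient genome-wide CH
methylation in the neonatal stage, 5hmC at CG sites, an unmethylated
spike-in carrying the bisulfite conversion-failure signal, and a
two-replicate design at ~15x per-strand depth. Read counts are binomial
(optionally beta-binomial) draws over the latent methylome; observed
methylation mixes in the conversion-failure rate at unmethylated bases:
observed_p = true_p + (1 - true_p) * failure_rate.

Every output is exactly reproducible from (config, seed); the returned
:class:`SimulationTruth` is sufficient to score recovery of all planted
structure without re-deriving anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CallTableMeta, CytosineCallTable, GeneModel

#: Six DMR trajectory archetypes as true CG levels in (first, second, third)
#: stage. 1: high, stable, late loss. 2: high, loss, loss. 5: low, gain,
#: gain. 6: low, stable, late gain. 3 and 4 are approximations (flagged) of
#: the two small groups: 3 gains on the second transition from an
#: intermediate start, 4 shows a transient loss.
TRAJECTORY_ARCHETYPES: dict[int, tuple[float, float, float]] = {
    1: (0.88, 0.88, 0.33),
    2: (0.85, 0.45, 0.20),
    3: (0.45, 0.45, 0.90),  # approximate
    4: (0.80, 0.35, 0.75),  # approximate
    5: (0.15, 0.55, 0.85),
    6: (0.15, 0.15, 0.75),
}

APPROXIMATE_ARCHETYPES = frozenset({3, 4})


@dataclass
class SimulationConfig:
    """Desk-scale emulation of the study design.

    Defaults mirror the study's conditions at reduced genome size: ~15x
    per-strand depth, two replicates, three stages (neonatal P0.5
    prospermatogonia, then Kit- and Kit+ spermatogonia), CG background
    levels near 76%, high transient CH methylation in the first stage only,
    genome-wide 5hmC of 1.4% at CG sites, and a 0.3% conversion-failure
    rate (conversion efficiency 99.7%, above the study's 99.5% floor).
    """

    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    cg_spacing: float = 100.0  # mean inter-dyad distance, bp
    ch_spacing: float | None = 50.0  # mean inter-CH distance per strand; None = no CH
    stages: tuple[str, ...] = ("P0.5", "Kit-", "Kit+")
    cg_background: tuple[float, ...] = (0.761, 0.766, 0.764)
    ch_level: tuple[float, ...] = (0.078, 0.0, 0.0)
    pmds_per_chrom: int = 2
    pmd_length_range: tuple[int, int] = (800_000, 1_500_000)
    pmd_level: float = 0.45
    dmr_archetypes: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(TRAJECTORY_ARCHETYPES)
    )
    dmrs_per_archetype: int = 10
    dmr_width: int = 800
    dmr_n_sites: int = 8
    dmr_site_spacing: int = 100  # matches the DMR screen's window step
    hmc_level: float = 0.014  # true 5hmC at CG sites (BS-visible, oxBS-invisible)
    ch_hmc_level: float = 0.0
    conversion_failure_rate: float = 0.003
    depth: float = 15.0  # mean reads per strand per replicate
    depth_dispersion: float | None = None  # NB size parameter; None = Poisson
    site_concentration: float | None = 50.0  # beta concentration of per-site CG heterogeneity
    replicates: int = 2
    spike_sites: int = 10_000
    spike_depth: float = 20.0
    n_genes: int = 100
    pmd_gene_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        probs = list(self.cg_background) + list(self.ch_level) + [
            self.pmd_level, self.hmc_level, self.ch_hmc_level,
            self.conversion_failure_rate,
        ]
        for levels in self.dmr_archetypes.values():
            if len(levels) != len(self.stages):
                raise ValueError("archetype level tuples must match the number of stages")
            probs.extend(levels)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all configured probabilities must lie in [0, 1]")
        if len(self.cg_background) != len(self.stages) or len(self.ch_level) != len(self.stages):
            raise ValueError("per-stage level tuples must match the number of stages")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.depth <= 0 or self.spike_depth <= 0:
            raise ValueError("depths must be positive")


@dataclass
class SimulationTruth:
    """Planted ground truth for recovery scoring."""

    pmds: pd.DataFrame  # chrom, start, end, level
    dmrs: pd.DataFrame  # chrom, start, end, archetype, level_<stage>..., approximate
    hmc_level: float
    conversion_failure_rate: float
    seed: int
    config: SimulationConfig
    genes: list[GeneModel] | None = None
    gene_truth: pd.DataFrame | None = None  # id, is_pmd_gene, linked, changed_t1, changed_t2


@dataclass
class MethylomeSimulation:
    """Per-stage, per-replicate call tables plus spike-ins and truth."""

    calls: dict[tuple[str, int], CytosineCallTable]
    spike_ins: dict[tuple[str, int], CytosineCallTable]
    truth: SimulationTruth

    def stage_tables(self, stage: str) -> list[CytosineCallTable]:
        return [t for (s, _), t in sorted(self.calls.items()) if s == stage]


# ---------------------------------------------------------------- genome layout


def _dyad_positions(rng, length: int, spacing: float) -> np.ndarray:
    n_est = int(length / spacing * 1.5) + 10
    gaps = np.maximum(rng.exponential(spacing, n_est).astype(np.int64), 2)
    pos = np.cumsum(gaps)
    return pos[pos < length - 1]

def _place_intervals(rng, length, count, len_lo, len_hi) -> list[tuple[int, int]]:
    """Place ``count`` non-overlapping intervals by carving the chromosome
    into equal blocks and offsetting within each."""
    out = []
    block = length // max(count, 1)
    for i in range(count):
        ilen = int(rng.integers(len_lo, len_hi + 1))
        if ilen >= block:
            ilen = block // 2
        start = int(i * block + rng.integers(0, block - ilen))
        out.append((start, start + ilen))
    return out


def _plant_layout(config: SimulationConfig, rng) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Decide dyad positions, PMD intervals and DMR sites for every chromosome.

    Returns (per-chrom layout dict, pmd truth frame, dmr truth frame).
    DMR sites are planted at regular spacing inside each DMR interval,
    replacing any background dyads there, so each DMR carries exactly
    ``dmr_n_sites`` CG dyads.
    """
    n_stages = len(config.stages)
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    layout: dict[str, dict] = {}
    pmd_rows, dmr_rows = [], []

    arche_labels = sorted(config.dmr_archetypes)
    dmr_queue = [a for a in arche_labels for _ in range(config.dmrs_per_archetype)]
    rng.shuffle(dmr_queue)
    per_chrom = np.array_split(np.array(dmr_queue), len(chrom_names))

    for chrom, length, chrom_dmrs in zip(chrom_names, config.chrom_lengths, per_chrom):
        pmds = _place_intervals(
            rng, length, config.pmds_per_chrom, *config.pmd_length_range
        ) if config.pmds_per_chrom else []
        for s, e in pmds:
            pmd_rows.append({"chrom": chrom, "start": s, "end": e, "level": config.pmd_level})

        dyads = _dyad_positions(rng, length, config.cg_spacing)

        # candidate DMR anchors: outside PMDs, away from chromosome ends,
        # pairwise separation >= 10 kb
        dmr_intervals = []
        guard = 10_000
        n_want = len(chrom_dmrs)
        attempts = 0
        while len(dmr_intervals) < n_want and attempts < 10_000:
            attempts += 1
            q = int(rng.integers(guard, length - guard - config.dmr_width))
            if any(q < pe + guard and ps - guard < q + config.dmr_width for ps, pe in pmds):
                continue
            if any(abs(q - s) < guard for s, _ in dmr_intervals):
                continue
            dmr_intervals.append((q, q + config.dmr_width))
        dmr_intervals.sort()

        spacing = config.dmr_site_spacing
        if (config.dmr_n_sites - 1) * spacing >= config.dmr_width:
            spacing = max((config.dmr_width - 2) // max(config.dmr_n_sites - 1, 1), 2)
        dmr_site_pos, dmr_site_levels = [], []
        keep = np.ones(len(dyads), dtype=bool)
        for (s, e), arche in zip(dmr_intervals, chrom_dmrs):
            sites = s + spacing * np.arange(config.dmr_n_sites)
            keep &= ~((dyads >= s - 4) & (dyads < e + 4))
            dmr_site_pos.append(sites)
            levels = config.dmr_archetypes[int(arche)]
            dmr_site_levels.append(np.tile(levels, (config.dmr_n_sites, 1)))
            row = {
                "chrom": chrom, "start": int(s), "end": int(e),
                "archetype": int(arche),
                "approximate": int(arche) in APPROXIMATE_ARCHETYPES,
            }
            for j, st in enumerate(config.stages):
                row[f"level_{st}"] = levels[j]
            dmr_rows.append(row)

        dyads = dyads[keep]
        in_pmd = np.zeros(len(dyads), dtype=bool)
        for s, e in pmds:
            in_pmd |= (dyads >= s) & (dyads < e)

        # latent per-site CG levels, shared across stages up to the stage shift
        base = np.array(config.cg_background, dtype=float)
        site_mean = np.where(in_pmd, config.pmd_level, base[0])
        if config.site_concentration is not None:
            c = config.site_concentration
            u = rng.beta(np.maximum(site_mean * c, 1e-3), np.maximum((1 - site_mean) * c, 1e-3))
        else:
            u = site_mean
        levels = np.empty((len(dyads), n_stages))
        for j in range(n_stages):
            shift = np.where(in_pmd, 0.0, base[j] - base[0])
            levels[:, j] = np.clip(u + shift, 0.0, 1.0)

        if dmr_site_pos:
            all_pos = np.concatenate([dyads] + dmr_site_pos)
            all_lvl = np.concatenate([levels] + dmr_site_levels, axis=0)
            order = np.argsort(all_pos, kind="mergesort")
            dyads, levels = all_pos[order], all_lvl[order]

        entry = {"length": length, "cg_pos": dyads, "cg_levels": levels}

        if config.ch_spacing is not None:
            ch_levels = np.array(config.ch_level, dtype=float)
            cg_occupied = np.union1d(dyads, dyads + 1)
            for strand in "+-":
                pos = _dyad_positions(rng, length, config.ch_spacing)
                pos = pos[~np.isin(pos, cg_occupied)]
                context = np.where(rng.random(len(pos)) < 1 / 3, "CHG", "CHH")
                entry[f"ch_pos_{strand}"] = pos
                entry[f"ch_context_{strand}"] = context
                entry["ch_levels"] = ch_levels
        layout[chrom] = entry

    pmd_truth = pd.DataFrame(pmd_rows, columns=["chrom", "start", "end", "level"])
    dmr_cols = ["chrom", "start", "end", "archetype", "approximate"] + [
        f"level_{st}" for st in config.stages
    ]
    dmr_truth = (
        pd.DataFrame(dmr_rows, columns=dmr_cols)
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
        if dmr_rows
        else pd.DataFrame(columns=dmr_cols)
    )
    return layout, pmd_truth, dmr_truth


# ------------------------------------------------------------------ read draws


def _draw_depth(rng, n: int, mean: float, dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mean, n)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, n)


def _observe(rng, true_p: np.ndarray, depth: np.ndarray, failure: float) -> np.ndarray:
    observed_p = true_p + (1.0 - true_p) * failure
    return rng.binomial(depth, observed_p)


def _emit_sample(rng, layout, config: SimulationConfig, stage_idx: int,
                 include_hmc: bool = True) -> pd.DataFrame:
    """One replicate's call table rows for one stage.

    With ``include_hmc`` the planted 5hmC rides on top of the latent 5mC
    level (bisulfite reads both marks as methylated); the oxBS arm passes
    ``include_hmc=False`` to observe 5mC only.
    """
    frames = []
    fail = config.conversion_failure_rate
    cg_extra = config.hmc_level if include_hmc else 0.0
    ch_extra = config.ch_hmc_level if include_hmc else 0.0
    for chrom, entry in layout.items():
        pos = entry["cg_pos"]
        true_p = np.clip(entry["cg_levels"][:, stage_idx] + cg_extra, 0.0, 1.0)
        for strand, offset in (("+", 0), ("-", 1)):
            depth = _draw_depth(rng, len(pos), config.depth, config.depth_dispersion)
            meth = _observe(rng, true_p, depth, fail)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos + offset,
                        "strand": strand,
                        "context": "CG",
                        "n_meth": meth,
                        "n_total": depth,
                    }
                )
            )
        if config.ch_spacing is not None:
            ch_true = min(entry["ch_levels"][stage_idx] + ch_extra, 1.0)
            for strand in "+-":
                cpos = entry[f"ch_pos_{strand}"]
                depth = _draw_depth(rng, len(cpos), config.depth, config.depth_dispersion)
                meth = _observe(rng, np.full(len(cpos), ch_true), depth, fail)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": cpos,
                            "strand": strand,
                            "context": entry[f"ch_context_{strand}"],
                            "n_meth": meth,
                            "n_total": depth,
                        }
                    )
                )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _emit_spike(rng, config: SimulationConfig) -> pd.DataFrame:
    n = config.spike_sites
    depth = _draw_depth(rng, n, config.spike_depth, config.depth_dispersion)
    meth = _observe(rng, np.zeros(n), depth, config.conversion_failure_rate)
    context = np.where(
        rng.random(n) < 0.08, "CG", np.where(rng.random(n) < 0.3, "CHG", "CHH")
    )
    return pd.DataFrame(
        {
            "chrom": "lambda",
            "pos": np.arange(n, dtype=np.int64),
            "strand": "+",
            "context": context,
            "n_meth": meth,
            "n_total": depth,
        }
    )


# ------------------------------------------------------------------- top level


def simulate_methylome(config: SimulationConfig | None = None) -> MethylomeSimulation:
    """Generate BS call tables for every stage and replicate, with spike-ins.

    The plain BS methylome includes the planted 5hmC on top of the CG level
    (bisulfite cannot distinguish the two marks).
    """
    config = config or SimulationConfig()
    config.validate()
    root = np.random.default_rng(config.seed)
    layout_rng, emit_seed = root.spawn(1)[0], root.integers(2**31)
    layout, pmd_truth, dmr_truth = _plant_layout(config, layout_rng)
    truth = SimulationTruth(
        pmds=pmd_truth,
        dmrs=dmr_truth,
        hmc_level=config.hmc_level,
        conversion_failure_rate=config.conversion_failure_rate,
        seed=config.seed,
        config=config,
    )
    calls, spikes = {}, {}
    emit_root = np.random.default_rng(emit_seed)
    for stage_idx, stage in enumerate(config.stages):
        for rep in range(1, config.replicates + 1):
            rng = emit_root.spawn(1)[0]
            df = _emit_sample(rng, layout, config, stage_idx, include_hmc=True)
            meta = CallTableMeta(assay="BS", compartment="genome", stage=stage, replicate=rep)
            calls[(stage, rep)] = CytosineCallTable(df, meta)
            spike_df = _emit_spike(rng, config)
            spikes[(stage, rep)] = CytosineCallTable(
                spike_df,
                CallTableMeta(assay="BS", compartment="spike_in", stage=stage, replicate=rep),
            )
    return MethylomeSimulation(calls=calls, spike_ins=spikes, truth=truth)


def simulate_oxbs_pair(
    config: SimulationConfig | None = None, stage: str | None = None
) -> tuple[list[CytosineCallTable], list[CytosineCallTable], SimulationTruth]:
    """Paired BS and oxBS call tables for one stage (default: the first).

    BS observes 5mC + 5hmC; oxBS observes 5mC only. The planted 5hmC level
    rides on top of the latent CG methylation, so E[BS - oxBS] equals the
    configured ``hmc_level`` at every CG site.
    """
    config = config or SimulationConfig()
    config.validate()
    if config.hmc_level + max(
        max(levels) for levels in ([config.cg_background] + list(config.dmr_archetypes.values()))
    ) > 1.0 + 1e-9:
        raise ValueError("5mC + 5hmC exceeds 1 at some sites")
    stage = stage or config.stages[0]
    stage_idx = list(config.stages).index(stage)
    root = np.random.default_rng(config.seed)
    layout_rng, emit_seed = root.spawn(1)[0], root.integers(2**31)
    layout, pmd_truth, dmr_truth = _plant_layout(config, layout_rng)
    truth = SimulationTruth(
        pmds=pmd_truth, dmrs=dmr_truth, hmc_level=config.hmc_level,
        conversion_failure_rate=config.conversion_failure_rate,
        seed=config.seed, config=config,
    )
    emit_root = np.random.default_rng(emit_seed)
    bs_tables, oxbs_tables = [], []
    for rep in range(1, config.replicates + 1):
        rng = emit_root.spawn(1)[0]
        bs = _emit_sample(rng, layout, config, stage_idx, include_hmc=True)
        ox = _emit_sample(rng, layout, config, stage_idx, include_hmc=False)
        bs_tables.append(
            CytosineCallTable(bs, CallTableMeta("BS", "genome", stage, rep))
        )
        oxbs_tables.append(
            CytosineCallTable(ox, CallTableMeta("oxBS", "genome", stage, rep))
        )
    return bs_tables, oxbs_tables, truth


def simulate_genes(config: SimulationConfig, truth: SimulationTruth) -> list[GeneModel]:
    """Gene models with a configured fraction of promoters inside PMDs."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    n_pmd = int(round(config.n_genes * config.pmd_gene_fraction))
    genes: list[GeneModel] = []
    pmds = truth.pmds
    for i in range(config.n_genes):
        gid = f"gene{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(5_000, 60_000))
        if i < n_pmd and len(pmds):
            seg = pmds.iloc[int(rng.integers(len(pmds)))]
            lo = int(seg.start) + 3_000
            hi = max(int(seg.end) - glen - 3_000, lo + 1)
            start = int(rng.integers(lo, hi))
            chrom = seg.chrom
        else:
            ci = int(rng.integers(len(chrom_names)))
            chrom = chrom_names[ci]
            start = int(rng.integers(10_000, config.chrom_lengths[ci] - glen - 10_000))
        genes.append(GeneModel(gid, chrom, start, start + glen, strand))
    return genes


def simulate_expression(
    config: SimulationConfig,
    truth: SimulationTruth,
    genes: list[GeneModel] | None = None,
    p_change_linked: float = 0.5,
    p_change_null: float = 0.02,
) -> tuple[pd.DataFrame, list[GeneModel], pd.DataFrame]:
    """FPKM table per stage with PMD silencing and DMR-linked changes.

    PMD genes (promoter inside a planted PMD) draw from a low-FPKM
    distribution in every stage. Genes whose regulatory domain overlaps a
    planted DMR change between consecutive stages with probability
    ``p_change_linked`` (vs ``p_change_null`` for the rest), with effect
    sizes clearing the fold > 2 and delta-FPKM > 5 thresholds.

    Returns (expression frame, gene models, per-gene truth frame); the
    truth frame is also attached to ``truth.gene_truth``.
    """
    from .genes import build_regulatory_domains, link_dmrs_to_genes
    from .pmd import assign_pmd_genes

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    if genes is None:
        genes = simulate_genes(config, truth)
    pmd_labels = assign_pmd_genes(genes, truth.pmds)
    domains = build_regulatory_domains(genes)
    links = link_dmrs_to_genes(truth.dmrs, domains)
    linked_ids = {gid for ids in links.values() for gid in ids}

    n_stages = len(config.stages)
    rows, truth_rows = [], []
    for g in genes:
        is_pmd = pmd_labels[g.id] == "PMD gene"
        linked = g.id in linked_ids
        if is_pmd:
            base = float(rng.lognormal(np.log(0.4), 0.8))
        else:
            base = float(rng.lognormal(np.log(10.0), 1.0))
        vals = [base]
        changed = []
        p_change = p_change_linked if linked else p_change_null
        for _ in range(n_stages - 1):
            cur = vals[-1]
            if rng.random() < p_change:
                factor = float(rng.uniform(3.0, 6.0))
                # a downward change can only clear the 5-FPKM delta from a
                # high enough baseline; low-expressed genes change upward
                if rng.random() < 0.5 and cur - cur / factor > 5.0:
                    new = cur / factor
                else:
                    new = cur * factor
                    if new - cur <= 5.0:
                        new = cur + 6.0 + factor
                changed.append(True)
            else:
                new = cur * float(rng.lognormal(0.0, 0.03))
                changed.append(False)
            vals.append(new)
        rows.append([g.id] + vals)
        truth_rows.append(
            {"id": g.id, "is_pmd_gene": is_pmd, "linked": linked,
             **{f"changed_t{j + 1}": changed[j] for j in range(n_stages - 1)}}
        )
    expr = pd.DataFrame(rows, columns=["id"] + list(config.stages)).set_index("id")
    gene_truth = pd.DataFrame(truth_rows).set_index("id")
    truth.genes = genes
    truth.gene_truth = gene_truth
    return expr, genes, gene_truth


def two_stage_dmr_config(
    seed: int,
    genome_length: int = 5_000_000,
    n_dmrs: int = 100,
    delta: float = 0.40,
    background: float = 0.80,
    depth: float = 15.0,
    replicates: int = 2,
) -> SimulationConfig:
    """Config for DMR-caller calibration: two stages with identical
    methylomes except ``n_dmrs`` planted regions differing by ``delta``."""
    return SimulationConfig(
        chrom_lengths=(genome_length,),
        stages=("A", "B"),
        cg_background=(background, background),
        ch_level=(0.0, 0.0),
        ch_spacing=None,
        pmds_per_chrom=0,
        dmr_archetypes={1: (background + 0.05, background + 0.05 - delta)},
        dmrs_per_archetype=n_dmrs,
        depth=depth,
        replicates=replicates,
        seed=seed,
    )
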