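"""Site filtering, strand merging, conversion correction and methylation levels.

All levels are pooled-read fractions (sum of methylated reads over sum of
total reads), the convention used for genome-wide WGBS summaries. Per-site
fractions appear only where a downstream test needs a vector of sites.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import CytosineCallTable, CallTableMeta

# coverage filters applied to strand-merged tables
MIN_CG_COVERAGE = 6
MIN_CH_COVERAGE = 4
MAX_COVERAGE = 100

CH_CONTEXTS = ("CHG", "CHH")


@dataclass
class MethylomeSample:
    """A filtered genome call table plus its spike-in and nonconversion rate."""

    calls: CytosineCallTable
    spike_in: CytosineCallTable | None
    nonconversion_rate: float
    stage: str | None = None
    replicate: str | int | None = None
    assay: str = "BS"


def merge_symmetric_cg(table: CytosineCallTable) -> CytosineCallTable:
    """Combine counts from the two strands of each CG dyad.

    The plus-strand cytosine at position p and the minus-strand cytosine at
    p+1 report the same CpG; their counts are summed into one strand-free
    record anchored at the plus-strand position p. A CG covered on only one
    strand is kept as a single record (anchored at its plus-strand dyad
    coordinate). Non-CG records pass through unchanged.
    """
    df = table.data
    is_cg = df["context"] == "CG"
    cg = df[is_cg]
    rest = df[~is_cg]
    if len(cg) == 0:
        return CytosineCallTable(df.copy(), table.meta)
    dyad = cg["pos"].to_numpy(copy=True)
    minus = (cg["strand"] == "-").to_numpy()
    dyad[minus] -= 1
    merged = (
        pd.DataFrame(
            {
                "chrom": cg["chrom"].to_numpy(),
                "pos": dyad,
                "n_meth": cg["n_meth"].to_numpy(),
                "n_total": cg["n_total"].to_numpy(),
            }
        )
        .groupby(["chrom", "pos"], sort=False, as_index=False)
        .sum()
    )
    merged["strand"] = "."
    merged["context"] = "CG"
    merged = merged[["chrom", "pos", "strand", "context", "n_meth", "n_total"]]
    out = pd.concat([merged, rest], ignore_index=True)
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return CytosineCallTable(out, table.meta)


def filter_by_coverage(
    table: CytosineCallTable,
    min_cg: int = MIN_CG_COVERAGE,
    min_ch: int = MIN_CH_COVERAGE,
    max_coverage: int = MAX_COVERAGE,
) -> CytosineCallTable:
    """Apply the coverage filters: CG >= min_cg, CH >= min_ch, all <= max_coverage.

    Idempotent; expects CG records already strand-merged so the CG cutoff
    refers to dyad coverage.
    """
    df = table.data
    is_cg = df["context"] == "CG"
    keep = (
        ((is_cg & (df["n_total"] >= min_cg)) | (~is_cg & (df["n_total"] >= min_ch)))
        & (df["n_total"] <= max_coverage)
    )
    return CytosineCallTable(df[keep].reset_index(drop=True), table.meta)


def estimate_nonconversion(spike_table: CytosineCallTable) -> float:
    """Pooled apparent methylation of the unmethylated spike-in.

    The spike-in (lambda phage) is fully unmethylated, so any methylated
    call is a bisulfite conversion failure. Returns sum(n_meth)/sum(n_total)
    over all spike-in cytosines; the conversion rate is 1 minus this value.
    """
    df = spike_table.data
    total = int(df["n_total"].sum())
    if total == 0:
        raise ValueError("spike-in table has no covered cytosines; cannot estimate nonconversion")
    return float(df["n_meth"].sum()) / total


def correct_nonconversion(observed_level: float | np.ndarray, rate: float):
    """Invert the conversion-failure mixing model.

    A truly unmethylated cytosine is read as methylated with probability
    ``rate``, so observed = true + (1 - true) * rate. The inverse,
    (observed - rate) / (1 - rate), is clamped at 0.
    """
    if rate >= 1:
        raise ValueError("nonconversion rate must be < 1")
    if rate < 0:
        raise ValueError("nonconversion rate must be >= 0")
    corrected = (np.asarray(observed_level, dtype=float) - rate) / (1.0 - rate)
    corrected = np.maximum(corrected, 0.0)
    if np.isscalar(observed_level) or np.ndim(observed_level) == 0:
        return float(corrected)
    return corrected


def pool_tables(tables: list[CytosineCallTable]) -> CytosineCallTable:
    """Pool replicate call tables at the count level (per chrom/pos/strand/context)."""
    if not tables:
        raise ValueError("no tables to pool")
    df = pd.concat([t.data for t in tables], ignore_index=True)
    pooled = (
        df.groupby(["chrom", "pos", "strand", "context"], sort=False, as_index=False)[
            ["n_meth", "n_total"]
        ]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    meta = tables[0].meta
    return CytosineCallTable(pooled, CallTableMeta(meta.assay, meta.compartment, meta.stage, None))


def methylation_level(
    table: CytosineCallTable,
    region: tuple[str, int, int] | None = None,
    context: str | None = None,
) -> float:
    """Pooled-read methylation level of a table, region and/or context subset.

    ``context`` may be 'CG', 'CHG', 'CHH' or 'CH' (= CHG + CHH). Returns NaN
    when no record qualifies.
    """
    df = table.data
    if context is not None:
        if context == "CH":
            df = df[df["context"].isin(CH_CONTEXTS)]
        else:
            df = df[df["context"] == context]
    if region is not None:
        chrom, start, end = region
        df = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)]
    total = df["n_total"].sum()
    if total == 0:
        return float("nan")
    return float(df["n_meth"].sum() / total)


def context_breakdown(
    table: CytosineCallTable, nonconversion_rate: float = 0.0
) -> dict[str, float]:
    """Fractions of all (covered) cytosines that are methylated at CG, at CH, or unmethylated.

    Methylation levels per context are nonconversion-corrected before being
    weighted by the share of cytosine sites in each context, so the three
    headline fractions sum to 1. Also reports per-dinucleotide-class levels
    (CHG/CHH) for the CH breakdown.
    """
    df = table.data
    is_cg = df["context"] == "CG"
    # a strand-merged CG dyad record ('.') stands for two cytosines
    n_cg = int((np.where(df.loc[is_cg, "strand"] == ".", 2, 1)).sum()) if is_cg.any() else 0
    n_ch = int((~is_cg).sum())
    n_all = n_cg + n_ch
    if n_all == 0:
        raise ValueError("empty call table")
    lvl_cg = methylation_level(table, context="CG")
    lvl_ch = methylation_level(table, context="CH")
    lvl_cg = correct_nonconversion(lvl_cg, nonconversion_rate) if n_cg else 0.0
    lvl_ch = correct_nonconversion(lvl_ch, nonconversion_rate) if n_ch else 0.0
    frac_mcg = (n_cg / n_all) * lvl_cg
    frac_mch = (n_ch / n_all) * lvl_ch
    out = {
        "methylated_cg": frac_mcg,
        "methylated_ch": frac_mch,
        "unmethylated": 1.0 - frac_mcg - frac_mch,
        "total_methylated": frac_mcg + frac_mch,
    }
    for ctx in CH_CONTEXTS:
        lvl = methylation_level(table, context=ctx)
        if not np.isnan(lvl):
            out[f"level_{ctx}"] = correct_nonconversion(lvl, nonconversion_rate)
    return out


def window_levels(
    table: CytosineCallTable,
    window_size: int,
    step: int | None = None,
    min_sites: int = 1,
    context: str | None = "CG",
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Pooled methylation level in fixed windows (tiling or sliding).

    Windows start at 0 and advance by ``step`` (default: ``window_size``,
    i.e. nonoverlapping tiling). Windows with fewer than ``min_sites``
    qualifying sites get a missing (NaN) level but are still emitted, so
    tracks from different samples share a grid. Returns a frame with
    chrom, start, end, level, n_sites, n_reads.
    """
    if step is None:
        step = window_size
    if step < 1 or window_size < step:
        raise ValueError("require window_size >= step >= 1")
    df = table.data
    if context is not None:
        if context == "CH":
            df = df[df["context"].isin(CH_CONTEXTS)]
        else:
            df = df[df["context"] == context]
    frames = []
    chroms = (
        sorted(chrom_sizes) if chrom_sizes is not None else sorted(df["chrom"].unique())
    )
    for chrom in chroms:
        sub = df[df["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        if chrom_sizes is not None:
            length = chrom_sizes[chrom]
        elif len(pos):
            length = int(pos[-1]) + 1
        else:
            continue
        starts = np.arange(0, max(length - window_size, 0) + 1, step, dtype=np.int64)
        if len(starts) == 0:
            starts = np.array([0], dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_size, side="left")
        cmeth = np.concatenate([[0], np.cumsum(sub["n_meth"].to_numpy())])
        ctot = np.concatenate([[0], np.cumsum(sub["n_total"].to_numpy())])
        n_sites = hi - lo
        n_reads = ctot[hi] - ctot[lo]
        meth = cmeth[hi] - cmeth[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(n_reads > 0, meth / np.maximum(n_reads, 1), np.nan)
        level = np.where(n_sites >= min_sites, level, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window_size,
                    "level": level,
                    "n_sites": n_sites,
                    "n_reads": n_reads,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "level", "n_sites", "n_reads"])
    return pd.concat(frames, ignore_index=True)


def correlate_windows(
    track_a: pd.DataFrame, track_b: pd.DataFrame, method: str = "pearson"
) -> float:
    """Correlation between two window tracks on a shared grid.

    Pairs where either level is missing are dropped; returns NaN with fewer
    than three complete pairs.
    """
    merged = track_a.merge(
        track_b, on=["chrom", "start", "end"], suffixes=("_a", "_b")
    ).dropna(subset=["level_a", "level_b"])
    if len(merged) < 3:
        return float("nan")
    a = merged["level_a"].to_numpy()
    b = merged["level_b"].to_numpy()
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def prepare_sample(
    genome_table: CytosineCallTable,
    spike_table: CytosineCallTable | None = None,
    stage: str | None = None,
    replicate: str | int | None = None,
) -> MethylomeSample:
    """Standard preprocessing: strand-merge CGs, apply coverage filters,
    estimate nonconversion from the spike-in."""
    merged = merge_symmetric_cg(genome_table)
    filtered = filter_by_coverage(merged)
    rate = estimate_nonconversion(spike_table) if spike_table is not None else 0.0
    return MethylomeSample(
        calls=filtered,
        spike_in=spike_table,
        nonconversion_rate=rate,
        stage=stage or genome_table.meta.stage,
        replicate=replicate if replicate is not None else genome_table.meta.replicate,
        assay=genome_table.meta.assay,
    )
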