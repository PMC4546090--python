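"""Stage-specific DMR calling.

Two stages are compared in 500-bp windows sliding by 100 bp. A window is a
candidate when it holds at least five CG sites covered at least ten times in
both stages (replicates pooled at the count level). Each candidate gets a
Welch two-sample t-test on the per-site methylation fractions and a pooled
level difference; after genome-wide Benjamini-Hochberg correction, windows
with an absolute difference above 30 percentage points, P below 0.02 and
FDR below 0.05 are significant, and overlapping significant windows of the
same direction are merged into DMRs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CytosineCallTable, GeneModel
from .pmd import promoter_interval

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 500
DEFAULT_STEP = 100
DEFAULT_MIN_SITES = 5
DEFAULT_MIN_SITE_COVERAGE = 10
DEFAULT_DELTA = 30.0  # percentage points
DEFAULT_PMAX = 0.02
DEFAULT_FDR = 0.05

CANDIDATE_COLUMNS = [
    "chrom", "start", "end", "n_sites",
    "level_a", "level_b", "delta", "t", "df", "p_value",
]


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p for two fraction vectors.

    When both groups have zero variance the statistic is undefined; the
    decision is then deterministic: p = 1 for equal means, p = 0 when every
    paired comparison moves in the same direction (which is forced when both
    vectors are constant and unequal).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.info("zero-variance window with unequal means: p set to 0")
        return np.inf if b.mean() > a.mean() else -np.inf, 0.0
    res = stats.ttest_ind(b, a, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _merged_site_frame(
    tables_a: CytosineCallTable | list[CytosineCallTable],
    tables_b: CytosineCallTable | list[CytosineCallTable],
    min_site_coverage: int,
) -> pd.DataFrame:
    """Inner-join the two stages' CG sites, keeping sites covered
    >= min_site_coverage in both (replicates pooled at the count level)."""
    from .core import pool_tables

    if isinstance(tables_a, CytosineCallTable):
        tables_a = [tables_a]
    if isinstance(tables_b, CytosineCallTable):
        tables_b = [tables_b]
    a = pool_tables(tables_a).data
    b = pool_tables(tables_b).data
    a = a[a["context"] == "CG"][["chrom", "pos", "n_meth", "n_total"]]
    b = b[b["context"] == "CG"][["chrom", "pos", "n_meth", "n_total"]]
    m = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    m = m[(m["n_total_a"] >= min_site_coverage) & (m["n_total_b"] >= min_site_coverage)]
    m["f_a"] = m["n_meth_a"] / m["n_total_a"]
    m["f_b"] = m["n_meth_b"] / m["n_total_b"]
    return m.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def enumerate_windows(
    tables_a: CytosineCallTable | list[CytosineCallTable],
    tables_b: CytosineCallTable | list[CytosineCallTable],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_sites: int = DEFAULT_MIN_SITES,
    min_site_coverage: int = DEFAULT_MIN_SITE_COVERAGE,
) -> pd.DataFrame:
    """Enumerate candidate windows and Welch-test each one.

    Windows are anchored at multiples of ``step`` from position 0. Per-site
    fractions enter the t-test; the reported delta is the pooled-read level
    difference (stage B minus stage A) in percentage points. The Welch
    statistic is computed in closed form from windowed moments, which is
    algebraically identical to the per-window two-sample test.
    """
    sites = _merged_site_frame(tables_a, tables_b, min_site_coverage)
    frames = []
    for chrom, sub in sites.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        if len(pos) < min_sites:
            continue
        fa, fb = sub["f_a"].to_numpy(), sub["f_b"].to_numpy()
        cs = {
            "fa": np.concatenate([[0.0], np.cumsum(fa)]),
            "fa2": np.concatenate([[0.0], np.cumsum(fa * fa)]),
            "fb": np.concatenate([[0.0], np.cumsum(fb)]),
            "fb2": np.concatenate([[0.0], np.cumsum(fb * fb)]),
            "ma": np.concatenate([[0], np.cumsum(sub["n_meth_a"].to_numpy())]),
            "ta": np.concatenate([[0], np.cumsum(sub["n_total_a"].to_numpy())]),
            "mb": np.concatenate([[0], np.cumsum(sub["n_meth_b"].to_numpy())]),
            "tb": np.concatenate([[0], np.cumsum(sub["n_total_b"].to_numpy())]),
        }
        first = (int(pos[0]) // step) * step
        starts = np.arange(max(first - window + step, 0), int(pos[-1]) + 1, step, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        n = hi - lo
        ok = n >= min_sites
        if not ok.any():
            continue
        starts, lo, hi, n = starts[ok], lo[ok], hi[ok], n[ok].astype(float)
        mean_a = (cs["fa"][hi] - cs["fa"][lo]) / n
        mean_b = (cs["fb"][hi] - cs["fb"][lo]) / n
        var_a = np.maximum((cs["fa2"][hi] - cs["fa2"][lo]) - n * mean_a**2, 0.0) / (n - 1)
        var_b = np.maximum((cs["fb2"][hi] - cs["fb2"][lo]) - n * mean_b**2, 0.0) / (n - 1)
        level_a = (cs["ma"][hi] - cs["ma"][lo]) / (cs["ta"][hi] - cs["ta"][lo])
        level_b = (cs["mb"][hi] - cs["mb"][lo]) / (cs["tb"][hi] - cs["tb"][lo])
        se2 = var_a / n + var_b / n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean_b - mean_a) / np.sqrt(se2)
            dof = se2**2 / ((var_a / n) ** 2 / (n - 1) + (var_b / n) ** 2 / (n - 1))
            p = 2.0 * stats.t.sf(np.abs(t), dof)
        # both-groups-zero-variance windows: deterministic decision
        degenerate = se2 == 0
        equal = degenerate & (mean_a == mean_b)
        unequal = degenerate & ~equal
        p[equal], t[equal] = 1.0, 0.0
        p[unequal] = 0.0
        t[unequal] = np.sign(mean_b - mean_a)[unequal] * np.inf
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window,
                    "n_sites": n.astype(int),
                    "level_a": level_a,
                    "level_b": level_b,
                    "delta": (level_b - level_a) * 100.0,
                    "t": t,
                    "df": dof,
                    "p_value": p,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def adjust_bh(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving in p)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.array([])
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmrs(
    candidates: pd.DataFrame,
    tables_a: CytosineCallTable | list[CytosineCallTable] | None = None,
    tables_b: CytosineCallTable | list[CytosineCallTable] | None = None,
    delta_threshold: float = DEFAULT_DELTA,
    p_threshold: float = DEFAULT_PMAX,
    q_threshold: float = DEFAULT_FDR,
    min_site_coverage: int = DEFAULT_MIN_SITE_COVERAGE,
) -> pd.DataFrame:
    """Merge significant candidate windows into DMRs.

    BH correction is applied once across all candidates of the comparison.
    Significant windows (|delta| > delta_threshold points, p < p_threshold,
    q < q_threshold) are merged when they overlap and share a direction;
    gain and loss runs are never merged together. Stage levels of each DMR
    are recomputed as pooled-read levels over the merged interval when the
    stage tables are supplied, else as read-weighted means of the
    constituent windows.
    """
    cols = [
        "chrom", "start", "end", "direction", "level_a", "level_b",
        "delta", "q_min", "n_windows",
    ]
    if len(candidates) == 0:
        return pd.DataFrame(columns=cols)
    cand = candidates.copy()
    cand["q_value"] = adjust_bh(cand["p_value"].to_numpy())
    sig = cand[
        (cand["delta"].abs() > delta_threshold)
        & (cand["p_value"] < p_threshold)
        & (cand["q_value"] < q_threshold)
    ].copy()
    if len(sig) == 0:
        return pd.DataFrame(columns=cols)
    sig["direction"] = np.where(sig["delta"] > 0, "gain", "loss")
    sig = sig.sort_values(["chrom", "direction", "start"], kind="mergesort")

    dmrs: list[dict] = []
    for (chrom, direction), grp in sig.groupby(["chrom", "direction"], sort=False):
        start = end = None
        members: list[pd.Series] = []
        for row in grp.itertuples():
            if start is None:
                start, end, members = row.start, row.end, [row]
            elif row.start < end:  # strict overlap merges; abutting windows do not
                end = max(end, row.end)
                members.append(row)
            else:
                dmrs.append(_finish_dmr(chrom, direction, start, end, members))
                start, end, members = row.start, row.end, [row]
        if start is not None:
            dmrs.append(_finish_dmr(chrom, direction, start, end, members))

    out = pd.DataFrame(dmrs, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True)
    if tables_a is not None and tables_b is not None:
        sites = _merged_site_frame(tables_a, tables_b, min_site_coverage)
        la, lb = [], []
        for row in out.itertuples():
            sub = sites[
                (sites["chrom"] == row.chrom)
                & (sites["pos"] >= row.start)
                & (sites["pos"] < row.end)
            ]
            la.append(sub["n_meth_a"].sum() / sub["n_total_a"].sum())
            lb.append(sub["n_meth_b"].sum() / sub["n_total_b"].sum())
        out["level_a"], out["level_b"] = la, lb
        out["delta"] = (out["level_b"] - out["level_a"]) * 100.0
    return out


def _finish_dmr(chrom, direction, start, end, members) -> dict:
    w = np.array([m.n_sites for m in members], dtype=float)
    w = w / w.sum() if w.sum() else None
    level_a = float(np.average([m.level_a for m in members], weights=w))
    level_b = float(np.average([m.level_b for m in members], weights=w))
    return {
        "chrom": chrom,
        "start": int(start),
        "end": int(end),
        "direction": direction,
        "level_a": level_a,
        "level_b": level_b,
        "delta": (level_b - level_a) * 100.0,
        "q_min": float(min(m.q_value for m in members)),
        "n_windows": len(members),
    }


def find_dmrs(
    tables_a,
    tables_b,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_sites: int = DEFAULT_MIN_SITES,
    min_site_coverage: int = DEFAULT_MIN_SITE_COVERAGE,
    delta_threshold: float = DEFAULT_DELTA,
    p_threshold: float = DEFAULT_PMAX,
    q_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """End-to-end DMR screen between two stages (enumerate, test, adjust, merge)."""
    cand = enumerate_windows(
        tables_a, tables_b, window=window, step=step,
        min_sites=min_sites, min_site_coverage=min_site_coverage,
    )
    return call_dmrs(
        cand, tables_a, tables_b,
        delta_threshold=delta_threshold,
        p_threshold=p_threshold,
        q_threshold=q_threshold,
        min_site_coverage=min_site_coverage,
    )


def annotate_dmr_location(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    exons: pd.DataFrame | None = None,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> pd.Series:
    """Label each DMR promoter/exon/intron/intergenic by priority.

    Promoters are strand-aware windows around the TSS. Exon annotation is
    optional (a chrom/start/end frame); without it every non-promoter
    gene-body overlap is labelled intronic.
    """
    labels = []
    for row in dmrs.itertuples():
        label = "intergenic"
        for g in genes:
            if g.chrom != row.chrom:
                continue
            ps, pe = promoter_interval(g, promoter_upstream, promoter_downstream)
            if row.start < pe and ps < row.end:
                label = "promoter"
                break
            if row.start < g.end and g.start < row.end:
                label = "intron"
        if label == "intron" and exons is not None and len(exons):
            hit = exons[
                (exons["chrom"] == row.chrom)
                & (exons["start"] < row.end)
                & (row.start < exons["end"])
            ]
            if len(hit):
                label = "exon"
        labels.append(label)
    return pd.Series(labels, index=dmrs.index, name="location")


def dmr_promoter_overlap(dmrs: pd.DataFrame, genes: list[GeneModel], **kwargs) -> pd.DataFrame:
    """Subset of DMRs overlapping a gene promoter."""
    loc = annotate_dmr_location(dmrs, genes, **kwargs)
    return dmrs[loc == "promoter"]
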