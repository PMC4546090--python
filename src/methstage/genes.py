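"""DMR-to-gene association via basal-plus-extension regulatory domains,
expression-change classification, and enrichment testing.

Each gene gets a basal domain (5 kb upstream to 1 kb downstream of the TSS,
strand-aware) extended up to 1 Mb on each side but truncated at the nearest
neighbouring basal domain. A DMR is linked to every gene whose extended
domain it overlaps. Expression changes between two stages are called when
the fold change exceeds 2.0 AND the absolute FPKM difference exceeds 5.0;
enrichment of change among DMR-linked genes is a Pearson chi-squared test
on the 2x2 table without continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel

logger = logging.getLogger(__name__)

BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000

FOLD_THRESHOLD = 2.0
DELTA_FPKM_THRESHOLD = 5.0


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    basal_start: int
    basal_end: int
    start: int  # extended interval
    end: int


def _basal(gene: GeneModel) -> tuple[int, int]:
    if gene.strand == "+":
        start, end = gene.tss - BASAL_UPSTREAM, gene.tss + BASAL_DOWNSTREAM
    else:
        start, end = gene.tss - BASAL_DOWNSTREAM, gene.tss + BASAL_UPSTREAM
    return max(start, 0), max(end, 0)


def build_regulatory_domains(
    genes: list[GeneModel], chrom_sizes: dict[str, int] | None = None
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains, GREAT-style.

    The extension on each side stops at the 1 Mb cap from the TSS or at the
    nearest flanking gene's basal domain, whichever is closer; a basal
    domain is never truncated. When two neighbouring basal domains overlap
    there is simply no extension between them.
    """
    domains: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, glist in by_chrom.items():
        glist = sorted(glist, key=lambda g: g.tss)
        basals = [_basal(g) for g in glist]
        size = chrom_sizes.get(chrom) if chrom_sizes else None
        for i, g in enumerate(glist):
            bs, be = basals[i]
            left_cap = max(g.tss - MAX_EXTENSION, 0)
            right_cap = g.tss + MAX_EXTENSION
            if size is not None:
                right_cap = min(right_cap, size)
                be = min(be, size)
            # nearest neighbouring basal boundary on each side
            left_limit = max(
                (obe for j, (obs, obe) in enumerate(basals) if j != i and obe <= bs),
                default=0,
            )
            right_limit = min(
                (obs for j, (obs, obe) in enumerate(basals) if j != i and obs >= be),
                default=right_cap,
            )
            start = max(left_cap, left_limit)
            end = min(right_cap, right_limit)
            start = min(start, bs)  # basal is always contained
            end = max(end, be)
            domains.append(RegulatoryDomain(g.id, chrom, bs, be, int(start), int(end)))
    return sorted(domains, key=lambda d: (d.chrom, d.start, d.gene_id))


def link_dmrs_to_genes(
    dmrs: pd.DataFrame, domains: list[RegulatoryDomain]
) -> dict[int, list[str]]:
    """Map each DMR (by frame index) to the genes whose extended regulatory
    domain it overlaps by >= 1 bp. DMRs with no link are reported (logged)
    and mapped to an empty list."""
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    links: dict[int, list[str]] = {}
    n_orphan = 0
    for idx, row in dmrs.iterrows():
        hits = [
            d.gene_id
            for d in by_chrom.get(row["chrom"], [])
            if row["start"] < d.end and d.start < row["end"]
        ]
        links[idx] = sorted(hits)
        n_orphan += not hits
    if n_orphan:
        logger.info("%d DMRs link to no gene (beyond 1 Mb of any TSS)", n_orphan)
    return links


def classify_expression_change(
    expr: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    fold_threshold: float = FOLD_THRESHOLD,
    delta_threshold: float = DELTA_FPKM_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene expression-change call between two stages.

    call = 'up'/'down' (direction of stage B relative to stage A) when the
    fold change (larger / smaller FPKM) exceeds ``fold_threshold`` and the
    absolute difference exceeds ``delta_threshold``; otherwise 'none'.
    When the smaller FPKM is zero the fold change is undefined and the fold
    criterion is treated as satisfied (a gene switching on from zero is
    unambiguously changed if the difference clears the delta threshold).
    """
    a = expr[stage_a].to_numpy(dtype=float)
    b = expr[stage_b].to_numpy(dtype=float)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / lo, np.inf)
    fold = np.where(hi == 0, 1.0, fold)  # 0 -> 0: no change
    delta = np.abs(b - a)
    changed = (fold > fold_threshold) & (delta > delta_threshold)
    call = np.where(~changed, "none", np.where(b > a, "up", "down"))
    return pd.DataFrame(
        {"fold_change": fold, "delta_fpkm": delta, "call": call}, index=expr.index
    )


def enrichment_chisq(
    linked_changed: int, linked_total: int, all_changed: int, all_total: int
) -> tuple[float, float]:
    """Pearson chi-squared (df = 1, no continuity correction) comparing the
    expression-change rate of DMR-linked genes with the rest of the gene set.

    The 2x2 table contrasts linked vs non-linked genes by changed vs
    unchanged; ``all_*`` counts refer to the entire gene set (including the
    linked genes).
    """
    other_changed = all_changed - linked_changed
    other_total = all_total - linked_total
    table = np.array(
        [
            [linked_changed, linked_total - linked_changed],
            [other_changed, other_total - other_changed],
        ]
    )
    if (table < 0).any():
        raise ValueError("inconsistent counts: linked counts exceed totals")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("chi-squared test undefined with an empty margin")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        logger.warning("chi-squared expected cell count < 1; p-value unreliable")
    return float(chi2), float(p)
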