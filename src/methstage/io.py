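"""Readers and writers for the text formats the pipeline touches.

Internally every coordinate is 0-based, half-open (BED convention).
Bismark cytosine reports are 1-based and are shifted on read; BED files
pass through unchanged. Conversion happens only at these boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: dtype schema of a cytosine call table
CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]

VALID_CONTEXTS = frozenset({"CG", "CHG", "CHH"})
VALID_STRANDS = frozenset({"+", "-"})


@dataclass
class CallTableMeta:
    """Provenance of a cytosine call table."""

    assay: str = "BS"  # BS or oxBS
    compartment: str = "genome"  # genome, spike_in, repeat_consensus:<name>
    stage: str | None = None
    replicate: str | int | None = None


@dataclass
class CytosineCallTable:
    """Per-cytosine methylated/total read counts with strand and context.

    ``data`` holds one row per (chrom, pos, strand) with columns
    chrom, pos (0-based), strand ('+'/'-' or '.' once strand-merged),
    context (CG/CHG/CHH), n_meth, n_total.
    """

    data: pd.DataFrame
    meta: CallTableMeta = field(default_factory=CallTableMeta)

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"call table missing columns: {missing}")
        bad = self.data["n_meth"] > self.data["n_total"]
        if bad.any():
            raise ValueError("n_meth exceeds n_total in call table")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_empty(self) -> bool:
        return len(self.data) == 0


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware transcription start/end sites."""

    id: str
    chrom: str
    start: int  # 0-based, half-open interval [start, end)
    end: int
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


def read_cytosine_report(
    path: str | Path,
    assay: str = "BS",
    compartment: str = "genome",
    stage: str | None = None,
    replicate: str | int | None = None,
) -> CytosineCallTable:
    """Read a Bismark-style cytosine report into a call table.

    Expected columns (TAB-separated, no header): chrom, 1-based position,
    strand, methylated count, unmethylated count, context. Positions are
    shifted to 0-based on read. Malformed rows (negative counts, unknown
    strand or context, non-numeric fields) are dropped with a logged line
    number.
    """
    path = Path(path)
    rows: list[tuple] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                parts = line.split()
            if len(parts) < 6:
                logger.warning("%s:%d: too few fields, row skipped", path, lineno)
                n_bad += 1
                continue
            chrom, pos_s, strand, meth_s, unmeth_s, context = parts[:6]
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError:
                logger.warning("%s:%d: non-numeric field, row skipped", path, lineno)
                n_bad += 1
                continue
            if meth < 0 or unmeth < 0 or strand not in VALID_STRANDS or context not in VALID_CONTEXTS:
                logger.warning("%s:%d: invalid strand/context/count, row skipped", path, lineno)
                n_bad += 1
                continue
            rows.append((chrom, pos - 1, strand, context, meth, meth + unmeth))
    if not rows:
        logger.warning("%s: no valid cytosine records", path)
        df = pd.DataFrame(columns=CALL_COLUMNS)
        df = df.astype({"pos": np.int64, "n_meth": np.int64, "n_total": np.int64})
    else:
        df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if n_bad:
        logger.warning("%s: %d malformed rows rejected", path, n_bad)
    meta = CallTableMeta(assay=assay, compartment=compartment, stage=stage, replicate=replicate)
    return CytosineCallTable(df, meta)


def write_cytosine_report(table: CytosineCallTable, path: str | Path) -> None:
    """Write a call table back to the Bismark cytosine-report dialect (1-based)."""
    df = table.data
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] + 1,
            "strand": df["strand"],
            "meth": df["n_meth"],
            "unmeth": df["n_total"] - df["n_meth"],
            "context": df["context"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write intervals (chrom/start/end + optional extra columns) as BED.

    Coordinates are written as-is (internal coordinates already follow the
    BED 0-based half-open convention).
    """
    for col in ("chrom", "start", "end"):
        if col not in intervals.columns:
            raise ValueError(f"interval frame missing column {col!r}")
    if len(intervals) and (intervals["end"] <= intervals["start"]).any():
        raise ValueError("intervals with end <= start cannot be written as BED")
    cols = ["chrom", "start", "end"] + [
        c for c in intervals.columns if c not in ("chrom", "start", "end")
    ]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    """Read a BED file into a chrom/start/end frame (extra columns kept)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    base = ["chrom", "start", "end"]
    if names is None:
        names = base + [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = names[: df.shape[1]]
    return df.astype({"start": np.int64, "end": np.int64})


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    """Write a window track (chrom/start/end/level) as bedGraph, skipping missing windows."""
    ok = track.dropna(subset=["level"])
    ok[["chrom", "start", "end", "level"]].to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a gene table TSV (header: id, chrom, start, end, strand).

    TSS/TES are derived from the strand: TSS = start on '+', end on '-'.
    Duplicate gene ids are fatal.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError("gene strands must be '+' or '-'")
    return [
        GeneModel(str(r.id), str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    ]


def write_gene_table(genes: list[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["id", "chrom", "start", "end", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path, stages: list[str] | None = None) -> pd.DataFrame:
    """Read an expression TSV (gene id + one FPKM column per stage).

    Returns a frame indexed by gene id with one float column per stage.
    Non-numeric FPKM cells and missing stage columns are fatal.
    """
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValueError("expression table needs an 'id' column")
    if df["id"].duplicated().any():
        raise ValueError("duplicate gene ids in expression table")
    df = df.set_index("id")
    if stages is not None:
        missing = set(stages) - set(df.columns)
        if missing:
            raise ValueError(f"expression table missing stage columns: {sorted(missing)}")
        df = df[list(stages)]
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index.tolist()
            raise ValueError(f"non-numeric FPKM in column {col!r}, genes {bad[:5]}") from exc
    if (df < 0).any().any():
        raise ValueError("negative FPKM values in expression table")
    return df


def write_expression_table(expr: pd.DataFrame, path: str | Path) -> None:
    expr.rename_axis("id").reset_index().to_csv(path, sep="\t", index=False)
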