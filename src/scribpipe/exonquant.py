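"""Exon quantification and cohort preparation.

Parses per-exon RNA-seq quantifications and clinical tables, computes RPKM
from raw read counts over BED-defined exons, converts RPKM profiles into
*relative exon usage* (each exon's RPKM divided by the summed RPKM of all
other exons of the gene in the same sample, times 100), joins usage with
clinical records on patient barcode, and applies the minimum-follow-up
censor filter.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``. A read overlaps an exon if they share at least one base;
a read spanning an exon junction is counted once for every exon it touches
(``bedtools multicov`` semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExonDef",
    "ExonUsageMatrix",
    "compute_rpkm",
    "count_overlaps",
    "relative_usage",
    "usage_matrix_from_rpkm",
    "read_bed",
    "read_exon_quant",
    "read_clinical",
    "derive_survival",
    "merge_clinical",
    "censor_min_followup",
]


@dataclass(frozen=True)
class ExonDef:
    """One exon interval, BED convention (0-based, half-open)."""

    exon_id: int
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"exon {self.exon_id}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class ExonUsageMatrix:
    """Patients x exons RPKM values and derived relative-usage percentages.

    ``rpkm`` is a patients-by-exons DataFrame (index: barcode, columns:
    exon id). ``usage`` holds ``100 * r_i / (S - r_i)`` with ``S`` the
    patient's total RPKM; entries where the denominator is zero are NaN.
    """

    rpkm: pd.DataFrame
    usage: pd.DataFrame

    @property
    def barcodes(self) -> pd.Index:
        return self.rpkm.index

    @property
    def exon_ids(self) -> pd.Index:
        return self.rpkm.columns


def compute_rpkm(
    read_count: float, exon: ExonDef, total_aligned_reads: int
) -> float:
    """Reads per kilobase of exon per million aligned reads.

    rpkm = read_count / ((total_aligned_reads / 1e6) * (length_bp / 1e3))
    """
    if total_aligned_reads <= 0:
        raise ValueError("total_aligned_reads must be > 0")
    if exon.length_bp <= 0:
        raise ValueError("exon length must be > 0")
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    return read_count / ((total_aligned_reads / 1e6) * (exon.length_bp / 1e3))


def count_overlaps(
    alignments: Iterable[tuple[int, int]], exons: Sequence[ExonDef]
) -> np.ndarray:
    """Count reads overlapping each exon by >= 1 bp.

    ``alignments`` are half-open ``(start, end)`` intervals on the same
    chromosome as ``exons``. A read spanning two exons increments both
    counts. Returns counts in the order of ``exons``.
    """
    starts = []
    ends = []
    for s, e in alignments:
        if s >= e:
            raise ValueError(f"malformed interval [{s}, {e}): start >= end")
        starts.append(s)
        ends.append(e)
    rs = np.asarray(starts, dtype=np.int64)
    re_ = np.asarray(ends, dtype=np.int64)
    counts = np.zeros(len(exons), dtype=np.int64)
    for i, exon in enumerate(exons):
        # overlap of half-open intervals: read.start < exon.end and read.end > exon.start
        counts[i] = int(np.count_nonzero((rs < exon.end) & (re_ > exon.start)))
    return counts


def relative_usage(rpkm_vector: Sequence[float] | np.ndarray) -> np.ndarray:
    """Relative usage of each exon: ``100 * r_i / (S - r_i)`` with S = sum(r).

    Where the denominator ``S - r_i`` is zero (the exon carries all of the
    signal, or the whole vector is zero) the entry is NaN.
    """
    r = np.asarray(rpkm_vector, dtype=float)
    if np.any(r < 0):
        raise ValueError("RPKM values must be non-negative")
    denom = r.sum() - r
    with np.errstate(divide="ignore", invalid="ignore"):
        usage = np.where(denom > 0, 100.0 * r / denom, np.nan)
    return usage


def usage_matrix_from_rpkm(rpkm: pd.DataFrame) -> ExonUsageMatrix:
    """Build an :class:`ExonUsageMatrix` from a patients-by-exons RPKM table.

    Patients whose total RPKM is zero have every usage value undefined and
    are dropped (with a logged count) — they carry no usage information.
    """
    total = rpkm.sum(axis=1)
    zero = total == 0
    if zero.any():
        logger.info("dropping %d patients with zero total RPKM", int(zero.sum()))
        rpkm = rpkm.loc[~zero]
    usage = pd.DataFrame(
        np.vstack([relative_usage(row) for row in rpkm.to_numpy()]),
        index=rpkm.index,
        columns=rpkm.columns,
    )
    return ExonUsageMatrix(rpkm=rpkm.copy(), usage=usage)


# ---------------------------------------------------------------------------
# readers


def read_bed(path) -> list[ExonDef]:
    """Read exon definitions from a headerless BED file.

    Columns: chrom, start, end[, name]. The name column, when present, is
    parsed as the ordinal exon id; otherwise exons are numbered 1..n in
    file order.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    exons = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        exon_id = i
        if len(row) >= 4:
            try:
                exon_id = int(str(row[3]).split("_")[-1])
            except ValueError:
                exon_id = i
        exons.append(
            ExonDef(exon_id=exon_id, chrom=str(row[0]), start=int(row[1]), end=int(row[2]))
        )
    ids = [e.exon_id for e in exons]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate exon ids in BED file")
    return exons


def read_exon_quant(path) -> pd.DataFrame:
    """Read an exon-quantification TSV into a patients-by-exons RPKM table.

    Accepts the long form (columns ``barcode``, ``exon_id``, ``rpkm``) or a
    wide matrix (one row per patient, ``barcode`` column plus one column per
    exon). Quoted fields and CRLF line endings are tolerated by the pandas
    reader.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if {"barcode", "exon_id", "rpkm"} <= set(cols):
        wide = df.pivot_table(
            index=cols["barcode"], columns=cols["exon_id"], values=cols["rpkm"]
        )
        wide.index.name = "barcode"
        return wide
    if "barcode" in cols:
        wide = df.set_index(cols["barcode"])
        wide.columns = [int(c) if str(c).isdigit() else c for c in wide.columns]
        return wide
    raise ValueError("exon quantification table must have a 'barcode' column")


_ALIVE = {"alive", "living"}
_DEAD = {"dead", "deceased"}


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV and derive survival time and event flag.

    Expected columns (case-insensitive): ``barcode``, ``vital_status``,
    ``days_to_death``, ``days_to_last_followup``, and optionally
    ``er_status`` / ``her2_status``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    return derive_survival(df)


def derive_survival(clinical: pd.DataFrame) -> pd.DataFrame:
    """Derive ``survival_time`` and ``event`` from vital status and day fields.

    ``event`` is True for dead patients; ``survival_time`` is days-to-death
    for events and days-to-last-follow-up otherwise. Records whose survival
    time cannot be derived (alive with missing follow-up, dead with missing
    days-to-death) are dropped with a logged count.
    """
    df = clinical.copy()
    vs = df["vital_status"].astype(str).str.strip().str.lower()
    unknown = ~vs.isin(_ALIVE | _DEAD)
    if unknown.any():
        raise ValueError(
            f"unrecognized vital_status values: {sorted(df.loc[unknown, 'vital_status'].unique())}"
        )
    df["event"] = vs.isin(_DEAD)
    death = pd.to_numeric(df.get("days_to_death"), errors="coerce")
    follow = pd.to_numeric(df.get("days_to_last_followup"), errors="coerce")
    df["survival_time"] = np.where(df["event"], death, follow)
    bad = df["survival_time"].isna()
    if bad.any():
        logger.info("dropping %d records with underivable survival time", int(bad.sum()))
        df = df.loc[~bad]
    return df


def merge_clinical(usage: ExonUsageMatrix, clinical: pd.DataFrame) -> pd.DataFrame:
    """Inner-join usage profiles with clinical records on patient barcode.

    Returns one row per matched patient: usage columns named ``exon_<id>``
    plus the clinical columns. Duplicate barcodes in either input are an
    error naming the offending barcode; unmatched patients are dropped with
    a logged count.
    """
    if usage.usage.index.duplicated().any():
        dup = usage.usage.index[usage.usage.index.duplicated()][0]
        raise ValueError(f"duplicate barcode in usage matrix: {dup!r}")
    if clinical["barcode"].duplicated().any():
        dup = clinical.loc[clinical["barcode"].duplicated(), "barcode"].iloc[0]
        raise ValueError(f"duplicate barcode in clinical table: {dup!r}")
    u = usage.usage.copy()
    u.columns = [f"exon_{c}" for c in u.columns]
    joined = u.join(clinical.set_index("barcode"), how="inner")
    dropped = len(u) - len(joined)
    if dropped:
        logger.info("dropped %d usage rows without clinical match", dropped)
    if joined.empty:
        logger.warning("merge produced no rows: disjoint barcode sets")
    joined.index.name = "barcode"
    return joined.sort_index()


def censor_min_followup(records: pd.DataFrame, min_days: float = 90) -> pd.DataFrame:
    """Keep records with ``survival_time >= min_days`` (inclusive boundary)."""
    return records.loc[records["survival_time"] >= min_days].copy()
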