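"""FPKM-based differential-expression screen over a genomic target region.

A gene is called differentially expressed when its largest per-diplotype
FPKM exceeds a floor (default 0.1, below which FPKM estimates are noise) and
the C/C-versus-B/B contrast satisfies |log2 fold change| >= 0.58, i.e. at
least a 1.5-fold difference between the two homozygous diplotypes. The floor
applies to the maximum across diplotypes, not to every diplotype — a gene
essentially silent in one homozygote but expressed in the other is exactly
the kind of candidate the screen must keep.

Genomic coordinates are 1-based inclusive bp (mm10-style positions); region
filtering uses any-base overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log2
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FPKM_FLOOR = 0.1
DEFAULT_LFC_THRESHOLD = 0.58

#: The physically defined target region on chromosome 2 (bp, 1-based).
DEFAULT_TARGET_REGION = (59_400_000, 65_300_000)


class UndefinedFoldChangeError(ValueError):
    """Raised when a fold change involves a non-positive FPKM."""


@dataclass(frozen=True)
class TargetRegion:
    """A genomic interval in 1-based inclusive bp."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region start must be < end, got {self.start}..{self.end}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


def log2_fold_change(fpkm_num: float, fpkm_den: float) -> float:
    """log2(numerator / denominator); both FPKMs must be positive."""
    if fpkm_num <= 0 or fpkm_den <= 0:
        raise UndefinedFoldChangeError(
            f"fold change undefined for FPKM pair ({fpkm_num}, {fpkm_den})"
        )
    return log2(fpkm_num / fpkm_den)


@dataclass(frozen=True)
class FpkmRecord:
    """Per-gene, per-organ FPKM values by diplotype with derived fold changes."""

    gene: str
    organ: str
    start: int
    end: int
    fpkm_cc: float
    fpkm_bc: float
    fpkm_bb: float

    def __post_init__(self) -> None:
        for name in ("fpkm_cc", "fpkm_bc", "fpkm_bb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 for {self.gene}")
        if self.start > self.end:
            raise ValueError(f"interval start > end for {self.gene}")

    @property
    def fold_change_defined(self) -> bool:
        return self.fpkm_cc > 0 and self.fpkm_bb > 0

    @property
    def log2fc_cc_bb(self) -> float:
        return log2_fold_change(self.fpkm_cc, self.fpkm_bb)

    @property
    def log2fc_bc_bb(self) -> float:
        return log2_fold_change(self.fpkm_bc, self.fpkm_bb)

    @property
    def max_fpkm(self) -> float:
        return max(self.fpkm_cc, self.fpkm_bc, self.fpkm_bb)


def de_call(
    record: FpkmRecord,
    fpkm_floor: float = DEFAULT_FPKM_FLOOR,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> bool:
    """Differential-expression decision for one record.

    True iff the maximum diplotype FPKM exceeds ``fpkm_floor`` and the
    C/C-vs-B/B |log2 fold change| is at least ``lfc_threshold``. Records with
    an undefined fold change (a zero FPKM in the contrast) are not called DE
    and are flagged with a warning rather than dropped silently.
    """
    if not record.fold_change_defined:
        logger.warning(
            "gene %s (%s): undefined C/C vs B/B fold change (zero FPKM); not called DE",
            record.gene,
            record.organ,
        )
        return False
    return (
        record.max_fpkm > fpkm_floor
        and abs(record.log2fc_cc_bb) >= lfc_threshold
    )


def screen_region(
    records,
    region: TargetRegion | tuple[int, int] = DEFAULT_TARGET_REGION,
    fpkm_floor: float = DEFAULT_FPKM_FLOOR,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> dict[str, list[FpkmRecord]]:
    """DE genes within a target region, grouped by organ, sorted by position."""
    if not isinstance(region, TargetRegion):
        region = TargetRegion(*region)
    out: dict[str, list[FpkmRecord]] = {}
    for rec in records:
        if region.overlaps(rec.start, rec.end) and de_call(
            rec, fpkm_floor=fpkm_floor, lfc_threshold=lfc_threshold
        ):
            out.setdefault(rec.organ, []).append(rec)
    for organ in out:
        out[organ].sort(key=lambda r: r.start)
    return out


def records_from_frame(frame: pd.DataFrame) -> list[FpkmRecord]:
    """Build records from a table with columns organ, gene, start, end, fpkm_*."""
    return [
        FpkmRecord(
            gene=row["gene"],
            organ=row["organ"],
            start=int(row["start"]),
            end=int(row["end"]),
            fpkm_cc=float(row["fpkm_cc"]),
            fpkm_bc=float(row["fpkm_bc"]),
            fpkm_bb=float(row["fpkm_bb"]),
        )
        for _, row in frame.iterrows()
    ]


def read_fpkm_table(path: str | Path) -> list[FpkmRecord]:
    sep = "," if str(path).endswith(".csv") else "\t"
    return records_from_frame(pd.read_csv(path, sep=sep))


def report_frame(
    records,
    fpkm_floor: float = DEFAULT_FPKM_FLOOR,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Screen report: inputs plus derived log2FC columns and the DE flag."""
    rows = []
    for rec in records:
        defined = rec.fold_change_defined
        rows.append(
            {
                "organ": rec.organ,
                "gene": rec.gene,
                "start": rec.start,
                "end": rec.end,
                "fpkm_cc": rec.fpkm_cc,
                "fpkm_bc": rec.fpkm_bc,
                "fpkm_bb": rec.fpkm_bb,
                "log2fc_cc_bb": rec.log2fc_cc_bb if defined else float("nan"),
                "log2fc_bc_bb": (
                    rec.log2fc_bc_bb
                    if rec.fpkm_bc > 0 and rec.fpkm_bb > 0
                    else float("nan")
                ),
                "de": de_call(rec, fpkm_floor=fpkm_floor, lfc_threshold=lfc_threshold),
            }
        )
    return pd.DataFrame(rows)
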