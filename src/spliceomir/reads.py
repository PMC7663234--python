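"""Loading, filtering and segmental classification of aligned small-RNA reads.

Reads arrive as genomic intervals (BED6, a documented TSV, or a minimal SAM
subset — alignment itself happens upstream).  Each read is filtered on
length, mismatch count and identity, then assigned to one hairpin window
and one segmental category.  A read must sit *entirely* inside a window to
be assignable; inside the window its category is the unique segment label
it covers, or ``overlap`` when it crosses a segment border.  There is no
fuzz tolerance at borders: a read extending a single nucleotide past a
mature boundary is an overlap read, while isomiR-style trimming that stays
within the mature segment still counts as mature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import (
    OVERLAP,
    UNASSIGNED,
    GenomicInterval,
    SegmentMap,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 17
DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MIN_IDENTITY = 0.90

#: documented TSV columns for read input
TSV_COLUMNS = ("read_id", "chrom", "start", "end", "strand", "length", "mismatches")


@dataclass(frozen=True)
class AlignedRead:
    """One aligned small-RNA read.

    ``identity_fraction`` defaults to ``(length - mismatches) / length`` when
    the input format carries no explicit identity.
    """

    read_id: str
    interval: GenomicInterval
    length: int
    mismatches: int
    identity_fraction: float

    def __post_init__(self) -> None:
        if self.length != len(self.interval):
            raise ValueError(
                f"read {self.read_id!r}: length {self.length} != interval span "
                f"{len(self.interval)}"
            )
        if self.mismatches < 0:
            raise ValueError(f"read {self.read_id!r}: negative mismatch count")


@dataclass(frozen=True)
class SegmentCall:
    """Assignment of one read to a hairpin and a segmental category."""

    read_id: str
    hairpin_id: str | None
    category: str


def _make_read(
    read_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    mismatches: int,
    identity: float | None = None,
) -> AlignedRead:
    if start < 0:
        raise ValueError(f"read {read_id!r}: negative start coordinate {start}")
    interval = GenomicInterval(chrom=chrom, start=start, end=end, strand=strand)
    length = end - start
    if identity is None:
        identity = (length - mismatches) / length
    return AlignedRead(
        read_id=read_id,
        interval=interval,
        length=length,
        mismatches=mismatches,
        identity_fraction=identity,
    )


def load_reads(path: str | Path, fmt: str = "bed") -> list[AlignedRead]:
    """Load aligned reads from BED6, TSV or a minimal SAM file.

    * ``bed`` — BED6; the score column is read as the mismatch count.
    * ``tsv`` — tab-separated with a header holding :data:`TSV_COLUMNS`
      (an optional ``identity`` column overrides the computed identity).
    * ``sam`` — mapped primary records only; mismatches from the ``NM`` tag.

    Unmapped/secondary/supplementary SAM records are dropped and counted in
    the log.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    if fmt == "bed":
        reads = _load_bed(path)
    elif fmt == "tsv":
        reads = _load_tsv(path)
    elif fmt == "sam":
        reads = _load_sam(path)
    else:
        raise ValueError(f"unknown read format {fmt!r} (expected bed, tsv or sam)")
    if not reads:
        warnings.warn(f"no reads loaded from {path}")
    return reads


def _load_bed(path: Path) -> list[AlignedRead]:
    reads = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno} is not BED6")
            chrom, start, end, name, score, strand = fields[:6]
            reads.append(
                _make_read(name, chrom, int(start), int(end), strand, int(score))
            )
    return reads


def _load_tsv(path: Path) -> list[AlignedRead]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(TSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
    has_identity = "identity" in frame.columns
    reads = []
    for row in frame.itertuples(index=False):
        reads.append(
            _make_read(
                str(row.read_id),
                str(row.chrom),
                int(row.start),
                int(row.end),
                str(row.strand),
                int(row.mismatches),
                float(row.identity) if has_identity else None,
            )
        )
    return reads


def _load_sam(path: Path) -> list[AlignedRead]:
    reads = []
    dropped = 0
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                dropped += 1
                continue
            mm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            reads.append(
                _make_read(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    int(mm),
                )
            )
    if dropped:
        logger.info("dropped %d unmapped/secondary/supplementary records", dropped)
    return reads


def filter_reads(
    reads: Iterable[AlignedRead],
    min_length: int = DEFAULT_MIN_LENGTH,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[AlignedRead]:
    """Keep reads passing all three quality thresholds.

    Defaults mirror standard small-RNA practice for this assay: length
    >= 17 nt, at most 2 mismatches, and >= 90% identity.  The predicate is a
    pure conjunction, so filter order cannot matter.
    """
    return [
        r
        for r in reads
        if r.length >= min_length
        and r.mismatches <= max_mismatches
        and r.identity_fraction >= min_identity
    ]


class SegmentIndex:
    """Interval index over hairpin windows for fast read assignment."""

    def __init__(self, segment_maps: Mapping[str, SegmentMap]):
        self.maps = dict(segment_maps)
        self._trees: dict[str, IntervalTree] = {}
        for hid, smap in self.maps.items():
            tree = self._trees.setdefault(smap.window.chrom, IntervalTree())
            tree.addi(smap.window.start, smap.window.end, hid)

    def candidate_windows(self, read: AlignedRead, strand_mode: str) -> list[str]:
        """Hairpins whose window fully contains the read (strand permitting)."""
        tree = self._trees.get(read.interval.chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(read.interval.start, read.interval.end):
            smap = self.maps[iv.data]
            if not smap.window.contains(read.interval):
                continue  # both read ends must map inside the window
            if strand_mode == "same" and smap.window.strand != read.interval.strand:
                continue
            hits.append(iv.data)
        return hits

    def assign(self, read: AlignedRead, strand_mode: str = "same") -> SegmentCall:
        """Assign one read to a hairpin window and segmental category.

        When several windows fully contain the read, the hairpin whose window
        midpoint is closest to the read midpoint wins; exact ties go to the
        lexicographically smallest hairpin_id (logged).  Inside the chosen
        window the category is the unique covered segment label, or
        ``overlap`` for a read crossing a segment border.
        """
        if strand_mode not in ("same", "both"):
            raise ValueError(f"strand_mode must be 'same' or 'both', got {strand_mode!r}")
        hits = self.candidate_windows(read, strand_mode)
        if not hits:
            return SegmentCall(read.read_id, None, UNASSIGNED)
        if len(hits) > 1:
            read_mid2 = read.interval.start + read.interval.end

            def distance(hid: str) -> int:
                w = self.maps[hid].window
                return abs(read_mid2 - (w.start + w.end))

            hits.sort(key=lambda hid: (distance(hid), hid))
            if distance(hits[0]) == distance(hits[1]):
                logger.info(
                    "read %s: midpoint tie between %s and %s; picked %s",
                    read.read_id,
                    hits[0],
                    hits[1],
                    hits[0],
                )
        hid = hits[0]
        smap = self.maps[hid]
        labels = smap.labels_in(*smap.to_local(read.interval))
        category = labels.pop() if len(labels) == 1 else OVERLAP
        return SegmentCall(read.read_id, hid, category)


def assign_read(
    read: AlignedRead,
    segment_maps: Mapping[str, SegmentMap] | SegmentIndex,
    strand_mode: str = "same",
) -> SegmentCall:
    """Assign a single read (convenience wrapper over :class:`SegmentIndex`)."""
    index = (
        segment_maps
        if isinstance(segment_maps, SegmentIndex)
        else SegmentIndex(segment_maps)
    )
    return index.assign(read, strand_mode)


def assign_reads(
    reads: Sequence[AlignedRead],
    segment_maps: Mapping[str, SegmentMap] | SegmentIndex,
    strand_mode: str = "same",
) -> list[SegmentCall]:
    index = (
        segment_maps
        if isinstance(segment_maps, SegmentIndex)
        else SegmentIndex(segment_maps)
    )
    return [index.assign(r, strand_mode) for r in reads]


def calls_to_frame(
    calls: Sequence[SegmentCall], sample_id: str | None = None
) -> pd.DataFrame:
    """Tabulate calls; optionally tag every row with a sample_id."""
    frame = pd.DataFrame(
        {
            "read_id": [c.read_id for c in calls],
            "hairpin_id": [c.hairpin_id for c in calls],
            "category": [c.category for c in calls],
        }
    )
    if sample_id is not None:
        frame.insert(0, "sample_id", sample_id)
    return frame


def segment_partition(
    calls: pd.DataFrame,
    by: str = "miRNA",
    normalized: bool = False,
) -> pd.DataFrame:
    """Segmental composition table from a call frame.

    ``by`` is one of ``miRNA``, ``sample`` or ``miRNA×sample`` (``x`` also
    accepted).  Unassigned calls are dropped (count logged).  With
    ``normalized=True`` every row is scaled to sum to 1; for the
    ``sample`` view the normalized composition is the unweighted mean of the
    per-miRNA fractions in that sample (so each miRNA contributes equally),
    while the raw view pools counts across miRNAs.
    """
    n_unassigned = int((calls["category"] == UNASSIGNED).sum())
    if n_unassigned:
        logger.info("segment_partition: dropping %d unassigned calls", n_unassigned)
    assigned = calls[calls["category"] != UNASSIGNED]
    if assigned.empty:
        warnings.warn("segment_partition: no assignable calls")
        return pd.DataFrame()

    by = by.replace("x", "×")
    if by == "miRNA":
        keys = ["hairpin_id"]
    elif by == "sample":
        keys = ["sample_id"]
    elif by == "miRNA×sample":
        keys = ["hairpin_id", "sample_id"]
    else:
        raise ValueError(f"unknown grouping {by!r}")
    for key in keys:
        if key not in assigned.columns:
            raise ValueError(f"calls frame lacks a {key!r} column needed for by={by!r}")

    if by == "sample" and normalized:
        per_mirna = (
            assigned.groupby(["sample_id", "hairpin_id"])["category"]
            .value_counts()
            .unstack(fill_value=0)
        )
        fractions = per_mirna.div(per_mirna.sum(axis=1), axis=0)
        table = fractions.groupby(level="sample_id").mean()
    else:
        table = assigned.groupby(keys)["category"].value_counts().unstack(fill_value=0)
        if normalized:
            table = table.div(table.sum(axis=1), axis=0)
    return table.sort_index(axis=1)


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)
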