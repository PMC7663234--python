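"""Pre-miRNA hairpin annotations, segmental maps, and genomic clusters.

A hairpin precursor (pre-miRNA) is annotated in miRBase-style GFF3 as a
``miRNA_primary_transcript`` feature with one or two ``miRNA`` children
(the mature 5p/3p products, linked by ``Derives_from``).  For segmental
read classification each hairpin is expanded into a *window* — the hairpin
plus an extension flank on both sides — and the window is partitioned into
disjoint labelled segments:

* ``mature_5p`` / ``mature_3p`` — the annotated mature products;
* ``undefined_complement`` — when only one arm has an annotated mature,
  the star-like interval on the opposite arm, placed by mirroring the
  mature across the hairpin with a 2-nt offset (the Dicer 3' overhang
  heuristic), without any secondary-structure prediction;
* ``extension`` — every remaining window position (terminal tails and the
  loop between arms).

All internal coordinates are 0-based half-open.  Segment coordinates are
*window-local and strand-aware*: local position 0 is the 5' end of the
window, so the same geometry rules apply to + and - strand hairpins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from gffutils.feature import feature_from_line

MATURE_5P = "mature_5p"
MATURE_3P = "mature_3p"
UNDEFINED_COMPLEMENT = "undefined_complement"
EXTENSION = "extension"
OVERLAP = "overlap"
UNASSIGNED = "unassigned"

#: segment labels that can appear in a SegmentMap, 5'-to-3' typical order
SEGMENT_LABELS = (MATURE_5P, MATURE_3P, UNDEFINED_COMPLEMENT, EXTENSION)
#: categories a read call can take
READ_CATEGORIES = (MATURE_5P, MATURE_3P, UNDEFINED_COMPLEMENT, EXTENSION, OVERLAP)

DEFAULT_EXTENSION_FLANK = 50
DEFAULT_OVERHANG = 2
DEFAULT_CLUSTER_DISTANCE = 10_000


class GFFParseError(ValueError):
    """Raised for a malformed GFF3 line, carrying the 1-based line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class HairpinRecord:
    """A pre-miRNA hairpin precursor."""

    hairpin_id: str
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class MatureRecord:
    """An annotated mature miRNA product on one arm of its parent hairpin."""

    mature_id: str
    parent: str
    interval: GenomicInterval
    arm: str  # "5p" or "3p"

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be '5p' or '3p', got {self.arm!r}")


@dataclass(frozen=True)
class Segment:
    """One labelled window-local interval of a segment map."""

    label: str
    start: int
    end: int


@dataclass(frozen=True)
class SegmentMap:
    """Disjoint labelled partition of a hairpin window.

    ``segments`` are window-local, strand-aware (position 0 = 5' end of the
    window) and together cover ``[0, len(window))`` with no gaps.  The loop
    between the two arms is labelled ``extension`` along with the terminal
    tails; this choice is recorded in ``includes_loop_in_extension``.
    """

    hairpin_id: str
    window: GenomicInterval
    extension_flank: int
    segments: tuple[Segment, ...]
    includes_loop_in_extension: bool = True

    def __post_init__(self) -> None:
        pos = 0
        for seg in self.segments:
            if seg.start != pos or seg.end <= seg.start:
                raise ValueError(
                    f"{self.hairpin_id}: segments must tile the window; "
                    f"got {seg} at position {pos}"
                )
            pos = seg.end
        if pos != len(self.window):
            raise ValueError(
                f"{self.hairpin_id}: segments cover [0,{pos}) "
                f"but window has length {len(self.window)}"
            )

    def label_at(self, local_pos: int) -> str:
        """Label of a single window-local position."""
        for seg in self.segments:
            if seg.start <= local_pos < seg.end:
                return seg.label
        raise IndexError(f"position {local_pos} outside window of {self.hairpin_id}")

    def to_local(self, interval: GenomicInterval) -> tuple[int, int]:
        """Map a genomic interval to window-local (5'-oriented) coordinates."""
        w = self.window
        if w.strand == "+":
            return interval.start - w.start, interval.end - w.start
        return w.end - interval.end, w.end - interval.start

    def to_genomic(self, local_start: int, local_end: int) -> tuple[int, int]:
        """Map window-local coordinates back to genomic start/end."""
        w = self.window
        if w.strand == "+":
            return w.start + local_start, w.start + local_end
        return w.end - local_end, w.end - local_start

    def labels_in(self, local_start: int, local_end: int) -> set[str]:
        """Distinct segment labels intersecting a window-local interval."""
        out: set[str] = set()
        for seg in self.segments:
            if seg.start < local_end and local_start < seg.end:
                out.add(seg.label)
        return out


@dataclass(frozen=True)
class ClusterPair:
    """Two hairpins on the same chromosome within the cluster distance."""

    mirna_a: str
    mirna_b: str
    distance: int


# ---------------------------------------------------------------------------
# GFF3 parsing (miRBase dialect)
# ---------------------------------------------------------------------------


def _attr_first(feature, *keys: str) -> str | None:
    for key in keys:
        values = feature.attributes.get(key)
        if values:
            return values[0]
    return None


def read_hairpin_annotations(
    gff3_path: str | Path,
) -> tuple[list[HairpinRecord], list[MatureRecord]]:
    """Parse miRBase-dialect GFF3 into hairpin and mature records.

    Features of type ``miRNA_primary_transcript`` become hairpins; ``miRNA``
    features become matures, resolved to their parent via ``Derives_from``.
    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    The mature arm is called from the position of the mature midpoint
    relative to the hairpin midpoint on the 5'-oriented axis (5' half and
    exact midpoint -> 5p).

    Raises :class:`GFFParseError` (with the line number) on malformed lines
    and :class:`ValueError` for a mature outside its parent's span; matures
    with an unknown parent are skipped with a warning.
    """
    hairpins: list[HairpinRecord] = []
    by_accession: dict[str, HairpinRecord] = {}
    by_name: dict[str, HairpinRecord] = {}
    pending_matures: list[tuple[str, str, GenomicInterval]] = []

    with open(gff3_path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
                interval = GenomicInterval(
                    chrom=feat.seqid,
                    start=feat.start - 1,  # GFF3 is 1-based inclusive
                    end=feat.end,
                    strand=feat.strand,
                )
            except Exception as exc:
                raise GFFParseError(
                    f"{gff3_path}: malformed GFF3 at line {lineno}: {exc}"
                ) from exc
            if feat.featuretype == "miRNA_primary_transcript":
                accession = _attr_first(feat, "ID") or f"hairpin_line{lineno}"
                name = _attr_first(feat, "Name") or accession
                if name in by_name:
                    raise GFFParseError(
                        f"{gff3_path}: duplicate hairpin id {name!r} at line {lineno}"
                    )
                record = HairpinRecord(hairpin_id=name, interval=interval)
                hairpins.append(record)
                by_accession[accession] = record
                by_name[name] = record
            elif feat.featuretype == "miRNA":
                mature_id = (
                    _attr_first(feat, "Name")
                    or _attr_first(feat, "ID")
                    or f"mature_line{lineno}"
                )
                parent_key = _attr_first(feat, "Derives_from", "derives_from")
                if parent_key is None:
                    warnings.warn(
                        f"mature {mature_id!r} (line {lineno}) has no "
                        "Derives_from attribute; skipped"
                    )
                    continue
                pending_matures.append((mature_id, parent_key, interval))
            # other feature types are ignored

    matures: list[MatureRecord] = []
    seen_arms: dict[tuple[str, str], str] = {}
    for mature_id, parent_key, interval in pending_matures:
        parent = by_accession.get(parent_key) or by_name.get(parent_key)
        if parent is None:
            warnings.warn(
                f"mature {mature_id!r} derives from unknown hairpin "
                f"{parent_key!r}; skipped"
            )
            continue
        if not parent.interval.contains(interval) or (
            interval.strand != parent.interval.strand
        ):
            raise ValueError(
                f"mature {mature_id!r} lies outside its parent hairpin "
                f"{parent.hairpin_id!r}"
            )
        arm = _call_arm(parent.interval, interval)
        key = (parent.hairpin_id, arm)
        if key in seen_arms:
            raise ValueError(
                f"hairpin {parent.hairpin_id!r} has two matures on the {arm} arm "
                f"({seen_arms[key]!r} and {mature_id!r})"
            )
        seen_arms[key] = mature_id
        matures.append(
            MatureRecord(
                mature_id=mature_id,
                parent=parent.hairpin_id,
                interval=interval,
                arm=arm,
            )
        )
    return hairpins, matures


def _call_arm(hairpin: GenomicInterval, mature: GenomicInterval) -> str:
    """5p if the mature midpoint sits in the 5' half of the hairpin.

    Midpoints are compared as doubled integers to stay exact; an exact tie
    is called 5p.  On the minus strand the 5' end is the higher genomic
    coordinate, so the comparison flips.
    """
    mature_mid2 = mature.start + mature.end
    hairpin_mid2 = hairpin.start + hairpin.end
    if hairpin.strand == "+":
        return "5p" if mature_mid2 <= hairpin_mid2 else "3p"
    return "5p" if mature_mid2 >= hairpin_mid2 else "3p"


# ---------------------------------------------------------------------------
# Segment maps
# ---------------------------------------------------------------------------


def _mirror_complement(
    local_start: int, local_end: int, hairpin_len: int, overhang: int
) -> tuple[int, int]:
    """Mirror a hairpin-local mature interval onto the opposite arm.

    The star-like complement of mature ``[s, e)`` on a hairpin of length L is
    ``[L - e + overhang, L - s + overhang)``: the reflection of the mature
    across the hairpin centre, shifted 3'-ward by the Dicer 2-nt overhang,
    before clipping to the hairpin.
    """
    return hairpin_len - local_end + overhang, hairpin_len - local_start + overhang


def build_segment_map(
    hairpin: HairpinRecord,
    matures: Sequence[MatureRecord],
    extension_flank: int = DEFAULT_EXTENSION_FLANK,
    overhang: int = DEFAULT_OVERHANG,
) -> SegmentMap:
    """Partition a hairpin window into labelled segments.

    ``matures`` are the mature records of *this* hairpin (one or two).  With
    both arms annotated the map holds the two matures plus extension; with a
    single arm an ``undefined_complement`` is constructed on the opposite arm
    by the mirror rule, clipped to the hairpin and truncated (with a warning)
    if it would overlap the mature.  Zero matures is an error: the hairpin
    cannot be oriented.
    """
    own = [m for m in matures if m.parent == hairpin.hairpin_id]
    if not own:
        raise ValueError(
            f"hairpin {hairpin.hairpin_id!r} has no annotated mature; "
            "cannot build a segment map"
        )
    if len(own) > 2:
        raise ValueError(f"hairpin {hairpin.hairpin_id!r} has >2 matures")

    hp = hairpin.interval
    L = hairpin.length
    window = GenomicInterval(
        chrom=hp.chrom,
        start=hp.start - extension_flank,
        end=hp.end + extension_flank,
        strand=hp.strand,
    )

    def hairpin_local(m: MatureRecord) -> tuple[int, int]:
        if hp.strand == "+":
            return m.interval.start - hp.start, m.interval.end - hp.start
        return hp.end - m.interval.end, hp.end - m.interval.start

    labelled: list[tuple[str, int, int]] = []  # hairpin-local
    for m in own:
        s, e = hairpin_local(m)
        labelled.append((MATURE_5P if m.arm == "5p" else MATURE_3P, s, e))

    if len(own) == 1:
        (label, s, e) = labelled[0]
        cs, ce = _mirror_complement(s, e, L, overhang)
        cs, ce = max(cs, 0), min(ce, L)
        # truncate against the mature if the mirror lands on top of it
        if cs < e and s < ce:
            if label == MATURE_5P:
                cs = max(cs, e)
            else:
                ce = min(ce, s)
            warnings.warn(
                f"{hairpin.hairpin_id}: mirrored complement overlaps the "
                "mature; truncated"
            )
        if cs < ce:
            labelled.append((UNDEFINED_COMPLEMENT, cs, ce))
        else:
            warnings.warn(
                f"{hairpin.hairpin_id}: mirrored complement vanished after "
                "clipping; no undefined_complement segment"
            )
    else:
        order = sorted(labelled, key=lambda t: t[1])
        if order[0][2] > order[1][1]:
            raise ValueError(
                f"hairpin {hairpin.hairpin_id!r}: annotated matures overlap"
            )

    # shift to window-local coordinates and fill gaps with extension
    window_len = L + 2 * extension_flank
    placed = sorted(
        ((lab, s + extension_flank, e + extension_flank) for lab, s, e in labelled),
        key=lambda t: t[1],
    )
    segments: list[Segment] = []
    cursor = 0
    for lab, s, e in placed:
        if s > cursor:
            segments.append(Segment(EXTENSION, cursor, s))
        segments.append(Segment(lab, s, e))
        cursor = e
    if cursor < window_len:
        segments.append(Segment(EXTENSION, cursor, window_len))

    return SegmentMap(
        hairpin_id=hairpin.hairpin_id,
        window=window,
        extension_flank=extension_flank,
        segments=tuple(segments),
    )


def build_segment_maps(
    hairpins: Iterable[HairpinRecord],
    matures: Sequence[MatureRecord],
    extension_flank: int = DEFAULT_EXTENSION_FLANK,
    overhang: int = DEFAULT_OVERHANG,
) -> dict[str, SegmentMap]:
    """Segment maps for every hairpin, keyed by hairpin_id."""
    by_parent: dict[str, list[MatureRecord]] = {}
    for m in matures:
        by_parent.setdefault(m.parent, []).append(m)
    return {
        h.hairpin_id: build_segment_map(
            h, by_parent.get(h.hairpin_id, []), extension_flank, overhang
        )
        for h in hairpins
    }


# ---------------------------------------------------------------------------
# Genomic clusters
# ---------------------------------------------------------------------------


def find_cluster_neighbors(
    hairpins: Sequence[HairpinRecord],
    max_distance: int = DEFAULT_CLUSTER_DISTANCE,
) -> list[ClusterPair]:
    """All unordered same-chromosome hairpin pairs closer than ``max_distance``.

    Distance is the end-to-start gap between the two intervals (0 when they
    overlap); the threshold is strict, so a gap of exactly ``max_distance``
    is *not* a cluster.  Output is sorted by (id_a, id_b) with id_a < id_b.
    """
    by_chrom: dict[str, list[HairpinRecord]] = {}
    for h in hairpins:
        by_chrom.setdefault(h.interval.chrom, []).append(h)

    pairs: list[ClusterPair] = []
    for chrom_hairpins in by_chrom.values():
        ordered = sorted(chrom_hairpins, key=lambda h: (h.interval.start, h.hairpin_id))
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                gap = b.interval.start - a.interval.end
                if gap >= max_distance:
                    break  # starts are sorted: all later b are at least this far
                ia, ib = sorted((a.hairpin_id, b.hairpin_id))
                pairs.append(ClusterPair(ia, ib, max(0, gap)))
    pairs.sort(key=lambda p: (p.mirna_a, p.mirna_b))
    return pairs


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_segment_maps_tsv(maps: dict[str, SegmentMap], path: str | Path) -> None:
    """Window-local segment table: hairpin_id, label, local_start, local_end."""
    with open(path, "w") as out:
        out.write("hairpin_id\tlabel\tlocal_start\tlocal_end\n")
        for hid in sorted(maps):
            for seg in maps[hid].segments:
                out.write(f"{hid}\t{seg.label}\t{seg.start}\t{seg.end}\n")


def write_segment_maps_bed(maps: dict[str, SegmentMap], path: str | Path) -> None:
    """Segments as BED6 in genomic coordinates (name = hairpin_id:label)."""
    rows = []
    for hid in sorted(maps):
        smap = maps[hid]
        for seg in smap.segments:
            gs, ge = smap.to_genomic(seg.start, seg.end)
            rows.append(
                (smap.window.chrom, gs, ge, f"{hid}:{seg.label}", 0, smap.window.strand)
            )
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as out:
        for row in rows:
            out.write("\t".join(str(x) for x in row) + "\n")


def write_cluster_pairs_tsv(pairs: Sequence[ClusterPair], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("mirna_a\tmirna_b\tdistance\n")
        for p in pairs:
            out.write(f"{p.mirna_a}\t{p.mirna_b}\t{p.distance}\n")


def write_gff3(
    hairpins: Sequence[HairpinRecord],
    matures: Sequence[MatureRecord],
    path: str | Path,
) -> None:
    """Write records back out in the miRBase GFF3 dialect (1-based inclusive)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        mature_by_parent: dict[str, list[MatureRecord]] = {}
        for m in matures:
            mature_by_parent.setdefault(m.parent, []).append(m)
        for h in hairpins:
            iv = h.interval
            out.write(
                f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\tID={h.hairpin_id};Name={h.hairpin_id}\n"
            )
            for m in mature_by_parent.get(h.hairpin_id, []):
                mi = m.interval
                out.write(
                    f"{mi.chrom}\t.\tmiRNA\t{mi.start + 1}\t{mi.end}\t.\t{mi.strand}"
                    f"\t.\tID={m.mature_id};Name={m.mature_id};"
                    f"Derives_from={h.hairpin_id}\n"
                )
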