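"""Synthetic annotations, reads and count matrices with known ground truth.

The generator emulates the structure of a spliceosome-fraction small-RNA
profiling experiment: three cell-line groups with three biological
replicates each, a toy chromosome of non-overlapping pre-miRNA hairpins
(some planted in genomic clusters closer than 10 kb, some with a single
annotated arm), per-miRNA segmental read mixtures, negative-binomial count
noise, and planted fold changes against the reference group.  Everything
is a pure function of (spec, seed), so every downstream stage can be
tested against the emitted truth without any external data.

Negative-binomial parameterization is mean/size: a count with mean ``m``
and size (dispersion) ``k`` has variance ``m + m^2 / k``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    EXTENSION,
    MATURE_3P,
    MATURE_5P,
    OVERLAP,
    READ_CATEGORIES,
    UNDEFINED_COMPLEMENT,
    GenomicInterval,
    HairpinRecord,
    MatureRecord,
    SegmentMap,
    build_segment_maps,
    write_gff3,
)
from .compare import call_trend
from .quantify import CountMatrix, validate_samples
from .reads import AlignedRead

MATURE_LEN = 22


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the generator.

    Defaults mirror the emulated design: 3 groups x 3 replicates; hairpins
    of 60-110 nt with ~22-nt matures near the termini; about a fifth of
    hairpins in sub-10-kb clusters; a third single-arm (to exercise the
    undefined complement); a mature-dominant segmental mixture with a
    sizeable overlap share; read lengths 17-30 nt; negative-binomial count
    noise with size 10; planted |log2 fold changes| of at least 1 for
    Up/Down miRNAs and within-band wobble for Same.
    """

    n_mirnas: int = 30
    hairpin_length: tuple[int, int] = (60, 110)
    chrom: str = "chrS"
    single_arm_fraction: float = 0.35
    cluster_fraction: float = 0.2
    groups: tuple[str, ...] = ("MCF10A", "MCF7", "MDA231")
    n_replicates: int = 3
    #: fractions over (mature_5p, mature_3p, undefined_complement,
    #: extension, overlap); renormalized per hairpin when a category is
    #: infeasible (e.g. no undefined complement on a two-arm hairpin)
    mixture: tuple[float, float, float, float, float] = (0.55, 0.10, 0.05, 0.12, 0.18)
    mean_reads_per_mirna: float = 2000.0
    dispersion: float = 10.0
    read_length: tuple[int, int] = (17, 30)
    decoy_fraction: float = 0.05
    #: planted trend-class probabilities for each non-reference group
    trend_fractions: tuple[float, float, float] = (0.3, 0.4, 0.3)  # U, D, S
    #: |log2FC| range for planted U/D miRNAs
    lfc_range: tuple[float, float] = (1.0, 2.0)
    #: probability that a planted Down miRNA is entirely absent in the group
    absent_fraction: float = 0.3
    #: nominal per-sample depth for count-matrix simulation
    depth: float = 10_000.0
    #: floor on a miRNA's reference-group mean count in count simulation
    min_base_mean: float = 40.0
    extension_flank: int = 50

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("segment mixture must sum to 1")
        if self.depth <= 0 or self.mean_reads_per_mirna <= 0:
            raise ValueError("depths must be positive")
        if self.n_mirnas < 1:
            raise ValueError("need at least one miRNA")
        if abs(sum(self.trend_fractions) - 1.0) > 1e-9:
            raise ValueError("trend fractions must sum to 1")

    @property
    def reference_group(self) -> str:
        return self.groups[0]

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{g}_rep{r}", "group": g, "replicate": r}
            for g in self.groups
            for r in range(1, self.n_replicates + 1)
        ]
        return validate_samples(pd.DataFrame(rows))


@dataclass
class TruthBundle:
    """Ground truth emitted alongside simulated data."""

    arms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    cluster_pairs: list[tuple[str, str]] = field(default_factory=list)
    mixtures: dict[str, dict[str, float]] = field(default_factory=dict)
    true_means: pd.DataFrame | None = None  # mirna x group expected counts
    fold_changes: pd.DataFrame | None = None
    trend_truth: dict[str, dict[str, str]] = field(default_factory=dict)
    presence: dict[str, set[str]] = field(default_factory=dict)
    reads: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "arms": {k: list(v) for k, v in self.arms.items()},
            "cluster_pairs": [list(p) for p in self.cluster_pairs],
            "mixtures": self.mixtures,
            "true_means": None
            if self.true_means is None
            else self.true_means.to_dict(),
            "fold_changes": None
            if self.fold_changes is None
            else self.fold_changes.to_dict(),
            "trend_truth": self.trend_truth,
            "presence": {k: sorted(v) for k, v in self.presence.items()},
        }
        with open(path, "w") as out:
            json.dump(payload, out, indent=1, sort_keys=True)


@dataclass
class AnnotationFixture:
    """A simulated annotation set plus its expression ground truth."""

    spec: SimulationSpec
    seed: int
    hairpins: list[HairpinRecord]
    matures: list[MatureRecord]
    segment_maps: dict[str, SegmentMap]
    truth: TruthBundle


def _plant_expression(
    spec: SimulationSpec, mirnas: Sequence[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[str, str]]]:
    """Base means, per-group fold changes, and the implied trend truth."""
    n = len(mirnas)
    weights = rng.lognormal(0.0, 1.0, n)
    base = np.maximum(spec.depth * weights / weights.sum(), spec.min_base_mean)
    fold = pd.DataFrame(1.0, index=list(mirnas), columns=list(spec.groups))
    for group in spec.groups[1:]:
        classes = rng.choice(["U", "D", "S"], size=n, p=spec.trend_fractions)
        lfc = rng.uniform(*spec.lfc_range, size=n)
        fc = np.ones(n)
        fc[classes == "U"] = 2.0 ** lfc[classes == "U"]
        fc[classes == "D"] = 2.0 ** -lfc[classes == "D"]
        fc[classes == "S"] = rng.uniform(0.85, 1.15, size=n)[classes == "S"]
        absent = (classes == "D") & (rng.random(n) < spec.absent_fraction)
        fc[absent] = 0.0
        fold[group] = fc
    means = fold.mul(pd.Series(base, index=list(mirnas)), axis=0)
    trend_truth = {
        f"{g}_vs_{spec.reference_group}": {
            m: call_trend(means.at[m, spec.reference_group], means.at[m, g]).label
            for m in mirnas
        }
        for g in spec.groups[1:]
    }
    return means, fold, trend_truth


def _feasible_mixture(spec: SimulationSpec, smap: SegmentMap) -> dict[str, float]:
    labels = {seg.label for seg in smap.segments}
    weights = dict(zip(READ_CATEGORIES, spec.mixture))
    for label in (MATURE_5P, MATURE_3P, UNDEFINED_COMPLEMENT):
        if label not in labels:
            weights[label] = 0.0
    total = sum(weights.values())
    if total <= 0:
        raise ValueError(f"no feasible read category for {smap.hairpin_id}")
    return {k: v / total for k, v in weights.items()}


def make_annotation_fixture(spec: SimulationSpec, seed: int) -> AnnotationFixture:
    """Toy-chromosome hairpin annotations with planted clusters and truth.

    Hairpins are laid out left to right; with probability
    ``cluster_fraction`` a hairpin is placed 0.2-3 kb after its predecessor
    (forming a cluster chain), otherwise 11-25 kb away (safely outside the
    10-kb cluster distance).  Matures sit within 5 nt of the hairpin
    termini; ``single_arm_fraction`` of hairpins get only one annotated arm.
    """
    rng = np.random.default_rng(seed)
    hairpins: list[HairpinRecord] = []
    matures: list[MatureRecord] = []
    truth = TruthBundle()

    width = len(str(max(spec.n_mirnas, 1)))
    cursor = 1000
    chain: list[HairpinRecord] = []  # current cluster chain
    for i in range(spec.n_mirnas):
        length = int(rng.integers(spec.hairpin_length[0], spec.hairpin_length[1] + 1))
        clustered = i > 0 and rng.random() < spec.cluster_fraction
        gap = int(rng.integers(200, 3000)) if clustered else int(rng.integers(11_000, 25_000))
        start = cursor + gap
        strand = "+" if rng.random() < 0.5 else "-"
        hid = f"syn-mir-{i + 1:0{width}d}"
        hp = HairpinRecord(
            hid, GenomicInterval(spec.chrom, start, start + length, strand)
        )
        hairpins.append(hp)
        cursor = start + length

        if clustered:
            # chain pairs closer than 10 kb are planted cluster truth
            for prev in chain:
                if hp.interval.start - prev.interval.end < 10_000:
                    truth.cluster_pairs.append(
                        tuple(sorted((prev.hairpin_id, hid)))  # type: ignore[arg-type]
                    )
            chain.append(hp)
        else:
            chain = [hp]

        if rng.random() < spec.single_arm_fraction:
            arms = ("5p",) if rng.random() < 0.5 else ("3p",)
        else:
            arms = ("5p", "3p")
        truth.arms[hid] = arms
        for arm in arms:
            offset = int(rng.integers(0, 6))
            if arm == "5p":
                local = (offset, offset + MATURE_LEN)
            else:
                local = (length - MATURE_LEN - offset, length - offset)
            if strand == "+":
                g = (start + local[0], start + local[1])
            else:
                g = (start + length - local[1], start + length - local[0])
            matures.append(
                MatureRecord(
                    mature_id=f"{hid}-{arm}",
                    parent=hid,
                    interval=GenomicInterval(spec.chrom, g[0], g[1], strand),
                    arm=arm,
                )
            )
    truth.cluster_pairs.sort()

    segment_maps = build_segment_maps(
        hairpins, matures, extension_flank=spec.extension_flank
    )
    adjusted = 0
    for hid, smap in segment_maps.items():
        mix = _feasible_mixture(spec, smap)
        if any(
            mix[c] == 0.0 and w > 0 for c, w in zip(READ_CATEGORIES, spec.mixture)
        ):
            adjusted += 1
        truth.mixtures[hid] = mix
    if adjusted:
        warnings.warn(
            f"renormalized segment mixture for {adjusted} hairpin(s) with "
            "infeasible categories"
        )

    mirnas = [h.hairpin_id for h in hairpins]
    means, fold, trend_truth = _plant_expression(spec, mirnas, rng)
    truth.true_means = means
    truth.fold_changes = fold
    truth.trend_truth = trend_truth
    truth.presence = {
        g: {
            m
            for m in mirnas
            if means.at[m, g] * spec.n_replicates >= 10 and means.at[m, g] > 0
        }
        for g in spec.groups
    }
    return AnnotationFixture(
        spec=spec,
        seed=seed,
        hairpins=hairpins,
        matures=matures,
        segment_maps=segment_maps,
        truth=truth,
    )


def _nb_count(rng: np.random.Generator, mean: float, size: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.negative_binomial(size, size / (size + mean)))


def _realize_read(
    rng: np.random.Generator,
    smap: SegmentMap,
    category: str,
    read_length: tuple[int, int],
) -> tuple[int, int]:
    """Window-local coordinates realizing a category exactly.

    Contained reads are drawn inside their segment; overlap reads straddle
    the 5' border of the first mature/complement segment by >= 2 nt on each
    side, staying clear of any second border.
    """
    lo, hi = read_length
    if category == OVERLAP:
        seg = next(s for s in smap.segments if s.label != EXTENSION)
        left = int(rng.integers(2, 11))
        right_min = max(2, lo - left)
        right_max = min(hi - left, (seg.end - seg.start) - 1)
        if right_min > right_max:  # very short segment: push further left
            left = lo - right_max
            right_min = right_max
        right = int(rng.integers(right_min, right_max + 1))
        return seg.start - left, seg.start + right
    candidates = [
        s for s in smap.segments if s.label == category and (s.end - s.start) >= lo
    ]
    if not candidates:
        raise ValueError(
            f"{smap.hairpin_id}: no segment of length >= {lo} for {category!r}"
        )
    weights = np.array([s.end - s.start for s in candidates], dtype=float)
    seg = candidates[rng.choice(len(candidates), p=weights / weights.sum())]
    length = int(rng.integers(lo, min(hi, seg.end - seg.start) + 1))
    start = int(rng.integers(seg.start, seg.end - length + 1))
    return start, start + length


def simulate_reads(
    fixture: AnnotationFixture,
    group: str,
    replicate: int,
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Simulate one sample's aligned reads with per-read category truth.

    Per miRNA the read count is negative-binomial around
    ``mean_reads_per_mirna`` times the group's planted fold change; each
    read's category is drawn from the miRNA's (feasibility-adjusted)
    mixture and its coordinates placed to realize that category exactly.
    A ``decoy_fraction`` of extra reads violate the quality filters —
    alternating sub-17-nt reads and 3-mismatch reads — and are flagged in
    the truth frame.

    Returns (reads, truth) where truth has columns read_id, mirna,
    category, decoy.
    """
    spec = fixture.spec
    if group not in spec.groups:
        raise ValueError(f"unknown group {group!r}")
    sample_id = f"{group}_rep{replicate}"
    ss = np.random.SeedSequence(
        entropy=fixture.seed, spawn_key=(spec.groups.index(group), replicate)
    )
    rng = np.random.default_rng(ss)

    reads: list[AlignedRead] = []
    rows: list[dict] = []
    counter = 0
    for hp in fixture.hairpins:
        hid = hp.hairpin_id
        smap = fixture.segment_maps[hid]
        fc = float(fixture.truth.fold_changes.at[hid, group])
        n = _nb_count(rng, spec.mean_reads_per_mirna * fc, spec.dispersion)
        if n == 0:
            continue
        mix = fixture.truth.mixtures[hid]
        cats = [c for c in READ_CATEGORIES if mix[c] > 0]
        probs = np.array([mix[c] for c in cats])
        drawn = rng.choice(len(cats), size=n, p=probs)
        for j in drawn:
            category = cats[j]
            s, e = _realize_read(rng, smap, category, spec.read_length)
            gs, ge = smap.to_genomic(s, e)
            mm = int(rng.random() < 0.2)
            counter += 1
            read_id = f"{sample_id}:r{counter:07d}"
            reads.append(
                AlignedRead(
                    read_id=read_id,
                    interval=GenomicInterval(
                        smap.window.chrom, gs, ge, smap.window.strand
                    ),
                    length=ge - gs,
                    mismatches=mm,
                    identity_fraction=(ge - gs - mm) / (ge - gs),
                )
            )
            rows.append(
                {"read_id": read_id, "mirna": hid, "category": category, "decoy": False}
            )

    n_decoys = int(round(spec.decoy_fraction * len(reads)))
    for d in range(n_decoys):
        hp = fixture.hairpins[int(rng.integers(0, len(fixture.hairpins)))]
        smap = fixture.segment_maps[hp.hairpin_id]
        seg = next(s for s in smap.segments if s.label != EXTENSION)
        if d % 2 == 0:  # too short
            length = int(rng.integers(10, 17))
            mm = 0
        else:  # too many mismatches
            length = int(rng.integers(17, min(spec.read_length[1], seg.end - seg.start) + 1))
            mm = 3
        start = int(rng.integers(seg.start, seg.end - length + 1))
        gs, ge = smap.to_genomic(start, start + length)
        read_id = f"{sample_id}:d{d + 1:05d}"
        reads.append(
            AlignedRead(
                read_id=read_id,
                interval=GenomicInterval(smap.window.chrom, gs, ge, smap.window.strand),
                length=length,
                mismatches=mm,
                identity_fraction=(length - mm) / length,
            )
        )
        rows.append(
            {
                "read_id": read_id,
                "mirna": hp.hairpin_id,
                "category": "decoy",
                "decoy": True,
            }
        )

    truth = pd.DataFrame(rows, columns=["read_id", "mirna", "category", "decoy"])
    fixture.truth.reads[sample_id] = truth
    return reads, truth


def simulate_count_matrix(
    spec: SimulationSpec, seed: int
) -> tuple[CountMatrix, TruthBundle]:
    """Simulate a raw miRNA x sample count matrix with planted trends.

    Counts are negative-binomial around the planted per-group means; the
    U/D/S trend truth is derived from the true means under the same +/-20%
    band the comparator uses.
    """
    rng = np.random.default_rng(seed)
    width = len(str(max(spec.n_mirnas, 1)))
    mirnas = [f"syn-mir-{i + 1:0{width}d}" for i in range(spec.n_mirnas)]
    means, fold, trend_truth = _plant_expression(spec, mirnas, rng)

    samples = spec.sample_sheet()
    data = pd.DataFrame(0, index=mirnas, columns=list(samples["sample_id"]))
    for row in samples.itertuples(index=False):
        for m in mirnas:
            data.at[m, row.sample_id] = _nb_count(
                rng, float(means.at[m, row.group]), spec.dispersion
            )
    data.index.name = "mirna"

    truth = TruthBundle(
        true_means=means,
        fold_changes=fold,
        trend_truth=trend_truth,
        presence={
            g: {
                m
                for m in mirnas
                if means.at[m, g] > 0 and means.at[m, g] * spec.n_replicates >= 10
            }
            for g in spec.groups
        },
    )
    return CountMatrix(data=data, samples=samples, normalized=False), truth


def write_reads_bed(reads: Sequence[AlignedRead], path: str | Path) -> None:
    """BED6 with the mismatch count in the score column."""
    with open(path, "w") as out:
        for r in reads:
            iv = r.interval
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.read_id}\t{r.mismatches}"
                f"\t{iv.strand}\n"
            )


def simulate_experiment(spec: SimulationSpec, seed: int, outdir: str | Path) -> dict:
    """Write a complete synthetic dataset: GFF3, per-sample BED6 reads,
    sample sheet CSV, and a truth JSON.  Returns the file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture = make_annotation_fixture(spec, seed)
    gff = outdir / "annotation.gff3"
    write_gff3(fixture.hairpins, fixture.matures, gff)

    sheet = spec.sample_sheet()
    sheet_path = outdir / "samples.csv"
    sheet.to_csv(sheet_path, index=False)

    read_paths = {}
    for row in sheet.itertuples(index=False):
        reads, _ = simulate_reads(fixture, row.group, int(row.replicate))
        path = outdir / f"{row.sample_id}.bed"
        write_reads_bed(reads, path)
        read_paths[row.sample_id] = str(path)

    truth_path = outdir / "truth.json"
    fixture.truth.to_json(truth_path)
    return {
        "gff": str(gff),
        "samples": str(sheet_path),
        "reads": read_paths,
        "truth": str(truth_path),
    }
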