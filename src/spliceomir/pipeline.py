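"""One reproducible run: annotate -> classify -> quantify -> compare.

``run_pipeline`` consumes a :class:`RunConfig`, writes every intermediate
table (segment maps, calls, count matrices, Venn/trend/consistency tables)
plus a JSON summary with the read counts surviving each filter stage, the
config hash and the seed.  Re-running with the same config and inputs is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, compare, quantify, reads as reads_mod

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Paths and thresholds for a pipeline run.

    Threshold defaults are the assay's standard values: reads of >= 17 nt
    with <= 2 mismatches at >= 90% identity; >= 10 pooled reads per group
    for presence; a +/-20% Same band; adjusted p < 0.05; clusters closer
    than 10 kb; a 50-nt extension flank; > 50 joint reads for the
    top-expressed comparison set.
    """

    gff: str
    reads: dict[str, str]  # sample_id -> path
    samples: str
    out_dir: str
    read_format: str = "bed"
    literature: str | None = None
    de_table: str | None = None
    ref_group: str | None = None  # default: first group in the sheet
    test_group: str | None = None  # default: last group in the sheet
    min_length: int = 17
    max_mismatches: int = 2
    min_identity: float = 0.90
    min_group_reads: int = 10
    band: float = 0.20
    alpha: float = 0.05
    cluster_distance: int = 10_000
    extension_flank: int = 50
    min_joint_reads: float = 50.0
    strand_mode: str = "same"
    pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_length",
            "max_mismatches",
            "min_identity",
            "min_group_reads",
            "band",
            "alpha",
            "cluster_distance",
            "extension_flank",
            "min_joint_reads",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (out_dir excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dict it also writes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("spliceomir")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    try:
        _run(config, out, summary)
    finally:
        root.removeHandler(handler)
        handler.close()
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _run(config: RunConfig, out: Path, summary: dict) -> None:
    # --- annotate ---------------------------------------------------------
    annotate = _stage("annotate")(_annotate)
    maps, pairs = annotate(config, out)
    summary["stages"]["annotate"] = {
        "n_hairpins": len(maps),
        "n_cluster_pairs": len(pairs),
    }

    # --- classify ---------------------------------------------------------
    classify = _stage("classify")(_classify)
    calls, read_counts = classify(config, out, maps)
    summary["stages"]["classify"] = read_counts

    # --- quantify ---------------------------------------------------------
    quantify_stage = _stage("quantify")(_quantify)
    counts, presence, rpm, means = quantify_stage(config, out, calls)
    summary["stages"]["quantify"] = {
        "n_mirnas_detected": int(counts.data.shape[0]),
        "n_mirnas_present": int(len(set.union(*presence.values()))) if presence else 0,
        "presence_per_group": {g: len(s) for g, s in presence.items()},
    }

    # --- compare ----------------------------------------------------------
    compare_stage = _stage("compare")(_compare)
    compare_summary = compare_stage(config, out, counts, presence, means)
    summary["stages"]["compare"] = compare_summary


def _annotate(config: RunConfig, out: Path):
    hairpins, matures = annotation.read_hairpin_annotations(config.gff)
    maps = annotation.build_segment_maps(
        hairpins, matures, extension_flank=config.extension_flank
    )
    pairs = annotation.find_cluster_neighbors(
        hairpins, max_distance=config.cluster_distance
    )
    annotation.write_segment_maps_tsv(maps, out / "segment_maps.tsv")
    annotation.write_segment_maps_bed(maps, out / "segment_maps.bed")
    annotation.write_cluster_pairs_tsv(pairs, out / "cluster_pairs.tsv")
    return maps, pairs


def _classify(config: RunConfig, out: Path, maps):
    index = reads_mod.SegmentIndex(maps)
    frames = []
    stage_counts = {"loaded": 0, "passed_filters": 0, "assigned": 0, "unassigned": 0}
    for sample_id in sorted(config.reads):
        loaded = reads_mod.load_reads(config.reads[sample_id], config.read_format)
        kept = reads_mod.filter_reads(
            loaded,
            min_length=config.min_length,
            max_mismatches=config.max_mismatches,
            min_identity=config.min_identity,
        )
        calls = reads_mod.assign_reads(kept, index, strand_mode=config.strand_mode)
        frame = reads_mod.calls_to_frame(calls, sample_id=sample_id)
        frames.append(frame)
        stage_counts["loaded"] += len(loaded)
        stage_counts["passed_filters"] += len(kept)
        n_un = int((frame["category"] == annotation.UNASSIGNED).sum())
        stage_counts["unassigned"] += n_un
        stage_counts["assigned"] += len(kept) - n_un
    all_calls = pd.concat(frames, ignore_index=True)
    reads_mod.write_calls_tsv(all_calls, out / "calls.tsv")
    assigned = all_calls[all_calls["category"] != annotation.UNASSIGNED]
    for by, fname in (("miRNA", "partition_by_mirna.tsv"), ("sample", "partition_by_sample.tsv")):
        raw = reads_mod.segment_partition(assigned, by=by, normalized=False)
        norm = reads_mod.segment_partition(assigned, by=by, normalized=True)
        raw.add_suffix("_reads").join(norm.add_suffix("_frac")).to_csv(
            out / fname, sep="\t"
        )
    return all_calls, stage_counts


def _quantify(config: RunConfig, out: Path, calls: pd.DataFrame):
    samples = quantify.read_sample_sheet(config.samples)
    counts = quantify.build_count_matrix(calls, samples)
    presence, filtered = quantify.presence_filter(
        counts, min_reads_per_group=config.min_group_reads
    )
    rpm = quantify.rpm_normalize(filtered)
    means = quantify.group_means(rpm)
    quantify.write_counts_tsv(counts, out / "counts_raw.tsv")
    quantify.write_counts_tsv(rpm, out / "counts_rpm.tsv")
    means.to_csv(out / "group_means_rpm.tsv", sep="\t")
    quantify.replicate_correlation(filtered).to_csv(
        out / "replicate_correlation.tsv", sep="\t"
    )
    return filtered, presence, rpm, means


def _compare(config: RunConfig, out: Path, counts, presence, means):
    samples = counts.samples
    groups = list(dict.fromkeys(samples["group"]))
    ref = config.ref_group or groups[0]
    test = config.test_group or groups[-1]
    if ref not in groups or test not in groups:
        raise ValueError(f"ref/test group not in sample sheet: {ref!r}, {test!r}")
    result: dict = {}

    if len(groups) == 3:
        venn = compare.venn_partition({g: presence[g] for g in groups})
        venn.to_frame().to_csv(out / "venn.tsv", sep="\t", index=False)
        with open(out / "venn.json", "w") as fh:
            json.dump(
                {
                    "union_size": venn.union_size,
                    "set_totals": {g: venn.set_total(g) for g in groups},
                    "regions": {
                        "&".join(sorted(k)): v for k, v in venn.regions.items()
                    },
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        result["venn_union"] = venn.union_size

    universe = means.index
    if config.de_table:
        de = quantify.read_de_table(config.de_table)
        significant = quantify.select_significant(de, alpha=config.alpha)
        universe = universe.intersection(significant["mirna"])
        result["n_significant"] = int(len(universe))

    trend_labels = {}
    for g in groups:
        if g == ref:
            continue
        table = compare.trend_table(means.loc[universe], ref, g, band=config.band)
        table.to_csv(out / f"trends_{g}_vs_{ref}.tsv", sep="\t")
        trend_labels[f"{g}_vs_{ref}"] = dict(table["label"])
    if trend_labels:
        trend_summary, paired = compare.partition_trends(trend_labels)
        trend_summary.to_csv(out / "trend_partition.tsv", sep="\t", index=False)
        paired.to_csv(out / "trend_paired.tsv", sep="\t")
        result["trend_counts"] = {
            name: {
                row["label"]: int(row["count"])
                for _, row in trend_summary[trend_summary["comparison"] == name].iterrows()
            }
            for name in trend_labels
        }

    fc = compare.fold_change_table(means, ref, test, pseudocount=config.pseudocount)
    fc.to_frame().to_csv(out / f"fold_change_{test}_vs_{ref}.tsv", sep="\t")

    top = quantify.select_top_expressed(
        counts, groups=(ref, test), min_joint_reads=config.min_joint_reads
    )
    result["n_top_expressed"] = len(top)

    if config.literature:
        literature = compare.read_literature_table(config.literature)
        trends = compare.trend_table(means, ref, test, band=config.band)
        selected = trends.loc[trends.index.intersection(pd.Index(top))]
        table = compare.consistency_table(selected, literature)
        table.to_csv(out / "consistency.tsv", sep="\t")
        result["consistency_verdicts"] = (
            table["verdict"].value_counts().sort_index().to_dict()
        )
    else:
        result["consistency_skipped"] = True
        logger.info("no literature table given; consistency stage skipped")
    return result
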