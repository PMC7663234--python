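"""Comparative layer: Venn partitions, expression trends, literature consistency.

Presence sets from three cell lines are partitioned into the seven regions
of a three-set Venn diagram.  Expression changes against a reference group
are discretized to Up / Down / Same, where Same means the test mean stays
within +/-20% of the reference mean (band boundaries inclusive to Same).
Each trend can then be scored against literature-mined direction
annotations (miRCancer-style Up/Down publication counts per miRNA): a
unanimous literature direction that matches the observed trend is
*consistent*, a unanimous contradiction *opposite*, divided literature
*mixed*, one or two publications *minimal support*, and no record at all
*not available*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_BAND = 0.20
DEFAULT_PSEUDOCOUNT = 0.5

TREND_UP = "U"
TREND_DOWN = "D"
TREND_SAME = "S"

VERDICT_CONSISTENT = "consistent"
VERDICT_OPPOSITE = "opposite"
VERDICT_MIXED = "mixed"
VERDICT_MINIMAL = "minimal_support"
VERDICT_NA = "not_available"

MINIMAL_SUPPORT_MAX_PUBLICATIONS = 2


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VennPartition:
    """Seven-region partition of three named sets.

    ``regions`` is keyed by the frozenset of set names whose exclusive
    intersection the region is (e.g. ``frozenset({'A'})`` for "A only").
    """

    set_names: tuple[str, str, str]
    regions: dict[frozenset, int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def set_total(self, name: str) -> int:
        if name not in self.set_names:
            raise KeyError(name)
        return sum(count for key, count in self.regions.items() if name in key)

    def region(self, *names: str) -> int:
        return self.regions[frozenset(names)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(key)), "count": count}
            for key, count in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows)


def venn_partition(presence_sets: Mapping[str, set]) -> VennPartition:
    """Exact seven-region partition of three named presence sets."""
    if len(presence_sets) != 3:
        raise ValueError(f"need exactly 3 sets, got {len(presence_sets)}")
    names = tuple(presence_sets)
    sets = {n: set(presence_sets[n]) for n in names}
    regions: dict[frozenset, int] = {}
    for mask in range(1, 8):
        inside = [n for i, n in enumerate(names) if mask >> i & 1]
        outside = [n for n in names if n not in inside]
        members = set.intersection(*(sets[n] for n in inside))
        for n in outside:
            members -= sets[n]
        regions[frozenset(inside)] = len(members)
    return VennPartition(set_names=names, regions=regions)


def sets_from_region_counts(
    names: tuple[str, str, str], region_counts: Mapping[frozenset, int]
) -> dict[str, set]:
    """Reconstruct three sets realizing given exclusive region counts.

    Members are synthetic placeholder ids; useful for re-deriving set and
    union totals from published region counts.
    """
    sets: dict[str, set] = {n: set() for n in names}
    for key, count in region_counts.items():
        tag = "+".join(sorted(key))
        for i in range(count):
            member = f"{tag}#{i}"
            for name in key:
                sets[name].add(member)
    return sets


# ---------------------------------------------------------------------------
# Trend discretization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrendCall:
    """Discretized expression change of one miRNA versus the reference."""

    mirna: str
    ref_mean: float
    test_mean: float
    ratio: float  # test/ref; inf when ref == 0 < test, nan when both zero
    label: str


def call_trend(
    ref_mean: float,
    test_mean: float,
    band: float = DEFAULT_BAND,
    mirna: str = "",
) -> TrendCall:
    """Up/Down/Same call with a stability band around the reference.

    Same means ``(1 - band) <= test/ref <= (1 + band)`` (both boundaries
    inclusive to Same).  Zero handling is symmetric: both means zero is
    Same; a zero reference with a positive test mean is Up; a positive
    reference with a zero test mean falls below the band, hence Down.
    """
    if ref_mean < 0 or test_mean < 0:
        raise ValueError("means must be non-negative")
    if ref_mean == 0 and test_mean == 0:
        return TrendCall(mirna, ref_mean, test_mean, float("nan"), TREND_SAME)
    if ref_mean == 0:
        return TrendCall(mirna, ref_mean, test_mean, float("inf"), TREND_UP)
    ratio = test_mean / ref_mean
    if ratio > 1 + band:
        label = TREND_UP
    elif ratio < 1 - band:
        label = TREND_DOWN
    else:
        label = TREND_SAME
    return TrendCall(mirna, ref_mean, test_mean, ratio, label)


def trend_table(
    group_means: pd.DataFrame,
    ref: str,
    test: str,
    band: float = DEFAULT_BAND,
) -> pd.DataFrame:
    """Per-miRNA trend calls for one test-vs-reference comparison."""
    for g in (ref, test):
        if g not in group_means.columns:
            raise ValueError(f"unknown group {g!r}")
    calls = [
        call_trend(row[ref], row[test], band, mirna=str(mirna))
        for mirna, row in group_means.iterrows()
    ]
    return pd.DataFrame(
        {
            "mirna": [c.mirna for c in calls],
            "ref_mean": [c.ref_mean for c in calls],
            "test_mean": [c.test_mean for c in calls],
            "ratio": [c.ratio for c in calls],
            "label": [c.label for c in calls],
        }
    ).set_index("mirna")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def partition_trends(
    trend_labels: Mapping[str, Mapping[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and rounded percentages of U/D/S across comparisons.

    ``trend_labels`` maps comparison name -> {mirna -> label}; every
    comparison must cover the same miRNA universe.  Returns (summary,
    paired) where summary has one row per (comparison, label) with count
    and integer percentage (rounded half away from zero), and paired lists
    each miRNA's label under every comparison.
    """
    comparisons = list(trend_labels)
    if not comparisons:
        raise ValueError("no comparisons given")
    universe = set(trend_labels[comparisons[0]])
    for name in comparisons[1:]:
        if set(trend_labels[name]) != universe:
            raise ValueError("comparisons cover different miRNA universes")
    total = len(universe)

    rows = []
    for name in comparisons:
        labels = trend_labels[name]
        for lab in (TREND_UP, TREND_DOWN, TREND_SAME):
            count = sum(1 for v in labels.values() if v == lab)
            pct = _round_half_away(count / total * 100) if total else 0
            rows.append(
                {"comparison": name, "label": lab, "count": count, "percent": pct}
            )
    summary = pd.DataFrame(rows)
    paired = pd.DataFrame(
        {name: pd.Series(dict(trend_labels[name])) for name in comparisons}
    ).sort_index()
    paired.index.name = "mirna"
    return summary, paired


# ---------------------------------------------------------------------------
# Literature consistency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LiteratureRecord:
    """Publication-count summary of a miRNA's reported cancer direction."""

    mirna: str
    n_publications_up: int
    n_publications_down: int

    def __post_init__(self) -> None:
        if self.n_publications_up < 0 or self.n_publications_down < 0:
            raise ValueError("publication counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_publications_up + self.n_publications_down


@dataclass(frozen=True)
class ConsistencyCall:
    mirna: str
    sf_trend: str
    verdict: str


def consistency_classify(
    sf_trend: TrendCall | str,
    literature: LiteratureRecord | None,
    mirna: str = "",
) -> ConsistencyCall:
    """Score an observed trend against literature direction annotations.

    Verdicts, in precedence order: no record (or a record without any
    publication) -> ``not_available``; 1-2 publications total ->
    ``minimal_support``; both directions reported -> ``mixed``; a unanimous
    direction agreeing with the trend -> ``consistent``, disagreeing ->
    ``opposite``.  A Same trend against unanimous literature has no natural
    direction to match and is scored ``mixed``.
    """
    if isinstance(sf_trend, TrendCall):
        label = sf_trend.label
        mirna = mirna or sf_trend.mirna
    else:
        label = sf_trend
    if label not in (TREND_UP, TREND_DOWN, TREND_SAME):
        raise ValueError(f"unknown trend label {label!r}")

    if literature is None or literature.total == 0:
        return ConsistencyCall(mirna, label, VERDICT_NA)
    mirna = mirna or literature.mirna
    if literature.total <= MINIMAL_SUPPORT_MAX_PUBLICATIONS:
        return ConsistencyCall(mirna, label, VERDICT_MINIMAL)
    if literature.n_publications_up > 0 and literature.n_publications_down > 0:
        return ConsistencyCall(mirna, label, VERDICT_MIXED)
    reported = TREND_UP if literature.n_publications_up > 0 else TREND_DOWN
    if label == TREND_SAME:
        return ConsistencyCall(mirna, label, VERDICT_MIXED)
    verdict = VERDICT_CONSISTENT if label == reported else VERDICT_OPPOSITE
    return ConsistencyCall(mirna, label, verdict)


def consistency_table(
    trends: pd.DataFrame,
    literature: Mapping[str, LiteratureRecord],
) -> pd.DataFrame:
    """Consistency verdicts for every miRNA in a trend table."""
    calls = [
        consistency_classify(str(row["label"]), literature.get(str(mirna)), str(mirna))
        for mirna, row in trends.iterrows()
    ]
    return pd.DataFrame(
        {
            "mirna": [c.mirna for c in calls],
            "sf_trend": [c.sf_trend for c in calls],
            "verdict": [c.verdict for c in calls],
        }
    ).set_index("mirna")


def read_literature_table(path: str | Path) -> dict[str, LiteratureRecord]:
    """Literature CSV: either counts (mirna, n_up, n_down) or long format
    (mirna, direction) with one row per publication."""
    table = pd.read_csv(path)
    if {"n_up", "n_down"} <= set(table.columns):
        return {
            str(r.mirna): LiteratureRecord(str(r.mirna), int(r.n_up), int(r.n_down))
            for r in table.itertuples(index=False)
        }
    if "direction" in table.columns:
        return literature_from_long(table)
    raise ValueError(
        f"literature table {path} needs (mirna, n_up, n_down) or (mirna, direction)"
    )


def literature_from_long(table: pd.DataFrame) -> dict[str, LiteratureRecord]:
    """Collapse per-publication rows (mirna, direction in {Up, Down}) to counts."""
    bad = set(table["direction"]) - {"Up", "Down"}
    if bad:
        raise ValueError(f"unknown literature directions {sorted(bad)}")
    out = {}
    for mirna, sub in table.groupby("mirna"):
        out[str(mirna)] = LiteratureRecord(
            str(mirna),
            int((sub["direction"] == "Up").sum()),
            int((sub["direction"] == "Down").sum()),
        )
    return out


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------


def fold_change_table(
    group_means: pd.DataFrame,
    ref: str,
    test: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-miRNA log2 ratio of test to reference group means.

    A symmetric pseudocount keeps zero means finite; for means well above
    the pseudocount the value approaches the plain log2 ratio.
    """
    for g in (ref, test):
        if g not in group_means.columns:
            raise ValueError(f"unknown group {g!r}")
    values = np.log2(
        (group_means[test] + pseudocount) / (group_means[ref] + pseudocount)
    )
    values.name = f"log2({test}/{ref})"
    return values
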