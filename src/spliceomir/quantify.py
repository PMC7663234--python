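"""miRNA x sample count matrices: thresholds, normalization, group summaries.

The experimental design is a handful of groups (cell lines) with a few
replicates each.  Counts are reads assigned to a hairpin (any segmental
category by default).  The expression presence rule pools a group's
replicates: a miRNA counts as expressed in a group when the group's summed
raw reads reach ``min_reads_per_group`` (default 10).  RPM normalization
divides by the per-sample total of miRNA-assigned reads — not the raw
library size, since only miRNA-aligned reads survive upstream filtering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pathlib import Path
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

DEFAULT_MIN_READS_PER_GROUP = 10
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_JOINT_READS = 50


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet CSV with columns sample_id, group, replicate."""
    sheet = pd.read_csv(path)
    missing = {"sample_id", "group", "replicate"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns {sorted(missing)}")
    return validate_samples(sheet)


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    if samples.duplicated(subset=["group", "replicate"]).any():
        raise ValueError("duplicate (group, replicate) in sample sheet")
    return samples.reset_index(drop=True)


@dataclass(frozen=True)
class CountMatrix:
    """miRNA x sample matrix plus its sample sheet.

    ``data`` rows are hairpin ids, columns sample ids; ``normalized`` marks
    RPM-scaled values (raw otherwise).  ``assigned_totals`` remembers each
    sample's total of miRNA-assigned reads at build time, so RPM scaling
    keeps the same denominator after rows are dropped by the presence
    filter.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False
    assigned_totals: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("count matrix has negative entries")
        unknown = set(self.data.columns) - set(self.samples["sample_id"])
        if unknown:
            raise ValueError(f"samples missing from sheet: {sorted(unknown)}")

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.samples["group"]))

    def samples_of(self, group: str) -> list[str]:
        hits = self.samples.loc[self.samples["group"] == group, "sample_id"]
        if hits.empty:
            raise ValueError(f"unknown group {group!r}")
        return list(hits)


def build_count_matrix(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    include_categories: str | Sequence[str] = "all",
) -> CountMatrix:
    """Count assigned calls per (hairpin, sample).

    ``calls`` needs columns sample_id, hairpin_id, category (unassigned rows
    are excluded).  ``include_categories`` restricts counting, e.g. to
    mature segments only.  Samples present in the calls but absent from the
    sheet are an error; sheet samples without calls get a zero column.
    """
    samples = validate_samples(samples)
    assigned = calls[calls["hairpin_id"].notna() & (calls["category"] != "unassigned")]
    if include_categories != "all":
        assigned = assigned[assigned["category"].isin(set(include_categories))]
    unknown = set(assigned["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"calls reference samples not in the sheet: {sorted(unknown)}")
    table = (
        assigned.groupby(["hairpin_id", "sample_id"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=samples["sample_id"], fill_value=0)
    )
    table.index.name = "mirna"
    table = table.sort_index()
    return CountMatrix(
        data=table,
        samples=samples,
        normalized=False,
        assigned_totals=table.sum(axis=0),
    )


def presence_filter(
    counts: CountMatrix,
    min_reads_per_group: int = DEFAULT_MIN_READS_PER_GROUP,
) -> tuple[dict[str, set[str]], CountMatrix]:
    """Per-group presence sets and the matrix restricted to present miRNAs.

    A miRNA is present in a group when its raw reads summed over the group's
    replicates are >= ``min_reads_per_group``; rows present in no group are
    dropped (values are never altered).  Applying the filter twice is a
    no-op.
    """
    if counts.normalized:
        raise ValueError("presence filter must run on raw counts")
    presence: dict[str, set[str]] = {}
    keep = pd.Series(False, index=counts.data.index)
    for group in counts.groups():
        total = counts.data[counts.samples_of(group)].sum(axis=1)
        members = total[total >= min_reads_per_group].index
        presence[group] = set(members)
        keep.loc[members] = True
    filtered = replace(counts, data=counts.data.loc[keep])
    return presence, filtered


def rpm_normalize(counts: CountMatrix) -> CountMatrix:
    """Reads-per-million scaling against per-sample assigned-read totals.

    Uses the matrix's remembered ``assigned_totals`` when present (so the
    denominator is unaffected by row filtering), else the current column
    sums.
    """
    totals = (
        counts.assigned_totals
        if counts.assigned_totals is not None
        else counts.data.sum(axis=0)
    )
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValueError(
            f"cannot RPM-normalize: zero assigned reads in sample(s) "
            f"{list(zero.index)}"
        )
    return replace(counts, data=counts.data / totals * 1e6, normalized=True)


def group_means(counts: CountMatrix) -> pd.DataFrame:
    """Arithmetic mean over replicates, one column per group."""
    return pd.DataFrame(
        {g: counts.data[counts.samples_of(g)].mean(axis=1) for g in counts.groups()}
    )


def replicate_correlation(counts: CountMatrix, method: str = "pearson") -> pd.DataFrame:
    """Sample-sample correlation of expression profiles.

    Pearson is computed on log10(x + 1)-transformed values; ``spearman``
    ranks the raw profiles.  A constant profile has no defined correlation
    and yields NaN against every other sample.
    """
    if counts.data.shape[1] < 2:
        raise ValueError("need at least two samples for a correlation matrix")
    if method == "pearson":
        transformed = np.log10(counts.data + 1)
        return transformed.corr(method="pearson")
    if method == "spearman":
        return counts.data.corr(method="spearman")
    raise ValueError(f"unknown correlation method {method!r}")


def select_significant(de_table: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Rows with adjusted p-value strictly below alpha, most significant first.

    The differential-expression table is produced externally (any count
    model); required columns are ``mirna`` and ``padj``.
    """
    if "padj" not in de_table.columns:
        raise ValueError("differential-expression table lacks a 'padj' column")
    hits = de_table[de_table["padj"] < alpha]
    return hits.sort_values("padj", kind="stable").reset_index(drop=True)


def select_top_expressed(
    counts: CountMatrix,
    groups: tuple[str, str],
    min_joint_reads: float = DEFAULT_MIN_JOINT_READS,
) -> list[str]:
    """miRNAs whose reads summed over two groups exceed ``min_joint_reads``.

    The bound is strict (> 50 by default), computed on the stated pair of
    groups only.
    """
    ref, test = groups
    joint = counts.data[counts.samples_of(ref) + counts.samples_of(test)].sum(axis=1)
    return sorted(joint[joint > min_joint_reads].index)


def write_counts_tsv(counts: CountMatrix, path: str | Path) -> None:
    counts.data.to_csv(path, sep="\t")


def read_de_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "padj" not in table.columns:
        raise ValueError(f"DE table {path} lacks a 'padj' column")
    return table
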