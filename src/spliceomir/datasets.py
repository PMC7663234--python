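"""Published summary data for worked examples and cross-checks.

These are reported summary statistics from spliceosome-fraction (SF)
small-RNA profiling of three breast-derived cell lines — the
non-tumorigenic MCF-10A and the carcinoma lines MCF-7 and MDA-MB-231 —
kept here as inputs for worked examples: the three-set presence-overlap
region counts, the Up/Down/Same tallies over the significantly
differentially expressed SF-miRNAs, and the group-mean expression table of
the 25 most abundant SF-miRNAs with the reported trend labels for each
cancer line versus MCF-10A.
"""

from __future__ import annotations

import pandas as pd

#: canonical group names used throughout the examples
GROUP_MCF10A = "MCF10A"
GROUP_MCF7 = "MCF7"
GROUP_MDA = "MDA231"

VENN_SET_NAMES = (GROUP_MCF10A, GROUP_MCF7, GROUP_MDA)

#: exclusive region counts of the SF-miRNA presence sets of the three lines
VENN_REGION_COUNTS: dict[frozenset, int] = {
    frozenset({GROUP_MCF10A}): 83,
    frozenset({GROUP_MCF7}): 3,
    frozenset({GROUP_MDA}): 28,
    frozenset({GROUP_MCF10A, GROUP_MCF7}): 3,
    frozenset({GROUP_MCF10A, GROUP_MDA}): 24,
    frozenset({GROUP_MCF7, GROUP_MDA}): 5,
    frozenset({GROUP_MCF10A, GROUP_MCF7, GROUP_MDA}): 45,
}

#: reported U/D/S tallies over the 73 significant SF-miRNAs, per comparison
#: (each cancer line versus the MCF-10A reference)
TREND_TALLIES: dict[str, dict[str, int]] = {
    f"{GROUP_MCF7}_vs_{GROUP_MCF10A}": {"U": 19, "D": 52, "S": 2},
    f"{GROUP_MDA}_vs_{GROUP_MCF10A}": {"U": 26, "D": 45, "S": 2},
}

N_SIGNIFICANT = 73

# mirna, mean MCF-10A, mean MCF-7, mean MDA-MB-231, trend MCF7/MCF10A,
# trend MDA/MCF10A (reported group means, RPM scale)
_TOP_EXPRESSED_ROWS = [
    ("hsa-mir-6087", 5847.1, 1124.3, 705.3, "D", "D"),
    ("hsa-mir-21", 362.6, 1173.3, 1155.5, "U", "U"),
    ("hsa-mir-1246", 484.6, 83.8, 32.0, "D", "D"),
    ("hsa-mir-3687", 460.6, 34.9, 8.2, "D", "D"),
    ("hsa-mir-100", 13.1, 0.0, 483.4, "D", "U"),
    ("hsa-mir-612", 450.5, 1.6, 3.0, "D", "D"),
    ("hsa-mir-7704", 296.4, 41.8, 20.2, "D", "D"),
    ("hsa-let-7f-1", 54.0, 90.6, 184.7, "U", "U"),
    ("hsa-let-7f-2", 32.1, 86.0, 173.2, "U", "U"),
    ("hsa-let-7g", 20.4, 84.8, 170.6, "U", "U"),
    ("hsa-mir-3064", 196.6, 46.3, 8.8, "D", "D"),
    ("hsa-mir-1291", 88.0, 147.6, 14.9, "U", "D"),
    ("hsa-let-7i", 21.2, 62.3, 140.3, "U", "U"),
    ("hsa-mir-5047", 163.8, 14.5, 1.2, "D", "D"),
    ("hsa-mir-622", 54.6, 74.2, 16.8, "U", "D"),
    ("hsa-mir-19b-1", 14.0, 60.1, 50.6, "U", "U"),
    ("hsa-mir-20a", 15.1, 53.2, 51.0, "U", "U"),
    ("hsa-mir-222", 6.5, 0.0, 105.5, "D", "U"),
    ("hsa-mir-30a", 5.2, 0.8, 91.1, "D", "U"),
    ("hsa-mir-148a", 47.4, 32.4, 4.0, "D", "D"),
    ("hsa-mir-7161", 74.7, 1.9, 1.2, "D", "D"),
    ("hsa-mir-24-1", 27.1, 10.2, 40.3, "D", "U"),
    ("hsa-mir-1248", 66.8, 4.5, 5.3, "D", "D"),
    ("hsa-mir-3607", 57.0, 10.8, 4.3, "D", "D"),
    ("hsa-mir-221", 8.5, 0.0, 59.7, "D", "U"),
]


def top_expressed_table() -> pd.DataFrame:
    """Reported group means and trends of the 25 most abundant SF-miRNAs."""
    return pd.DataFrame(
        _TOP_EXPRESSED_ROWS,
        columns=[
            "mirna",
            f"mean_{GROUP_MCF10A}",
            f"mean_{GROUP_MCF7}",
            f"mean_{GROUP_MDA}",
            f"trend_{GROUP_MCF7}",
            f"trend_{GROUP_MDA}",
        ],
    ).set_index("mirna")
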