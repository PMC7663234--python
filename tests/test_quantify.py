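"""Count matrices, presence thresholds, normalization, group summaries."""

import numpy as np
import pandas as pd
import pytest

from spliceomir.quantify import (
    CountMatrix,
    build_count_matrix,
    group_means,
    presence_filter,
    replicate_correlation,
    rpm_normalize,
    select_significant,
    select_top_expressed,
    validate_samples,
)


def _sheet(groups=("G1", "G2", "G3"), reps=3):
    rows = [
        {"sample_id": f"{g}_rep{r}", "group": g, "replicate": r}
        for g in groups
        for r in range(1, reps + 1)
    ]
    return pd.DataFrame(rows)


def _matrix(data: dict, groups=("G1", "G2", "G3"), reps=3):
    sheet = _sheet(groups, reps)
    frame = pd.DataFrame(data, index=list(sheet["sample_id"])).T
    return CountMatrix(data=frame, samples=sheet)


class TestBuildCountMatrix:
    def test_counts_calls_per_cell(self):
        calls = pd.DataFrame(
            {
                "sample_id": ["A"] * 3 + ["B"],
                "read_id": ["r1", "r2", "r3", "r4"],
                "hairpin_id": ["mirX"] * 3 + ["mirX"],
                "category": ["mature_5p"] * 4,
            }
        )
        sheet = pd.DataFrame(
            {"sample_id": ["A", "B"], "group": ["g1", "g2"], "replicate": [1, 1]}
        )
        cm = build_count_matrix(calls, sheet)
        assert cm.data.loc["mirX", "A"] == 3 and cm.data.loc["mirX", "B"] == 1

    def test_unknown_sample_is_an_error(self):
        calls = pd.DataFrame(
            {
                "sample_id": ["ghost"],
                "read_id": ["r1"],
                "hairpin_id": ["mirX"],
                "category": ["mature_5p"],
            }
        )
        sheet = pd.DataFrame(
            {"sample_id": ["A"], "group": ["g1"], "replicate": [1]}
        )
        with pytest.raises(ValueError, match="ghost"):
            build_count_matrix(calls, sheet)

    def test_category_restriction_drops_non_mature(self):
        calls = pd.DataFrame(
            {
                "sample_id": ["A"] * 10,
                "read_id": [f"r{i}" for i in range(10)],
                "hairpin_id": ["mirX"] * 10,
                "category": ["mature_5p"] * 6 + ["overlap"] * 3 + ["extension"],
            }
        )
        sheet = pd.DataFrame({"sample_id": ["A"], "group": ["g"], "replicate": [1]})
        full = build_count_matrix(calls, sheet)
        mature = build_count_matrix(
            calls, sheet, include_categories={"mature_5p", "mature_3p"}
        )
        assert full.data.loc["mirX", "A"] == 10
        assert mature.data.loc["mirX", "A"] == 6

    def test_duplicate_group_replicate_rejected(self):
        sheet = pd.DataFrame(
            {"sample_id": ["A", "B"], "group": ["g", "g"], "replicate": [1, 1]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            validate_samples(sheet)


class TestPresenceFilter:
    def test_boundary_at_ten_pooled_reads(self):
        cm = _matrix(
            {
                "below": [3, 3, 3, 0, 0, 0, 0, 0, 0],
                "at": [4, 3, 3, 0, 0, 0, 0, 0, 0],
            }
        )
        presence, filtered = presence_filter(cm)
        assert "below" not in presence["G1"] and "at" in presence["G1"]
        assert list(filtered.data.index) == ["at"]

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        cm = _matrix(
            {f"m{i}": list(rng.integers(0, 20, 9)) for i in range(30)}
        )
        p1, f1 = presence_filter(cm)
        p2, f2 = presence_filter(f1)
        assert p1 == p2
        pd.testing.assert_frame_equal(f1.data, f2.data)

    def test_rows_removed_but_values_untouched(self):
        cm = _matrix({"keep": [20] * 9, "drop": [0] * 9})
        _, filtered = presence_filter(cm)
        pd.testing.assert_frame_equal(filtered.data, cm.data.loc[["keep"]])

    def test_planted_presence_pattern_recovered(self):
        # m_all present everywhere; m_g1 only in G1; m_none nowhere
        cm = _matrix(
            {
                "m_all": [30] * 9,
                "m_g1": [30, 30, 30, 0, 1, 0, 0, 0, 2],
                "m_none": [1, 1, 1, 2, 0, 0, 3, 0, 0],
            }
        )
        presence, _ = presence_filter(cm)
        assert presence["G1"] == {"m_all", "m_g1"}
        assert presence["G2"] == {"m_all"}
        assert presence["G3"] == {"m_all"}


class TestRpmNormalize:
    def test_simple_arithmetic(self):
        sheet = pd.DataFrame(
            {"sample_id": ["A"], "group": ["g"], "replicate": [1]}
        )
        cm = CountMatrix(
            data=pd.DataFrame({"A": [5, 49_995]}, index=["mirX", "rest"]),
            samples=sheet,
        )
        rpm = rpm_normalize(cm)
        assert rpm.data.loc["mirX", "A"] == pytest.approx(100.0)
        assert rpm.normalized

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(8)
        cm = _matrix({f"m{i}": list(rng.integers(1, 500, 9)) for i in range(40)})
        rpm = rpm_normalize(cm)
        assert np.allclose(rpm.data.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_total_names_the_sample(self):
        cm = _matrix({"m1": [0] * 9})
        with pytest.raises(ValueError, match="G1_rep1"):
            rpm_normalize(cm)

    def test_commutes_with_presence_filter_on_retained_rows(self):
        # the RPM denominator is the assigned-read total fixed at build
        # time, so filtering rows then scaling equals scaling then filtering
        rng = np.random.default_rng(12)
        calls = pd.DataFrame(
            {
                "sample_id": rng.choice([f"G1_rep{r}" for r in (1, 2, 3)], 600),
                "read_id": [f"r{i}" for i in range(600)],
                "hairpin_id": rng.choice(
                    [f"m{i}" for i in range(40)],
                    600,
                    p=np.exp(np.linspace(0, 6, 40))
                    / np.exp(np.linspace(0, 6, 40)).sum(),
                ),
                "category": "mature_5p",
            }
        )
        sheet = _sheet(groups=("G1",), reps=3)
        cm = build_count_matrix(calls, sheet)
        _, filtered = presence_filter(cm)
        assert 0 < filtered.data.shape[0] < cm.data.shape[0]
        filter_then_scale = rpm_normalize(filtered).data
        scale_then_filter = rpm_normalize(cm).data.loc[filtered.data.index]
        pd.testing.assert_frame_equal(filter_then_scale, scale_then_filter)


class TestGroupMeans:
    def test_means_and_single_replicate(self):
        cm = _matrix({"m": [10, 20, 30, 7, 7, 7, 5, 0, 0]})
        means = group_means(cm)
        assert means.loc["m", "G1"] == 20
        assert means.loc["m", "G2"] == 7
        single = CountMatrix(
            data=pd.DataFrame({"s": [42]}, index=["m"]),
            samples=pd.DataFrame(
                {"sample_id": ["s"], "group": ["g"], "replicate": [1]}
            ),
        )
        assert group_means(single).loc["m", "g"] == 42

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        cm = _matrix({f"m{i}": list(rng.integers(0, 50, 9)) for i in range(15)})
        means = group_means(cm)
        for m in cm.data.index:
            for g in ("G1", "G2", "G3"):
                cols = [f"{g}_rep{r}" for r in (1, 2, 3)]
                assert means.loc[m, g] == pytest.approx(
                    sum(cm.data.loc[m, c] for c in cols) / 3
                )


class TestReplicateCorrelation:
    def test_identical_replicates_correlate_perfectly(self):
        cm = _matrix({f"m{i}": [i * 3 + 1] * 9 for i in range(5)})
        corr = replicate_correlation(cm)
        assert corr.loc["G1_rep1", "G1_rep2"] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_anti_ordered_profiles_give_minus_one_with_ranks(self):
        sheet = pd.DataFrame(
            {"sample_id": ["a", "b"], "group": ["g1", "g2"], "replicate": [1, 1]}
        )
        cm = CountMatrix(
            data=pd.DataFrame({"a": [1, 2, 3], "b": [9, 5, 1]},
                              index=["m1", "m2", "m3"]),
            samples=sheet,
        )
        corr = replicate_correlation(cm, method="spearman")
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_constant_profile_yields_missing_value(self):
        sheet = pd.DataFrame(
            {"sample_id": ["a", "b"], "group": ["g1", "g2"], "replicate": [1, 1]}
        )
        cm = CountMatrix(
            data=pd.DataFrame({"a": [5, 5, 5], "b": [1, 2, 3]},
                              index=["m1", "m2", "m3"]),
            samples=sheet,
        )
        corr = replicate_correlation(cm)
        assert np.isnan(corr.loc["a", "b"])

    def test_planted_within_group_similarity_exceeds_between(self):
        rng = np.random.default_rng(31)
        base = {g: rng.lognormal(3, 1, 50) for g in ("G1", "G2", "G3")}
        data = {}
        sheet = _sheet()
        for row in sheet.itertuples(index=False):
            noise = rng.lognormal(0, 0.2, 50)
            data[row.sample_id] = np.rint(base[row.group] * noise)
        cm = CountMatrix(data=pd.DataFrame(data), samples=sheet)
        corr = replicate_correlation(cm)
        within, between = [], []
        for i, a in enumerate(sheet.itertuples(index=False)):
            for b in list(sheet.itertuples(index=False))[i + 1 :]:
                (within if a.group == b.group else between).append(
                    corr.loc[a.sample_id, b.sample_id]
                )
        assert np.mean(within) > np.mean(between)


class TestSelections:
    def test_alpha_boundary_is_strict(self):
        table = pd.DataFrame(
            {"mirna": ["a", "b"], "log2fc": [1, -1], "padj": [0.05, 0.049]}
        )
        hits = select_significant(table)
        assert list(hits["mirna"]) == ["b"]

    def test_empty_table_gives_empty_list(self):
        table = pd.DataFrame({"mirna": [], "padj": []})
        assert select_significant(table).empty

    def test_missing_padj_column_is_an_error(self):
        with pytest.raises(ValueError, match="padj"):
            select_significant(pd.DataFrame({"mirna": ["a"], "p": [0.01]}))

    def test_sorted_by_significance(self):
        rng = np.random.default_rng(17)
        padj = rng.uniform(0, 1, 100)
        table = pd.DataFrame({"mirna": [f"m{i}" for i in range(100)], "padj": padj})
        hits = select_significant(table)
        expected = table[table["padj"] < 0.05].sort_values("padj")
        assert list(hits["mirna"]) == list(expected["mirna"])
        assert len(hits) == int((padj < 0.05).sum())

    def test_joint_reads_boundary_is_strict(self):
        cm = _matrix(
            {
                "at50": [20, 20, 5, 0, 0, 0, 5, 0, 0],   # G1+G3 = 50
                "at51": [20, 20, 5, 0, 0, 0, 6, 0, 0],   # G1+G3 = 51
            }
        )
        top = select_top_expressed(cm, groups=("G1", "G3"))
        assert top == ["at51"]

    def test_unknown_group_is_an_error(self):
        cm = _matrix({"m": [1] * 9})
        with pytest.raises(ValueError, match="unknown group"):
            select_top_expressed(cm, groups=("G1", "nope"))

    def test_matches_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(19)
        cm = _matrix({f"m{i}": list(rng.integers(0, 30, 9)) for i in range(40)})
        top = set(select_top_expressed(cm, groups=("G1", "G2")))
        cols = [f"G{g}_rep{r}" for g in (1, 2) for r in (1, 2, 3)]
        expected = {
            m for m in cm.data.index if cm.data.loc[m, cols].sum() > 50
        }
        assert top == expected
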