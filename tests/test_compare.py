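"""Dataset-level aggregation: boxplot statistics, lpLCR exclusion, outlier
fractions, coverage histograms and two-dataset comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcrscan import (
    AnalysisParams,
    ChargeSign,
    DatasetManifest,
    ScatterPoint,
    SequenceRecord,
    boxplot_stats,
    compare_datasets,
    covered_percentage_histogram,
    disprot_like_config,
    exclude_lplcrs,
    fgnup_like_config,
    generate_disprot_like,
    generate_fgnup_like,
    outlier_fraction,
    summarize_dataset,
    summarize_protein,
)


# ---------------------------------------------------------------------------
# Boxplot statistics
# ---------------------------------------------------------------------------

def test_boxplot_stats_tukey():
    st_ = boxplot_stats([1, 2, 3, 4, 100])
    assert st_.median == 3
    assert st_.outlier_values == (100.0,)
    assert st_.whisker_high == 4 and st_.whisker_low == 1

    flat = boxplot_stats([5, 5, 5])
    assert flat.mean == 5 and flat.std == 0 and flat.outlier_values == ()

    assert boxplot_stats([8, 7]).mean == 7.5
    assert boxplot_stats([4]).std == 0.0
    with pytest.raises(ValueError):
        boxplot_stats([])


@given(st.lists(st.integers(0, 500), min_size=1, max_size=12))
def test_boxplot_stats_matches_direct_computation(values):
    """On all small integer datasets the quartiles equal numpy's linear-
    interpolation quantiles computed directly, and whiskers/outliers follow
    the 1.5 IQR rule exactly."""
    stats = boxplot_stats(values)
    arr = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    assert (stats.q1, stats.median, stats.q3) == (q1, med, q3)
    assert stats.q1 <= stats.median <= stats.q3
    lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
    assert set(stats.outlier_values) == set(arr[(arr < lo) | (arr > hi)])
    inside = arr[(arr >= lo) & (arr <= hi)]
    assert stats.whisker_low == inside.min()
    assert stats.whisker_high == inside.max()
    assert stats.n == len(values)
    assert stats.mean == pytest.approx(arr.mean())


# ---------------------------------------------------------------------------
# lpLCR exclusion
# ---------------------------------------------------------------------------

def _protein_with_positive_lengths(lengths, seq_id="p"):
    seq = "DDD".join("K" + "G" * (n - 2) + "K" for n in lengths)
    return summarize_protein(SequenceRecord(seq_id, seq))


def test_exclude_lplcrs_drops_one_maximum_per_protein():
    s1 = _protein_with_positive_lengths([127, 9, 4], "a")
    s2 = _protein_with_positive_lengths([6], "b")
    pooled = exclude_lplcrs([s1, s2])
    assert sorted(pooled) == [4, 9]  # the 127 and the singleton's 6 are gone

    # exactly one value removed per protein with >= 1 positive LCR
    total_before = len(s1.ranked_positive) + len(s2.ranked_positive)
    assert len(pooled) == total_before - 2


def test_exclude_lplcrs_detect_mode_spares_short_maxima():
    from lcrscan import LpLcrMode

    s = _protein_with_positive_lengths([30, 9, 4])
    assert sorted(exclude_lplcrs([s], mode=LpLcrMode.DETECT)) == [4, 9, 30]
    big = _protein_with_positive_lengths([250, 9, 4])
    assert sorted(exclude_lplcrs([big], mode=LpLcrMode.DETECT)) == [4, 9]


# ---------------------------------------------------------------------------
# Outlier fraction
# ---------------------------------------------------------------------------

def _points(lengths):
    return [
        ScatterPoint(f"p{i}", ChargeSign.POSITIVE, n, 0.1, "USER")
        for i, n in enumerate(lengths)
    ]


def test_outlier_fraction():
    pts = _points([50] * 4999 + [250])
    assert outlier_fraction(pts, 200) == pytest.approx(0.0002)
    assert outlier_fraction(_points([10, 20]), 200) == 0.0
    assert outlier_fraction(_points([300, 400]), 200) == 1.0
    assert outlier_fraction(_points([200]), 200) == 0.0  # strictly greater
    with pytest.raises(ValueError):
        outlier_fraction([], 200)


# ---------------------------------------------------------------------------
# Coverage histograms
# ---------------------------------------------------------------------------

def test_covered_percentage_histogram_bins():
    hist = covered_percentage_histogram([100.0], bin_width=10)
    assert hist["count"].sum() == 1
    assert hist.iloc[-1]["count"] == 1  # last bin is closed at 100

    hist0 = covered_percentage_histogram([0.0, 3.2, 9.9], bin_width=10)
    assert hist0.iloc[0]["count"] == 3

    counts = covered_percentage_histogram(list(np.linspace(0, 100, 37)), 5)
    assert counts["count"].sum() == 37


# ---------------------------------------------------------------------------
# Dataset summaries
# ---------------------------------------------------------------------------

def test_summarize_dataset_worked_example(worked_example):
    manifest = DatasetManifest("demo", records=[worked_example])
    summary = summarize_dataset(manifest)
    assert summary.n_proteins == 1
    assert summary.mean_longest_positive == 8
    assert summary.mean_longest_negative == 7
    assert summary.outlier_fraction_positive == 0.0
    (pt_pos, pt_neg) = summary.scatter_points
    assert (pt_pos.length, pt_neg.length) == (8, 7)

    twin = SequenceRecord("example2", worked_example.residues)
    both = summarize_dataset(
        DatasetManifest("demo2", records=[worked_example, twin])
    )
    assert both.n_proteins == 2
    assert both.mean_longest_positive == 8

    with pytest.raises(ValueError):
        summarize_dataset(DatasetManifest("empty"))


def test_scatter_points_respect_length_filter():
    """A protein whose LCRs are all <= 2 residues contributes no point."""
    manifest = DatasetManifest(
        "d", records=[SequenceRecord("tiny", "GKDG")]
    )
    summary = summarize_dataset(manifest)
    assert summary.scatter_points == []


def test_compare_identical_datasets_zero_delta(worked_example):
    m = DatasetManifest("d", records=[worked_example])
    a, b = summarize_dataset(m), summarize_dataset(m)
    report = compare_datasets(a, b)
    assert report["mean_longest_positive"]["delta"] == 0
    assert report["mean_longest_negative"]["delta"] == 0
    assert all(v["delta"] == 0 for v in report["abundance"].values())


def test_compare_rejects_parameter_mismatch(worked_example):
    m = DatasetManifest("d", records=[worked_example])
    a = summarize_dataset(m, AnalysisParams(min_length=2))
    b = summarize_dataset(m, AnalysisParams(min_length=20))
    with pytest.raises(ValueError):
        compare_datasets(a, b)


# ---------------------------------------------------------------------------
# Synthetic-dataset contrasts
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def synthetic_records():
    fg_records, _ = generate_fgnup_like(fgnup_like_config(n_sequences=150),
                                        seed=42)
    dp_records, _ = generate_disprot_like(disprot_like_config(n_sequences=150),
                                          seed=43)
    return fg_records, dp_records


@pytest.fixture(scope="module")
def synthetic_pair(synthetic_records):
    fg_records, dp_records = synthetic_records
    fg = summarize_dataset(DatasetManifest("fg", records=fg_records))
    dp = summarize_dataset(DatasetManifest("dp", records=dp_records))
    return fg, dp


def test_fg_like_longest_positive_exceeds_disprot_twofold(synthetic_pair):
    fg, dp = synthetic_pair
    assert fg.mean_longest_positive > 2 * dp.mean_longest_positive


def test_fg_like_planted_lplcr_recovery_of_mean(synthetic_pair):
    """Mean longest positive LCR tracks the planted 150-residue segment."""
    fg, _ = synthetic_pair
    assert abs(fg.mean_longest_positive - 150) / 150 < 0.10


def test_comparison_report_flags_lplcrs_only_in_fg_like(synthetic_records):
    """At a detection threshold below the planted mean, lpLCRs are found in
    the FG-Nup-like dataset and nowhere in the DisProt-like one."""
    fg_records, dp_records = synthetic_records
    params = AnalysisParams(min_lplcr_length=120)
    fg = summarize_dataset(DatasetManifest("fg", records=fg_records), params)
    dp = summarize_dataset(DatasetManifest("dp", records=dp_records), params)
    report = compare_datasets(fg, dp)
    assert report["lplcr_detected"]["dp"] == 0
    assert report["lplcr_detected"]["fg"] > 0.85 * fg.n_proteins


def test_exclusion_aligns_fg_with_disprot(synthetic_pair):
    fg, dp = synthetic_pair
    fg_pre = [l.length for s in fg.summaries for l in s.ranked_positive]
    dp_pool = [l.length for s in dp.summaries for l in s.ranked_positive]
    fg_post = exclude_lplcrs(fg.summaries)
    assert np.mean(fg_pre) > 2 * np.mean(dp_pool)
    assert abs(np.mean(fg_post) - np.mean(dp_pool)) / np.mean(dp_pool) < 0.25


def test_coverage_mass_shifts_down_with_min_length(synthetic_pair):
    """Raising the minimum LCR length moves coverage mass toward low bins."""
    _, dp = synthetic_pair
    hist2 = dp.covered_histograms[("POSITIVE", 2)]
    hist40 = dp.covered_histograms[("POSITIVE", 40)]
    below10 = lambda h: h[h["bin_high"] <= 10]["count"].sum()
    assert below10(hist40) > below10(hist2)
    for h in (hist2, hist40):
        assert h["count"].sum() == dp.n_proteins
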