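"""Dataset-level comparisons of charge patterning.

Aggregates per-protein summaries into the comparative statistics that
separate FG nucleoporins from generic disordered proteins: longest-LCR
scatter data (length vs charge content), Tukey boxplot statistics of pooled
LCR lengths, re-analysis after excluding each protein's longest positive LCR,
outlier fractions at a length threshold, and LCR-covered-percentage
histograms at increasing minimum LCR lengths. All contrasts are descriptive;
no hypothesis tests are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import DatasetManifest
from .lcr import ChargeSign
from .metrics import (
    LpLcrMode,
    ProteinChargeSummary,
    lcr_covered_percentage,
    residue_abundance,
    summarize_protein,
)


@dataclass(frozen=True)
class AnalysisParams:
    """Parameters shared by every dataset-level statistic.

    min_length: LCRs must be strictly longer than this to enter any
        statistic (default 2: the greater-than-two-residues rule).
    lplcr_mode / min_lplcr_length / max_lplcr_content: lpLCR selection.
    outlier_length_threshold: scatter points longer than this count as
        outliers (default 200 residues).
    covered_min_lengths: thresholds at which covered-percentage histograms
        are computed (default 2, 20, 40).
    hist_bin_width: covered-percentage histogram bin width, percent.
    """

    min_length: int = 2
    lplcr_mode: LpLcrMode = LpLcrMode.DETECT
    min_lplcr_length: int = 200
    max_lplcr_content: Optional[float] = None
    outlier_length_threshold: int = 200
    covered_min_lengths: tuple[int, ...] = (2, 20, 40)
    hist_bin_width: float = 5.0
    extend_to_opposite: bool = False
    std_ddof: int = 1  # sample standard deviation by default
    quantile_method: str = "linear"


@dataclass(frozen=True)
class ScatterPoint:
    """One per-protein longest LCR, as plotted in length-vs-content scatters."""

    seq_id: str
    sign: ChargeSign
    length: int
    charge_content: float
    dataset_tag: str


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey five-number summary plus mean/std and explicit outliers."""

    n: int
    mean: float
    std: float
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outlier_values: tuple[float, ...]


def boxplot_stats(
    values: Iterable[float], ddof: int = 1, quantile_method: str = "linear"
) -> BoxplotStats:
    """Boxplot statistics under the Tukey convention.

    Quartiles by linear interpolation (configurable through numpy's quantile
    methods); whiskers at the most extreme observations within 1.5 IQR of the
    quartiles; everything outside the whiskers is an outlier. Standard
    deviation is the sample one by default (``ddof=1``; 0 for a single value).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("boxplot_stats requires at least one value")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=quantile_method)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    std = float(arr.std(ddof=ddof)) if arr.size > ddof else 0.0
    return BoxplotStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        std=std,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outlier_values=tuple(sorted(float(v) for v in outliers)),
    )


def exclude_lplcrs(
    summaries: Iterable[ProteinChargeSummary],
    mode: LpLcrMode = LpLcrMode.LONGEST,
    min_lplcr_length: int = 200,
) -> list[int]:
    """Pooled positive LCR lengths after removing each protein's lpLCR.

    In LONGEST mode (default) exactly one LCR — the longest positive — is
    dropped from every protein that has at least one positive LCR. In DETECT
    mode the longest positive LCR is dropped only when it reaches
    ``min_lplcr_length``.
    """
    pooled: list[int] = []
    for s in summaries:
        lengths = [l.length for l in s.ranked_positive]
        if not lengths:
            continue
        drop = mode is LpLcrMode.LONGEST or lengths[0] >= min_lplcr_length
        pooled.extend(lengths[1:] if drop else lengths)
    return pooled


def outlier_fraction(
    scatter: Sequence[ScatterPoint], length_threshold: int = 200
) -> float:
    """Fraction of scatter points whose LCR length exceeds the threshold."""
    if not scatter:
        raise ValueError("outlier_fraction requires at least one point")
    above = sum(1 for p in scatter if p.length > length_threshold)
    return above / len(scatter)


def covered_percentage_histogram(
    coverages: Sequence[float], bin_width: float = 5.0
) -> pd.DataFrame:
    """Bin covered percentages over [0, 100].

    Bins are half-open [lo, hi) with the final bin closed at 100, so counts
    always sum to the number of proteins. Returns columns bin_low, bin_high,
    count.
    """
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    edges[-1] = 100.0
    counts, _ = np.histogram(np.asarray(coverages, dtype=float), bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )


@dataclass
class DatasetSummary:
    """All aggregate statistics of one dataset at one parameter setting."""

    dataset_tag: str
    n_proteins: int
    params: AnalysisParams
    abundance_table: pd.Series
    summaries: list[ProteinChargeSummary]
    scatter_points: list[ScatterPoint]
    lcr_length_stats: dict[str, BoxplotStats]  # keys POSITIVE / NEGATIVE
    mean_longest_positive: float
    mean_longest_negative: float
    outlier_fraction_positive: float
    outlier_fraction_all: float
    covered_histograms: dict[tuple[str, int], pd.DataFrame] = field(
        default_factory=dict
    )


def _scatter_points(
    summaries: Sequence[ProteinChargeSummary], tag: str
) -> list[ScatterPoint]:
    pts: list[ScatterPoint] = []
    for s in summaries:
        for lcr in (s.longest_positive, s.longest_negative):
            if lcr is not None:
                pts.append(
                    ScatterPoint(s.seq_id, lcr.sign, lcr.length,
                                 lcr.charge_content, tag)
                )
    return pts


def summarize_dataset(
    manifest: DatasetManifest, params: AnalysisParams = AnalysisParams()
) -> DatasetSummary:
    """Aggregate a whole dataset: per-protein summaries, scatter points,
    pooled LCR-length boxplot statistics, longest-LCR means, outlier
    fractions and covered-percentage histograms.

    Only LCRs passing the ``length > min_length`` filter contribute to any
    statistic; a protein whose LCRs all fail the filter contributes no
    scatter point.
    """
    if not manifest.records:
        raise ValueError(f"dataset {manifest.name!r} contains no records")
    # the manifest name labels the summary; record tags only carry provenance
    tag = manifest.name or manifest.records[0].dataset_tag
    anns = manifest.annotations

    summaries = [
        summarize_protein(
            rec,
            annotations=[a for a in anns if a.seq_id == rec.id],
            min_length=params.min_length,
            lplcr_mode=params.lplcr_mode,
            min_lplcr_length=params.min_lplcr_length,
            max_lplcr_content=params.max_lplcr_content,
            extend_to_opposite=params.extend_to_opposite,
        )
        for rec in manifest.records
    ]

    scatter = _scatter_points(summaries, tag)
    pos_scatter = [p for p in scatter if p.sign is ChargeSign.POSITIVE]

    length_stats: dict[str, BoxplotStats] = {}
    for sign, key in ((ChargeSign.POSITIVE, "POSITIVE"),
                      (ChargeSign.NEGATIVE, "NEGATIVE")):
        pooled = [
            l.length
            for s in summaries
            for l in (s.ranked_positive if sign is ChargeSign.POSITIVE
                      else s.ranked_negative)
        ]
        if pooled:
            length_stats[key] = boxplot_stats(
                pooled, ddof=params.std_ddof,
                quantile_method=params.quantile_method,
            )

    longest_pos = [s.longest_positive.length for s in summaries
                   if s.longest_positive]
    longest_neg = [s.longest_negative.length for s in summaries
                   if s.longest_negative]

    histograms: dict[tuple[str, int], pd.DataFrame] = {}
    for min_len in params.covered_min_lengths:
        for sign, key in ((ChargeSign.POSITIVE, "POSITIVE"),
                          (ChargeSign.NEGATIVE, "NEGATIVE")):
            covs = [
                lcr_covered_percentage(rec, sign, min_len)
                for rec in manifest.records
            ]
            histograms[(key, min_len)] = covered_percentage_histogram(
                covs, params.hist_bin_width
            )

    return DatasetSummary(
        dataset_tag=tag,
        n_proteins=len(manifest.records),
        params=params,
        abundance_table=residue_abundance(manifest.records),
        summaries=summaries,
        scatter_points=scatter,
        lcr_length_stats=length_stats,
        mean_longest_positive=float(np.mean(longest_pos)) if longest_pos
        else float("nan"),
        mean_longest_negative=float(np.mean(longest_neg)) if longest_neg
        else float("nan"),
        outlier_fraction_positive=outlier_fraction(
            pos_scatter, params.outlier_length_threshold
        ) if pos_scatter else 0.0,
        outlier_fraction_all=outlier_fraction(
            scatter, params.outlier_length_threshold
        ) if scatter else 0.0,
        covered_histograms=histograms,
    )


def compare_datasets(a: DatasetSummary, b: DatasetSummary) -> dict:
    """Side-by-side descriptive comparison of two dataset summaries.

    Both summaries must have been computed with identical parameters.
    Returns a JSON-serializable report: abundance table deltas, longest-LCR
    means, pooled boxplot statistics, outlier fractions, and which datasets
    contain detected lpLCRs.
    """
    if a.params != b.params:
        raise ValueError("dataset summaries were computed with different "
                         "parameters and cannot be compared")

    def stats_dict(d: DatasetSummary) -> dict:
        out = {}
        for key, st in d.lcr_length_stats.items():
            out[key] = {
                "n": st.n, "mean": st.mean, "std": st.std,
                "median": st.median, "q1": st.q1, "q3": st.q3,
                "n_outliers": len(st.outlier_values),
            }
        return out

    abundance = pd.DataFrame(
        {a.dataset_tag: a.abundance_table, b.dataset_tag: b.abundance_table}
    ).fillna(0.0)
    abundance["delta"] = abundance[a.dataset_tag] - abundance[b.dataset_tag]

    def lplcr_count(d: DatasetSummary) -> int:
        return sum(1 for s in d.summaries if s.lplcr is not None)

    return {
        "datasets": [a.dataset_tag, b.dataset_tag],
        "n_proteins": {a.dataset_tag: a.n_proteins, b.dataset_tag: b.n_proteins},
        "abundance": abundance.to_dict(orient="index"),
        "mean_longest_positive": {
            a.dataset_tag: a.mean_longest_positive,
            b.dataset_tag: b.mean_longest_positive,
            "delta": a.mean_longest_positive - b.mean_longest_positive,
        },
        "mean_longest_negative": {
            a.dataset_tag: a.mean_longest_negative,
            b.dataset_tag: b.mean_longest_negative,
            "delta": a.mean_longest_negative - b.mean_longest_negative,
        },
        "lcr_length_stats": {
            a.dataset_tag: stats_dict(a), b.dataset_tag: stats_dict(b)
        },
        "outlier_fraction_positive": {
            a.dataset_tag: a.outlier_fraction_positive,
            b.dataset_tag: b.outlier_fraction_positive,
            "delta": a.outlier_fraction_positive - b.outlier_fraction_positive,
        },
        "lplcr_detected": {
            a.dataset_tag: lplcr_count(a), b.dataset_tag: lplcr_count(b)
        },
        "params": {
            "min_length": a.params.min_length,
            "lplcr_mode": a.params.lplcr_mode.value,
            "min_lplcr_length": a.params.min_lplcr_length,
            "outlier_length_threshold": a.params.outlier_length_threshold,
            "quantile_method": a.params.quantile_method,
            "std_ddof": a.params.std_ddof,
        },
    }
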