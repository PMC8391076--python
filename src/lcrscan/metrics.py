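"""Per-sequence and per-protein charge-patterning metrics.

Covers residue abundance, FG-motif density and the FG-nucleoporin selection
filter, disorder fraction, LCR-covered percentage, ranked LCR statistics
(rank gaps and ratios), and flagging of long positive low-charge-density
regions (lpLCRs).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import RegionAnnotation, SequenceRecord, merge_regions
from .lcr import LCR, ChargeSign, charge_profile, filter_lcrs, scan_lcrs

#: Default reporting order for abundance tables: most order-promoting
#: (aromatic/aliphatic) through to the charged, most disorder-promoting
#: residues, with the remaining canonical residues alphabetical at the end.
ABUNDANCE_ORDER = (
    "W", "F", "Y", "I", "L", "V",
    "D", "E", "K", "R",
    "A", "C", "G", "H", "M", "N", "P", "Q", "S", "T",
)


def residue_abundance(
    records: Sequence[SequenceRecord],
    order: Sequence[str] = ABUNDANCE_ORDER,
) -> pd.Series:
    """Pooled residue abundance: counts of each residue over the summed
    length of all records.

    Fractions sum to 1 over the residues actually present; the returned
    Series is indexed in ``order`` (default: order-promoting to
    disorder-promoting) with any residue outside ``order`` appended.
    """
    if not records:
        raise ValueError("residue_abundance requires at least one record")
    counts: dict[str, int] = {}
    total = 0
    for rec in records:
        total += len(rec.residues)
        for r in rec.residues:
            counts[r] = counts.get(r, 0) + 1
    index = list(order) + sorted(set(counts) - set(order))
    return pd.Series(
        [counts.get(r, 0) / total for r in index], index=index, name="abundance"
    )


def fg_motif_density(record: SequenceRecord) -> float:
    """FG dipeptides per residue (FG/AA).

    Exact occurrences of phenylalanine immediately followed by glycine,
    divided by sequence length. FG cannot self-overlap so a plain substring
    count is exact.
    """
    return record.residues.count("FG") / len(record.residues)


def disorder_fraction(
    record: SequenceRecord, annotations: Iterable[RegionAnnotation]
) -> float:
    """Fraction of the protein covered by disordered-region annotations.

    Overlapping annotations are merged before counting, so every residue is
    counted once. Annotations extending past the sequence raise a
    validation error.
    """
    merged = merge_regions(a for a in annotations if a.seq_id == record.id)
    covered = 0
    for a in merged:
        if a.end > len(record):
            raise ValueError(
                f"region ({a.start},{a.end}) exceeds length of {record.id!r}"
            )
        covered += len(a)
    return covered / len(record)


def is_fg_nup_candidate(
    record: SequenceRecord,
    annotations: Iterable[RegionAnnotation],
    disorder_threshold: float = 0.30,
    fg_threshold: float = 0.15,
) -> bool:
    """FG-nucleoporin selection filter.

    True iff the protein is both highly disordered (disorder fraction
    strictly above ``disorder_threshold``) and FG-motif dense (FG/AA strictly
    above ``fg_threshold``). Both inequalities are strict.
    """
    return (
        disorder_fraction(record, annotations) > disorder_threshold
        and fg_motif_density(record) > fg_threshold
    )


def lcr_covered_percentage(
    record: SequenceRecord,
    sign: ChargeSign,
    min_length: int = 2,
    lcrs: Optional[Sequence[LCR]] = None,
) -> float:
    """Percent of the sequence covered by sign-matching LCRs longer than
    ``min_length``.

    100 x (summed lengths of kept LCRs) / sequence length. Pre-scanned LCRs
    may be passed to avoid rescanning.
    """
    if lcrs is None:
        lcrs = scan_lcrs(record)
    kept = [l for l in filter_lcrs(lcrs, min_length) if l.sign is sign]
    return 100.0 * sum(l.length for l in kept) / len(record)


def top_k_lcrs(lcrs: Iterable[LCR], sign: ChargeSign, k: int) -> list[LCR]:
    """Up to k sign-matching LCRs, longest first; ties broken by earlier start."""
    if k < 1:
        raise ValueError("k must be >= 1")
    matching = [l for l in lcrs if l.sign is sign]
    matching.sort(key=lambda l: (-l.length, l.start))
    return matching[:k]


@dataclass(frozen=True)
class RankStatistics:
    """Length gaps and ratios between the top-ranked LCRs of one protein.

    Fields are None when the protein has too few LCRs of the relevant sign
    (fewer than 2 for the 1st/2nd statistics, fewer than 3 for 2nd/3rd).
    """

    gap_12: Optional[int] = None
    gap_23: Optional[int] = None
    ratio_12: Optional[float] = None
    ratio_23: Optional[float] = None


def rank_gap_and_ratio(ranked: Sequence[LCR]) -> RankStatistics:
    """Gaps and ratios of the longest vs second- vs third-longest LCRs.

    ``ranked`` must already be sorted by length, non-increasing (as produced
    by :func:`top_k_lcrs`).
    """
    lengths = [l.length for l in ranked]
    if any(lengths[i] < lengths[i + 1] for i in range(len(lengths) - 1)):
        raise ValueError("ranked LCRs must be sorted by non-increasing length")
    gap_12 = ratio_12 = gap_23 = ratio_23 = None
    if len(lengths) >= 2:
        gap_12 = lengths[0] - lengths[1]
        ratio_12 = lengths[0] / lengths[1]
    if len(lengths) >= 3:
        gap_23 = lengths[1] - lengths[2]
        ratio_23 = lengths[1] / lengths[2]
    return RankStatistics(gap_12=gap_12, gap_23=gap_23,
                          ratio_12=ratio_12, ratio_23=ratio_23)


class LpLcrMode(enum.Enum):
    """How the per-protein lpLCR is selected.

    DETECT flags the longest positive LCR only when it passes the length
    (and optionally charge-content) thresholds — the operational definition
    of an outlier lpLCR. LONGEST always returns the longest positive LCR,
    the per-protein unit used in exclusion re-analyses and rank statistics.
    """

    DETECT = "detect"
    LONGEST = "longest"


@dataclass
class ProteinChargeSummary:
    """All per-protein charge-patterning metrics for one analyzed sequence."""

    seq_id: str
    length: int
    ranked_positive: list[LCR] = field(default_factory=list)
    ranked_negative: list[LCR] = field(default_factory=list)
    covered_pct_positive: float = 0.0
    covered_pct_negative: float = 0.0
    covered_min_length: int = 2
    fg_density: float = 0.0
    disorder_frac: Optional[float] = None
    lplcr: Optional[LCR] = None

    @property
    def longest_positive(self) -> Optional[LCR]:
        return self.ranked_positive[0] if self.ranked_positive else None

    @property
    def longest_negative(self) -> Optional[LCR]:
        return self.ranked_negative[0] if self.ranked_negative else None


def flag_lplcr(
    summary: ProteinChargeSummary,
    mode: LpLcrMode = LpLcrMode.DETECT,
    min_lplcr_length: int = 200,
    max_content: Optional[float] = None,
) -> Optional[LCR]:
    """Select the protein's lpLCR according to ``mode``.

    DETECT: the longest positive LCR, if its length is at least
    ``min_lplcr_length`` and (when ``max_content`` is given) its charge
    content does not exceed it; otherwise None. LONGEST: the longest
    positive LCR unconditionally (None only if the protein has none).
    """
    longest = summary.longest_positive
    if longest is None:
        return None
    if mode is LpLcrMode.LONGEST:
        return longest
    if longest.length < min_lplcr_length:
        return None
    if max_content is not None and longest.charge_content > max_content:
        return None
    return longest


def summarize_protein(
    record: SequenceRecord,
    annotations: Iterable[RegionAnnotation] = (),
    min_length: int = 2,
    lplcr_mode: LpLcrMode = LpLcrMode.DETECT,
    min_lplcr_length: int = 200,
    max_lplcr_content: Optional[float] = None,
    extend_to_opposite: bool = False,
) -> ProteinChargeSummary:
    """Scan one sequence and assemble its full per-protein summary.

    Ranked LCR lists and covered percentages are computed after the
    ``length > min_length`` filter (default: greater than two residues),
    matching the inclusion rule of every dataset-level statistic.
    """
    all_lcrs = scan_lcrs(record, extend_to_opposite=extend_to_opposite)
    kept = filter_lcrs(all_lcrs, min_length)
    summary = ProteinChargeSummary(
        seq_id=record.id,
        length=len(record),
        ranked_positive=top_k_lcrs(kept, ChargeSign.POSITIVE, k=len(kept) or 1),
        ranked_negative=top_k_lcrs(kept, ChargeSign.NEGATIVE, k=len(kept) or 1),
        covered_pct_positive=lcr_covered_percentage(
            record, ChargeSign.POSITIVE, min_length, lcrs=all_lcrs
        ),
        covered_pct_negative=lcr_covered_percentage(
            record, ChargeSign.NEGATIVE, min_length, lcrs=all_lcrs
        ),
        covered_min_length=min_length,
        fg_density=fg_motif_density(record),
    )
    anns = list(annotations)
    if anns:
        summary.disorder_frac = disorder_fraction(record, anns)
    summary.lplcr = flag_lplcr(
        summary, lplcr_mode, min_lplcr_length, max_lplcr_content
    )
    return summary


def summary_table_rows(summaries: Sequence[ProteinChargeSummary]) -> list[dict]:
    """Per-protein summaries as plain dicts for DataFrame / TSV export."""
    rows = []
    for s in summaries:
        lp, ln = s.longest_positive, s.longest_negative
        rows.append(
            {
                "seq_id": s.seq_id,
                "length": s.length,
                "longest_pos_len": lp.length if lp else 0,
                "longest_pos_content": lp.charge_content if lp else float("nan"),
                "longest_neg_len": ln.length if ln else 0,
                "covered_pos_pct": s.covered_pct_positive,
                "covered_neg_pct": s.covered_pct_negative,
                "fg_density": s.fg_density,
                "disorder_fraction": s.disorder_frac,
                "lplcr_flag": s.lplcr is not None,
            }
        )
    return rows


# The full charge profile is re-exported here because per-protein reporting
# (f+, f-, tick marks in schematics) reads it alongside these metrics.
__all__ = [
    "ABUNDANCE_ORDER",
    "LpLcrMode",
    "ProteinChargeSummary",
    "RankStatistics",
    "charge_profile",
    "disorder_fraction",
    "fg_motif_density",
    "flag_lplcr",
    "is_fg_nup_candidate",
    "lcr_covered_percentage",
    "rank_gap_and_ratio",
    "residue_abundance",
    "summarize_protein",
    "summary_table_rows",
    "top_k_lcrs",
]
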