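"""Charge classification and like-charge-region (LCR) extraction.

A like-charge region is a maximal stretch of sequence whose charged residues
all carry the same sign: positive (lysine K, arginine R) or negative
(aspartate D, glutamate E). Every other residue — including histidine — is
treated as neutral. Each LCR is characterized by its span, length, charge
count and charge content (charged residues per unit length); long positive
LCRs of low charge content (lpLCRs) are the signature feature of FG
nucleoporins that this package quantifies.

Span convention: an LCR runs from its first to its last same-sign charged
residue, inclusive. Neutral residues trailing the last charge (before the
next opposite charge) are not part of the LCR. An alternative convention in
which the region extends up to, but not including, the next opposite charge
is available via ``extend_to_opposite=True``; the two conventions must never
be mixed within one analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import SequenceRecord

POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")


class ChargeSign(enum.Enum):
    POSITIVE = 1
    NEGATIVE = -1
    NEUTRAL = 0

    def __str__(self) -> str:  # TSV-friendly
        return self.name


def classify_residue(residue: str) -> ChargeSign:
    """Classify one amino-acid letter: K/R positive, D/E negative, else neutral.

    Histidine is neutral (its side chain is mostly uncharged at physiological
    pH). Ambiguity codes are neutral. Non-letter input raises ``ValueError``.
    """
    if len(residue) != 1 or not residue.isalpha():
        raise ValueError(f"expected a single amino-acid letter, got {residue!r}")
    r = residue.upper()
    if r in POSITIVE_RESIDUES:
        return ChargeSign.POSITIVE
    if r in NEGATIVE_RESIDUES:
        return ChargeSign.NEGATIVE
    return ChargeSign.NEUTRAL


@dataclass(frozen=True)
class ChargeProfile:
    """Per-position charge signs and the summary fractions f+ and f-."""

    seq_id: str
    signs: tuple[ChargeSign, ...]
    n_positive: int
    n_negative: int

    @property
    def length(self) -> int:
        return len(self.signs)

    @property
    def f_plus(self) -> float:
        return self.n_positive / self.length

    @property
    def f_minus(self) -> float:
        return self.n_negative / self.length


def charge_profile(record: SequenceRecord) -> ChargeProfile:
    """Compute the per-position charge profile of a record."""
    signs = tuple(classify_residue(r) for r in record.residues)
    return ChargeProfile(
        seq_id=record.id,
        signs=signs,
        n_positive=sum(1 for s in signs if s is ChargeSign.POSITIVE),
        n_negative=sum(1 for s in signs if s is ChargeSign.NEGATIVE),
    )


@dataclass(frozen=True)
class LCR:
    """One like-charge region (1-based inclusive span)."""

    seq_id: str
    sign: ChargeSign
    start: int
    end: int
    charge_count: int

    def __post_init__(self) -> None:
        if self.sign is ChargeSign.NEUTRAL:
            raise ValueError("an LCR carries a positive or negative sign")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid LCR span ({self.start},{self.end})")
        if self.charge_count < 1:
            raise ValueError("an LCR contains at least one charged residue")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def charge_content(self) -> float:
        """Charged residues per residue of LCR length, in (0, 1]."""
        return self.charge_count / self.length


def scan_lcrs(
    record: SequenceRecord, extend_to_opposite: bool = False
) -> list[LCR]:
    """Extract all LCRs of a sequence, ordered by start position.

    Each maximal run of same-sign charged residues yields one LCR spanning
    its first to last charge inclusive. Runs at either terminus, with no
    flanking opposite charge, still yield LCRs; a sequence with no charged
    residue yields an empty list. Consecutive LCRs alternate in sign and
    their spans are disjoint.

    With ``extend_to_opposite=True`` each LCR's end is pushed to the residue
    immediately before the next opposite-sign charge (or the sequence end),
    so trailing neutral residues are counted in the length.
    """
    seq = record.residues
    lcrs: list[LCR] = []
    cur_sign: ChargeSign | None = None
    cur_start = 0  # 1-based position of first charge of current run
    cur_last = 0  # 1-based position of last charge seen in current run
    cur_count = 0

    def close(end: int) -> None:
        lcrs.append(LCR(record.id, cur_sign, cur_start, end, cur_count))

    for pos, residue in enumerate(seq, start=1):
        sign = classify_residue(residue)
        if sign is ChargeSign.NEUTRAL:
            continue
        if sign is cur_sign:
            cur_last = pos
            cur_count += 1
        else:
            if cur_sign is not None:
                close(pos - 1 if extend_to_opposite else cur_last)
            cur_sign, cur_start, cur_last, cur_count = sign, pos, pos, 1
    if cur_sign is not None:
        close(len(seq) if extend_to_opposite else cur_last)
    return lcrs


def filter_lcrs(lcrs: Iterable[LCR], min_length: int = 2) -> list[LCR]:
    """Keep LCRs strictly longer than ``min_length`` residues, order preserved.

    The default (2) reproduces the "greater than two amino acids" inclusion
    rule used for every dataset-level statistic: lengths 1 and 2 are dropped,
    3 and up are kept.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    return [l for l in lcrs if l.length > min_length]


def lcr_table_rows(lcrs: Sequence[LCR]) -> list[dict]:
    """LCRs as plain dicts, ready for a pandas DataFrame / TSV export."""
    return [
        {
            "seq_id": l.seq_id,
            "sign": str(l.sign),
            "start": l.start,
            "end": l.end,
            "length": l.length,
            "charge_count": l.charge_count,
            "charge_content": l.charge_content,
        }
        for l in lcrs
    ]
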