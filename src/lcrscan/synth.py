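"""Synthetic sequence generation with planted ground truth.

Two generators emulate the statistical structure of the real datasets:

* DisProt-like: charge-rich disordered material. Each position is
  independently positive (K/R) with probability f+, negative (D/E) with
  probability f-, otherwise neutral filler drawn from a background
  composition. Charge placement is independent Bernoulli — densities are
  specified, not a dependency structure.

* FG-Nup-like: a two-segment architecture. An N-terminal extended segment
  containing only sparse positive charges (the planted lpLCR), followed by a
  charge-rich DisProt-like segment. The planted segment's first and last
  positions are forced to be charged, and the charge-rich segment opens with
  a negative charge, so the planted span is exactly the span the scanner
  reports and recovery is exactly testable. FG dipeptides are interleaved
  into the neutral filler to reach a target FG/AA density.

Every generated dataset carries a :class:`SyntheticTruth` recording planted
spans, charge fractions and FG counts, so recovery tests can compare the
scanner's output against what was planted. One global seed drives one
substream per sequence, so datasets are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import SequenceRecord
from .metrics import LpLcrMode, flag_lplcr, summarize_protein

#: Canonical residues that carry no charge here (everything but K, R, D, E).
NEUTRAL_RESIDUES = tuple("ACFGHILMNPQSTVWY")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the package's standard study
    conditions.

    length_dist: (mean, sd) of total sequence length, residues.
    f_plus / f_minus: per-position charge probabilities of charge-rich
        material (default 0.10 / 0.10, a typical disordered-region charge
        density).
    lplcr_length_dist: (mean, sd) of the planted lpLCR segment (default
        150 +/- 20 residues, well past the 200-residue detection threshold's
        "long" regime divided by the charge-rich remainder).
    lplcr_charge_density: positive-charge fraction inside the planted
        segment (default 0.03 — sparse).
    lplcr_position: "N_TERMINAL" plants an lpLCR, "NONE" does not.
    fg_density: target FG dipeptides per residue (0 disables enrichment;
        FG-Nup-like defaults use 0.2, above the 0.15 FG/AA selection filter).
    background_composition: residue -> weight table for neutral filler
        (default uniform over the 16 neutral canonical residues).
    """

    n_sequences: int = 200
    length_dist: tuple[float, float] = (300.0, 30.0)
    f_plus: float = 0.10
    f_minus: float = 0.10
    lplcr_length_dist: tuple[float, float] = (150.0, 20.0)
    lplcr_charge_density: float = 0.03
    lplcr_position: str = "NONE"
    fg_density: float = 0.0
    background_composition: tuple[tuple[str, float], ...] = tuple(
        (r, 1.0) for r in NEUTRAL_RESIDUES
    )

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        if not 0.0 <= self.f_plus + self.f_minus <= 1.0:
            raise ValueError("f_plus + f_minus must lie in [0, 1]")
        if not 0.0 < self.lplcr_charge_density < 1.0:
            raise ValueError("lplcr_charge_density must lie in (0, 1)")
        if self.lplcr_position not in ("N_TERMINAL", "NONE"):
            raise ValueError("lplcr_position must be N_TERMINAL or NONE")
        if self.lplcr_position == "N_TERMINAL" and (
            self.lplcr_length_dist[0] + 10 > self.length_dist[0]
        ):
            raise ValueError(
                "planted lpLCR segment mean exceeds sequence length mean"
            )
        for sign_set in ("KRDE",):
            if any(r in sign_set for r, _ in self.background_composition):
                raise ValueError("background composition must be charge-free")


def fgnup_like_config(**overrides) -> SyntheticConfig:
    """Standard FG-Nup-like conditions: planted N-terminal lpLCR
    (150 +/- 20 aa at 3% positive-charge density), DisProt-like charge-rich
    remainder (f+ = f- = 0.10) and FG enrichment to 0.2 FG/AA."""
    base = SyntheticConfig(lplcr_position="N_TERMINAL", fg_density=0.2)
    return replace(base, **overrides)


def disprot_like_config(**overrides) -> SyntheticConfig:
    """Standard DisProt-like conditions: f+ = f- = 0.10, length 300 +/- 30,
    no planted lpLCR, no FG enrichment."""
    return replace(SyntheticConfig(), **overrides)


@dataclass(frozen=True)
class SequenceTruth:
    """Planted parameters of one generated sequence."""

    seq_id: str
    lplcr_start: Optional[int]  # 1-based inclusive; None if nothing planted
    lplcr_end: Optional[int]
    f_plus: float
    f_minus: float
    fg_count: int


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    seed: int
    config: SyntheticConfig
    per_sequence: list[SequenceTruth] = field(default_factory=list)


def _background(rng: np.random.Generator, n: int,
                composition: Sequence[tuple[str, float]]) -> np.ndarray:
    letters = np.array([r for r, _ in composition])
    weights = np.array([w for _, w in composition], dtype=float)
    weights /= weights.sum()
    return rng.choice(letters, size=n, p=weights)


def _charge_rich(rng: np.random.Generator, n: int, f_plus: float,
                 f_minus: float,
                 composition: Sequence[tuple[str, float]]) -> np.ndarray:
    """Independent-per-position Bernoulli charge placement over filler."""
    seq = _background(rng, n, composition)
    u = rng.random(n)
    pos_mask = u < f_plus
    neg_mask = (u >= f_plus) & (u < f_plus + f_minus)
    seq[pos_mask] = rng.choice(["K", "R"], size=int(pos_mask.sum()))
    seq[neg_mask] = rng.choice(["D", "E"], size=int(neg_mask.sum()))
    return seq


def _plant_lplcr(rng: np.random.Generator, n: int, density: float,
                 composition: Sequence[tuple[str, float]]) -> np.ndarray:
    """Sparse positive-only segment with charged first and last positions."""
    seq = _background(rng, n, composition)
    n_charges = max(2, round(density * n))
    interior = rng.choice(np.arange(1, n - 1), size=min(n_charges - 2, n - 2),
                          replace=False) if n > 2 else np.array([], dtype=int)
    charged = np.concatenate(([0, n - 1], interior)).astype(int)
    seq[charged] = rng.choice(["K", "R"], size=charged.size)
    return seq


def _enrich_fg(rng: np.random.Generator, seq: np.ndarray,
               mutable: np.ndarray, target_density: float) -> None:
    """Overwrite random adjacent mutable (filler) pairs with FG until the
    whole sequence reaches the target FG/AA density, in place."""
    n = seq.size
    target = int(round(target_density * n))
    current = ("".join(seq)).count("FG")
    needed = target - current
    if needed <= 0:
        return
    candidates = [i for i in range(n - 1) if mutable[i] and mutable[i + 1]]
    taken = np.zeros(n, dtype=bool)
    for i in rng.permutation(len(candidates)):
        if needed <= 0:
            break
        j = candidates[i]
        if taken[j] or taken[j + 1]:
            continue
        seq[j], seq[j + 1] = "F", "G"
        taken[j] = taken[j + 1] = True
        needed -= 1


def _lengths(rng: np.random.Generator, dist: tuple[float, float],
             minimum: int) -> int:
    return max(minimum, int(round(rng.normal(dist[0], dist[1]))))


def generate_disprot_like(
    config: SyntheticConfig, seed: int
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Generate charge-rich DisProt-like sequences (no planted lpLCR)."""
    if config.lplcr_position != "NONE":
        raise ValueError("DisProt-like generation requires lplcr_position NONE")
    streams = np.random.SeedSequence(seed).spawn(config.n_sequences)
    records: list[SequenceRecord] = []
    truth = SyntheticTruth(seed=seed, config=config)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        n = _lengths(rng, config.length_dist, minimum=20)
        seq = _charge_rich(rng, n, config.f_plus, config.f_minus,
                           config.background_composition)
        if config.fg_density > 0:
            mutable = ~np.isin(seq, ["K", "R", "D", "E"])
            _enrich_fg(rng, seq, mutable, config.fg_density)
        residues = "".join(seq)
        seq_id = f"disprot_like_{i:04d}"
        records.append(SequenceRecord(seq_id, residues,
                                      dataset_tag="SYNTHETIC"))
        truth.per_sequence.append(
            SequenceTruth(seq_id, None, None, config.f_plus, config.f_minus,
                          residues.count("FG"))
        )
    return records, truth


def generate_fgnup_like(
    config: SyntheticConfig, seed: int
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Generate FG-Nup-like sequences: planted N-terminal lpLCR followed by
    a charge-rich segment opening with a negative charge.

    The planted span is exactly (1, segment length) under the scanner's
    first-to-last-charge convention.
    """
    if config.lplcr_position != "N_TERMINAL":
        raise ValueError("FG-Nup-like generation requires lplcr_position "
                         "N_TERMINAL")
    streams = np.random.SeedSequence(seed).spawn(config.n_sequences)
    records: list[SequenceRecord] = []
    truth = SyntheticTruth(seed=seed, config=config)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        total = _lengths(rng, config.length_dist, minimum=30)
        planted = _lengths(rng, config.lplcr_length_dist, minimum=3)
        if planted + 1 > total:
            raise ValueError(
                f"drawn lpLCR segment ({planted}) exceeds sequence length "
                f"({total}); narrow the length distributions"
            )
        lp = _plant_lplcr(rng, planted, config.lplcr_charge_density,
                          config.background_composition)
        rich = _charge_rich(rng, total - planted, config.f_plus,
                            config.f_minus, config.background_composition)
        # Terminate the planted run at the segment boundary so the truth
        # span is identifiable under the scan convention.
        rich[0] = rng.choice(["D", "E"])
        seq = np.concatenate([lp, rich])
        if config.fg_density > 0:
            mutable = ~np.isin(seq, ["K", "R", "D", "E"])
            _enrich_fg(rng, seq, mutable, config.fg_density)
        residues = "".join(seq)
        seq_id = f"fgnup_like_{i:04d}"
        records.append(SequenceRecord(seq_id, residues,
                                      dataset_tag="SYNTHETIC"))
        truth.per_sequence.append(
            SequenceTruth(seq_id, 1, planted, config.f_plus, config.f_minus,
                          residues.count("FG"))
        )
    return records, truth


def span_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Intersection-over-union of two 1-based inclusive spans."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union


def recovery_report(
    records: Sequence[SequenceRecord],
    truth: SyntheticTruth,
    min_length: int = 2,
    detect_threshold: int = 200,
    overlap_threshold: float = 0.9,
) -> dict:
    """Compare scanned LCRs against the planted ground truth.

    For sequences with a planted lpLCR: length bias (recovered minus planted)
    and span overlap (intersection over union) of the longest positive LCR.
    For all sequences: DETECT-mode flag rate at ``detect_threshold`` and
    pooled charge-fraction recovery errors.
    """
    truth_map = {t.seq_id: t for t in truth.per_sequence}
    if {r.id for r in records} != set(truth_map):
        raise ValueError("records do not match the truth table")

    biases: list[float] = []
    overlaps: list[float] = []
    n_flagged = 0
    n_pos = n_neg = n_total = 0
    for rec in records:
        t = truth_map[rec.id]
        summary = summarize_protein(rec, min_length=min_length)
        flagged = flag_lplcr(summary, LpLcrMode.DETECT,
                             min_lplcr_length=detect_threshold)
        n_flagged += flagged is not None
        for r in rec.residues:
            n_total += 1
            n_pos += r in "KR"
            n_neg += r in "DE"
        if t.lplcr_start is not None:
            longest = summary.longest_positive
            if longest is None:
                biases.append(-(t.lplcr_end - t.lplcr_start + 1))
                overlaps.append(0.0)
            else:
                planted = (t.lplcr_start, t.lplcr_end)
                biases.append(longest.length
                              - (t.lplcr_end - t.lplcr_start + 1))
                overlaps.append(span_overlap(
                    (longest.start, longest.end), planted))

    report: dict = {
        "n_sequences": len(records),
        "detect_flag_rate": n_flagged / len(records),
        "observed_f_plus": n_pos / n_total,
        "observed_f_minus": n_neg / n_total,
    }
    if overlaps:
        report.update(
            n_planted=len(overlaps),
            mean_length_bias=float(np.mean(biases)),
            mean_overlap=float(np.mean(overlaps)),
            frac_overlap_above_threshold=float(
                np.mean([o >= overlap_threshold for o in overlaps])
            ),
        )
    return report


def write_truth_table(truth: SyntheticTruth, path) -> None:
    """Truth as TSV: seq_id, lplcr span, planted fractions, FG count."""
    with open(path, "w") as fh:
        fh.write("seq_id\tlplcr_start\tlplcr_end\tf_plus\tf_minus\tfg_count\n")
        for t in truth.per_sequence:
            s = "" if t.lplcr_start is None else t.lplcr_start
            e = "" if t.lplcr_end is None else t.lplcr_end
            fh.write(f"{t.seq_id}\t{s}\t{e}\t{t.f_plus}\t{t.f_minus}\t"
                     f"{t.fg_count}\n")
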