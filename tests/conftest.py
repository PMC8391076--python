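import random

import pytest
from hypothesis import HealthCheck, settings

from lcrscan import SequenceRecord

settings.register_profile(
    "det",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

#: Sequence instantiating the supplementary worked example's charge pattern:
#: a positive LCR (length 8, 4 charges) followed by a negative LCR
#: (length 7, 3 charges).
WORKED_EXAMPLE = "KAKGSKTKGDNADQSDP"


@pytest.fixture
def worked_example() -> SequenceRecord:
    return SequenceRecord("example", WORKED_EXAMPLE)


def brute_force_lcrs(seq: str) -> list[tuple[str, int, int, int, int]]:
    """Independent oracle: enumerate maximal same-sign charge runs directly.

    Collects the 1-based positions of all charged residues, groups maximal
    consecutive blocks of equal sign, and reports
    (sign, start, end, length, charge_count) per block with the span running
    from the block's first to its last charge.
    """
    charges = [
        (i, "POSITIVE" if c in "KR" else "NEGATIVE")
        for i, c in enumerate(seq, start=1)
        if c in "KRDE"
    ]
    runs: list[list] = []
    for pos, sign in charges:
        if runs and runs[-1][0] == sign:
            runs[-1][1].append(pos)
        else:
            runs.append([sign, [pos]])
    return [
        (sign, ps[0], ps[-1], ps[-1] - ps[0] + 1, len(ps))
        for sign, ps in runs
    ]


def random_protein(rng: random.Random, length: int, p_charge: float) -> str:
    """Random sequence with per-position charge probability ``p_charge``
    (split evenly between signs) over a neutral background."""
    out = []
    for _ in range(length):
        u = rng.random()
        if u < p_charge / 2:
            out.append(rng.choice("KR"))
        elif u < p_charge:
            out.append(rng.choice("DE"))
        else:
            out.append(rng.choice("ACFGHILMNPQSTVWY"))
    return "".join(out)
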