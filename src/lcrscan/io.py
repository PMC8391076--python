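"""Sequence and annotation I/O.

Reads and writes protein sequences (FASTA), disordered-region annotation
tables (TSV, 1-based inclusive coordinates) and dataset manifests (JSON),
and extracts annotated disordered subsequences for downstream charge
analysis. Coordinates are 1-based inclusive throughout the package, matching
the convention of curated disorder databases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: Recognized provenance tags for a dataset.
DATASET_TAGS = ("FG_NUPS", "DISPROT", "UNIPROT_PRED", "SYNTHETIC", "USER")

#: The 20 canonical amino acids.
CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity / non-standard codes accepted in permissive mode; treated as
#: uncharged, non-F, non-G residues by every metric.
AMBIGUOUS = set("BJOUXZ")
ACCEPTED = CANONICAL | AMBIGUOUS


class ParseError(ValueError):
    """A malformed input file (FASTA entry or region-table row)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein, or one disordered subsequence analyzed as a unit."""

    id: str
    residues: str
    description: str = ""
    dataset_tag: str = "USER"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if not self.residues.isalpha():
            raise ValidationError(
                f"record {self.id!r}: residues must contain only letters"
            )
        if self.dataset_tag not in DATASET_TAGS:
            raise ValidationError(
                f"record {self.id!r}: unknown dataset tag {self.dataset_tag!r}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def validate_alphabet(self, strict: bool = False) -> None:
        """Reject residues outside the accepted alphabet.

        With ``strict=True`` ambiguity codes (B, J, O, U, X, Z) are rejected
        as well; by default they are accepted and treated as neutral.
        """
        allowed = CANONICAL if strict else ACCEPTED
        bad = set(self.residues) - allowed
        if bad:
            raise ValidationError(
                f"record {self.id!r}: disallowed residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class RegionAnnotation:
    """A disordered region on a sequence, 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    evidence: str = "predicted"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"region on {self.seq_id!r}: invalid span "
                f"({self.start}, {self.end}); need 1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class DatasetManifest:
    """A named collection of records plus their disorder annotations."""

    name: str
    records: list[SequenceRecord] = field(default_factory=list)
    annotations: list[RegionAnnotation] = field(default_factory=list)
    notes: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dupes}")
        known = set(ids)
        for ann in self.annotations:
            if ann.seq_id not in known:
                raise ValidationError(
                    f"annotation references unknown sequence {ann.seq_id!r}"
                )

    def record_map(self) -> dict[str, SequenceRecord]:
        return {r.id: r for r in self.records}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path, dataset_tag: str = "USER"
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Residues are upper-cased. An entry with an empty body raises
    :class:`ParseError` naming the offending identifier.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).strip()
        if not seq:
            raise ParseError(f"{path}: entry {entry.id!r} has an empty sequence")
        if not seq.isalpha():
            raise ParseError(
                f"{path}: entry {entry.id!r} contains non-letter characters"
            )
        records.append(
            SequenceRecord(
                id=entry.id,
                residues=seq,
                description=entry.description,
                dataset_tag=dataset_tag,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving ids and residue strings."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# Region tables
# ---------------------------------------------------------------------------

REGION_COLUMNS = ("seq_id", "start", "end", "evidence")


def merge_regions(regions: Iterable[RegionAnnotation]) -> list[RegionAnnotation]:
    """Merge overlapping or touching regions per sequence.

    Returns maximal non-overlapping regions sorted by (seq_id, start).
    Evidence tags of merged rows are joined with ``+`` (duplicates dropped,
    order of first appearance kept). Idempotent.
    """
    by_seq: dict[str, list[RegionAnnotation]] = {}
    for r in regions:
        by_seq.setdefault(r.seq_id, []).append(r)

    merged: list[RegionAnnotation] = []
    for seq_id in sorted(by_seq):
        rows = sorted(by_seq[seq_id], key=lambda r: (r.start, r.end))
        cur_start, cur_end = rows[0].start, rows[0].end
        cur_ev = [rows[0].evidence]
        for r in rows[1:]:
            if r.start <= cur_end + 1:  # overlap or adjacency
                cur_end = max(cur_end, r.end)
                if r.evidence not in cur_ev:
                    cur_ev.append(r.evidence)
            else:
                merged.append(
                    RegionAnnotation(seq_id, cur_start, cur_end, "+".join(cur_ev))
                )
                cur_start, cur_end, cur_ev = r.start, r.end, [r.evidence]
        merged.append(
            RegionAnnotation(seq_id, cur_start, cur_end, "+".join(cur_ev))
        )
    return merged


def read_region_table(path: str | Path, merge: bool = True) -> list[RegionAnnotation]:
    """Read a TSV of disordered regions (columns seq_id, start, end, evidence).

    Coordinates are 1-based inclusive. Rows violating ``1 <= start <= end``
    raise :class:`ValidationError` with the offending row number. Overlapping
    rows for one sequence are merged into maximal regions unless
    ``merge=False``.
    """
    path = Path(path)
    regions: list[RegionAnnotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["seq_id", "start", "end"]:
            raise ParseError(
                f"{path}: expected header starting 'seq_id\\tstart\\tend', "
                f"got {header!r}"
            )
        has_evidence = len(header) >= 4 and header[3] == "evidence"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                seq_id, start, end = parts[0], int(parts[1]), int(parts[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row: {line!r}") from exc
            evidence = parts[3] if has_evidence and len(parts) > 3 else "predicted"
            try:
                regions.append(RegionAnnotation(seq_id, start, end, evidence))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return merge_regions(regions) if merge else regions


def write_region_table(
    regions: Iterable[RegionAnnotation], path: str | Path
) -> None:
    with open(Path(path), "w") as fh:
        fh.write("\t".join(REGION_COLUMNS) + "\n")
        for r in regions:
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.evidence}\n")


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

def extract_regions(
    records: Sequence[SequenceRecord],
    annotations: Iterable[RegionAnnotation],
    concatenate: bool = False,
) -> list[SequenceRecord]:
    """Cut annotated disordered regions out of full-length sequences.

    By default each region becomes its own record (id suffixed with
    ``/start-end``), preserving region identity for multi-region proteins.
    With ``concatenate=True`` all regions of one protein are joined into a
    single record per protein (id suffixed ``/disordered``), pooling the
    disordered material the way per-protein statistics sometimes require.
    Records with no annotation are omitted.
    """
    rec_map = {r.id: r for r in records}
    by_seq: dict[str, list[RegionAnnotation]] = {}
    for ann in annotations:
        rec = rec_map.get(ann.seq_id)
        if rec is None:
            raise ValidationError(
                f"annotation references unknown sequence {ann.seq_id!r}"
            )
        if ann.end > len(rec):
            raise ValidationError(
                f"region ({ann.start},{ann.end}) exceeds length "
                f"{len(rec)} of {ann.seq_id!r}"
            )
        by_seq.setdefault(ann.seq_id, []).append(ann)

    out: list[SequenceRecord] = []
    for rec in records:  # preserve input record order
        anns = sorted(by_seq.get(rec.id, []), key=lambda a: a.start)
        if not anns:
            continue
        if concatenate:
            residues = "".join(rec.residues[a.start - 1 : a.end] for a in anns)
            out.append(
                SequenceRecord(
                    id=f"{rec.id}/disordered",
                    residues=residues,
                    description=rec.description,
                    dataset_tag=rec.dataset_tag,
                )
            )
        else:
            for a in anns:
                out.append(
                    SequenceRecord(
                        id=f"{rec.id}/{a.start}-{a.end}",
                        residues=rec.residues[a.start - 1 : a.end],
                        description=rec.description,
                        dataset_tag=rec.dataset_tag,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    payload = {
        "name": manifest.name,
        "notes": manifest.notes,
        "records": [
            {
                "id": r.id,
                "description": r.description,
                "residues": r.residues,
                "dataset_tag": r.dataset_tag,
            }
            for r in manifest.records
        ],
        "annotations": [
            {
                "seq_id": a.seq_id,
                "start": a.start,
                "end": a.end,
                "evidence": a.evidence,
            }
            for a in manifest.annotations
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_manifest(path: str | Path) -> DatasetManifest:
    payload = json.loads(Path(path).read_text())
    return DatasetManifest(
        name=payload["name"],
        notes=payload.get("notes", ""),
        records=[SequenceRecord(**r) for r in payload["records"]],
        annotations=[RegionAnnotation(**a) for a in payload.get("annotations", [])],
    )
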