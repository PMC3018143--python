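"""Synteny typing of paired BAC-end placements.

A clone whose two end reads both align to the reference is informative
about synteny between the two genomes:

* type 1 — only one end produced a hit;
* type 2 — both ends on the same chromosome, in the inward-facing
  opposing orientation (leftmost placement on ``+``, rightmost on ``-``)
  and with a clone footprint of at most ``max_span`` (default 300 kb,
  twice the largest expected insert);
* type 3 — both ends on the same chromosome but failing the distance or
  orientation requirement (intra-chromosomal discordance);
* type 4 — ends on different chromosomes (inter-chromosomal discordance,
  or a paralog picked up in place of a lost syntenic copy).

Distance is the outermost-coordinate span of the two placements (the
clone's footprint on the reference), not the gap between them.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ContractError
from .hits import BestPlacement, CloneRecord, PairingTally

DEFAULT_MAX_SPAN = 300_000


@dataclass(frozen=True)
class CloneClassification:
    clone_id: str
    synteny_type: int
    placement_a: BestPlacement          # leftmost by (chrom, start, end, strand)
    placement_b: BestPlacement | None   # None for type 1
    distance: int | None                # same-chromosome pairs only
    orientation_ok: bool | None

    @property
    def chrom_a(self) -> str:
        return self.placement_a.target_chrom

    @property
    def chrom_b(self) -> str | None:
        return self.placement_b.target_chrom if self.placement_b else None

    @property
    def placements(self) -> list[BestPlacement]:
        out = [self.placement_a]
        if self.placement_b is not None:
            out.append(self.placement_b)
        return out


def classify_clone(record: CloneRecord, max_span: int = DEFAULT_MAX_SPAN) -> CloneClassification:
    """Assign the synteny type of one clone from its end placements."""
    placed = record.placements
    if not placed:
        raise ContractError(f"clone {record.clone_id} has no placements to classify")
    if len(placed) == 1:
        return CloneClassification(
            clone_id=record.clone_id, synteny_type=1,
            placement_a=placed[0], placement_b=None,
            distance=None, orientation_ok=None,
        )
    a, b = sorted(placed, key=lambda p: (p.target_chrom, p.start, p.end, p.strand))
    if a.target_chrom != b.target_chrom:
        return CloneClassification(
            clone_id=record.clone_id, synteny_type=4,
            placement_a=a, placement_b=b, distance=None, orientation_ok=None,
        )
    span = max(a.end, b.end) - min(a.start, b.start)
    ok = a.strand == "+" and b.strand == "-"
    stype = 2 if ok and span <= max_span else 3
    return CloneClassification(
        clone_id=record.clone_id, synteny_type=stype,
        placement_a=a, placement_b=b, distance=span, orientation_ok=ok,
    )


def classify_clones(
    records: Iterable[CloneRecord], max_span: int = DEFAULT_MAX_SPAN
) -> list[CloneClassification]:
    return [classify_clone(r, max_span=max_span) for r in records]


@dataclass(frozen=True)
class TypeCounts:
    """Per-(library, target) synteny-type tallies, Table-1 style."""

    library: str
    target: str
    n1: int
    n2: int
    n3: int
    n4: int
    ends_with_hit: int = 0
    bacs_with_hit: int = 0

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3", "n4", "ends_with_hit", "bacs_with_hit"):
            if getattr(self, name) < 0:
                raise ContractError(f"negative count {name}")

    @property
    def n_both_ends(self) -> int:
        return self.n2 + self.n3 + self.n4

    @property
    def label(self) -> tuple[str, str]:
        return (self.library, self.target)


def tabulate_types(
    classifications: Iterable[CloneClassification],
    library: str = "",
    target: str = "",
    tally: PairingTally | None = None,
) -> TypeCounts:
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for c in classifications:
        counts[c.synteny_type] += 1
    return TypeCounts(
        library=library, target=target,
        n1=counts[1], n2=counts[2], n3=counts[3], n4=counts[4],
        ends_with_hit=tally.n_ends_with_hit if tally else 0,
        bacs_with_hit=tally.n_clones_with_hit if tally else 0,
    )


def combine_counts(rows: Sequence[TypeCounts], library: str = "Combined") -> TypeCounts:
    """Column-sum of per-library rows for the same target."""
    targets = {r.target for r in rows}
    if len(targets) > 1:
        raise ContractError(f"cannot combine counts across targets {sorted(targets)}")
    return TypeCounts(
        library=library,
        target=rows[0].target if rows else "",
        n1=sum(r.n1 for r in rows), n2=sum(r.n2 for r in rows),
        n3=sum(r.n3 for r in rows), n4=sum(r.n4 for r in rows),
        ends_with_hit=sum(r.ends_with_hit for r in rows),
        bacs_with_hit=sum(r.bacs_with_hit for r in rows),
    )


_TSV_COLUMNS = [
    "clone_id", "type",
    "chrom_A", "start_A", "end_A", "strand_A", "evalue_A", "bit_A",
    "chrom_B", "start_B", "end_B", "strand_B", "evalue_B", "bit_B",
    "distance", "orientation_ok",
]


def write_classifications(classifications: Iterable[CloneClassification], path) -> None:
    """Classification table as TSV; coordinates 0-based half-open."""
    rows = []
    for c in classifications:
        a, b = c.placement_a, c.placement_b
        rows.append({
            "clone_id": c.clone_id, "type": c.synteny_type,
            "chrom_A": a.target_chrom, "start_A": a.start, "end_A": a.end,
            "strand_A": a.strand, "evalue_A": a.e_value, "bit_A": a.bit_score,
            "chrom_B": b.target_chrom if b else None,
            "start_B": b.start if b else None, "end_B": b.end if b else None,
            "strand_B": b.strand if b else None,
            "evalue_B": b.e_value if b else None, "bit_B": b.bit_score if b else None,
            "distance": c.distance,
            "orientation_ok": c.orientation_ok,
        })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_classifications(path) -> list[CloneClassification]:
    df = pd.read_csv(path, sep="\t")
    out: list[CloneClassification] = []
    for row in df.itertuples(index=False):
        pa = BestPlacement(
            clone_id=row.clone_id, end_label="A", target_chrom=row.chrom_A,
            start=int(row.start_A), end=int(row.end_A), strand=row.strand_A,
            e_value=float(row.evalue_A), bit_score=float(row.bit_A),
        )
        pb = None
        if isinstance(row.chrom_B, str):
            pb = BestPlacement(
                clone_id=row.clone_id, end_label="B", target_chrom=row.chrom_B,
                start=int(row.start_B), end=int(row.end_B), strand=row.strand_B,
                e_value=float(row.evalue_B), bit_score=float(row.bit_B),
            )
        distance = None if pd.isna(row.distance) else int(row.distance)
        orientation = None if pd.isna(row.orientation_ok) else bool(row.orientation_ok)
        out.append(
            CloneClassification(
                clone_id=row.clone_id, synteny_type=int(row.type),
                placement_a=pa, placement_b=pb,
                distance=distance, orientation_ok=orientation,
            )
        )
    return out
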