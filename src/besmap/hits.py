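"""Reading, filtering and pairing of BAC-end alignment hits.

The input dialect is the standard 12-column tab-separated alignment table
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore).  Subject coordinates arrive 1-based inclusive and may be
reversed to indicate a minus-strand match; they are normalised on parse.
Internally all interval arithmetic is 0-based half-open.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ContractError, ParseError, QueryIdError

TABULAR_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

#: strict significance cutoff: hits must be *below* this e-value to be kept
DEFAULT_MAX_EVALUE = 1e-10


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment of a BAC end read to the reference, coordinates normalised.

    ``target_start``/``target_end`` are 1-based inclusive with start <= end;
    ``strand`` records the original subject orientation.
    """

    query_id: str
    target_chrom: str
    target_start: int
    target_end: int
    strand: str
    percent_identity: float
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.target_start > self.target_end:
            raise ContractError(
                f"hit {self.query_id}: start {self.target_start} > end {self.target_end}"
            )
        if self.e_value < 0:
            raise ContractError(f"hit {self.query_id}: negative e-value")


@dataclass(frozen=True)
class EndNaming:
    """Clone/end read-naming convention, e.g. ``clone000123.F``.

    Sequencing centres differ in how mate ends are labelled; the separator
    and the two labels are configurable.  Labels are canonicalised to
    ``F``/``R`` internally.
    """

    separator: str = "."
    forward: str = "F"
    reverse: str = "R"

    def split(self, query_id: str) -> tuple[str, str]:
        clone_id, sep, label = query_id.rpartition(self.separator)
        if not sep or not clone_id:
            raise QueryIdError(
                f"query id {query_id!r} does not contain separator {self.separator!r} "
                f"(convention: <clone>{self.separator}{self.forward}|{self.reverse})"
            )
        if label == self.forward:
            return clone_id, "F"
        if label == self.reverse:
            return clone_id, "R"
        raise QueryIdError(
            f"query id {query_id!r}: end label {label!r} not in "
            f"({self.forward!r}, {self.reverse!r})"
        )

    def join(self, clone_id: str, end_label: str) -> str:
        label = {"F": self.forward, "R": self.reverse}[end_label]
        return f"{clone_id}{self.separator}{label}"


def _open_lines(source) -> tuple[str, Iterable[str]]:
    if hasattr(source, "read"):
        return getattr(source, "name", "<stream>"), source
    path = Path(source)
    return str(path), path.open()


def parse_tabular_hits(source) -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment file into :class:`AlignmentHit` s.

    Rows with subject start > end are normalised and assigned strand ``-``.
    Blank lines and ``#`` comments are ignored.  A malformed row raises
    :class:`ParseError` naming the offending line.
    """
    name, lines = _open_lines(source)
    hits: list[AlignmentHit] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(
                f"{name}, line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            pident = float(fields[2])
            sstart = int(fields[8])
            send = int(fields[9])
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise ParseError(f"{name}, line {lineno}: {exc}") from None
        if evalue < 0:
            raise ParseError(f"{name}, line {lineno}: negative e-value {evalue}")
        if sstart > send:
            strand, lo, hi = "-", send, sstart
        else:
            strand, lo, hi = "+", sstart, send
        hits.append(
            AlignmentHit(
                query_id=fields[0],
                target_chrom=fields[1],
                target_start=lo,
                target_end=hi,
                strand=strand,
                percent_identity=pident,
                e_value=evalue,
                bit_score=bitscore,
            )
        )
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits back out in the 12-column tabular dialect.

    Alignment bookkeeping columns that the in-memory model does not retain
    (mismatches, gap opens, query coordinates) are reconstructed from the
    span length and identity; minus-strand hits get reversed subject
    coordinates, as produced by the aligner.
    """
    with Path(path).open("w") as fh:
        for h in hits:
            length = h.target_end - h.target_start + 1
            mismatch = round(length * (1.0 - h.percent_identity / 100.0))
            if h.strand == "-":
                sstart, send = h.target_end, h.target_start
            else:
                sstart, send = h.target_start, h.target_end
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.target_chrom, f"{h.percent_identity:.2f}",
                        length, mismatch, 0, 1, length, sstart, send,
                        f"{h.e_value:.3g}", f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


def filter_hits(hits: Iterable[AlignmentHit], max_e: float = DEFAULT_MAX_EVALUE) -> list[AlignmentHit]:
    """Keep hits with e-value strictly below ``max_e``; order preserved."""
    return [h for h in hits if h.e_value < max_e]


@dataclass(frozen=True)
class BestPlacement:
    """The single selected placement of one clone end on the reference.

    ``start``/``end`` are 0-based half-open.
    """

    clone_id: str
    end_label: str
    target_chrom: str
    start: int
    end: int
    strand: str
    e_value: float
    bit_score: float

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _selection_key(hit: AlignmentHit) -> tuple:
    # maximal bit score, then minimal e-value, then lexicographic (chrom, start)
    return (-hit.bit_score, hit.e_value, hit.target_chrom, hit.target_start)


def best_hit_per_end(
    hits: Iterable[AlignmentHit], naming: EndNaming = EndNaming()
) -> dict[tuple[str, str], BestPlacement]:
    """Select one placement per (clone, end).

    Ties on bit score are broken by e-value, then lexicographically by
    (chromosome, start), so the result is invariant under input order.
    """
    best: dict[tuple[str, str], AlignmentHit] = {}
    for hit in hits:
        key = naming.split(hit.query_id)
        cur = best.get(key)
        if cur is None or _selection_key(hit) < _selection_key(cur):
            best[key] = hit
    return {
        (clone, end): BestPlacement(
            clone_id=clone,
            end_label=end,
            target_chrom=h.target_chrom,
            start=h.target_start - 1,
            end=h.target_end,
            strand=h.strand,
            e_value=h.e_value,
            bit_score=h.bit_score,
        )
        for (clone, end), h in best.items()
    }


@dataclass
class CloneRecord:
    """A BAC clone with up to two selected end placements."""

    clone_id: str
    library_label: str = ""
    placement_F: BestPlacement | None = None
    placement_R: BestPlacement | None = None

    @property
    def placements(self) -> list[BestPlacement]:
        return [p for p in (self.placement_F, self.placement_R) if p is not None]


@dataclass(frozen=True)
class PairingTally:
    """Library-level hit bookkeeping (the Table-1 style count columns)."""

    n_ends: int
    n_ends_with_hit: int
    n_clones: int
    n_clones_with_hit: int
    n_clones_both_ends: int

    def __post_init__(self) -> None:
        if not (self.n_clones_both_ends <= self.n_clones_with_hit <= self.n_clones):
            raise ContractError("tally ordering violated: both <= >=1 <= universe")


def pair_ends(
    placements: Mapping[tuple[str, str], BestPlacement] | Iterable[BestPlacement],
    all_sequenced_ends: Iterable[str] | None = None,
    naming: EndNaming = EndNaming(),
    library_label: str = "",
) -> tuple[list[CloneRecord], PairingTally]:
    """Pair end placements into clone records and tally hit statistics.

    ``all_sequenced_ends`` is the universe of sequenced end ids (so ends
    without a hit are counted); duplicate re-sequencing attempts for the
    same (clone, end) collapse to a single entry.  Returns records only for
    clones with at least one placed end.
    """
    if not isinstance(placements, Mapping):
        pl_map: dict[tuple[str, str], BestPlacement] = {}
        for p in placements:
            key = (p.clone_id, p.end_label)
            if key in pl_map and pl_map[key] != p:
                raise ContractError(
                    f"conflicting placements for {p.clone_id} end {p.end_label} "
                    "after best-hit selection"
                )
            pl_map[key] = p
    else:
        pl_map = dict(placements)

    if all_sequenced_ends is not None:
        universe = {naming.split(qid) for qid in all_sequenced_ends}
        universe.update(pl_map)
    else:
        universe = set(pl_map)

    clones = sorted({clone for clone, _ in universe})
    records: list[CloneRecord] = []
    n_both = 0
    n_with = 0
    for clone in clones:
        pf = pl_map.get((clone, "F"))
        pr = pl_map.get((clone, "R"))
        if pf is None and pr is None:
            continue
        n_with += 1
        if pf is not None and pr is not None:
            n_both += 1
        records.append(
            CloneRecord(clone_id=clone, library_label=library_label,
                        placement_F=pf, placement_R=pr)
        )
    tally = PairingTally(
        n_ends=len(universe),
        n_ends_with_hit=len(pl_map),
        n_clones=len(clones),
        n_clones_with_hit=n_with,
        n_clones_both_ends=n_both,
    )
    return records, tally
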