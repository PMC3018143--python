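"""Microsatellite scanning and library-level sequencing statistics.

The scanner reports maximal *perfect* tandem repeats of period 2-4
(di/tri/tetranucleotide).  Motifs are canonicalised to the lexicographic
minimum over all rotations of the motif and of its reverse complement, so
AC, CA, GT and TG runs all aggregate under "AC" regardless of strand.
Mononucleotide runs and runs whose unit is itself periodic (e.g. ACAC as
a tetramer) are excluded.  Minimum run lengths default to 12 bp for di-
and trinucleotides and 16 bp for tetranucleotides — long enough to be
useful as genotyping markers; they are configurable.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import ValidationError

DEFAULT_MIN_LEN: dict[int, int] = {2: 12, 3: 12, 4: 16}
_CLASS_NAME = {2: "di", 3: "tri", 4: "tetra"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over rotations of the motif and its reverse complement."""
    rc = reverse_complement(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def _fundamental_period(motif: str) -> int:
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return p
    return n


@dataclass(frozen=True)
class SSRHit:
    """One perfect microsatellite run, 0-based half-open coordinates."""

    sequence_id: str
    motif: str          # canonical
    motif_class: str    # di / tri / tetra
    start: int
    end: int
    copies: float


def scan_ssrs(
    sequence: str,
    sequence_id: str = "",
    min_len: Mapping[int, int] | None = None,
) -> list[SSRHit]:
    """Scan one sequence for maximal perfect tandem repeats of period 2-4.

    ``N`` breaks runs; any other non-DNA character raises
    :class:`ValidationError`.
    """
    s = sequence.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValidationError(
            f"sequence {sequence_id or '<anonymous>'} contains non-DNA characters: "
            f"{sorted(bad)}"
        )
    thresholds = dict(DEFAULT_MIN_LEN if min_len is None else min_len)
    n = len(s)
    hits: list[SSRHit] = []
    for period, need in sorted(thresholds.items()):
        # maximal runs where s[j] == s[j + period]
        regions: list[list[int]] = []
        i = 0
        while i + period < n:
            if s[i] != "N" and s[i] == s[i + period]:
                j = i
                while j + period < n and s[j] != "N" and s[j] == s[j + period]:
                    j += 1
                regions.append([i, j + period])
                i = j + 1
            else:
                i += 1
        # adjacent maximal runs can share up to period-1 bases; resolve so
        # that same-period calls never overlap, with a strand-symmetric rule:
        # the longer run keeps the contested bases, equal lengths trim both
        original = [tuple(r) for r in regions]
        for k in range(len(regions) - 1):
            (a1, e1), (a2, e2) = original[k], original[k + 1]
            if a2 < e1:
                if e1 - a1 > e2 - a2:
                    regions[k + 1][0] = e1
                elif e2 - a2 > e1 - a1:
                    regions[k][1] = a2
                else:
                    regions[k][1], regions[k + 1][0] = a2, e1
        for start, end in regions:
            unit = s[start:start + period]
            if end - start >= need and _fundamental_period(unit) == period:
                hits.append(
                    SSRHit(
                        sequence_id=sequence_id,
                        motif=canonical_motif(unit),
                        motif_class=_CLASS_NAME[period],
                        start=start,
                        end=end,
                        copies=round((end - start) / period, 2),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.end, h.motif_class))
    return hits


def scan_fasta(path, min_len: Mapping[int, int] | None = None) -> dict[str, list[SSRHit]]:
    """Scan every record of a FASTA file; returns hits keyed by sequence id."""
    out: dict[str, list[SSRHit]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        out[record.id] = scan_ssrs(str(record.seq), sequence_id=record.id, min_len=min_len)
    return out


@dataclass
class SSRSummary:
    n_sequences: int
    n_with_ssr: int
    by_class: dict[str, int]
    by_motif: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.by_class.values())

    @property
    def fraction_with_ssr(self) -> float:
        return self.n_with_ssr / self.n_sequences if self.n_sequences else 0.0


def summarize_ssrs(hits: Iterable[SSRHit], total_sequences: int) -> SSRSummary:
    by_class: Counter[str] = Counter()
    by_motif: Counter[str] = Counter()
    seqs: set[str] = set()
    for h in hits:
        by_class[h.motif_class] += 1
        by_motif[h.motif] += 1
        seqs.add(h.sequence_id)
    return SSRSummary(
        n_sequences=total_sequences,
        n_with_ssr=len(seqs),
        by_class=dict(by_class),
        by_motif=dict(by_motif),
    )


def write_ssr_gff3(hits: Iterable[SSRHit], path) -> None:
    """SSR calls as GFF3 (1-based inclusive coordinates)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            attrs = f"motif={h.motif};copies={h.copies};class={h.motif_class}"
            fh.write(
                f"{h.sequence_id}\tbesmap\tmicrosatellite\t{h.start + 1}\t{h.end}\t"
                f".\t+\t.\t{attrs}\n"
            )


def write_ssr_summary(summary: SSRSummary, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_sequences\t{summary.n_sequences}\n")
        fh.write(f"n_with_ssr\t{summary.n_with_ssr}\n")
        fh.write(f"fraction_with_ssr\t{summary.fraction_with_ssr:.4f}\n")
        fh.write(f"total_ssrs\t{summary.total}\n")
        for cls in ("di", "tri", "tetra"):
            fh.write(f"n_{cls}\t{summary.by_class.get(cls, 0)}\n")
        for motif in sorted(summary.by_motif):
            fh.write(f"motif_{motif}\t{summary.by_motif[motif]}\n")


@dataclass(frozen=True)
class LibraryStats:
    """Sequencing throughput and coverage of one BAC library."""

    n_clones_sequenced: int
    n_end_sequences: int
    total_bp: int
    mean_length: float
    clone_coverage: float      # n_clones x mean insert / genome size
    sequence_coverage: float   # total read bp / genome size


def library_stats(
    n_clones: int,
    mean_insert: float,
    seq_lengths: Sequence[int],
    genome_size: float,
) -> LibraryStats:
    if genome_size <= 0:
        raise ValidationError("genome size must be positive")
    total = int(sum(seq_lengths))
    n = len(seq_lengths)
    return LibraryStats(
        n_clones_sequenced=n_clones,
        n_end_sequences=n,
        total_bp=total,
        mean_length=total / n if n else 0.0,
        clone_coverage=n_clones * mean_insert / genome_size,
        sequence_coverage=total / genome_size,
    )
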