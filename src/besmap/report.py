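"""Comparative-map output writers: summary tables, browser tracks, Circos
links and score distributions.

Coordinate conventions are explicit per format: BED is 0-based half-open,
GFF3 is 1-based inclusive, Circos links carry 0-based half-open anchors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import CloneClassification, TypeCounts, combine_counts
from .errors import ValidationError
from .rearrange import discordant_ratio, intra_ratio

SUMMARY_COLUMNS = [
    "library", "target", "sequences_w_hit", "bacs_w_hit",
    "type1", "type2", "type3", "type4", "ratio_3_23", "ratio_34_234",
]


def _ratio_str(x: float | None) -> str:
    return "" if x is None else f"{x:.3f}"


def summary_frame(rows: Sequence[TypeCounts], add_combined: bool = True) -> pd.DataFrame:
    """Table-1-style summary: one row per (library, target) plus a Combined
    row per target summing the library rows."""
    all_rows = list(rows)
    if add_combined:
        targets = []
        for r in all_rows:
            if r.target not in targets:
                targets.append(r.target)
        for target in targets:
            group = [r for r in all_rows if r.target == target and r.library != "Combined"]
            if len(group) > 1:
                all_rows.append(combine_counts(group))
    records = []
    for r in all_rows:
        records.append({
            "library": r.library, "target": r.target,
            "sequences_w_hit": r.ends_with_hit, "bacs_w_hit": r.bacs_with_hit,
            "type1": r.n1, "type2": r.n2, "type3": r.n3, "type4": r.n4,
            "ratio_3_23": _ratio_str(intra_ratio(r)),
            "ratio_34_234": _ratio_str(discordant_ratio(r)),
        })
    return pd.DataFrame(records, columns=SUMMARY_COLUMNS)


def write_summary(rows: Sequence[TypeCounts], path, add_combined: bool = True) -> None:
    summary_frame(rows, add_combined=add_combined).to_csv(path, sep="\t", index=False)


def _validated_span(
    clone_id: str, chrom: str, start: int, end: int, chrom_sizes: Mapping[str, int]
) -> tuple[int, int]:
    if chrom not in chrom_sizes:
        raise ValidationError(f"clone {clone_id}: unknown chromosome {chrom!r}")
    size = chrom_sizes[chrom]
    if start >= size:
        raise ValidationError(
            f"clone {clone_id}: placement start {start} beyond end of {chrom} ({size} bp)"
        )
    return start, min(end, size)


def write_tracks(
    classifications: Iterable[CloneClassification],
    chrom_sizes: Mapping[str, int],
    out_dir,
    prefix: str = "type",
    gff3: bool = False,
) -> dict[int, Path]:
    """One BED file per synteny type; every placement appears exactly once.

    Ends are clipped to the chromosome length; a placement starting beyond
    the chromosome end raises :class:`ValidationError` naming the record.
    Optionally mirrors each track as GFF3 (1-based inclusive).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines: dict[int, list[str]] = {1: [], 2: [], 3: [], 4: []}
    gff_lines: dict[int, list[str]] = {1: [], 2: [], 3: [], 4: []}
    for c in classifications:
        for placement in c.placements:
            start, end = _validated_span(
                c.clone_id, placement.target_chrom, placement.start, placement.end,
                chrom_sizes,
            )
            score = min(1000, int(placement.bit_score))
            name = f"{c.clone_id}/{placement.end_label}"
            lines[c.synteny_type].append(
                f"{placement.target_chrom}\t{start}\t{end}\t{name}\t{score}\t{placement.strand}\n"
            )
            if gff3:
                gff_lines[c.synteny_type].append(
                    f"{placement.target_chrom}\tbesmap\tBAC_end_hit\t{start + 1}\t{end}\t"
                    f"{score}\t{placement.strand}\t.\tID={name};synteny_type={c.synteny_type}\n"
                )
    paths: dict[int, Path] = {}
    for stype in (1, 2, 3, 4):
        bed = out_dir / f"{prefix}{stype}.bed"
        bed.write_text("".join(lines[stype]))
        paths[stype] = bed
        if gff3:
            gff = out_dir / f"{prefix}{stype}.gff3"
            gff.write_text("##gff-version 3\n" + "".join(gff_lines[stype]))
    return paths


def write_circos_links(
    classifications: Iterable[CloneClassification],
    path,
    types: Sequence[int] = (3,),
) -> int:
    """Two-anchor Circos link lines (``chrA sA eA chrB sB eB id=<clone>``),
    one per clone of the requested type(s); returns the number written."""
    n = 0
    with Path(path).open("w") as fh:
        for c in classifications:
            if c.synteny_type not in types or c.placement_b is None:
                continue
            a, b = c.placement_a, c.placement_b
            fh.write(
                f"{a.target_chrom} {a.start} {a.end} "
                f"{b.target_chrom} {b.start} {b.end} id={c.clone_id}\n"
            )
            n += 1
    return n


def score_distribution(
    classifications: Iterable[CloneClassification],
    truncate_at: float = 1e-10,
) -> pd.DataFrame:
    """Histogram of e-value decades per synteny type.

    Each placement contributes one count to the bin ``floor(log10(e))`` of
    its e-value; bins above the significance cutoff are excluded (the
    distribution is truncated where the hit filter truncated it).
    """
    counts: dict[tuple[int, int], int] = {}
    for c in classifications:
        for placement in c.placements:
            e = placement.e_value
            if e >= truncate_at:
                continue
            exponent = -200 if e <= 0 else math.floor(math.log10(e))
            key = (exponent, c.synteny_type)
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["exponent"]).set_index("exponent")
    exponents = sorted({k[0] for k in counts})
    types = sorted({k[1] for k in counts})
    data = {
        f"type{t}": [counts.get((x, t), 0) for x in exponents] for t in types
    }
    frame = pd.DataFrame(data, index=pd.Index(exponents, name="exponent"))
    return frame


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).open(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValidationError(f"{path}, line {lineno}: expected 'name<TAB>length'")
        sizes[fields[0]] = int(fields[1])
    return sizes
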