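"""Independent brute-force oracles and random-record generators shared by the
unit and acceptance tests.  These deliberately re-derive behaviour from the
rule statements rather than calling the library's implementation."""
from __future__ import annotations

import numpy as np

from besmap.hits import BestPlacement, CloneRecord


def oracle_synteny_type(record: CloneRecord, max_span: int) -> int:
    """Exhaustive rule evaluation, written independently of classify_clone."""
    placements = record.placements
    assert placements, "oracle requires at least one placement"
    if len(placements) == 1:
        return 1
    if len({p.target_chrom for p in placements}) == 2:
        return 4
    lo = min(p.start for p in placements)
    hi = max(p.end for p in placements)
    left = min(placements, key=lambda p: (p.start, p.end, p.strand))
    right = max(placements, key=lambda p: (p.start, p.end, p.strand))
    if left.strand == "+" and right.strand == "-" and hi - lo <= max_span:
        return 2
    return 3


def _random_placement(rng: np.random.Generator, clone_id: str, end_label: str,
                      chroms=("chr1", "chr2", "chr3")) -> BestPlacement:
    start = int(rng.integers(0, 1_000_000))
    length = int(rng.integers(100, 800))
    return BestPlacement(
        clone_id=clone_id,
        end_label=end_label,
        target_chrom=chroms[int(rng.integers(len(chroms)))],
        start=start,
        end=start + length,
        strand="+" if rng.random() < 0.5 else "-",
        e_value=float(10.0 ** -rng.uniform(11, 60)),
        bit_score=float(rng.uniform(100, 600)),
    )


def random_clone_records(rng: np.random.Generator, n: int) -> list[CloneRecord]:
    """Random records covering one- and two-end cases, biased so that
    same-chromosome pairs (where the distance/orientation rules bite) are
    common."""
    records = []
    for i in range(n):
        cid = f"rnd{i:06d}"
        pf = _random_placement(rng, cid, "F")
        if rng.random() < 0.2:
            record = CloneRecord(clone_id=cid, placement_F=pf)
        else:
            pr = _random_placement(rng, cid, "R")
            if rng.random() < 0.6:
                # force same chromosome, often within typing distance
                pr = BestPlacement(
                    clone_id=cid, end_label="R",
                    target_chrom=pf.target_chrom,
                    start=max(0, pf.start + int(rng.integers(-400_000, 400_000))),
                    end=0, strand=pr.strand, e_value=pr.e_value,
                    bit_score=pr.bit_score,
                )
                pr = BestPlacement(
                    clone_id=cid, end_label="R", target_chrom=pr.target_chrom,
                    start=pr.start, end=pr.start + int(rng.integers(100, 800)),
                    strand=pr.strand, e_value=pr.e_value, bit_score=pr.bit_score,
                )
            record = CloneRecord(clone_id=cid, placement_F=pf, placement_R=pr)
        records.append(record)
    return records
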