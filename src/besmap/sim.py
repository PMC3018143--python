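"""Two-genome rearrangement and BAC-library simulator.

The model: a "query" genome (the species whose BAC library is sequenced)
and a "target" genome (the reference assembly the end reads are aligned
to) that derives from the query by ``k`` inversions and ``m`` reciprocal
translocations.  On top of the rearrangements sits a whole-genome
duplication remnant: a fraction of genes retain a paralog on another
chromosome, and for a fraction ``d`` of those the syntenic copy has been
lost in the target lineage, so the best alignment of an end read landing
in such a gene is redirected to the paralog — the process that mimics
inter-chromosomal rearrangement in real mate-pair data.

A clone library is drawn on the query genome (truncated-normal insert
length, two inward-facing end reads per clone) and each end independently
produces an alignment hit with probability ``p``, emulating the observed
per-end hit rate of a BAC-end survey.  Every clone carries a ground-truth
synteny type and the set of true breakpoints it straddles, so the whole
downstream pipeline (parsing, best-hit selection, pairing, classification,
rate estimation, breakpoint clustering) is testable without external data.

Breakpoints are sampled with a minimum separation of one insert length so
that each clone straddles at most one breakpoint, matching the
one-break-per-clone accounting the rate estimators assume.
"""
from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .hits import AlignmentHit, EndNaming

__all__ = [
    "SimConfig", "Genome", "Segment", "Breakpoint", "CoordinateMap",
    "ParalogRecord", "Clone", "TruthTable", "SimResult",
    "build_genome", "apply_rearrangements", "apply_paralog_model",
    "sample_bac_library", "emit_truth_hits", "simulate", "write_end_fasta",
    "write_chrom_sizes",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults describe the study conditions the package emulates: a
    73,728-clone library with 150 kb mean inserts on a 20 x 48 Mb genome,
    ~1,250 genes per chromosome of which 5% lose their syntenic copy after
    duplication, eight inversions per chromosome, and a 17% per-end hit
    rate against the reference assembly.
    """

    n_chromosomes: int = 20
    chrom_length: int = 48_000_000
    n_inversions: int = 160
    n_translocations: int = 0
    genes_per_chrom: int = 1250
    gene_length: int = 15_000
    dup_fraction: float = 1.0
    loss_prob: float = 0.05
    n_clones: int = 73_728
    insert_mean: int = 150_000
    insert_sd: int = 15_000
    end_length: int = 600
    detect_prob: float = 0.17
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_inversions": self.n_inversions,
            "n_translocations": self.n_translocations,
            "genes_per_chrom": self.genes_per_chrom,
            "gene_length": self.gene_length,
            "n_clones": self.n_clones,
            "insert_mean": self.insert_mean,
            "insert_sd": self.insert_sd,
            "end_length": self.end_length,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        for name, value in (
            ("dup_fraction", self.dup_fraction),
            ("loss_prob", self.loss_prob),
            ("detect_prob", self.detect_prob),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.insert_mean <= 2 * self.end_length:
            raise ConfigurationError(
                f"insert_mean ({self.insert_mean}) must exceed twice the end length "
                f"({self.end_length})"
            )
        if self.chrom_length <= self.insert_mean:
            raise ConfigurationError("chrom_length must exceed insert_mean")
        if self.genes_per_chrom * self.gene_length > self.chrom_length:
            raise ConfigurationError(
                "cannot place genes without overlap: "
                f"{self.genes_per_chrom} x {self.gene_length} bp > chromosome length"
            )
        if self.dup_fraction > 0 and self.n_chromosomes < 2:
            raise ConfigurationError(
                "paralogs need a second chromosome: dup_fraction > 0 requires "
                "n_chromosomes >= 2"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Genome:
    """Query-genome model: chromosome lengths plus per-chromosome gene intervals."""

    lengths: dict[str, int]
    genes: dict[str, np.ndarray]  # (g, 2) int64 arrays, 0-based half-open, sorted

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def gene_id(self, chrom: str, index: int) -> str:
        return f"{chrom}:g{index:05d}"


def build_genome(config: SimConfig, rng: np.random.Generator | None = None) -> Genome:
    """Place ``genes_per_chrom`` non-overlapping gene intervals uniformly per chromosome."""
    config.validate()
    rng = config.rng() if rng is None else rng
    lengths = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    genes: dict[str, np.ndarray] = {}
    g, glen = config.genes_per_chrom, config.gene_length
    for chrom in lengths:
        if g == 0:
            genes[chrom] = np.empty((0, 2), dtype=np.int64)
            continue
        # uniform non-overlapping placement: sort g draws over the free space,
        # then stretch by one gene length per preceding gene
        free = config.chrom_length - g * glen
        starts = np.sort(rng.integers(0, free + 1, size=g)) + np.arange(g) * glen
        genes[chrom] = np.stack([starts, starts + glen], axis=1)
    return Genome(lengths=lengths, genes=genes)


@dataclass(frozen=True)
class Segment:
    """A target-genome block: a query interval carried forward or reversed."""

    q_chrom: str
    q_start: int
    q_end: int
    strand: int  # +1 or -1

    def __len__(self) -> int:
        return self.q_end - self.q_start


@dataclass(frozen=True)
class Breakpoint:
    """A true rearrangement edge, in query-genome coordinates."""

    chrom: str
    pos: int
    kind: str  # "inversion-edge" or "translocation-edge"


class CoordinateMap:
    """Invertible piecewise map from query to target coordinates."""

    def __init__(self, layout: Mapping[str, Sequence[Segment]]):
        self._layout = {c: list(segs) for c, segs in layout.items()}
        self.target_lengths = {
            c: sum(len(s) for s in segs) for c, segs in self._layout.items()
        }
        fwd: dict[str, list[tuple[int, int, str, int, int]]] = defaultdict(list)
        inv: dict[str, tuple[list[int], list[Segment]]] = {}
        for t_chrom, segs in self._layout.items():
            offs: list[int] = []
            off = 0
            for seg in segs:
                fwd[seg.q_chrom].append((seg.q_start, seg.q_end, t_chrom, off, seg.strand))
                offs.append(off)
                off += len(seg)
            inv[t_chrom] = (offs, segs)
        self._fwd = {}
        for q_chrom, rows in fwd.items():
            rows.sort()
            self._fwd[q_chrom] = ([r[0] for r in rows], rows)
        self._inv = inv

    @classmethod
    def identity(cls, lengths: Mapping[str, int]) -> "CoordinateMap":
        return cls({c: [Segment(c, 0, n, 1)] for c, n in lengths.items()})

    @property
    def layout(self) -> dict[str, list[Segment]]:
        return {c: list(segs) for c, segs in self._layout.items()}

    def map_position(self, q_chrom: str, pos: int) -> tuple[str, int, int]:
        """Query base -> (target chromosome, target position, segment strand)."""
        starts, rows = self._fwd[q_chrom]
        i = bisect_right(starts, pos) - 1
        if i < 0:
            raise KeyError(f"{q_chrom}:{pos} outside mapped intervals")
        q_start, q_end, t_chrom, t_off, strand = rows[i]
        if not q_start <= pos < q_end:
            raise KeyError(f"{q_chrom}:{pos} outside mapped intervals")
        if strand > 0:
            return t_chrom, t_off + (pos - q_start), strand
        return t_chrom, t_off + (q_end - 1 - pos), strand

    def inverse_position(self, t_chrom: str, pos: int) -> tuple[str, int, int]:
        """Target base -> (query chromosome, query position, segment strand)."""
        offs, segs = self._inv[t_chrom]
        i = bisect_right(offs, pos) - 1
        if i < 0 or pos >= self.target_lengths[t_chrom]:
            raise KeyError(f"{t_chrom}:{pos} outside target chromosome")
        seg, off = segs[i], offs[i]
        if seg.strand > 0:
            return seg.q_chrom, seg.q_start + (pos - off), seg.strand
        return seg.q_chrom, seg.q_end - 1 - (pos - off), seg.strand


def _split(segs: list[Segment], t_pos: int) -> int:
    """Cut the segment list at target offset ``t_pos``; return boundary index."""
    off = 0
    for i, seg in enumerate(segs):
        n = len(seg)
        if t_pos == off:
            return i
        if off < t_pos < off + n:
            d = t_pos - off
            if seg.strand > 0:
                pair = [
                    Segment(seg.q_chrom, seg.q_start, seg.q_start + d, 1),
                    Segment(seg.q_chrom, seg.q_start + d, seg.q_end, 1),
                ]
            else:
                pair = [
                    Segment(seg.q_chrom, seg.q_end - d, seg.q_end, -1),
                    Segment(seg.q_chrom, seg.q_start, seg.q_end - d, -1),
                ]
            segs[i:i + 1] = pair
            return i + 1
        off += n
    if t_pos == off:
        return len(segs)
    raise ValueError(f"cut position {t_pos} beyond chromosome end {off}")


def _q_at(segs: Sequence[Segment], t_pos: int) -> tuple[str, int]:
    """Query coordinate of the base at target offset ``t_pos``."""
    off = 0
    for seg in segs:
        n = len(seg)
        if off <= t_pos < off + n:
            if seg.strand > 0:
                return seg.q_chrom, seg.q_start + (t_pos - off)
            return seg.q_chrom, seg.q_end - 1 - (t_pos - off)
        off += n
    raise ValueError(f"position {t_pos} beyond chromosome end {off}")


_MAX_PLACEMENT_TRIES = 500


def apply_rearrangements(
    genome: Genome,
    k_inv: int,
    k_trans: int,
    rng: np.random.Generator,
    min_separation: int = 150_000,
) -> tuple[CoordinateMap, list[Breakpoint]]:
    """Derive a target genome by ``k_inv`` inversions and ``k_trans`` reciprocal
    translocations; return the query->target coordinate map and the true
    breakpoints (2 per inversion, 2 per translocation) in query coordinates.

    Breakpoints are kept at least ``min_separation`` apart (and away from
    chromosome ends) in query space so a clone of that insert length can
    straddle at most one of them.
    """
    layout: dict[str, list[Segment]] = {
        c: [Segment(c, 0, n, 1)] for c, n in genome.lengths.items()
    }
    bp_by_qchrom: dict[str, list[int]] = defaultdict(list)
    breakpoints: list[Breakpoint] = []
    sep = int(min_separation)

    def q_ok(q_chrom: str, q_pos: int) -> bool:
        q_len = genome.lengths[q_chrom]
        if not sep <= q_pos <= q_len - sep:
            return False
        return all(abs(q_pos - b) >= sep for b in bp_by_qchrom[q_chrom])

    def weighted_chroms(min_len: int) -> tuple[list[str], np.ndarray]:
        names = [c for c, segs in layout.items()
                 if sum(len(s) for s in segs) >= min_len]
        if not names:
            raise ConfigurationError(
                "no chromosome long enough for the requested rearrangement "
                f"(need >= {min_len} bp)"
            )
        w = np.array([sum(len(s) for s in layout[c]) for c in names], dtype=float)
        return names, w / w.sum()

    def record(q_chrom: str, q_pos: int, kind: str) -> None:
        bp_by_qchrom[q_chrom].append(q_pos)
        breakpoints.append(Breakpoint(chrom=q_chrom, pos=q_pos, kind=kind))

    ops = ["inv"] * k_inv + ["trans"] * k_trans
    rng.shuffle(ops)
    for op in ops:
        if op == "inv":
            placed = False
            for _ in range(_MAX_PLACEMENT_TRIES):
                names, w = weighted_chroms(3 * sep + 2)
                t_chrom = names[rng.choice(len(names), p=w)]
                t_len = sum(len(s) for s in layout[t_chrom])
                a = int(rng.integers(sep, t_len - 2 * sep + 1))
                b = int(rng.integers(a + sep, t_len - sep + 1))
                qa = _q_at(layout[t_chrom], a)
                qb = _q_at(layout[t_chrom], b)
                if q_ok(*qa) and q_ok(*qb):
                    segs = layout[t_chrom]
                    i = _split(segs, a)
                    j = _split(segs, b)
                    segs[i:j] = [
                        Segment(s.q_chrom, s.q_start, s.q_end, -s.strand)
                        for s in reversed(segs[i:j])
                    ]
                    record(*qa, "inversion-edge")
                    record(*qb, "inversion-edge")
                    placed = True
                    break
            if not placed:
                raise ConfigurationError(
                    "could not place an inversion with the requested breakpoint "
                    "separation; reduce n_inversions or min_separation"
                )
        else:
            placed = False
            for _ in range(_MAX_PLACEMENT_TRIES):
                names, w = weighted_chroms(2 * sep + 1)
                if len(names) < 2:
                    raise ConfigurationError(
                        "reciprocal translocation needs two chromosomes of at least "
                        f"{2 * sep + 1} bp"
                    )
                ia, ib = rng.choice(len(names), size=2, replace=False, p=w)
                ca, cb = names[ia], names[ib]
                la = sum(len(s) for s in layout[ca])
                lb = sum(len(s) for s in layout[cb])
                xa = int(rng.integers(sep, la - sep + 1))
                xb = int(rng.integers(sep, lb - sep + 1))
                qa = _q_at(layout[ca], xa)
                qb = _q_at(layout[cb], xb)
                if q_ok(*qa) and q_ok(*qb):
                    i = _split(layout[ca], xa)
                    j = _split(layout[cb], xb)
                    tail_a = layout[ca][i:]
                    layout[ca][i:] = layout[cb][j:]
                    layout[cb][j:] = tail_a
                    record(*qa, "translocation-edge")
                    record(*qb, "translocation-edge")
                    placed = True
                    break
            if not placed:
                raise ConfigurationError(
                    "could not place a translocation with the requested breakpoint "
                    "separation"
                )
    return CoordinateMap(layout), breakpoints


@dataclass(frozen=True)
class ParalogRecord:
    """A duplicated gene: its query interval, the mapped syntenic location in
    the target, the retained paralog location, and whether the syntenic copy
    was lost (redirecting alignments to the paralog)."""

    gene_id: str
    q_chrom: str
    q_start: int
    q_end: int
    syn_chrom: str
    syn_start: int
    syn_end: int
    par_chrom: str
    par_start: int
    par_end: int
    syntenic_lost: bool


def apply_paralog_model(
    genome: Genome,
    dup_fraction: float,
    d: float,
    rng: np.random.Generator,
    coord_map: CoordinateMap | None = None,
) -> dict[str, ParalogRecord]:
    """Duplicate each gene with probability ``dup_fraction`` onto a uniformly
    chosen *other* target chromosome; among duplicated genes, flag the
    syntenic copy lost with probability ``d``."""
    if not 0.0 <= dup_fraction <= 1.0 or not 0.0 <= d <= 1.0:
        raise ConfigurationError("dup_fraction and d must be in [0, 1]")
    if dup_fraction > 0 and len(genome.lengths) < 2:
        raise ConfigurationError(
            "paralog placement needs a second chromosome (single-chromosome "
            "genome with dup_fraction > 0)"
        )
    cmap = coord_map if coord_map is not None else CoordinateMap.identity(genome.lengths)
    t_names = list(cmap.target_lengths)
    out: dict[str, ParalogRecord] = {}
    for chrom, arr in genome.genes.items():
        if len(arr) == 0:
            continue
        dup = rng.random(len(arr)) < dup_fraction
        lost = rng.random(len(arr)) < d
        for i in np.flatnonzero(dup):
            q_start, q_end = int(arr[i, 0]), int(arr[i, 1])
            glen = q_end - q_start
            syn_chrom, syn_mid, _ = cmap.map_position(chrom, (q_start + q_end) // 2)
            syn_start = max(0, syn_mid - glen // 2)
            syn_end = min(cmap.target_lengths[syn_chrom], syn_start + glen)
            others = [t for t in t_names if t != syn_chrom]
            par_chrom = others[int(rng.integers(len(others)))]
            par_room = max(1, cmap.target_lengths[par_chrom] - glen)
            par_start = int(rng.integers(0, par_room))
            gid = genome.gene_id(chrom, int(i))
            out[gid] = ParalogRecord(
                gene_id=gid, q_chrom=chrom, q_start=q_start, q_end=q_end,
                syn_chrom=syn_chrom, syn_start=syn_start, syn_end=syn_end,
                par_chrom=par_chrom, par_start=par_start, par_end=par_start + glen,
                syntenic_lost=bool(lost[i]),
            )
    return out


@dataclass(frozen=True)
class Clone:
    """A BAC clone on the query genome, 0-based half-open span."""

    clone_id: str
    chrom: str
    start: int
    end: int

    @property
    def insert(self) -> int:
        return self.end - self.start


def clone_ends(clone: Clone, end_length: int) -> list[tuple[str, int, int, int]]:
    """The two inward-facing end reads: (label, start, end, orientation)."""
    return [
        ("F", clone.start, clone.start + end_length, +1),
        ("R", clone.end - end_length, clone.end, -1),
    ]


def sample_bac_library(
    genome: Genome, config: SimConfig, rng: np.random.Generator
) -> list[Clone]:
    """Draw ``n_clones`` clones: chromosome ~ length-weighted, start uniform,
    insert ~ Normal(insert_mean, insert_sd) truncated to
    [2 x end_length, chromosome length]."""
    config.validate()
    n = config.n_clones
    names = genome.names
    lens = np.array([genome.lengths[c] for c in names], dtype=np.int64)
    chrom_idx = rng.choice(len(names), size=n, p=lens / lens.sum())
    lo = 2 * config.end_length
    hi = lens[chrom_idx].astype(float)
    if config.insert_sd == 0:
        inserts = np.full(n, config.insert_mean, dtype=np.int64)
    else:
        inserts = rng.normal(config.insert_mean, config.insert_sd, size=n)
        bad = (inserts < lo) | (inserts > hi)
        while bad.any():
            inserts[bad] = rng.normal(config.insert_mean, config.insert_sd, size=int(bad.sum()))
            bad = (inserts < lo) | (inserts > hi)
        inserts = inserts.astype(np.int64)
    starts = np.floor(rng.random(n) * (lens[chrom_idx] - inserts + 1)).astype(np.int64)
    return [
        Clone(
            clone_id=f"clone{i:06d}",
            chrom=names[int(chrom_idx[i])],
            start=int(starts[i]),
            end=int(starts[i] + inserts[i]),
        )
        for i in range(n)
    ]


_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def write_end_fasta(
    clones: Sequence[Clone],
    end_length: int,
    path,
    rng: np.random.Generator,
    naming: EndNaming = EndNaming(),
) -> None:
    """Write 2-line FASTA records of random nucleotides for every clone end.

    Sequence content is synthetic (the analysis consumes alignment hits,
    not raw reads); with a fixed generator the output is byte-identical.
    """
    with Path(path).open("wb") as fh:
        for clone in clones:
            for label, _s, _e, _o in clone_ends(clone, end_length):
                seq = _BASE_LUT[rng.integers(0, 4, size=end_length)].tobytes()
                fh.write(b">" + naming.join(clone.clone_id, label).encode() + b"\n")
                fh.write(seq + b"\n")


def write_chrom_sizes(lengths: Mapping[str, int], path) -> None:
    with Path(path).open("w") as fh:
        for chrom, n in lengths.items():
            fh.write(f"{chrom}\t{n}\n")


@dataclass
class TruthTable:
    """Ground truth for one simulated library."""

    breakpoints: list[Breakpoint]
    clone_truth: dict[str, int]                 # clone id -> true type (1-4), detected clones only
    clone_breakpoints: dict[str, tuple[int, ...]]  # clone id -> indices of straddled breakpoints
    paralog_map: dict[str, ParalogRecord] = field(default_factory=dict)

    def write_clone_truth(self, path) -> None:
        with Path(path).open("w") as fh:
            fh.write("clone_id\ttrue_type\n")
            for cid, t in sorted(self.clone_truth.items()):
                fh.write(f"{cid}\t{t}\n")

    def write_breakpoints(self, path) -> None:
        with Path(path).open("w") as fh:
            fh.write("chrom\tpos\tkind\n")
            for bp in self.breakpoints:
                fh.write(f"{bp.chrom}\t{bp.pos}\t{bp.kind}\n")


def _truth_type(
    placements: list[tuple[str, int, int, str]], max_span: int
) -> int:
    """Synteny type implied by the true placements (chrom, start, end, strand)."""
    if len(placements) == 1:
        return 1
    a, b = sorted(placements, key=lambda p: (p[0], p[1], p[2], p[3]))
    if a[0] != b[0]:
        return 4
    span = max(a[2], b[2]) - min(a[1], b[1])
    if a[3] == "+" and b[3] == "-" and span <= max_span:
        return 2
    return 3


def emit_truth_hits(
    clones: Sequence[Clone],
    coordinate_map: CoordinateMap,
    paralog_map: Mapping[str, ParalogRecord],
    p: float,
    rng: np.random.Generator,
    *,
    end_length: int = 600,
    breakpoints: Sequence[Breakpoint] = (),
    naming: EndNaming = EndNaming(),
    max_span: int = 300_000,
) -> tuple[list[AlignmentHit], TruthTable]:
    """Emit per-end alignment hits with detection probability ``p`` and the
    matching truth table.

    A detected end whose midpoint falls in a gene with a lost syntenic copy
    is redirected to the paralog location (random strand, depressed score);
    all other detected ends map through the coordinate map, with hit strand
    composed from the end's inward orientation and any spanning inversion.
    Synthetic bit scores are drawn high for orthologous placements and low
    for paralog redirections, so score distributions by type mirror the
    real survey's pattern.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"detection probability must be in [0, 1], got {p}")

    # lost-syntenic gene lookup, per query chromosome
    lost_idx: dict[str, tuple[np.ndarray, np.ndarray, list[ParalogRecord]]] = {}
    by_chrom: dict[str, list[ParalogRecord]] = defaultdict(list)
    for rec in paralog_map.values():
        if rec.syntenic_lost:
            by_chrom[rec.q_chrom].append(rec)
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.q_start)
        lost_idx[chrom] = (
            np.array([r.q_start for r in recs], dtype=np.int64),
            np.array([r.q_end for r in recs], dtype=np.int64),
            recs,
        )

    bp_pos: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for i, bp in enumerate(breakpoints):
        bp_pos[bp.chrom].append((bp.pos, i))
    for rows in bp_pos.values():
        rows.sort()

    def lost_gene_at(chrom: str, pos: int) -> ParalogRecord | None:
        entry = lost_idx.get(chrom)
        if entry is None:
            return None
        starts, ends, recs = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return recs[i]
        return None

    hits: list[AlignmentHit] = []
    clone_truth: dict[str, int] = {}
    clone_bps: dict[str, tuple[int, ...]] = {}

    for clone in clones:
        spanned = tuple(
            i for pos, i in bp_pos.get(clone.chrom, ())
            if clone.start < pos < clone.end
        )
        clone_bps[clone.clone_id] = spanned
        placements: list[tuple[str, int, int, str]] = []
        for label, s, e, orient in clone_ends(clone, end_length):
            if rng.random() >= p:
                continue
            mid = (s + e) // 2
            lost = lost_gene_at(clone.chrom, mid)
            if lost is not None:
                t_chrom = lost.par_chrom
                t_mid = (lost.par_start + lost.par_end) // 2
                strand = "+" if rng.random() < 0.5 else "-"
                bit = float(np.clip(rng.normal(220.0, 35.0), 120.0, 350.0))
                pid = float(np.clip(rng.normal(83.0, 3.0), 70.0, 100.0))
            else:
                t_chrom, t_mid, seg_strand = coordinate_map.map_position(clone.chrom, mid)
                strand = "+" if seg_strand * orient > 0 else "-"
                bit = float(np.clip(rng.normal(480.0, 60.0), 150.0, 900.0))
                pid = float(np.clip(rng.normal(94.0, 2.0), 80.0, 100.0))
            t_len = coordinate_map.target_lengths[t_chrom]
            t_start = int(max(0, min(t_mid - end_length // 2, t_len - end_length)))
            t_end = t_start + end_length
            hits.append(
                AlignmentHit(
                    query_id=naming.join(clone.clone_id, label),
                    target_chrom=t_chrom,
                    target_start=t_start + 1,
                    target_end=t_end,
                    strand=strand,
                    percent_identity=round(pid, 2),
                    e_value=max(10.0 ** (-bit / 10.0), 1e-180),
                    bit_score=round(bit, 1),
                )
            )
            placements.append((t_chrom, t_start, t_end, strand))
        if placements:
            clone_truth[clone.clone_id] = _truth_type(placements, max_span)

    truth = TruthTable(
        breakpoints=list(breakpoints),
        clone_truth=clone_truth,
        clone_breakpoints=clone_bps,
        paralog_map=dict(paralog_map),
    )
    return hits, truth


@dataclass
class SimResult:
    """Everything one seeded simulation produced."""

    config: SimConfig
    genome: Genome
    coord_map: CoordinateMap
    breakpoints: list[Breakpoint]
    paralog_map: dict[str, ParalogRecord]
    clones: list[Clone]
    hits: list[AlignmentHit]
    truth: TruthTable


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator with one seeded RNG threaded through all stages."""
    config.validate()
    rng = config.rng()
    genome = build_genome(config, rng)
    coord_map, breakpoints = apply_rearrangements(
        genome, config.n_inversions, config.n_translocations, rng,
        min_separation=config.insert_mean,
    )
    paralog_map = apply_paralog_model(
        genome, config.dup_fraction, config.loss_prob, rng, coord_map=coord_map
    )
    clones = sample_bac_library(genome, config, rng)
    hits, truth = emit_truth_hits(
        clones, coord_map, paralog_map, config.detect_prob, rng,
        end_length=config.end_length, breakpoints=breakpoints,
    )
    return SimResult(
        config=config, genome=genome, coord_map=coord_map,
        breakpoints=breakpoints, paralog_map=paralog_map,
        clones=clones, hits=hits, truth=truth,
    )
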