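"""Rearrangement-rate estimators and breakpoint clustering.

The estimators turn synteny-type tallies into genome-scale rates:

* intra-chromosomal ratio ``r = n3 / (n2 + n3)`` — the fraction of
  same-chromosome clone pairs that are discordant, the cleanest signal of
  intra-chromosomal rearrangement (inversions);
* discordance ratio ``f = (n3 + n4) / (n2 + n3 + n4)`` — all discordant
  clones, an upper bound that also counts paralog-driven type-4 signal;
* breakpoint spacing ``L / ratio`` — if one clone in ``1/ratio`` spans a
  break and inserts average ``L``, breaks are spaced about ``L / ratio``;
* breakpoints per chromosome ``C / spacing`` (inversions are half that,
  each inversion having two edges) and genome-wide ``G / spacing``.

Type-3 clones are clustered into candidate breakpoints by single linkage:
two clones co-cluster when both their leftmost placements and both their
rightmost placements fall within a window ``W`` of each other.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .classify import CloneClassification, TypeCounts
from .errors import ConfigurationError

DEFAULT_INSERT = 150_000
DEFAULT_CHROM_LENGTH = 48_000_000
DEFAULT_GENOME_SIZE = 1_000_000_000
DEFAULT_WINDOW = 150_000


def intra_ratio(counts: TypeCounts) -> float | None:
    """n3 / (n2 + n3); ``None`` when undefined (no same-chromosome pairs)."""
    denom = counts.n2 + counts.n3
    if denom == 0:
        return None
    return counts.n3 / denom


def discordant_ratio(counts: TypeCounts) -> float | None:
    """(n3 + n4) / (n2 + n3 + n4); ``None`` when undefined."""
    denom = counts.n2 + counts.n3 + counts.n4
    if denom == 0:
        return None
    return (counts.n3 + counts.n4) / denom


def breakpoint_spacing(ratio: float, insert_length: float = DEFAULT_INSERT) -> float | None:
    """Mean distance between breakpoints implied by a per-clone break rate.

    ``None`` (infinite spacing) when the ratio is zero.
    """
    if ratio is None or ratio == 0:
        return None
    if not 0 < ratio <= 1:
        raise ConfigurationError(f"ratio must be in (0, 1], got {ratio}")
    return insert_length / ratio


def breakpoints_per_chromosome(chrom_length: float, spacing: float) -> float:
    if spacing <= 0:
        raise ConfigurationError("spacing must be positive")
    return chrom_length / spacing


def genome_breakpoints(genome_size: float, spacing: float) -> float:
    return breakpoints_per_chromosome(genome_size, spacing)


def expected_double_hit_rate(p: float, observed: float | None = None):
    """Expected both-end hit fraction ``p**2`` under independent end detection.

    With an ``observed`` fraction supplied, returns
    ``(expected, observed / expected)``.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"hit rate must be in [0, 1], got {p}")
    expected = p * p
    if observed is None:
        return expected
    return expected, (observed / expected if expected > 0 else math.inf)


def expected_paralog_loss(genes_per_chrom: float, d: float) -> float:
    """Expected genes per chromosome whose syntenic copy is lost: ``g * d``."""
    if genes_per_chrom < 0 or not 0.0 <= d <= 1.0:
        raise ConfigurationError("need genes_per_chrom >= 0 and d in [0, 1]")
    return genes_per_chrom * d


@dataclass(frozen=True)
class RearrangementEstimate:
    """Ratio-based rearrangement rates for one count row."""

    intra_ratio: float | None
    discordant_ratio: float | None
    insert: float
    spacing_intra: float | None
    spacing_any: float | None
    chrom_length: float
    genome_size: float
    breakpoints_per_chrom: float | None
    inversions_per_chrom: float | None
    genome_breakpoints: float | None


def estimate_rearrangements(
    counts: TypeCounts,
    insert: float = DEFAULT_INSERT,
    chrom_length: float = DEFAULT_CHROM_LENGTH,
    genome_size: float = DEFAULT_GENOME_SIZE,
) -> RearrangementEstimate:
    r = intra_ratio(counts)
    f = discordant_ratio(counts)
    spacing_intra = breakpoint_spacing(r, insert) if r else None
    spacing_any = breakpoint_spacing(f, insert) if f else None
    bpc = breakpoints_per_chromosome(chrom_length, spacing_intra) if spacing_intra else None
    return RearrangementEstimate(
        intra_ratio=r,
        discordant_ratio=f,
        insert=insert,
        spacing_intra=spacing_intra,
        spacing_any=spacing_any,
        chrom_length=chrom_length,
        genome_size=genome_size,
        breakpoints_per_chrom=bpc,
        inversions_per_chrom=bpc / 2 if bpc is not None else None,
        genome_breakpoints=genome_breakpoints(genome_size, spacing_any) if spacing_any else None,
    )


@dataclass(frozen=True)
class BreakpointCluster:
    """A group of type-3 clones whose end placements co-locate: a candidate
    rearrangement breakpoint, represented by its two joined regions."""

    chrom: str
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    support: int
    member_ids: tuple[str, ...]


@dataclass
class ClusterResult:
    clusters: list[BreakpointCluster]          # support >= min_support only
    per_chromosome: dict[str, int]
    mean_support: float | None


def cluster_breakpoints(
    classifications: Iterable[CloneClassification],
    window: int = DEFAULT_WINDOW,
    min_support: int = 1,
) -> ClusterResult:
    """Single-linkage clustering of type-3 clones into candidate breakpoints.

    Two clones co-cluster iff they sit on the same chromosome and both
    their leftmost-placement midpoints and both their rightmost-placement
    midpoints are within ``window`` of each other.  Clusters with fewer
    than ``min_support`` members are discarded.  The result is
    deterministic and invariant under input order.
    """
    type3 = sorted(
        (c for c in classifications if c.synteny_type == 3),
        key=lambda c: c.clone_id,
    )
    by_chrom: dict[str, list[CloneClassification]] = {}
    for c in type3:
        by_chrom.setdefault(c.chrom_a, []).append(c)

    clusters: list[BreakpointCluster] = []
    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        ma = np.array([c.placement_a.midpoint for c in group], dtype=np.int64)
        mb = np.array([c.placement_b.midpoint for c in group], dtype=np.int64)
        adj = (
            (np.abs(ma[:, None] - ma[None, :]) <= window)
            & (np.abs(mb[:, None] - mb[None, :]) <= window)
        )
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        for k in range(n_comp):
            members = [group[i] for i in np.flatnonzero(labels == k)]
            starts_a = [m.placement_a.start for m in members]
            ends_a = [m.placement_a.end for m in members]
            starts_b = [m.placement_b.start for m in members]
            ends_b = [m.placement_b.end for m in members]
            clusters.append(
                BreakpointCluster(
                    chrom=chrom,
                    interval_a=(min(starts_a), max(ends_a)),
                    interval_b=(min(starts_b), max(ends_b)),
                    support=len(members),
                    member_ids=tuple(sorted(m.clone_id for m in members)),
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.interval_a, c.interval_b))
    retained = [c for c in clusters if c.support >= min_support]
    per_chrom = dict(Counter(c.chrom for c in retained))
    mean_support = (
        float(np.mean([c.support for c in retained])) if retained else None
    )
    return ClusterResult(
        clusters=retained, per_chromosome=per_chrom, mean_support=mean_support
    )


@dataclass
class RecoveryReport:
    """How clustered breakpoints line up with simulator ground truth."""

    recovered: set[int]          # indices of true breakpoints recovered
    spurious: list[BreakpointCluster]

    def recovery_rate(self, true_indices: Iterable[int]) -> float:
        idx = set(true_indices)
        if not idx:
            return float("nan")
        return len(self.recovered & idx) / len(idx)


def match_clusters_to_truth(
    result: ClusterResult,
    truth,
    min_support: int = 2,
) -> RecoveryReport:
    """Score clusters against a simulator truth table.

    A true breakpoint counts as recovered when at least ``min_support``
    members of a single cluster straddle it; a cluster is spurious when
    none of its members straddles any true breakpoint.
    """
    recovered: set[int] = set()
    spurious: list[BreakpointCluster] = []
    for cluster in result.clusters:
        hit_counts: Counter[int] = Counter()
        for cid in cluster.member_ids:
            for idx in truth.clone_breakpoints.get(cid, ()):
                hit_counts[idx] += 1
        if not hit_counts:
            spurious.append(cluster)
            continue
        for idx, n in hit_counts.items():
            if n >= min_support:
                recovered.add(idx)
    return RecoveryReport(recovered=recovered, spurious=spurious)


def write_estimates_tsv(estimates: Mapping[tuple[str, str], RearrangementEstimate], path) -> None:
    import pandas as pd

    rows = []
    for (library, target), est in estimates.items():
        rows.append({
            "library": library, "target": target,
            "intra_ratio": est.intra_ratio, "discordant_ratio": est.discordant_ratio,
            "insert_bp": est.insert,
            "spacing_intra_bp": est.spacing_intra, "spacing_any_bp": est.spacing_any,
            "breakpoints_per_chrom": est.breakpoints_per_chrom,
            "inversions_per_chrom": est.inversions_per_chrom,
            "genome_breakpoints": est.genome_breakpoints,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_clusters_tsv(result: ClusterResult, path) -> None:
    import pandas as pd

    rows = [
        {
            "chrom": c.chrom,
            "startA": c.interval_a[0], "endA": c.interval_a[1],
            "startB": c.interval_b[0], "endB": c.interval_b[1],
            "support": c.support,
            "members": ",".join(c.member_ids),
        }
        for c in result.clusters
    ]
    pd.DataFrame(
        rows, columns=["chrom", "startA", "endA", "startB", "endB", "support", "members"]
    ).to_csv(path, sep="\t", index=False)
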