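"""Distance-based clustering and ranking of candidate variant positions.

Candidates are grouped by single-linkage on the genomic distance between
consecutive positions: two neighbours join the same cluster iff their
1-based positions differ by at most ``max_gap`` (default 9000 bp).
Clusters never span contigs.  Ranking is by member count, descending —
the genome-wide maximum is the sex-linked candidate region, and the
ratio of the top count under the true system to the top count under the
opposite system is the screen's headline contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .snp_screen import CandidateVariant


@dataclass(frozen=True)
class ClusterParams:
    max_gap: int = 9000  # bp; merge iff next_pos - prev_pos <= max_gap
    min_cluster_size: int = 1

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass(frozen=True)
class VariantCluster:
    """A run of candidate positions with consecutive gaps <= max_gap.

    start/end are the 1-based positions of the first and last member.
    """

    contig: str
    start: int
    end: int
    n_variants: int
    members: tuple[int, ...] = field(repr=False, default=())

    def span(self) -> int:
        return self.end - self.start + 1


def cluster_positions(
    positions_by_contig: Mapping[str, Sequence[int]],
    params: ClusterParams = ClusterParams(),
) -> list[VariantCluster]:
    """Single-linkage gap clustering of sorted, deduplicated positions.

    Input must be sorted ascending and duplicate-free per contig
    (contract violation is fatal).  Clusters smaller than
    ``min_cluster_size`` are suppressed.
    """
    clusters: list[VariantCluster] = []
    for contig in sorted(positions_by_contig):
        positions = list(positions_by_contig[contig])
        if not positions:
            continue
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"positions on {contig} not sorted/unique")
        current = [positions[0]]
        for p in positions[1:]:
            if p - current[-1] <= params.max_gap:
                current.append(p)
            else:
                clusters.append(_make_cluster(contig, current))
                current = [p]
        clusters.append(_make_cluster(contig, current))
    return [c for c in clusters if c.n_variants >= params.min_cluster_size]


def _make_cluster(contig: str, members: list[int]) -> VariantCluster:
    return VariantCluster(
        contig=contig,
        start=members[0],
        end=members[-1],
        n_variants=len(members),
        members=tuple(members),
    )


def rank_clusters(clusters: Iterable[VariantCluster]) -> list[VariantCluster]:
    """Descending by member count; ties by span (desc), then position."""
    return sorted(
        clusters,
        key=lambda c: (-c.n_variants, -c.span(), c.contig, c.start),
    )


def positions_from_candidates(
    candidates: Iterable[CandidateVariant],
) -> dict[str, list[int]]:
    """Sorted unique positions per contig (SNP+INDEL at one pos collapse)."""
    by_contig: dict[str, set[int]] = {}
    for c in candidates:
        by_contig.setdefault(c.variant.contig, set()).add(c.variant.pos)
    return {contig: sorted(ps) for contig, ps in by_contig.items()}


def top_count_ratio(
    xy_clusters: Sequence[VariantCluster],
    zw_clusters: Sequence[VariantCluster],
) -> float:
    """Top-XY-count / top-ZW-count; NaN when either side is empty/zero."""
    xy_top = rank_clusters(xy_clusters)[0].n_variants if xy_clusters else 0
    zw_top = rank_clusters(zw_clusters)[0].n_variants if zw_clusters else 0
    if xy_top == 0 or zw_top == 0:
        return math.nan
    return xy_top / zw_top


def clusters_to_rows(clusters: Sequence[VariantCluster]) -> list[dict]:
    ranked = rank_clusters(clusters)
    return [
        {
            "rank": i,
            "contig": c.contig,
            "start": c.start,
            "end": c.end,
            "n_variants": c.n_variants,
            "span": c.span(),
            "density_per_kb": round(c.n_variants / c.span() * 1000, 4),
        }
        for i, c in enumerate(ranked, start=1)
    ]


def scan_report(
    xy_clusters: Sequence[VariantCluster],
    zw_clusters: Sequence[VariantCluster],
) -> dict:
    """Side-by-side ranked tables for both modes plus the top-count ratio.

    The ratio is reported as NaN (serialized "NA") when either mode has
    no clusters.
    """
    ratio = top_count_ratio(xy_clusters, zw_clusters)
    return {
        "xy": clusters_to_rows(xy_clusters),
        "zw": clusters_to_rows(zw_clusters),
        "top_xy_count": rank_clusters(xy_clusters)[0].n_variants if xy_clusters else 0,
        "top_zw_count": rank_clusters(zw_clusters)[0].n_variants if zw_clusters else 0,
        "xy_zw_ratio": ratio,
    }
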