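"""Detection of Y-hemizygous sequence from two pools' coverage tracks.

Sequence present only on the Y haplotype is covered at half the diploid
rate in the male pool (one copy per male instead of two) and near zero
in the female pool.  The scan combines both bedgraph tracks on a common
breakpoint refinement, normalizes each by its own modal (diploid)
coverage peak so diploid sequence sits at 1.0, selects bases with
male-half / female-absent coverage (defaults: male in [0.25, 0.75]
inclusive, female < 0.05 strict), and merges selected runs by distance,
counting selected bases per cluster.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .cluster_scan import rank_clusters as _rank_variant_clusters
from .io_formats import CoverageInterval


@dataclass(frozen=True)
class CoverageThresholds:
    male_low: float = 0.25   # inclusive, normalized
    male_high: float = 0.75  # inclusive, normalized
    female_max: float = 0.05  # strict upper bound, normalized
    max_gap: int = 9000       # bp, same merge semantics as the SNP scan

    def __post_init__(self) -> None:
        if not (0 <= self.male_low < self.male_high):
            raise ValueError("require 0 <= male_low < male_high")
        if not (self.female_max < self.male_low):
            raise ValueError("require female_max < male_low")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class CoverageCluster:
    """Merged selected runs; interval bounds are 1-based inclusive.

    ``n_bases`` counts only the selected bases (gaps between merged runs
    are not counted), so n_bases <= span.
    """

    contig: str
    start: int
    end: int
    n_bases: int

    def __post_init__(self) -> None:
        if self.n_bases < 1:
            raise ValueError("n_bases must be >= 1")
        if self.n_bases > self.span():
            raise ValueError("n_bases cannot exceed the interval span")

    def span(self) -> int:
        return self.end - self.start + 1

    # rank_clusters tie rules read n_variants; alias keeps one sort path
    @property
    def n_variants(self) -> int:
        return self.n_bases


JointInterval = tuple[str, int, int, float, float]  # contig, start, end, value_a, value_b


def union_tracks(
    track_a: Sequence[CoverageInterval],
    track_b: Sequence[CoverageInterval],
) -> list[JointInterval]:
    """Common breakpoint refinement of two tracks (bedtools-unionbedg-like).

    Every output interval carries both tracks' values; positions covered
    by neither track are omitted (both values would be 0), positions
    covered by one get 0 for the other.  Total mass of each input is
    preserved.
    """
    by_contig: dict[str, tuple[list[CoverageInterval], list[CoverageInterval]]] = defaultdict(
        lambda: ([], [])
    )
    for iv in track_a:
        by_contig[iv.contig][0].append(iv)
    for iv in track_b:
        by_contig[iv.contig][1].append(iv)

    out: list[JointInterval] = []
    for contig in sorted(by_contig):
        a_ivs, b_ivs = by_contig[contig]
        breaks = sorted({iv.start for iv in a_ivs + b_ivs} | {iv.end for iv in a_ivs + b_ivs})
        ai = bi = 0
        a_ivs.sort(key=lambda iv: iv.start)
        b_ivs.sort(key=lambda iv: iv.start)
        for lo, hi in zip(breaks, breaks[1:]):
            va = vb = 0.0
            while ai < len(a_ivs) and a_ivs[ai].end <= lo:
                ai += 1
            if ai < len(a_ivs) and a_ivs[ai].start <= lo < a_ivs[ai].end:
                va = a_ivs[ai].value
            while bi < len(b_ivs) and b_ivs[bi].end <= lo:
                bi += 1
            if bi < len(b_ivs) and b_ivs[bi].start <= lo < b_ivs[bi].end:
                vb = b_ivs[bi].value
            if va != 0.0 or vb != 0.0:
                out.append((contig, lo, hi, va, vb))
    return out


def modal_coverage(track: Sequence[CoverageInterval]) -> int:
    """Span-weighted mode of the integer coverage values, zero excluded.

    The dominant nonzero peak of a whole-genome coverage histogram is the
    diploid depth; ties break to the smallest value for determinism.
    """
    span_by_value: dict[int, int] = defaultdict(int)
    for iv in track:
        v = int(round(iv.value))
        if v > 0:
            span_by_value[v] += iv.span()
    if not span_by_value:
        raise ValueError("cannot take modal coverage of an all-zero track")
    return min(span_by_value, key=lambda v: (-span_by_value[v], v))


def modal_normalize(
    track: Sequence[CoverageInterval],
) -> tuple[list[CoverageInterval], int]:
    """Divide every value by the track's modal peak; returns (track, mode)."""
    m = modal_coverage(track)
    normalized = [
        CoverageInterval(iv.contig, iv.start, iv.end, iv.value / m) for iv in track
    ]
    return normalized, m


def select_sex_specific_bases(
    joint: Iterable[JointInterval],
    thr: CoverageThresholds = CoverageThresholds(),
) -> list[CoverageInterval]:
    """Maximal runs of bases with male-half / female-absent coverage.

    ``joint`` must carry normalized values ordered (female, male).  The
    male window is inclusive on both bounds, the female bound strict, as
    declared in :class:`CoverageThresholds`.  Selection is pointwise, so
    re-chunking the input intervals cannot change the result; adjacent
    selected intervals are merged into maximal runs (value 1 marks
    selection).
    """
    runs: list[CoverageInterval] = []
    for contig, start, end, female, male in joint:
        if thr.male_low <= male <= thr.male_high and female < thr.female_max:
            if runs and runs[-1].contig == contig and runs[-1].end == start:
                runs[-1] = CoverageInterval(contig, runs[-1].start, end, 1)
            else:
                runs.append(CoverageInterval(contig, start, end, 1))
    return runs


def cluster_selected_bases(
    runs: Sequence[CoverageInterval],
    max_gap: int = 9000,
) -> list[CoverageCluster]:
    """Merge selected runs by distance and count selected bases per cluster.

    Runs merge iff the 1-based distance between the last selected base of
    one and the first of the next is <= max_gap; ranked descending by
    n_bases with the variant-cluster tie rules.
    """
    by_contig: dict[str, list[CoverageInterval]] = defaultdict(list)
    for r in runs:
        by_contig[r.contig].append(r)

    clusters: list[CoverageCluster] = []
    for contig in sorted(by_contig):
        rs = sorted(by_contig[contig], key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise ValueError(f"selected runs overlap on {contig}")
        # 1-based inclusive bounds: run [start, end) -> [start+1 .. end]
        cur_start, cur_end, cur_bases = rs[0].start + 1, rs[0].end, rs[0].span()
        for r in rs[1:]:
            if (r.start + 1) - cur_end <= max_gap:
                cur_end = r.end
                cur_bases += r.span()
            else:
                clusters.append(CoverageCluster(contig, cur_start, cur_end, cur_bases))
                cur_start, cur_end, cur_bases = r.start + 1, r.end, r.span()
        clusters.append(CoverageCluster(contig, cur_start, cur_end, cur_bases))
    return _rank_variant_clusters(clusters)  # type: ignore[arg-type]


def coverage_scan(
    female_track: Sequence[CoverageInterval],
    male_track: Sequence[CoverageInterval],
    thr: CoverageThresholds = CoverageThresholds(),
) -> dict:
    """Full coverage stage: normalize, union, select, cluster, rank."""
    female_norm, female_mode = modal_normalize(female_track)
    male_norm, male_mode = modal_normalize(male_track)
    joint = union_tracks(female_norm, male_norm)
    runs = select_sex_specific_bases(joint, thr)
    clusters = cluster_selected_bases(runs, thr.max_gap)
    return {
        "female_modal_coverage": female_mode,
        "male_modal_coverage": male_mode,
        "selected_runs": runs,
        "clusters": clusters,
        "total_selected_bases": sum(r.span() for r in runs),
    }


def coverage_clusters_to_rows(clusters: Sequence[CoverageCluster]) -> list[dict]:
    return [
        {
            "rank": i,
            "contig": c.contig,
            "start": c.start,
            "end": c.end,
            "n_bases": c.n_bases,
            "span": c.span(),
        }
        for i, c in enumerate(clusters, start=1)
    ]
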