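"""Readers and writers for the text formats the pipeline touches.

Coordinate conventions, applied consistently throughout the package:

* VCF positions are 1-based; all internal SNP/cluster arithmetic stays on
  1-based point positions.
* BED and bedgraph are 0-based, half-open.  A 1-based point position ``p``
  becomes the BED interval ``[p-1, p)``; conversion happens only at the
  BED boundary, never inside the cluster math.

Variant depths follow the DP4 convention: strand-resolved reference and
alternate read counts ``(ref_fwd, ref_rev, alt_fwd, alt_rev)``.  Total
depth is the sum of the quadruple (not the caller's DP field), so all
allele-fraction filters see exactly the reads the caller counted per
allele.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import pysam

FEMALE = "female"
MALE = "male"

DP4 = tuple[int, int, int, int]


@dataclass(frozen=True)
class PoolVariant:
    """One biallelic variant site with per-pool strand-resolved depths.

    ``depths`` maps the canonical pool labels ``"female"``/``"male"`` to
    DP4 quadruples ``(ref_fwd, ref_rev, alt_fwd, alt_rev)``.
    """

    contig: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    variant_type: str  # SNP | MNP | INDEL
    depths: Mapping[str, DP4]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if set(self.depths) != {FEMALE, MALE}:
            raise ValueError(f"expected pools {{female, male}}, got {set(self.depths)}")
        for quad in self.depths.values():
            if len(quad) != 4 or any(d < 0 for d in quad):
                raise ValueError(f"invalid DP4 quadruple {quad}")

    def total_depth(self, pool: str) -> int:
        return sum(self.depths[pool])

    def alt_depth(self, pool: str) -> int:
        q = self.depths[pool]
        return q[2] + q[3]


@dataclass(frozen=True)
class GenomicInterval:
    """BED-semantics interval: 0-based start, exclusive end."""

    contig: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CoverageInterval:
    """Constant-coverage run, bedgraph semantics (0-based, half-open)."""

    contig: str
    start: int
    end: int
    value: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.value < 0:
            raise ValueError(f"coverage value must be >= 0, got {self.value}")

    def span(self) -> int:
        return self.end - self.start


def variant_type_of(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(ref) == len(alt):
        return "MNP"
    return "INDEL"


@dataclass
class VcfReadStats:
    """Per-file skip counters reported alongside the parsed variants."""

    records: int = 0
    kept: int = 0
    multiallelic: int = 0
    no_depth_annotation: int = 0


def _sample_dp4(sample) -> DP4 | None:
    """DP4 quadruple for one sample, falling back to an AD pair.

    Callers differ in how they expose per-sample allele depths: a
    strand-resolved DP4 quadruple, or an allelic-depth (ref, alt) pair.
    The AD fallback treats strands as pooled (all reads forward).
    """
    vals = None
    if "DP4" in sample and sample["DP4"] is not None:
        vals = sample["DP4"]
        if len(vals) == 4 and all(v is not None for v in vals):
            return tuple(int(v) for v in vals)  # type: ignore[return-value]
    if "AD" in sample and sample["AD"] is not None:
        ad = sample["AD"]
        if len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
            return (int(ad[0]), 0, int(ad[1]), 0)
    return None


def read_pool_vcf(
    path: str,
    female_label: str = FEMALE,
    male_label: str = MALE,
) -> tuple[list[PoolVariant], VcfReadStats]:
    """Read a two-pool VCF into :class:`PoolVariant` records.

    Multiallelic records and records lacking any per-sample depth
    annotation (DP4 or AD) are skipped and counted, never fatal; a
    missing sample name is fatal.
    """
    stats = VcfReadStats()
    out: list[PoolVariant] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for label in (female_label, male_label):
            if label not in samples:
                raise ValueError(
                    f"sample {label!r} not in VCF (has {samples})"
                )
        for rec in vcf:
            stats.records += 1
            if rec.alts is None or len(rec.alts) != 1:
                stats.multiallelic += 1
                continue
            fq = _sample_dp4(rec.samples[female_label])
            mq = _sample_dp4(rec.samples[male_label])
            if fq is None or mq is None:
                stats.no_depth_annotation += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            out.append(
                PoolVariant(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_type=variant_type_of(ref, alt),
                    depths={FEMALE: fq, MALE: mq},
                )
            )
            stats.kept += 1
    return out, stats


VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##source=poolsex
##FORMAT=<ID=DP4,Number=4,Type=Integer,Description="Strand-resolved ref/alt read counts: ref-fwd,ref-rev,alt-fwd,alt-rev">
"""


def write_pool_vcf(
    path: str,
    variants: Iterable[PoolVariant],
    contig_lengths: Mapping[str, int],
    female_label: str = FEMALE,
    male_label: str = MALE,
) -> None:
    """Write variants as a minimal two-sample VCF with FORMAT/DP4."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER_TEMPLATE)
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{female_label}\t{male_label}\n"
        )
        for v in variants:
            f4 = ",".join(str(d) for d in v.depths[FEMALE])
            m4 = ",".join(str(d) for d in v.depths[MALE])
            fh.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tDP4\t{f4}\t{m4}\n"
            )


def _open_text(path_or_stream) -> TextIO:
    if hasattr(path_or_stream, "read"):
        return path_or_stream
    if str(path_or_stream).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path_or_stream, "rb"))
    return open(path_or_stream)


def read_bedgraph(path_or_stream) -> list[CoverageInterval]:
    """Parse a 4-column bedgraph into sorted, non-overlapping intervals.

    Track lines and ``#`` comments are tolerated; out-of-order lines are
    re-sorted; overlapping intervals or negative values are fatal (the
    track is malformed).  Gaps represent coverage 0.
    """
    intervals: list[CoverageInterval] = []
    fh = _open_text(path_or_stream)
    try:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"malformed bedgraph line: {line!r}")
            contig, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if value < 0:
                raise ValueError(f"negative coverage at {contig}:{start}-{end}")
            intervals.append(CoverageInterval(contig, start, end, value))
    finally:
        if not hasattr(path_or_stream, "read"):
            fh.close()
    intervals.sort(key=lambda iv: (iv.contig, iv.start, iv.end))
    prev: CoverageInterval | None = None
    for iv in intervals:
        if prev is not None and iv.contig == prev.contig and iv.start < prev.end:
            raise ValueError(
                f"overlapping bedgraph intervals on {iv.contig}: "
                f"[{prev.start},{prev.end}) and [{iv.start},{iv.end})"
            )
        prev = iv
    return intervals


def write_bedgraph(
    path: str,
    track: Sequence[CoverageInterval],
    merge_adjacent: bool = True,
    omit_zero: bool = True,
) -> None:
    """Write a coverage track as 4-column bedgraph.

    Adjacent intervals with identical value are merged so that re-reading
    yields a normalized (minimal) representation; zero-valued intervals
    are omitted by default since bedgraph gaps mean zero.
    """
    track = sorted(track, key=lambda iv: (iv.contig, iv.start))
    with open(path, "w") as fh:
        pending: CoverageInterval | None = None
        for iv in track:
            if omit_zero and iv.value == 0:
                continue
            if (
                merge_adjacent
                and pending is not None
                and pending.contig == iv.contig
                and pending.end == iv.start
                and pending.value == iv.value
            ):
                pending = CoverageInterval(pending.contig, pending.start, iv.end, iv.value)
                continue
            if pending is not None:
                fh.write(_bedgraph_line(pending))
            pending = iv
        if pending is not None:
            fh.write(_bedgraph_line(pending))


def _bedgraph_line(iv: CoverageInterval) -> str:
    v = iv.value
    vs = str(int(v)) if float(v).is_integer() else f"{v:.6g}"
    return f"{iv.contig}\t{iv.start}\t{iv.end}\t{vs}\n"


def track_mass(track: Sequence[CoverageInterval]) -> float:
    """Total coverage mass, sum(value * span) — preserved by read/write."""
    return sum(iv.value * iv.span() for iv in track)


def write_cluster_bed(path: str, clusters, header_comment: str | None = None) -> None:
    """Write clusters as BED4+ (name = cluster_i, score = member count).

    Cluster intervals are held internally as 1-based inclusive bounds;
    the BED conversion is start-1 / end unchanged (half-open).  Output is
    ordered by (contig, start) deterministically.
    """
    rows = sorted(clusters, key=lambda c: (c.contig, c.start, c.end))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        for i, c in enumerate(rows, start=1):
            count = getattr(c, "n_variants", getattr(c, "n_bases", 0))
            fh.write(f"{c.contig}\t{c.start - 1}\t{c.end}\tcluster_{i}\t{count}\n")


def read_truth_bed(path: str) -> list[GenomicInterval]:
    """Read a BED4+ file of truth/cluster intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else None
            score = float(f[4]) if len(f) > 4 else None
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name=name, score=score))
    return out
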