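"""Synthetic two-pool sequencing data with a planted sex-linked region.

The generator emulates the statistical structure the downstream scans
assume, with a known, exported truth:

* two pools of ``n_per_pool`` diploid individuals per sex (default
  22 + 22), sequenced to Poisson depth (default mean 40);
* background population SNPs at a per-bp rate, with population allele
  frequencies drawn uniformly and pool allele counts binomially sampled
  from 2n chromosomes per pool;
* one fully sex-linked block (default 66 kb carrying 100 fixed
  X/Y-divergent sites): under male heterogamety every male is
  X/Y-heterozygous (pool alt fraction exactly 0.5 before error) and
  every female homozygous; the ZW system mirrors the sexes;
* a Y-specific insertion (default 55 kb, on its own contig) covered at
  half the diploid rate in the male pool and at a small spurious
  fraction (default 1%) in the female pool;
* per-base miscalls folded into the read-draw probability:
  reads are alt with probability q(1-e) + (1-q)e.

Coverage is modelled per base as Poisson and emitted in constant-size
bins (default 100 bp) carrying the bin-averaged value, which keeps
bedgraphs small; the coverage scan operates identically on binned
tracks.

Randomness comes from a single ``numpy.random.default_rng`` (PCG64)
stream consumed in a fixed order, so one seed gives byte-identical
outputs across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    FEMALE,
    MALE,
    CoverageInterval,
    GenomicInterval,
    PoolVariant,
    write_bedgraph,
    write_pool_vcf,
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the pool-seq simulation."""

    genome: tuple[tuple[str, int], ...] = (("sim1", 10_000_000),)
    n_per_pool: int = 22
    depth_mean: float = 40.0
    error_rate: float = 0.002
    background_snp_rate: float = 0.002
    maf_low: float = 0.05
    maf_high: float = 0.5
    system: str = "XY"
    sdr_start: int = 5_000_000  # 0-based, on genome[0]
    sdr_length: int = 66_000
    n_divergent_sites: int = 100
    y_contig: str = "simY"
    y_insertion_length: int = 55_000
    spurious_female_fraction: float = 0.01
    coverage_bin: int = 100

    def __post_init__(self) -> None:
        if not self.genome:
            raise ValueError("genome: need at least one contig")
        if self.system not in ("XY", "ZW"):
            raise ValueError(f"system: must be XY or ZW, got {self.system!r}")
        for name, rate in (
            ("error_rate", self.error_rate),
            ("background_snp_rate", self.background_snp_rate),
            ("spurious_female_fraction", self.spurious_female_fraction),
        ):
            if not (0 <= rate <= 1):
                raise ValueError(f"{name}: must be in [0,1], got {rate}")
        if not (0 <= self.maf_low <= self.maf_high <= 1):
            raise ValueError("maf_low/maf_high: require 0 <= low <= high <= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean: must be > 0")
        if self.n_per_pool < 1:
            raise ValueError("n_per_pool: must be >= 1")
        if self.coverage_bin < 1:
            raise ValueError("coverage_bin: must be >= 1")
        contig_len = dict(self.genome)[self.sdr_contig]
        if not (0 <= self.sdr_start and self.sdr_start + self.sdr_length <= contig_len):
            raise ValueError("sdr_start/sdr_length: interval outside genome")

    @property
    def sdr_contig(self) -> str:
        return self.genome[0][0]

    @property
    def sdr_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.sdr_contig, self.sdr_start, self.sdr_start + self.sdr_length, name="sdr"
        )

    @property
    def y_insertion_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.y_contig, 0, self.y_insertion_length, name="y_insertion"
        )


@dataclass(frozen=True)
class SimTruth:
    """Planted features, written alongside the outputs for acceptance."""

    sdr: GenomicInterval
    divergent_positions: tuple[int, ...]  # 1-based, on sdr contig
    y_insertion: GenomicInterval
    background_positions: dict[str, tuple[int, ...]]  # 1-based per contig
    background_frequencies: dict[str, tuple[float, ...]]


@dataclass
class SimResult:
    config: SimConfig
    seed: int
    variants: list[PoolVariant]
    female_track: list[CoverageInterval]
    male_track: list[CoverageInterval]
    truth: SimTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write VCF, both bedgraphs, truth BED/TSV and a config echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        contig_lengths = dict(self.config.genome)
        contig_lengths[self.config.y_contig] = self.config.y_insertion_length
        paths = {
            "vcf": outdir / "pools.vcf",
            "female_bedgraph": outdir / "female.bedgraph",
            "male_bedgraph": outdir / "male.bedgraph",
            "truth_bed": outdir / "truth.bed",
            "truth_tsv": outdir / "truth_sites.tsv",
            "config": outdir / "sim_config.json",
        }
        write_pool_vcf(paths["vcf"], self.variants, contig_lengths)
        write_bedgraph(paths["female_bedgraph"], self.female_track)
        write_bedgraph(paths["male_bedgraph"], self.male_track)
        t = self.truth
        with open(paths["truth_bed"], "w") as fh:
            fh.write(f"{t.sdr.contig}\t{t.sdr.start}\t{t.sdr.end}\tsdr\t.\n")
            fh.write(
                f"{t.y_insertion.contig}\t{t.y_insertion.start}\t"
                f"{t.y_insertion.end}\ty_insertion\t.\n"
            )
        with open(paths["truth_tsv"], "w") as fh:
            fh.write("contig\tpos\tkind\tpopulation_alt_freq\n")
            for pos in t.divergent_positions:
                fh.write(f"{t.sdr.contig}\t{pos}\tdivergent\t.\n")
            for contig in sorted(t.background_positions):
                for pos, freq in zip(
                    t.background_positions[contig], t.background_frequencies[contig]
                ):
                    fh.write(f"{contig}\t{pos}\tbackground\t{freq:.6f}\n")
        echo = asdict(self.config)
        echo["genome"] = [list(c) for c in self.config.genome]
        echo["seed"] = self.seed
        with open(paths["config"], "w") as fh:
            json.dump(echo, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return BASES[ref_idx], BASES[alt_idx]


def _site_depths(
    rng: np.random.Generator,
    q: np.ndarray,
    depth_mean: float,
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site DP4 columns for one pool at pool alt frequency q."""
    depth = rng.poisson(depth_mean, size=q.shape)
    p_alt = q * (1 - error_rate) + (1 - q) * error_rate
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    ref_fwd = rng.binomial(ref, 0.5)
    alt_fwd = rng.binomial(alt, 0.5)
    return ref_fwd, ref - ref_fwd, alt_fwd, alt - alt_fwd


def simulate(cfg: SimConfig, seed: int) -> SimResult:
    """Generate pool variants, coverage tracks and the planted truth."""
    rng = np.random.default_rng(seed)
    n_chrom = 2 * cfg.n_per_pool

    variants: list[PoolVariant] = []
    bg_positions: dict[str, tuple[int, ...]] = {}
    bg_freqs: dict[str, tuple[float, ...]] = {}

    # --- background SNPs, contig by contig ---
    for contig, length in cfg.genome:
        n_sites = rng.binomial(length, cfg.background_snp_rate)
        positions = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=n_sites)
        refs, alts = _random_alleles(rng, n_sites)
        qf = rng.binomial(n_chrom, freqs) / n_chrom
        qm = rng.binomial(n_chrom, freqs) / n_chrom
        f_dp4 = _site_depths(rng, qf, cfg.depth_mean, cfg.error_rate)
        m_dp4 = _site_depths(rng, qm, cfg.depth_mean, cfg.error_rate)
        bg_positions[contig] = tuple(int(p) for p in positions)
        bg_freqs[contig] = tuple(float(f) for f in freqs)
        variants.extend(
            _assemble_variants(contig, positions, refs, alts, f_dp4, m_dp4)
        )

    # --- planted divergent sites inside the sex-linked block ---
    sdr = cfg.sdr_interval
    div_positions = (
        np.sort(
            rng.choice(cfg.sdr_length, size=cfg.n_divergent_sites, replace=False)
        )
        + sdr.start
        + 1
    )
    refs, alts = _random_alleles(rng, cfg.n_divergent_sites)
    half = np.full(cfg.n_divergent_sites, 0.5)
    zero = np.zeros(cfg.n_divergent_sites)
    q_het, q_hom = (half, zero)
    qm, qf = (q_het, q_hom) if cfg.system == "XY" else (q_hom, q_het)
    f_dp4 = _site_depths(rng, qf, cfg.depth_mean, cfg.error_rate)
    m_dp4 = _site_depths(rng, qm, cfg.depth_mean, cfg.error_rate)
    variants.extend(
        _assemble_variants(sdr.contig, div_positions, refs, alts, f_dp4, m_dp4)
    )

    variants.sort(key=lambda v: (v.contig, v.pos))

    # --- coverage tracks: diploid genome + hemizygous Y insertion ---
    female_track: list[CoverageInterval] = []
    male_track: list[CoverageInterval] = []
    for contig, length in cfg.genome:
        female_track.extend(_binned_coverage(rng, contig, length, cfg.depth_mean, cfg.coverage_bin))
        male_track.extend(_binned_coverage(rng, contig, length, cfg.depth_mean, cfg.coverage_bin))
    female_track.extend(
        _binned_coverage(
            rng,
            cfg.y_contig,
            cfg.y_insertion_length,
            cfg.depth_mean * cfg.spurious_female_fraction,
            cfg.coverage_bin,
        )
    )
    male_track.extend(
        _binned_coverage(
            rng, cfg.y_contig, cfg.y_insertion_length, cfg.depth_mean / 2, cfg.coverage_bin
        )
    )

    truth = SimTruth(
        sdr=sdr,
        divergent_positions=tuple(int(p) for p in div_positions),
        y_insertion=cfg.y_insertion_interval,
        background_positions=bg_positions,
        background_frequencies=bg_freqs,
    )
    return SimResult(
        config=cfg,
        seed=seed,
        variants=variants,
        female_track=female_track,
        male_track=male_track,
        truth=truth,
    )


def _assemble_variants(contig, positions, refs, alts, f_dp4, m_dp4) -> list[PoolVariant]:
    out = []
    for i, pos in enumerate(positions):
        fq = tuple(int(col[i]) for col in f_dp4)
        mq = tuple(int(col[i]) for col in m_dp4)
        if fq[2] + fq[3] + mq[2] + mq[3] == 0:
            continue  # no alt reads anywhere: a caller would not emit it
        out.append(
            PoolVariant(
                contig=contig,
                pos=int(pos),
                ref_allele=str(refs[i]),
                alt_allele=str(alts[i]),
                variant_type="SNP",
                depths={FEMALE: fq, MALE: mq},
            )
        )
    return out


def _binned_coverage(
    rng: np.random.Generator,
    contig: str,
    length: int,
    mean_depth: float,
    bin_size: int,
) -> list[CoverageInterval]:
    """Per-base Poisson coverage emitted as bin-averaged values.

    Each base's depth is Poisson(mean_depth); a bin's emitted value is
    the average over its bases, drawn as Poisson(mean * width) / width.
    """
    n_bins = -(-length // bin_size)
    widths = np.full(n_bins, bin_size)
    if length % bin_size:
        widths[-1] = length % bin_size
    totals = rng.poisson(mean_depth * widths)
    out = []
    for i, (total, width) in enumerate(zip(totals, widths)):
        if total > 0:
            start = i * bin_size
            out.append(
                CoverageInterval(contig, start, start + int(width), float(total) / width)
            )
    return out


# ---------------------------------------------------------------------------
# cross-species amplicon panel generator
# ---------------------------------------------------------------------------

#: (males, females) per species, emulating a multi-taxon amplicon panel.
DEFAULT_PANEL_SEXES = ((4, 3), (5, 4), (5, 3), (4, 5), (4, 5))


@dataclass(frozen=True)
class PanelConfig:
    """Synthetic amplicon panel: shared sex-linked block + private SNPs.

    The target region mimics an enriched candidate locus: an anciently
    sex-linked 5' block whose X/Y-divergent sites are male-specific in
    every species, plus species-private male-specific sites elsewhere in
    the region (lineage-specific divergence, e.g. in coding sequence).
    """

    contig: str = "amp1"
    region_length: int = 80_000
    shared_block: tuple[int, int] = (0, 5_000)  # 0-based half-open
    n_shared_sites: int = 30
    n_private_sites_per_species: int = 10
    species_sexes: tuple[tuple[int, int], ...] = DEFAULT_PANEL_SEXES
    depth_mean: float = 800.0
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        lo, hi = self.shared_block
        if not (0 <= lo < hi <= self.region_length):
            raise ValueError("shared_block: interval outside region")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean: must be > 0")

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(f"species_{i + 1}" for i in range(len(self.species_sexes)))


@dataclass(frozen=True)
class PanelTruth:
    shared_sites: frozenset[tuple[str, int]]
    private_sites: dict[tuple[str, int], str]  # site -> owning species
    shared_block: GenomicInterval


def make_amplicon_panel(cfg: PanelConfig, seed: int):
    """Per-sample amplicon read counts with truth labels.

    Returns ``(panels, truth)`` where ``panels`` maps species name to a
    :class:`poolsex.amplicon.SpeciesPanel`.  Shared-block sites are
    male-specific (every male heterozygous, every female homozygous
    reference) in all species; private sites only in their owner, and
    monomorphic reference in all other species.
    """
    from .amplicon import SampleCall, SpeciesPanel

    rng = np.random.default_rng(seed)
    lo, hi = cfg.shared_block
    n_private_total = cfg.n_private_sites_per_species * len(cfg.species_sexes)

    shared_pos = np.sort(rng.choice(hi - lo, size=cfg.n_shared_sites, replace=False)) + lo + 1
    private_pos = (
        np.sort(rng.choice(cfg.region_length - hi, size=n_private_total, replace=False)) + hi + 1
    )
    owners = [
        cfg.species_names[i // cfg.n_private_sites_per_species]
        for i in range(n_private_total)
    ]
    rng.shuffle(owners)

    shared_sites = frozenset((cfg.contig, int(p)) for p in shared_pos)
    private_sites = {
        (cfg.contig, int(p)): owner for p, owner in zip(private_pos, owners)
    }
    all_sites = sorted(shared_sites | set(private_sites))

    panels: dict[str, SpeciesPanel] = {}
    for species, (n_m, n_f) in zip(cfg.species_names, cfg.species_sexes):
        panel = SpeciesPanel(species)
        sample_ids = [f"{species}_M{i + 1}" for i in range(n_m)] + [
            f"{species}_F{i + 1}" for i in range(n_f)
        ]
        sexes = ["M"] * n_m + ["F"] * n_f
        for sample, sex in zip(sample_ids, sexes):
            for site in all_sites:
                male_specific_here = site in shared_sites or (
                    private_sites.get(site) == species
                )
                q = 0.5 if (male_specific_here and sex == "M") else 0.0
                depth = int(rng.poisson(cfg.depth_mean))
                p_alt = q * (1 - cfg.error_rate) + (1 - q) * cfg.error_rate
                alt = int(rng.binomial(depth, p_alt))
                panel.calls.append(
                    SampleCall(
                        sample=sample,
                        species=species,
                        sex=sex,
                        site=site,
                        ref_count=depth - alt,
                        alt_count=alt,
                    )
                )
        panels[species] = panel

    truth = PanelTruth(
        shared_sites=shared_sites,
        private_sites=private_sites,
        shared_block=GenomicInterval(cfg.contig, lo, hi, name="shared_block"),
    )
    return panels, truth
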