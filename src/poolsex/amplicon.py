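"""Cross-species sex-diagnostic SNP discovery from deep amplicon data.

Per-individual genotypes are called from allele fractions with the same
window logic as the pool screen (deep amplicon coverage makes the
fraction a precise genotype estimate; the default minimum depth is
raised to 30).  Per species, a site is male-specific when every
informative male is heterozygous and every informative female
homozygous; male-specific sites are then intersected across species and
stratified by the number of supporting species, k.  A sex-determining
region inherited from a common ancestor shows up as k = n_species
sharing confined to the anciently sex-linked block, while
species-private divergence never reaches high k.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .snp_screen import HOMOZYGOUS, GenotypeClass, ScreenConfig, classify_fraction

Site = tuple[str, int]  # (contig, 1-based pos) on the shared reference

#: Pool thresholds reused per individual, with depth floor raised for
#: deep amplicon sequencing.
AMPLICON_SCREEN = ScreenConfig(min_depth=30)


def call_sample_genotype(
    fraction: float,
    depth: int,
    cfg: ScreenConfig = AMPLICON_SCREEN,
) -> GenotypeClass:
    """Per-individual genotype from an alt-allele fraction and depth."""
    if not (0 <= fraction <= 1):
        raise ValueError(f"fraction must be in [0,1], got {fraction}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    return classify_fraction(fraction, depth, cfg)


@dataclass(frozen=True)
class SampleCall:
    """One individual's observation at one site."""

    sample: str
    species: str
    sex: str  # F | M
    site: Site
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be >= 0")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def fraction(self) -> float:
        return self.alt_count / self.depth if self.depth > 0 else 0.0

    def genotype(self, cfg: ScreenConfig = AMPLICON_SCREEN) -> GenotypeClass:
        return call_sample_genotype(self.fraction, self.depth, cfg)


@dataclass
class SpeciesPanel:
    """Sexed amplicon samples of one species over a shared site set."""

    species: str
    calls: list[SampleCall] = field(default_factory=list)

    def sites(self) -> set[Site]:
        return {c.site for c in self.calls}

    def sexes(self) -> set[str]:
        return {c.sex for c in self.calls}


@dataclass
class SpeciesScreenStats:
    sites_tested: int = 0
    retained: int = 0
    uninformative: int = 0  # no informative sample in one sex


def species_male_specific_snps(
    panel: SpeciesPanel,
    cfg: ScreenConfig = AMPLICON_SCREEN,
    max_discordant: int = 0,
) -> tuple[set[Site], SpeciesScreenStats]:
    """Sites heterozygous in this species' males, homozygous in its females.

    LOW_DEPTH samples are excluded from the quorum (uneven enrichment
    coverage should not veto a site); at least one informative sample per
    sex is required, else the site is excluded and counted.  Strict mode
    (``max_discordant=0``) demands every informative male HET and every
    informative female homozygous; tolerance mode allows up to
    ``max_discordant`` discordant samples per sex.
    """
    if not {"F", "M"} <= panel.sexes():
        raise ValueError(f"panel {panel.species!r} needs >= 1 male and >= 1 female")
    by_site: dict[Site, list[SampleCall]] = defaultdict(list)
    for c in panel.calls:
        by_site[c.site].append(c)

    stats = SpeciesScreenStats()
    retained: set[Site] = set()
    for site, calls in by_site.items():
        stats.sites_tested += 1
        males = [c.genotype(cfg) for c in calls if c.sex == "M"]
        females = [c.genotype(cfg) for c in calls if c.sex == "F"]
        males = [g for g in males if g is not GenotypeClass.LOW_DEPTH]
        females = [g for g in females if g is not GenotypeClass.LOW_DEPTH]
        if not males or not females:
            stats.uninformative += 1
            continue
        male_bad = sum(g is not GenotypeClass.HET for g in males)
        female_bad = sum(g not in HOMOZYGOUS for g in females)
        if male_bad <= max_discordant and female_bad <= max_discordant:
            retained.add(site)
            stats.retained += 1
    return retained, stats


@dataclass
class SharedSnpReport:
    """Per-site species support and sharing level k."""

    species_by_site: dict[Site, frozenset[str]]
    min_species: int

    def sharing_level(self, site: Site) -> int:
        return len(self.species_by_site.get(site, frozenset()))

    def sites_at_least(self, k: int) -> set[Site]:
        return {s for s, sp in self.species_by_site.items() if len(sp) >= k}

    @property
    def retained(self) -> set[Site]:
        return self.sites_at_least(self.min_species)

    def stratified_counts(self) -> dict[int, int]:
        """Number of sites at each exact sharing level k."""
        return dict(Counter(len(sp) for sp in self.species_by_site.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contig": site[0],
                "pos": site[1],
                "n_species": len(sp),
                "species": ",".join(sorted(sp)),
            }
            for site, sp in sorted(self.species_by_site.items())
        ]
        return pd.DataFrame(rows, columns=["contig", "pos", "n_species", "species"])


def intersect_across_species(
    sets_by_species: Mapping[str, set[Site]],
    min_species: int = 2,
) -> SharedSnpReport:
    """Count supporting species per male-specific site; filter at >= k."""
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    species_by_site: dict[Site, set[str]] = defaultdict(set)
    for species, sites in sets_by_species.items():
        for site in sites:
            species_by_site[site].add(species)
    return SharedSnpReport(
        species_by_site={s: frozenset(sp) for s, sp in species_by_site.items()},
        min_species=min_species,
    )


LONG_TSV_COLUMNS = ["sample", "species", "sex", "contig", "pos", "ref_count", "alt_count"]


def read_call_table(path) -> dict[str, SpeciesPanel]:
    """Read the long-format per-sample TSV into per-species panels."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(LONG_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    panels: dict[str, SpeciesPanel] = {}
    for row in df.itertuples(index=False):
        call = SampleCall(
            sample=str(row.sample),
            species=str(row.species),
            sex=str(row.sex),
            site=(str(row.contig), int(row.pos)),
            ref_count=int(row.ref_count),
            alt_count=int(row.alt_count),
        )
        panels.setdefault(call.species, SpeciesPanel(call.species)).calls.append(call)
    return panels


def write_call_table(path, panels: Iterable[SpeciesPanel]) -> None:
    rows = [
        {
            "sample": c.sample,
            "species": c.species,
            "sex": c.sex,
            "contig": c.site[0],
            "pos": c.site[1],
            "ref_count": c.ref_count,
            "alt_count": c.alt_count,
        }
        for p in panels
        for c in p.calls
    ]
    pd.DataFrame(rows, columns=LONG_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
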