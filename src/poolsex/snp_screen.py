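"""Allele-balance genotype classification and the sex-linked SNP screen.

In a pool of n diploid individuals of one sex, a fully sex-linked variant
in the heterogametic sex (every male X/Y-heterozygous under male
heterogamety) sits at alt-read fraction ~0.5, while the homogametic pool
is homozygous (fraction ~0 or ~1 up to sequencing error).  The screen
classifies each pool's genotype from its alt-read fraction and keeps
variants showing exactly that pattern.

Default thresholds: both pools' DP4 depth >= 15; homozygosity = alt
fraction <= 7% or >= 93%; heterozygosity = alt fraction in 45-55%.  All
bounds are inclusive.  ZW mode interchanges the conditions for males and
females.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import DP4, FEMALE, MALE, PoolVariant


class GenotypeClass(enum.Enum):
    HOM_REF = "HOM_REF"
    HOM_ALT = "HOM_ALT"
    HET = "HET"
    LOW_DEPTH = "LOW_DEPTH"
    AMBIGUOUS = "AMBIGUOUS"


HOMOZYGOUS = frozenset({GenotypeClass.HOM_REF, GenotypeClass.HOM_ALT})


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the heterozygosity screen.

    mode
        ``"XY"`` keeps male-HET / female-homozygous variants, ``"ZW"``
        the interchanged pattern.
    min_depth
        minimum DP4 depth required in *both* pools (reads).
    hom_max_frac
        homozygosity window: alt fraction <= this, or >= 1 - this.
    het_low, het_high
        inclusive heterozygosity window on the alt fraction.
    """

    mode: str = "XY"
    min_depth: int = 15
    hom_max_frac: float = 0.07
    het_low: float = 0.45
    het_high: float = 0.55

    def __post_init__(self) -> None:
        if self.mode not in ("XY", "ZW"):
            raise ValueError(f"mode must be XY or ZW, got {self.mode!r}")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0 < self.hom_max_frac < self.het_low <= self.het_high < 1 - self.hom_max_frac):
            raise ValueError(
                "require 0 < hom_max_frac < het_low <= het_high < 1 - hom_max_frac"
            )


def classify_fraction(alt_fraction: float, total_depth: int, cfg: ScreenConfig) -> GenotypeClass:
    """Window logic shared by the pool screen and per-individual calls."""
    if total_depth < cfg.min_depth:
        return GenotypeClass.LOW_DEPTH
    f = alt_fraction
    if f <= cfg.hom_max_frac:
        return GenotypeClass.HOM_REF
    if f >= 1 - cfg.hom_max_frac:
        return GenotypeClass.HOM_ALT
    if cfg.het_low <= f <= cfg.het_high:
        return GenotypeClass.HET
    return GenotypeClass.AMBIGUOUS


def classify_pool_genotype(depths: DP4, cfg: ScreenConfig) -> GenotypeClass:
    """Classify one pool's genotype from its DP4 quadruple."""
    total = sum(depths)
    if total < cfg.min_depth:
        return GenotypeClass.LOW_DEPTH
    alt = depths[2] + depths[3]
    return classify_fraction(alt / total, total, cfg)


@dataclass(frozen=True)
class CandidateVariant:
    """A retained variant together with both pools' calls and fractions."""

    variant: PoolVariant
    female_class: GenotypeClass
    male_class: GenotypeClass
    female_fraction: float
    male_fraction: float


def _fraction(v: PoolVariant, pool: str) -> float:
    total = v.total_depth(pool)
    return v.alt_depth(pool) / total if total > 0 else 0.0


def screen_variants(
    variants: Iterable[PoolVariant],
    cfg: ScreenConfig,
) -> tuple[list[CandidateVariant], Counter]:
    """Retain variants whose two-pool pattern matches the chosen system.

    XY mode: male HET and female homozygous (HOM_REF or HOM_ALT — the
    reference base may itself be the Y allele).  ZW mode: interchanged.
    Everything else, including LOW_DEPTH or AMBIGUOUS in either pool, is
    dropped; drop reasons are tallied by the (female, male) class pair.
    """
    het_pool, hom_pool = (MALE, FEMALE) if cfg.mode == "XY" else (FEMALE, MALE)
    kept: list[CandidateVariant] = []
    drops: Counter = Counter()
    for v in variants:
        classes = {
            pool: classify_pool_genotype(v.depths[pool], cfg) for pool in (FEMALE, MALE)
        }
        if classes[het_pool] is GenotypeClass.HET and classes[hom_pool] in HOMOZYGOUS:
            kept.append(
                CandidateVariant(
                    variant=v,
                    female_class=classes[FEMALE],
                    male_class=classes[MALE],
                    female_fraction=_fraction(v, FEMALE),
                    male_fraction=_fraction(v, MALE),
                )
            )
        else:
            drops[(classes[FEMALE].value, classes[MALE].value)] += 1
    return kept, drops


def candidates_to_rows(candidates: Sequence[CandidateVariant]) -> list[dict]:
    """Flatten candidates for the TSV report."""
    return [
        {
            "contig": c.variant.contig,
            "pos": c.variant.pos,
            "type": c.variant.variant_type,
            "female_fraction": round(c.female_fraction, 4),
            "male_fraction": round(c.male_fraction, 4),
            "female_class": c.female_class.value,
            "male_class": c.male_class.value,
        }
        for c in candidates
    ]
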