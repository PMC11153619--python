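"""Per-individual amplicon genotyping and cross-species SNP intersection."""

import numpy as np
import pytest

from poolsex.amplicon import (
    AMPLICON_SCREEN,
    SampleCall,
    SpeciesPanel,
    call_sample_genotype,
    intersect_across_species,
    read_call_table,
    species_male_specific_snps,
    write_call_table,
)
from poolsex.simulate import PanelConfig, make_amplicon_panel
from poolsex.snp_screen import GenotypeClass, ScreenConfig, classify_fraction


@pytest.mark.parametrize(
    "fraction, depth, expected",
    [
        (0.50, 800, GenotypeClass.HET),
        (0.02, 800, GenotypeClass.HOM_REF),
        (0.98, 800, GenotypeClass.HOM_ALT),
        (0.30, 800, GenotypeClass.AMBIGUOUS),
        (0.50, 10, GenotypeClass.LOW_DEPTH),  # amplicon depth floor is 30
    ],
)
def test_individual_calls(fraction, depth, expected):
    assert call_sample_genotype(fraction, depth) is expected


def test_individual_calls_share_the_pool_classifier():
    """Same window logic as the pool screen across a (fraction, depth) grid."""
    for f in np.linspace(0, 1, 101):
        for depth in (0, 29, 30, 100, 1000):
            assert call_sample_genotype(float(f), depth) is classify_fraction(
                float(f), depth, AMPLICON_SCREEN
            )


def test_invalid_fraction_rejected():
    with pytest.raises(ValueError):
        call_sample_genotype(1.5, 100)


def make_panel(species, male_fractions, female_fractions, site=("amp1", 500), depth=800):
    panel = SpeciesPanel(species)
    for i, f in enumerate(male_fractions):
        alt = int(round(f * depth))
        panel.calls.append(SampleCall(f"{species}_M{i}", species, "M", site, depth - alt, alt))
    for i, f in enumerate(female_fractions):
        alt = int(round(f * depth))
        panel.calls.append(SampleCall(f"{species}_F{i}", species, "F", site, depth - alt, alt))
    return panel


class TestSpeciesScreen:
    def test_all_males_het_all_females_hom_retained(self):
        panel = make_panel("sp", [0.5] * 4, [0.01] * 5)
        sites, stats = species_male_specific_snps(panel)
        assert sites == {("amp1", 500)}
        assert stats.retained == 1

    def test_one_discordant_male_drops_in_strict_mode(self):
        panel = make_panel("sp", [0.5, 0.5, 0.5, 0.01], [0.01] * 5)
        sites, _ = species_male_specific_snps(panel)
        assert sites == set()

    def test_tolerance_mode_allows_discordance(self):
        panel = make_panel("sp", [0.5, 0.5, 0.5, 0.01], [0.01] * 5)
        sites, _ = species_male_specific_snps(panel, max_discordant=1)
        assert sites == {("amp1", 500)}

    def test_strict_subset_of_tolerant(self):
        rng = np.random.default_rng(55)
        panel = SpeciesPanel("sp")
        for pos in range(1, 60):
            for i in range(4):
                alt = int(rng.integers(0, 800))
                panel.calls.append(SampleCall(f"M{i}", "sp", "M", ("a", pos), 800 - alt, alt))
            for i in range(3):
                alt = int(rng.integers(0, 800))
                panel.calls.append(SampleCall(f"F{i}", "sp", "F", ("a", pos), 800 - alt, alt))
        strict, _ = species_male_specific_snps(panel, max_discordant=0)
        loose, _ = species_male_specific_snps(panel, max_discordant=2)
        assert strict <= loose

    def test_low_depth_excluded_from_quorum_not_fatal(self):
        panel = make_panel("sp", [0.5, 0.5], [0.01])
        panel.calls.append(SampleCall("sp_M9", "sp", "M", ("amp1", 500), 5, 5))  # depth 10
        sites, _ = species_male_specific_snps(panel)
        assert sites == {("amp1", 500)}

    def test_site_with_no_informative_sex_excluded_and_counted(self):
        panel = make_panel("sp", [0.5], [0.01])
        panel.calls.append(SampleCall("sp_M1b", "sp", "M", ("amp1", 900), 10, 10))
        panel.calls.append(SampleCall("sp_F1b", "sp", "F", ("amp1", 900), 5, 0))
        sites, stats = species_male_specific_snps(panel)
        assert ("amp1", 900) not in sites
        assert stats.uninformative == 1

    def test_panel_without_both_sexes_is_fatal(self):
        panel = SpeciesPanel("sp")
        panel.calls.append(SampleCall("m", "sp", "M", ("a", 1), 400, 400))
        with pytest.raises(ValueError, match="male and"):
            species_male_specific_snps(panel)

    def test_matches_per_site_rule_enumeration(self):
        """Random panels against a literal per-site restatement of the rule."""
        rng = np.random.default_rng(77)
        cfg = ScreenConfig(min_depth=30)
        panel = SpeciesPanel("sp")
        for pos in range(1, 200):
            for i in range(5):
                depth = int(rng.integers(0, 200))
                alt = int(rng.integers(0, depth + 1))
                panel.calls.append(SampleCall(f"M{i}", "sp", "M", ("a", pos), depth - alt, alt))
            for i in range(4):
                depth = int(rng.integers(0, 200))
                alt = int(rng.integers(0, depth + 1))
                panel.calls.append(SampleCall(f"F{i}", "sp", "F", ("a", pos), depth - alt, alt))
        got, _ = species_male_specific_snps(panel, cfg)
        expected = set()
        by_site = {}
        for c in panel.calls:
            by_site.setdefault(c.site, []).append(c)
        for site, calls in by_site.items():
            males = [c.genotype(cfg) for c in calls if c.sex == "M"]
            females = [c.genotype(cfg) for c in calls if c.sex == "F"]
            males = [g for g in males if g != GenotypeClass.LOW_DEPTH]
            females = [g for g in females if g != GenotypeClass.LOW_DEPTH]
            if (
                males
                and females
                and all(g == GenotypeClass.HET for g in males)
                and all(g in (GenotypeClass.HOM_REF, GenotypeClass.HOM_ALT) for g in females)
            ):
                expected.add(site)
        assert got == expected


class TestIntersection:
    def test_three_species_example(self):
        sets = {"A": {("c", 1), ("c", 2)}, "B": {("c", 2), ("c", 3)}, "C": {("c", 2)}}
        report = intersect_across_species(sets, min_species=3)
        assert report.retained == {("c", 2)}
        assert report.sharing_level(("c", 2)) == 3

    def test_min_species_one_is_union(self):
        sets = {"A": {("c", 1)}, "B": {("c", 2)}}
        assert intersect_across_species(sets, 1).retained == {("c", 1), ("c", 2)}

    def test_disjoint_sets_empty_at_two(self):
        sets = {"A": {("c", 1)}, "B": {("c", 2)}}
        assert intersect_across_species(sets, 2).retained == set()

    def test_anti_monotonicity_in_min_species(self):
        rng = np.random.default_rng(4)
        sets = {
            f"sp{i}": {("c", int(p)) for p in rng.choice(100, size=30, replace=False)}
            for i in range(5)
        }
        report = intersect_across_species(sets, 1)
        for k in range(1, 6):
            assert report.sites_at_least(k + 1) <= report.sites_at_least(k)

    def test_stratified_counts_sum_to_union(self):
        sets = {"A": {("c", 1), ("c", 2)}, "B": {("c", 2)}}
        strata = intersect_across_species(sets, 1).stratified_counts()
        assert strata == {1: 1, 2: 1}


class TestSyntheticPanelEndToEnd:
    def test_full_sharing_only_in_shared_block(self):
        cfg = PanelConfig()
        panels, truth = make_amplicon_panel(cfg, seed=5)
        sets = {sp: species_male_specific_snps(p)[0] for sp, p in panels.items()}
        report = intersect_across_species(sets, min_species=len(panels))
        assert report.retained <= truth.shared_sites
        assert not report.retained & set(truth.private_sites)
        # most shared-block sites survive the strict all-species screen
        assert len(report.retained) >= 0.5 * len(truth.shared_sites)

    def test_private_sites_never_shared_by_two(self):
        panels, truth = make_amplicon_panel(PanelConfig(), seed=6)
        sets = {sp: species_male_specific_snps(p)[0] for sp, p in panels.items()}
        report = intersect_across_species(sets, min_species=2)
        assert not report.retained & set(truth.private_sites)

    def test_zero_divergence_yields_empty_sets(self):
        cfg = PanelConfig(n_shared_sites=1, n_private_sites_per_species=1)
        panels, truth = make_amplicon_panel(cfg, seed=9)
        # rewrite every call as homozygous reference (no divergence anywhere)
        for panel in panels.values():
            panel.calls = [
                SampleCall(c.sample, c.species, c.sex, c.site, c.depth, 0)
                for c in panel.calls
            ]
        for panel in panels.values():
            sites, _ = species_male_specific_snps(panel)
            assert sites == set()


def test_call_table_round_trip(tmp_path):
    panels, _ = make_amplicon_panel(
        PanelConfig(n_shared_sites=3, n_private_sites_per_species=2), seed=2
    )
    path = tmp_path / "calls.tsv"
    write_call_table(path, panels.values())
    back = read_call_table(path)
    assert set(back) == set(panels)
    for sp in panels:
        assert back[sp].calls == panels[sp].calls


def test_call_table_missing_column_fatal(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("sample\tspecies\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_call_table(path)
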