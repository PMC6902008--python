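"""Gene-drop simulator: determinism, genetics, fates and dataset structure."""

import numpy as np
import pytest

from lethalscan.synthetic_population import (SimulationConfig,
                                             expected_cxc_litter_fraction,
                                             simulate_population)
from lethalscan.variant_prioritization import parse_hgvs_del


class TestExpectedCxc:
    def test_published_arithmetic(self):
        assert expected_cxc_litter_fraction(0.09) == pytest.approx(0.0081, abs=1e-15)

    @pytest.mark.parametrize("f,expect", [(0.0, 0.0), (1.0, 1.0)])
    def test_bounds(self, f, expect):
        assert expected_cxc_litter_fraction(f) == expect

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_cxc_litter_fraction(1.5)


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_founders=150, n_generations=1,
                               markers_per_chromosome=20, n_chromosomes=2, seed=42)
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        assert np.array_equal(a.panel.alleles, b.panel.alleles)
        assert a.pedigree.equals(b.pedigree)
        assert a.trait_records.equals(b.trait_records)
        assert [l.litter_id for l in a.litters] == [l.litter_id for l in b.litters]
        assert [v.dosages for v in a.wgs_variants] == [v.dosages for v in b.wgs_variants]

    def test_different_seed_differs(self):
        cfg = SimulationConfig(n_founders=150, n_generations=1,
                               markers_per_chromosome=20, n_chromosomes=2, seed=42)
        other = SimulationConfig(n_founders=150, n_generations=1,
                                 markers_per_chromosome=20, n_chromosomes=2, seed=43)
        assert not np.array_equal(simulate_population(cfg).panel.alleles,
                                  simulate_population(other).panel.alleles)


class TestFounderGenetics:
    def test_founder_carrier_fraction_matches_binomial(self):
        cfg = SimulationConfig(n_founders=10_000, n_generations=1,
                               markers_per_chromosome=10, n_chromosomes=1,
                               litters_per_generation=10, seed=5)
        ds = simulate_population(cfg)
        founders = ds.truth.iloc[:10_000]
        frac = (founders.dosage >= 1).mean()
        expected = 2 * 0.045 * 0.955
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(frac - expected) < 3 * se

    def test_founder_heterozygosity_matches_marker_frequencies(self):
        cfg = SimulationConfig(n_founders=2000, n_generations=1,
                               markers_per_chromosome=40, n_chromosomes=1,
                               litters_per_generation=10,
                               lethal_allele_freq=0.0, seed=9)
        ds = simulate_population(cfg)
        hap = ds.panel.alleles[:2 * 2000]
        p = hap.mean(axis=0)
        het = (hap[0::2] != hap[1::2]).mean(axis=0)
        expect = 2 * p * (1 - p)
        # binomial sampling noise per marker
        assert np.abs(het - expect).max() < 5 * np.sqrt(0.5 * 0.5 / 2000)

    def test_no_lethal_means_no_dosage(self):
        ds = simulate_population(SimulationConfig(
            n_founders=200, n_generations=1, markers_per_chromosome=10,
            n_chromosomes=1, lethal_allele_freq=0.0, seed=2))
        assert (ds.truth.dosage == 0).all()

    def test_too_rare_lethal_raises(self):
        with pytest.raises(ValueError, match="no founder haplotype"):
            simulate_population(SimulationConfig(
                n_founders=5, n_generations=1, markers_per_chromosome=5,
                n_chromosomes=1, lethal_allele_freq=1e-9, seed=1))


class TestMeiosis:
    def test_zero_map_length_gives_parental_haplotypes(self):
        # with no recombination every gamete is one intact parental haplotype
        cfg = SimulationConfig(n_founders=60, n_generations=1,
                               markers_per_chromosome=25, n_chromosomes=1,
                               chromosome_length_cM=0.0025, lethal_allele_freq=0.0,
                               seed=17)
        ds = simulate_population(cfg)
        panel = ds.panel
        founder_haps = {tuple(row) for row in panel.alleles[:2 * 60]}
        offspring = panel.alleles[2 * 60:]
        for row in offspring:
            assert tuple(row) in founder_haps

    def test_offspring_alleles_come_from_parents(self, small_dataset):
        ds = small_dataset
        panel = ds.panel
        idx = {a: i for i, a in enumerate(panel.animals)}
        ped = ds.pedigree.set_index("animal")
        checked = 0
        for animal in panel.animals[-50:]:
            sire, dam = ped.loc[animal, "sire"], ped.loc[animal, "dam"]
            if not sire or sire not in idx or dam not in idx:
                continue
            kid = panel.alleles[2 * idx[animal]: 2 * idx[animal] + 2]
            s = panel.alleles[2 * idx[sire]: 2 * idx[sire] + 2]
            d = panel.alleles[2 * idx[dam]: 2 * idx[dam] + 2]
            # one kid haplotype from each parent, allele-wise
            for hap, par in ((kid[0], s), (kid[1], d)):
                assert np.all((hap == par[0]) | (hap == par[1]))
            checked += 1
        assert checked > 10


class TestFatesAndPanel:
    def test_full_penetrance_no_homozygote_in_panel(self, small_dataset):
        ds = small_dataset
        panel_animals = set(ds.panel.animals)
        tr = ds.truth
        assert (tr.loc[tr.animal.isin(panel_animals), "dosage"] < 2).all()

    def test_homozygotes_exist_at_birth(self, small_dataset):
        assert (small_dataset.truth.dosage == 2).any()

    def test_litter_counts_consistent(self, small_dataset):
        for l in small_dataset.litters:
            assert l.live_born + l.stillborn == l.total_born
            assert len(l.piglets) == l.total_born
            assert l.n_weaned <= l.live_born

    def test_validation_litters_fully_genotyped(self, small_dataset):
        ds = small_dataset
        assert ds.validation_litter_ids
        for l in ds.litters:
            genotyped = all(p.genotype is not None for p in l.piglets)
            if l.litter_id in ds.validation_litter_ids:
                assert genotyped
            else:
                assert not any(p.genotype is not None for p in l.piglets)


class TestWgsSubset:
    def test_causal_variant_in_perfect_ld_with_truth(self, small_dataset):
        from lethalscan.haplotype_scan import CarrierStatus
        from lethalscan.variant_prioritization import haplotype_ld
        ds = small_dataset
        truth = CarrierStatus(dosage=dict(zip(ds.truth.animal, ds.truth.dosage)))
        causal = [v for v in ds.wgs_variants if v.consequence == "frameshift"]
        assert len(causal) == 1
        ld = haplotype_ld(causal[0], truth)
        assert ld.r_squared == pytest.approx(1.0)
        chrom, pos, seq = parse_hgvs_del(causal[0].variant_id)
        assert chrom == ds.lethal_chromosome
        assert seq == "GACGGTGTACGCCGGT"

    def test_subset_composition(self, small_dataset):
        ds = small_dataset
        assert len(ds.wgs_animals) == 71
        truth = dict(zip(ds.truth.animal, ds.truth.dosage))
        assert sum(truth[a] >= 1 for a in ds.wgs_animals) >= 5
        assert len(ds.wgs_variants) == ds.config.n_wgs_variants
        classes = [v.consequence for v in ds.wgs_variants if v.consequence]
        assert classes.count("missense") == 3
        assert classes.count("splice_acceptor") == 1
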