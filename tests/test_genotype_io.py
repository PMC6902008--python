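"""Panel I/O round-trips, the HWE exact test, and QC filter accounting."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest

from lethalscan.genotype_io import (MISSING, MarkerMap, PhasedPanel,
                                    apply_qc, hwe_exact_test, read_panel,
                                    write_panel)


def make_panel(alleles, phased=True, positions=None, chroms=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    m = alleles.shape[1]
    markers = MarkerMap(
        np.array([f"m{i}" for i in range(m)], dtype=object),
        np.array(chroms if chroms is not None else ["1"] * m, dtype=object),
        np.array(positions if positions is not None else np.arange(1, m + 1) * 100),
    )
    animals = [f"s{i}" for i in range(alleles.shape[0] // 2)]
    return PhasedPanel(markers, animals, alleles, phased=phased)


class TestReadWrite:
    def test_vcf_single_phased_genotype(self, tmp_path):
        p = tmp_path / "one.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpig1\n"
            "1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0|1\n")
        panel = read_panel(str(p), "vcf")
        assert panel.n_animals == 1 and panel.n_markers == 1
        assert panel.phased
        assert panel.alleles[0, 0] == 0 and panel.alleles[1, 0] == 1

    def test_vcf_multiallelic_skipped_and_counted(self, tmp_path):
        p = tmp_path / "multi.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpig1\n"
            "1\t100\t.\tG\tA,T\t.\tPASS\t.\tGT\t0|1\n"
            "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1|1\n")
        panel = read_panel(str(p), "vcf")
        assert panel.n_markers == 1
        assert len(panel.skipped_records) == 1
        assert "multi-allelic" in panel.skipped_records[0][1]

    def test_ped_letter_alleles_first_seen_zero(self, tmp_path):
        (tmp_path / "toy.map").write_text("1 m1 0 100\n")
        (tmp_path / "toy.ped").write_text("FAM pig1 0 0 0 -9 A A\nFAM pig2 0 0 0 -9 G A\n")
        panel = read_panel(str(tmp_path / "toy"), "ped_map")
        assert not panel.phased
        assert list(panel.alleles[:, 0]) == [0, 0, 1, 0]

    @pytest.mark.parametrize("fmt", ["vcf", "ped_map"])
    def test_round_trip_preserves_genotypes(self, tmp_path, fmt, rng):
        alleles = rng.integers(0, 2, size=(20, 15)).astype(np.int8)
        panel = make_panel(alleles, phased=True)
        path = str(tmp_path / ("rt.vcf" if fmt == "vcf" else "rt"))
        write_panel(panel, path, fmt)
        back = read_panel(path, fmt)
        # .ped recodes letters by first-seen, so compare genotype dosages,
        # which are coding-invariant up to a global allele swap per marker
        for j in range(panel.n_markers):
            orig = panel.alleles[:, j]
            new = back.alleles[:, j]
            assert (np.array_equal(orig, new)
                    or np.array_equal(orig, 1 - new))
        assert back.animals == panel.animals
        assert list(back.markers.positions) == list(panel.markers.positions)

    def test_vcf_round_trip_byte_identical_content(self, tmp_path, rng):
        alleles = rng.integers(0, 2, size=(10, 8)).astype(np.int8)
        panel = make_panel(alleles, phased=True)
        p1 = str(tmp_path / "a.vcf")
        write_panel(panel, p1, "vcf")
        back = read_panel(p1, "vcf")
        p2 = str(tmp_path / "b.vcf")
        write_panel(back, p2, "vcf")
        assert open(p1).read() == open(p2).read()

    def test_missing_map_column_is_parse_error(self, tmp_path):
        (tmp_path / "bad.map").write_text("1 m1 0\n")
        (tmp_path / "bad.ped").write_text("FAM p 0 0 0 -9 A A\n")
        with pytest.raises(ValueError, match="bad.map:1"):
            read_panel(str(tmp_path / "bad"), "ped_map")


def hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        weights[h] = Fraction(factorial(n),
                              factorial(h) * factorial(hom_rare)
                              * factorial(hom_common)) * 2 ** h
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_enumerated_example(self):
        # n=5, 4 rare alleles: weights 10/120/80 over het counts 0/2/4
        assert hwe_exact_test(3, 0, 2) == pytest.approx(10 / 210, rel=1e-12)

    def test_modal_configuration_is_one(self):
        assert hwe_exact_test(2, 2, 1) == pytest.approx(1.0, rel=1e-12)

    def test_matches_rational_oracle_all_small_inputs(self):
        for n in range(1, 21):
            for n_het in range(n + 1):
                for n_hom_alt in range(n - n_het + 1):
                    n_hom_ref = n - n_het - n_hom_alt
                    got = hwe_exact_test(n_hom_ref, n_het, n_hom_alt)
                    want = hwe_oracle(n_hom_ref, n_het, n_hom_alt)
                    assert got == pytest.approx(want, rel=1e-9), \
                        (n_hom_ref, n_het, n_hom_alt)

    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 0)


class TestApplyQc:
    def test_clean_panel_unchanged(self):
        # every genotype observed, MAF 0.5 everywhere
        alleles = np.array([[0, 0], [1, 1], [1, 1], [0, 0]], dtype=np.int8)
        panel = make_panel(alleles, phased=True)
        out, report = apply_qc(panel)
        assert out.n_markers == 2 and out.n_animals == 2
        assert report.n_animals_removed == 0
        assert report.n_markers_kept == 2
        assert report.n_markers_removed_callrate == 0
        assert report.n_markers_removed_maf == 0

    def test_call_rate_removal(self):
        # 1 of 5 animals missing -> call rate 0.80 < 0.85; second marker clean
        alleles = np.zeros((10, 2), dtype=np.int8)
        alleles[1::2, :] = 1
        alleles[0, 0] = MISSING
        panel = make_panel(alleles, phased=False)
        out, report = apply_qc(panel, max_sample_missing=0.5)
        assert report.n_markers_removed_callrate == 1
        assert out.n_markers == 1

    def test_hwe_removal_uses_exact_test(self):
        # genotype counts (3, 0, 2): exact P ~ 0.0476 < 0.05
        alleles = np.array([[0], [0], [0], [0], [0], [0],
                            [1], [1], [1], [1]], dtype=np.int8)
        panel = make_panel(alleles, phased=True)
        with pytest.raises(ValueError):  # removing the only marker empties the panel
            apply_qc(panel, min_maf=0.0, hwe_min_p=0.05)

    def test_maf_boundary_removed(self):
        # MAF exactly at the threshold is removed (criterion is strictly >)
        alleles = np.zeros((100, 2), dtype=np.int8)
        alleles[0, 0] = 1  # MAF 1/100 = 0.01 at marker 0
        # marker 1 near Hardy-Weinberg at MAF 0.5: 12 hom-alt, 26 het, 12 hom-ref
        alleles[:24, 1] = 1
        alleles[24:76:2, 1] = 1
        panel = make_panel(alleles, phased=True)
        out, report = apply_qc(panel, min_maf=0.01)
        assert report.n_markers_removed_maf == 1
        assert out.markers.ids[0] == "m1"

    def test_position_filter_takes_precedence(self):
        # unknown position and poor call rate: counted once, under position
        alleles = np.full((10, 2), MISSING, dtype=np.int8)
        alleles[:, 1] = np.tile([0, 1], 5)
        panel = make_panel(alleles, phased=False, positions=[-1, 200])
        out, report = apply_qc(panel, max_sample_missing=0.6)
        assert report.n_markers_removed_position == 1
        assert report.n_markers_removed_callrate == 0

    def test_idempotent(self, small_dataset):
        panel = small_dataset.panel
        once, _ = apply_qc(panel)
        twice, report = apply_qc(once)
        assert np.array_equal(once.alleles, twice.alleles)
        assert report.n_markers_kept == once.n_markers
        assert report.n_animals_removed == 0

    def test_report_accounts_for_every_marker(self, small_dataset):
        panel = small_dataset.panel
        _, report = apply_qc(panel)
        assert report.n_markers_input == panel.n_markers
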