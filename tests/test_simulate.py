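"""Simulator contracts: determinism, transmission rules, injectors."""

import numpy as np
import pytest

from xhetkin.simulate import (
    PedigreeMember,
    SimConfig,
    expected_xhet,
    inject_swap,
    simulate_cohort,
    trio,
)
from xhetkin.vcf_model import classify_genotype, matrix_from_vcf, merge_samples
from xhetkin.xregion import Interval, nonpar_x_interval


def test_same_seed_is_byte_identical(tmp_path):
    cfg = SimConfig(pedigree=tuple(trio()), n_sites_autosome=200, n_sites_x=200,
                    pseudo_het_rate=0.05, seed=9)
    p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
    simulate_cohort(cfg)[0].write_vcf(str(p1))
    simulate_cohort(cfg)[0].write_vcf(str(p2))
    assert p1.read_bytes() == p2.read_bytes()


def test_emitted_vcf_round_trips_through_reader(tmp_path):
    cfg = SimConfig(pedigree=tuple(trio()), n_sites_autosome=100, n_sites_x=100,
                    missing_rate=0.05, seed=4)
    cohort, _ = simulate_cohort(cfg)
    path = str(tmp_path / "c.vcf")
    cohort.write_vcf(path)
    back = matrix_from_vcf(path)
    direct = merge_samples([(cohort.sample_ids, cohort.sites)])
    assert back.site_keys == direct.site_keys
    assert (back.codes == direct.codes).all()


def test_male_nonpar_x_is_haploid_and_hemizygous():
    cfg = SimConfig(pedigree=tuple(trio()), n_sites_autosome=0, n_sites_x=300,
                    par_fraction=0.2, genotype_error=0.0, seed=2)
    cohort, truth = simulate_cohort(cfg)
    nonpar = nonpar_x_interval()
    assert truth.sexes == {"father": "XY", "mother": "XX", "child": "XY"}
    saw_nonpar = saw_par = False
    for site in cohort.sites:
        fa = site.calls["father"]
        if nonpar.contains(site.contig, site.position):
            saw_nonpar = True
            assert len(fa.alleles) == 1  # haploid emission
        else:
            saw_par = True
            assert len(fa.alleles) == 2  # PAR stays diploid in males
    assert saw_nonpar and saw_par


def test_diploid_male_x_switch():
    cfg = SimConfig(pedigree=tuple(trio()), n_sites_autosome=0, n_sites_x=50,
                    par_fraction=0.0, diploid_male_x=True, seed=2)
    cohort, _ = simulate_cohort(cfg)
    for site in cohort.sites:
        fa = site.calls["father"]
        assert len(fa.alleles) == 2 and fa.alleles[0] == fa.alleles[1]


def test_mendelian_consistency_autosomes():
    """Without error injection no child genotype contradicts its parents."""
    cfg = SimConfig(pedigree=tuple(trio()), n_sites_autosome=500, n_sites_x=0,
                    genotype_error=0.0, seed=6)
    cohort, _ = simulate_cohort(cfg)
    compatible = {  # child dosage given (father class, mother class)
        (0, 0): {0}, (0, 1): {0, 1}, (0, 2): {1},
        (1, 0): {0, 1}, (1, 1): {0, 1, 2}, (1, 2): {1, 2},
        (2, 0): {1}, (2, 1): {1, 2}, (2, 2): {2},
    }
    for site in cohort.sites:
        fa = classify_genotype(site.calls["father"])
        mo = classify_genotype(site.calls["mother"])
        ch = classify_genotype(site.calls["child"])
        assert ch in compatible[(fa, mo)], f"at {site.position}"


def test_pedigree_validation():
    with pytest.raises(ValueError, match="founders must precede"):
        SimConfig(pedigree=(
            PedigreeMember("kid", "dad", "mum", "XY"),
            PedigreeMember("dad", None, None, "XY"),
            PedigreeMember("mum", None, None, "XX"),
        ))
    with pytest.raises(ValueError, match="both parents"):
        PedigreeMember("kid", "dad", None, "XY")


def test_expected_xhet_closed_form():
    assert expected_xhet([0.5, 0.5]) == pytest.approx(2 / 3)
    assert expected_xhet([0.001] * 5) == pytest.approx(1.0, abs=1e-2)
    with pytest.raises(ValueError):
        expected_xhet([1.0])
    with pytest.raises(ValueError):
        expected_xhet([])


def test_swap_is_involution_and_self_identity():
    cfg = SimConfig(pedigree=tuple(trio()), n_sites_autosome=50, n_sites_x=50, seed=8)
    cohort, truth = simulate_cohort(cfg)
    before = [dict(s.calls) for s in cohort.sites]
    inject_swap(cohort, "father", "father", truth)
    assert [dict(s.calls) for s in cohort.sites] == before
    inject_swap(cohort, "father", "mother", truth)
    assert cohort.sites[0].calls["father"] == before[0]["mother"]
    inject_swap(cohort, "father", "mother", truth)
    assert [dict(s.calls) for s in cohort.sites] == before
    assert truth.swaps == [("father", "mother"), ("father", "mother")]


def test_pseudo_het_confined_to_traps():
    nonpar = nonpar_x_interval()
    traps = (
        (Interval("chrX", nonpar.start, nonpar.start + 20_000_000), "TRAP1"),
        (Interval("chrX", 100_000_000, 110_000_000), "TRAP2"),
    )
    cfg = SimConfig(pedigree=tuple(trio()), n_sites_autosome=0, n_sites_x=2000,
                    par_fraction=0.0, pseudo_het_rate=0.5, trap_intervals=traps,
                    genotype_error=0.0, seed=10)
    cohort, truth = simulate_cohort(cfg)
    assert truth.pseudo_het_calls  # injection happened
    for sid, contig, pos in truth.pseudo_het_calls:
        assert truth.sexes[sid] == "XY"
        assert any(iv.contains(contig, pos) for iv, _ in traps)
    # male het calls outside traps do not exist (no error injected)
    for site in cohort.sites:
        if not any(iv.contains(site.contig, site.position) for iv, _ in traps):
            assert classify_genotype(site.calls["father"]) != 1


def test_duplicate_sample_via_column_copy_gives_phi_half():
    from xhetkin.kinship import kinship_pair
    from xhetkin.vcf_model import GenotypeMatrix

    cfg = SimConfig(pedigree=tuple(trio()), n_sites_autosome=500, n_sites_x=0, seed=12)
    cohort, _ = simulate_cohort(cfg)
    m = merge_samples([(cohort.sample_ids, cohort.sites)])
    dup = GenotypeMatrix(
        sample_ids=m.sample_ids + ["mother_dup"],
        site_keys=m.site_keys,
        codes=np.vstack([m.codes, m.codes[m.sample_ids.index("mother")]]),
    )
    assert kinship_pair(dup, "mother", "mother_dup").phi == 0.5


def test_contamination_shifts_allele_fractions():
    """A contaminated sample's homozygous calls drift toward its donor."""
    from xhetkin.vcf_model import allele_fraction

    ped = (PedigreeMember("A", None, None, "XX"),
           PedigreeMember("B", None, None, "XX"))
    base = SimConfig(pedigree=ped, n_sites_autosome=2000, n_sites_x=0,
                     genotype_error=0.0, seed=30)
    clean, _ = simulate_cohort(base)
    dirty, truth = simulate_cohort(base.with_(contamination=(("A", "B", 0.3),)))
    assert truth.contamination == [("A", "B", 0.3)]

    def mean_homref_af(cohort):
        vals = [allele_fraction(s.calls["A"]) for s in cohort.sites
                if s.calls["A"].alleles == (0, 0)
                and classify_genotype(s.calls["B"]) == 2]
        return float(np.mean(vals))

    # at sites where A is hom-ref and donor B hom-alt, reads leak in
    assert mean_homref_af(dirty) > mean_homref_af(clean) + 0.1
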