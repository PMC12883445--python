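"""Genotype classification, allele fractions, VCF I/O and merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_call
from xhetkin.vcf_model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    VariantSite,
    allele_fraction,
    classify_genotype,
    matrix_from_vcf,
    merge_samples,
    read_vcf,
    write_matrix_vcf,
)
from xhetkin.xregion import Interval


@pytest.mark.parametrize(
    "alleles, expected",
    [
        ((0, 1), HET),
        ((1, 1), HOM_ALT),
        ((0, 0), HOM_REF),
        ((1, 2), HET),  # two distinct ALT alleles are still heterozygous
        ((2, 2), HOM_ALT),
        ((None, 1), MISSING),  # half-call policy: conservative
        ((None, None), MISSING),
        ((0,), HOM_REF),  # haploid male X
        ((1,), HOM_ALT),
        ((None,), MISSING),
    ],
)
def test_classify_genotype(alleles, expected):
    call = make_call(*alleles) if len(alleles) == 2 else make_call(alleles[0])
    assert classify_genotype(call) == expected


def test_classify_ignores_phasing_and_order():
    assert classify_genotype(make_call(0, 1, phased=True)) == HET
    assert classify_genotype(make_call(1, 0)) == HET
    assert classify_genotype(make_call(2, 1)) == HET


@pytest.mark.parametrize(
    "ad, expected",
    [
        ((10, 10), 0.5),
        ((0, 20), 1.0),
        ((15, 3, 2), 0.25),  # multiallelic: all non-ref reads over total
        ((0, 0), None),
        (None, None),
    ],
)
def test_allele_fraction(ad, expected):
    call = make_call(0, 1, ad=ad)
    assert allele_fraction(call) == expected


def test_allele_fraction_vaf_fallback():
    assert allele_fraction(make_call(0, 1, vaf=0.42)) == 0.42
    assert allele_fraction(make_call(0, 1, ad=(6, 6), vaf=0.42)) == 0.5


def _write_vcf(tmp_path, body, name="t.vcf", samples=("S1",)):
    header = (
        "##fileformat=VCFv4.2\n##contig=<ID=chrX>\n##contig=<ID=chr1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    path = tmp_path / name
    path.write_text(header + body)
    return str(path)


def test_read_vcf_parses_formats(tmp_path):
    path = _write_vcf(
        tmp_path,
        "chrX\t100\t.\tA\tT\t.\t.\t.\tGT:AD:DP:GQ\t0/1:10,12:22:55\n"
        "chrX\t200\t.\tG\tC\t.\t.\t.\tGT\t1\n",
    )
    samples, sites = read_vcf(path)
    sites = list(sites)
    assert samples == ["S1"] and len(sites) == 2
    c0 = sites[0].calls["S1"]
    assert c0.alleles == (0, 1) and c0.allele_depths == (10, 12)
    assert c0.depth == 22 and c0.quality == 55
    c1 = sites[1].calls["S1"]
    assert c1.alleles == (1,)  # haploid parse
    assert c1.depth is None and c1.allele_depths is None


def test_read_vcf_region_is_inclusive(tmp_path):
    body = "".join(
        f"chrX\t{p}\t.\tA\tT\t.\t.\t.\tGT\t0/1\n" for p in (99, 100, 200, 201)
    )
    path = _write_vcf(tmp_path, body)
    _, sites = read_vcf(path, region=Interval("chrX", 100, 200))
    assert [s.position for s in sites] == [100, 200]


def test_variant_site_validation():
    with pytest.raises(ValueError):
        VariantSite("chrX", 0, "A", ("T",))
    with pytest.raises(ValueError):
        VariantSite("chrX", 5, "", ("T",))
    assert VariantSite("chrX", 5, "A", ("T",)).is_snv
    assert not VariantSite("chrX", 5, "AT", ("T",)).is_snv


def _site(contig, pos, sample_calls):
    return VariantSite(contig, pos, "A", ("T",),
                       calls={s: make_call(*g) for s, g in sample_calls.items()})


def test_merge_samples_union_and_missing():
    stream_a = (["A"], [_site("chr1", 1, {"A": (0, 1)}), _site("chr1", 2, {"A": (1, 1)})])
    stream_b = (["B"], [_site("chr1", 2, {"B": (0, 0)}), _site("chr1", 3, {"B": (0, 1)})])
    m = merge_samples([stream_a, stream_b])
    assert m.n_sites == 3  # union of {1,2} and {2,3}
    assert m.codes[0].tolist() == [HET, HOM_ALT, MISSING]
    assert m.codes[1].tolist() == [MISSING, HOM_REF, HET]


def test_merge_identical_inputs_has_no_missing():
    sites = [_site("chr1", p, {"A": (0, 1)}) for p in (1, 2, 3)]
    m = merge_samples([(["A"], sites)])
    assert (m.codes != MISSING).all()


def test_merge_duplicate_sample_id_errors():
    s = [_site("chr1", 1, {"A": (0, 1)})]
    with pytest.raises(ValueError, match="duplicate sample id"):
        merge_samples([(["A"], s), (["A"], list(s))])


@settings(max_examples=30, derandomize=True)
@given(
    codes=st.lists(
        st.lists(st.sampled_from([HOM_REF, HET, HOM_ALT, MISSING]), min_size=4,
                 max_size=4),
        min_size=1, max_size=6,
    )
)
def test_matrix_vcf_round_trip(tmp_path_factory, codes):
    """Writing a GenotypeMatrix as VCF and re-reading reproduces the codes."""
    arr = np.array(codes, dtype=np.int8)
    matrix = GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(arr.shape[0])],
        site_keys=[("chr1", 10 * (j + 1), "A", ("T",)) for j in range(arr.shape[1])],
        codes=arr,
    )
    path = str(tmp_path_factory.mktemp("rt") / "m.vcf")
    write_matrix_vcf(matrix, path)
    back = matrix_from_vcf(path)
    assert back.sample_ids == matrix.sample_ids
    assert back.site_keys == matrix.site_keys
    assert (back.codes == matrix.codes).all()


def test_round_trip_agrees_with_bcftools(tmp_path):
    """bcftools reads our emitted VCF and sees the same genotypes."""
    import shutil
    import subprocess

    if shutil.which("bcftools") is None:
        pytest.skip("bcftools not on PATH")
    matrix = GenotypeMatrix(
        sample_ids=["S0", "S1"],
        site_keys=[("chr1", p, "A", ("T",)) for p in (10, 20, 30)],
        codes=np.array([[0, 1, 2], [MISSING, 2, 0]], dtype=np.int8),
    )
    path = str(tmp_path / "m.vcf")
    write_matrix_vcf(matrix, path)
    out = subprocess.run(
        ["bcftools", "query", "-f", "[%GT,]\n", path],
        capture_output=True, text=True, check=True,
    ).stdout.strip().splitlines()
    assert out == ["0/0,./.,", "0/1,1/1,", "1/1,0/0,"]
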