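"""Data model for variant sites and genotype calls, VCF I/O and merging.

Genotype classes are coded as small integers throughout the package:
``HOM_REF = 0``, ``HET = 1``, ``HOM_ALT = 2``, ``MISSING = -1``.  A
:class:`GenotypeMatrix` (samples x sites, int8) built from these codes is
the substrate for kinship estimation and missingness filtering.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from cyvcf2 import VCF

from .xregion import Interval, contig_matches

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_CLASS_NAMES = {HOM_REF: "hom-ref", HET: "het", HOM_ALT: "hom-alt", MISSING: "missing"}


class VcfFormatError(ValueError):
    """Raised for structurally unusable VCF input (e.g. no GT FORMAT)."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site.

    ``alleles`` holds allele indices (0 = REF, >=1 = ALT) with ``None`` for a
    missing allele; length 1 marks a haploid call, length 2 a diploid one.
    ``depth`` (DP), ``allele_depths`` (AD) and ``quality`` (GQ) are stored as
    read when present; AD summing to more than DP is tolerated because
    callers disagree on the relationship.  ``vaf`` is a caller-supplied
    allele fraction used only as a fallback when AD is absent.
    """

    alleles: tuple[Optional[int], ...]
    phased: bool = False
    depth: Optional[int] = None
    allele_depths: Optional[tuple[int, ...]] = None
    quality: Optional[float] = None
    vaf: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.alleles) not in (1, 2):
            raise ValueError(f"call must be haploid or diploid, got {self.alleles!r}")
        for a in self.alleles:
            if a is not None and a < 0:
                raise ValueError(f"negative allele index in {self.alleles!r}")


@dataclass
class VariantSite:
    """A variant record: one position, REF/ALT alleles, per-sample calls."""

    contig: str
    position: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref or any(not a for a in self.alts):
            raise ValueError(f"empty allele at {self.contig}:{self.position}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        # multiallelic sites are keyed by the full alt set, never split
        return (self.contig, self.position, self.ref, self.alts)


@dataclass
class GenotypeMatrix:
    """Samples x sites genotype-class codes (int8; MISSING = -1)."""

    sample_ids: list[str]
    site_keys: list[tuple[str, int, str, tuple[str, ...]]]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sample_ids), len(self.site_keys)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.site_keys)} sites"
            )
        valid = np.isin(self.codes, (HOM_REF, HET, HOM_ALT, MISSING))
        if not valid.all():
            raise ValueError("codes must be in {0, 1, 2, -1}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_keys)

    def row(self, sample_id: str) -> np.ndarray:
        return self.codes[self.sample_ids.index(sample_id)]


def classify_genotype(call: GenotypeCall) -> int:
    """Map a call to its genotype class.

    Any missing allele (including half-calls like ``./1``) classifies as
    MISSING.  Haploid calls map REF to hom-ref and any ALT to hom-alt.  For
    diploid calls, two distinct non-missing allele indices are het (so
    ``1/2`` counts as het); identical indices are hom-ref for ``0`` and
    hom-alt otherwise.  The phasing separator is irrelevant.
    """
    if any(a is None for a in call.alleles):
        return MISSING
    if len(call.alleles) == 1:
        return HOM_REF if call.alleles[0] == 0 else HOM_ALT
    a, b = call.alleles
    if a != b:
        return HET
    return HOM_REF if a == 0 else HOM_ALT


def class_name(code: int) -> str:
    return _CLASS_NAMES[code]


def allele_fraction(call: GenotypeCall) -> Optional[float]:
    """Fraction of reads supporting ANY non-reference allele, from AD.

    Returns ``None`` (undefined) when AD is absent, has fewer than two
    entries, or sums to zero; in that case a caller-supplied VAF FORMAT
    value is used as a fallback if present.  Undefined is a value, not an
    error — filter policy for undefined fractions lives in ``filters``.
    """
    ad = call.allele_depths
    if ad is not None and len(ad) >= 2:
        total = sum(ad)
        if total > 0:
            return sum(ad[1:]) / total
    return call.vaf


def _parse_gt_field(gt: str, context: str) -> tuple[tuple[Optional[int], ...], bool]:
    """Parse a raw GT string like ``0/1``, ``1|2``, ``1`` or ``./1``."""
    phased = "|" in gt
    parts = gt.replace("|", "/").split("/")
    if not parts or len(parts) > 2:
        raise VcfFormatError(f"malformed genotype {gt!r} at {context}")
    alleles: list[Optional[int]] = []
    for p in parts:
        if p == ".":
            alleles.append(None)
        else:
            try:
                alleles.append(int(p))
            except ValueError as exc:
                raise VcfFormatError(f"malformed genotype {gt!r} at {context}") from exc
    return tuple(alleles), phased


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_vcf(
    path: str, region: Optional[Interval] = None
) -> tuple[list[str], Iterator[VariantSite]]:
    """Read a VCF, returning ``(sample_ids, site iterator)``.

    FORMAT fields GT/AD/DP/GQ are parsed when present; absent fields become
    ``None``.  If ``region`` is given, sites are restricted to it (inclusive
    bounds on both ends) by streaming — no index is required.  A VCF without
    a GT FORMAT field is a hard error.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)

    def _iter() -> Iterator[VariantSite]:
        saw_site = False
        for v in vcf:
            saw_site = True
            if "GT" not in (v.FORMAT or []):
                raise VcfFormatError(
                    f"record {v.CHROM}:{v.POS} in {path} carries no GT field"
                )
            if region is not None and not (
                contig_matches(v.CHROM, region.contig)
                and region.start <= v.POS <= region.end
            ):
                continue
            yield _site_from_cyvcf2(v, samples)
        vcf.close()
        if not saw_site and not samples:
            raise VcfFormatError(f"{path}: no samples and no records")

    return samples, _iter()


def _fmt_int(arr, i: int) -> Optional[int]:
    if arr is None:
        return None
    val = arr[i]
    try:
        val = int(np.asarray(val).reshape(-1)[0])
    except (TypeError, ValueError):
        return None
    return val if val >= 0 else None  # cyvcf2 encodes missing ints as negatives


def _site_from_cyvcf2(v, samples: Sequence[str]) -> VariantSite:
    alts = tuple(v.ALT) if v.ALT else ()
    if not alts:
        alts = ("<NON_REF>",)  # degenerate records are kept parseable
    def fmt(tag: str):
        try:
            return v.format(tag)
        except KeyError:  # tag not declared in the header at all
            return None

    ad = fmt("AD")
    dp = fmt("DP")
    gq = fmt("GQ")
    vaf = fmt("VAF")
    if vaf is None:
        vaf = fmt("AF")
    calls: dict[str, GenotypeCall] = {}
    for i, sid in enumerate(samples):
        g = v.genotypes[i]
        phased = bool(g[-1])
        raw = g[:-1]
        alleles = tuple(None if a < 0 else int(a) for a in raw)
        if not alleles:
            alleles = (None,)
        ad_i: Optional[tuple[int, ...]] = None
        if ad is not None:
            row = [int(x) for x in np.asarray(ad[i]).reshape(-1)]
            if any(x >= 0 for x in row):
                ad_i = tuple(max(x, 0) for x in row)
        gq_val = _fmt_int(gq, i)
        vaf_val = None
        if vaf is not None:
            x = float(np.asarray(vaf[i]).reshape(-1)[0])
            if np.isfinite(x) and x >= 0:
                vaf_val = x
        calls[sid] = GenotypeCall(
            alleles=alleles,
            phased=phased,
            depth=_fmt_int(dp, i),
            allele_depths=ad_i,
            quality=float(gq_val) if gq_val is not None else None,
            vaf=vaf_val,
        )
    return VariantSite(contig=v.CHROM, position=v.POS, ref=v.REF, alts=alts, calls=calls)


def iter_vcf_sites(path: str, region: Optional[Interval] = None) -> Iterator[VariantSite]:
    """Convenience wrapper returning only the site iterator."""
    _, sites = read_vcf(path, region=region)
    return sites


def merge_samples(
    streams: Iterable[tuple[Sequence[str], Iterable[VariantSite]]]
) -> GenotypeMatrix:
    """Merge per-sample (or per-file) site streams into one GenotypeMatrix.

    The site universe is the union of site keys; a sample with no record at a
    site gets MISSING — mirroring multi-way VCF-merge semantics, so the
    downstream missingness filter sees merge gaps.  Duplicate sample ids
    across inputs are an error.
    """
    sample_ids: list[str] = []
    per_stream: list[tuple[list[str], dict]] = []
    for ids, sites in streams:
        ids = list(ids)
        for sid in ids:
            if sid in sample_ids:
                raise ValueError(f"duplicate sample id across inputs: {sid!r}")
        sample_ids.extend(ids)
        site_map = {s.key: s for s in sites}
        per_stream.append((ids, site_map))

    all_keys: set = set()
    for _, site_map in per_stream:
        all_keys.update(site_map)
    site_keys = sorted(all_keys, key=lambda k: (k[0], k[1], k[2], k[3]))
    key_index = {k: j for j, k in enumerate(site_keys)}

    codes = np.full((len(sample_ids), len(site_keys)), MISSING, dtype=np.int8)
    row = 0
    for ids, site_map in per_stream:
        for key, site in site_map.items():
            j = key_index[key]
            for i, sid in enumerate(ids):
                call = site.calls.get(sid)
                if call is not None:
                    codes[row + i, j] = classify_genotype(call)
        row += len(ids)
    return GenotypeMatrix(sample_ids=sample_ids, site_keys=site_keys, codes=codes)


def matrix_from_vcf(path: str, region: Optional[Interval] = None) -> GenotypeMatrix:
    """Load one (possibly multi-sample) VCF straight into a GenotypeMatrix."""
    samples, sites = read_vcf(path, region=region)
    return merge_samples([(samples, sites)])


_CODE_TO_GT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_matrix_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as a minimal multi-sample VCF (GT only).

    Round-trips exactly through :func:`matrix_from_vcf` for biallelic keys:
    codes are preserved bit-for-bit.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in sorted({k[0] for k in matrix.site_keys}):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        order = sorted(range(matrix.n_sites), key=lambda j: matrix.site_keys[j][:2])
        for j in order:
            contig, pos, ref, alts = matrix.site_keys[j]
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in matrix.codes[:, j])
            fh.write(
                f"{contig}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_matrix_tsv(matrix: GenotypeMatrix, path: str) -> None:
    """TSV dump: one row per site, one column per sample (codes; . = missing)."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tref\talt\t" + "\t".join(matrix.sample_ids) + "\n")
        for j, (contig, pos, ref, alts) in enumerate(matrix.site_keys):
            vals = "\t".join(
                "." if c == MISSING else str(int(c)) for c in matrix.codes[:, j]
            )
            fh.write(f"{contig}\t{pos}\t{ref}\t{','.join(alts)}\t{vals}\n")
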