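"""Synthetic-cohort generator: pedigrees with sex-aware X transmission,
read-depth/allele-depth models, and QC-failure injectors.

The generator emulates the data regime the QC method targets: trios and
small cohorts of short-read germline call sets, with hemizygous male
non-PAR X, Hardy-Weinberg founders, Mendelian transmission, Poisson read
depth with binomial allele depths, and optional injectors for sample
swaps, cross-sample contamination, and pseudo-heterozygosity (the
mis-mapping artifact that renders male hemizygous sites het with
diploid-looking allele fractions near 50%).

Everything is driven by a single numpy Generator seeded from the config;
the same config yields a byte-identical VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .vcf_model import GenotypeCall, VariantSite
from .xregion import Interval, RegionSet, nonpar_x_interval

# PAR1 of GRCh38-style chrX; sites placed here are diploid in all samples.
_PAR1 = Interval("chrX", 10_001, 2_781_478)

_HAPLOID = -9  # sentinel for the absent second allele
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    father: Optional[str]
    mother: Optional[str]
    sex: str  # "XX" | "XY"

    def __post_init__(self) -> None:
        if self.sex not in ("XX", "XY"):
            raise ValueError(f"sex must be XX or XY, got {self.sex!r}")
        if (self.father is None) != (self.mother is None):
            raise ValueError(f"{self.sample_id}: specify both parents or neither")


def trio(
    child: str = "child", father: str = "father", mother: str = "mother",
    child_sex: str = "XY",
) -> list[PedigreeMember]:
    """Convenience pedigree: one trio, founders first."""
    return [
        PedigreeMember(father, None, None, "XY"),
        PedigreeMember(mother, None, None, "XX"),
        PedigreeMember(child, father, mother, child_sex),
    ]


@dataclass(frozen=True)
class SimConfig:
    pedigree: tuple[PedigreeMember, ...]
    n_sites_autosome: int = 2000
    n_sites_x: int = 1000
    af_low: float = 0.05
    af_high: float = 0.5
    par_fraction: float = 0.10
    depth_mean: float = 40.0
    genotype_error: float = 0.001
    missing_rate: float = 0.0
    pseudo_het_rate: float = 0.0
    trap_intervals: tuple[tuple[Interval, str], ...] = ()
    swap_pairs: tuple[tuple[str, str], ...] = ()
    contamination: tuple[tuple[str, str, float], ...] = ()  # (target, donor, fraction)
    diploid_male_x: bool = False  # emit male non-PAR X as 1/1 instead of 1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.par_fraction, self.genotype_error, self.missing_rate,
                  self.pseudo_het_rate):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if not 0 < self.af_low <= self.af_high < 1:
            raise ValueError("need 0 < af_low <= af_high < 1")
        ids = set()
        for m in self.pedigree:
            if m.sample_id in ids:
                raise ValueError(f"duplicate sample id {m.sample_id!r}")
            for parent in (m.father, m.mother):
                if parent is not None and parent not in ids:
                    raise ValueError(
                        f"{m.sample_id}: parent {parent!r} unknown or listed later "
                        "(founders must precede descendants)"
                    )
            ids.add(m.sample_id)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth emitted alongside the cohort."""

    sexes: dict[str, str]
    pedigree: list[tuple[str, Optional[str], Optional[str]]]
    swaps: list[tuple[str, str]] = field(default_factory=list)
    contamination: list[tuple[str, str, float]] = field(default_factory=list)
    pseudo_het_calls: list[tuple[str, str, int]] = field(default_factory=list)
    trap_regions: Optional[RegionSet] = None


@dataclass
class Cohort:
    """In-memory simulated cohort: ordered samples and fully-called sites."""

    sample_ids: list[str]
    sites: list[VariantSite]
    site_afs: np.ndarray  # population alt-allele frequency per site

    def write_vcf(self, path: str) -> None:
        write_cohort_vcf(self, path)


def expected_xhet(afs: Sequence[float]) -> float:
    """Closed-form expected Xhet of an XX sample under Hardy-Weinberg.

    Per site with alt frequency p the het probability is 2p(1-p) and the
    hom-alt probability p^2; hom-ref genotypes are excluded from the
    denominator, so E[Xhet] ~ sum 2p(1-p) / sum (2p(1-p) + p^2).
    """
    p = np.asarray(afs, dtype=float)
    if p.size == 0 or ((p <= 0) | (p >= 1)).any():
        raise ValueError("allele frequencies must lie in (0,1)")
    het = 2 * p * (1 - p)
    homalt = p * p
    return float(het.sum() / (het.sum() + homalt.sum()))


def _site_layout(cfg: SimConfig, rng: np.random.Generator):
    """Contigs, positions, ref/alt bases and AFs for every simulated site."""
    nonpar = nonpar_x_interval()
    n_par = int(round(cfg.n_sites_x * cfg.par_fraction))
    n_nonpar = cfg.n_sites_x - n_par

    def draw_positions(n: int, lo: int, hi: int) -> np.ndarray:
        span = hi - lo + 1
        if n > span:
            raise ValueError(f"cannot place {n} unique sites in {span} bp")
        pos = rng.choice(span, size=n, replace=False) + lo
        return np.sort(pos)

    contigs: list[str] = []
    positions: list[int] = []
    kinds: list[str] = []  # "auto" | "par" | "nonpar"
    if cfg.n_sites_autosome:
        for p in draw_positions(cfg.n_sites_autosome, 1, 60_000_000):
            contigs.append("chr1"); positions.append(int(p)); kinds.append("auto")
    if n_par:
        for p in draw_positions(n_par, _PAR1.start, _PAR1.end):
            contigs.append("chrX"); positions.append(int(p)); kinds.append("par")
    if n_nonpar:
        for p in draw_positions(n_nonpar, nonpar.start, nonpar.end):
            contigs.append("chrX"); positions.append(int(p)); kinds.append("nonpar")

    n = len(positions)
    afs = rng.uniform(cfg.af_low, cfg.af_high, size=n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    refs = [_BASES[i] for i in ref_idx]
    alts = [_BASES[(i + s) % 4] for i, s in zip(ref_idx, alt_shift)]
    return contigs, positions, kinds, afs, refs, alts


def _simulate_alleles(cfg: SimConfig, kinds: list[str], afs: np.ndarray,
                      rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-sample (n_sites, 2) allele arrays; second column _HAPLOID on male
    non-PAR X."""
    n = len(kinds)
    is_nonpar = np.array([k == "nonpar" for k in kinds])
    alleles: dict[str, np.ndarray] = {}
    for m in cfg.pedigree:
        g = np.zeros((n, 2), dtype=np.int8)
        if m.father is None:  # founder: Hardy-Weinberg draws
            g[:, 0] = rng.random(n) < afs
            g[:, 1] = rng.random(n) < afs
        else:
            fa, mo = alleles[m.father], alleles[m.mother]
            # which of each parent's two alleles is transmitted
            pick_f = rng.integers(0, 2, size=n)
            pick_m = rng.integers(0, 2, size=n)
            g[:, 0] = fa[np.arange(n), pick_f]
            g[:, 1] = mo[np.arange(n), pick_m]
            if is_nonpar.any():
                # father is hemizygous there: he transmits his single allele
                # to XX offspring; XY offspring get the X from the mother only
                fa_single = np.where(fa[:, 0] == _HAPLOID, fa[:, 1], fa[:, 0])
                if m.sex == "XX":
                    g[is_nonpar, 0] = fa_single[is_nonpar]
                else:
                    g[is_nonpar, 0] = g[is_nonpar, 1]
        if m.sex == "XY":
            g[is_nonpar, 1] = _HAPLOID
        alleles[m.sample_id] = g
    return alleles


def _apply_error(g: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Per-call class flips: a fraction of calls move to a different class."""
    if rate <= 0:
        return
    n = g.shape[0]
    flip = rng.random(n) < rate
    for i in np.nonzero(flip)[0]:
        if g[i, 1] == _HAPLOID:
            g[i, 0] = 1 - g[i, 0]
        else:
            cur = int(g[i, 0] + g[i, 1])  # dosage 0/1/2
            new = int(rng.choice([d for d in (0, 1, 2) if d != cur]))
            g[i, 0], g[i, 1] = (new + 1) // 2, new // 2

_READ_ERR = 0.01  # per-read miscall probability for AD draws


def simulate_cohort(cfg: SimConfig) -> tuple[Cohort, SimTruth]:
    """Generate a cohort and its ground truth; reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    contigs, positions, kinds, afs, refs, alts = _site_layout(cfg, rng)
    alleles = _simulate_alleles(cfg, kinds, afs, rng)
    sample_ids = [m.sample_id for m in cfg.pedigree]
    sexes = {m.sample_id: m.sex for m in cfg.pedigree}
    n = len(positions)

    for sid in sample_ids:
        _apply_error(alleles[sid], cfg.genotype_error, rng)

    # pseudo-het injection: male non-PAR X calls rendered heterozygous with
    # a diploid-looking allele fraction; concentrated in trap intervals when
    # any are configured, genome-wide on male non-PAR X otherwise
    truth = SimTruth(
        sexes=sexes,
        pedigree=[(m.sample_id, m.father, m.mother) for m in cfg.pedigree],
        trap_regions=RegionSet("traps", list(cfg.trap_intervals))
        if cfg.trap_intervals else None,
    )
    pseudo_af: dict[tuple[str, int], float] = {}
    if cfg.pseudo_het_rate > 0:
        in_trap = np.ones(n, dtype=bool)
        if cfg.trap_intervals:
            in_trap = np.array([
                any(iv.contains(c, p) for iv, _ in cfg.trap_intervals)
                for c, p in zip(contigs, positions)
            ])
        is_nonpar = np.array([k == "nonpar" for k in kinds])
        for sid in sample_ids:
            if sexes[sid] != "XY":
                continue
            hit = (rng.random(n) < cfg.pseudo_het_rate) & is_nonpar & in_trap
            for i in np.nonzero(hit)[0]:
                alleles[sid][i] = (0, 1)
                af = float(np.clip(rng.normal(0.5, 0.08), 1e-3, 1 - 1e-3))
                pseudo_af[(sid, i)] = af
                truth.pseudo_het_calls.append((sid, contigs[i], positions[i]))

    # read model: DP ~ Poisson(depth_mean), alt AD ~ Binomial(DP, p_alt)
    depth = {sid: rng.poisson(cfg.depth_mean, size=n) for sid in sample_ids}
    p_alt: dict[str, np.ndarray] = {}
    for sid in sample_ids:
        g = alleles[sid]
        dosage = np.where(g[:, 1] == _HAPLOID, g[:, 0], g[:, 0] + g[:, 1])
        ploidy = np.where(g[:, 1] == _HAPLOID, 1, 2)
        frac = dosage / ploidy
        p = frac * (1 - _READ_ERR) + (1 - frac) * _READ_ERR
        for (s, i), af in pseudo_af.items():
            if s == sid:
                p[i] = af
        p_alt[sid] = p

    for target, donor, fraction in cfg.contamination:
        if target not in sample_ids or donor not in sample_ids:
            raise ValueError(f"contamination names unknown sample: {target}/{donor}")
        p_alt[target] = (1 - fraction) * p_alt[target] + fraction * p_alt[donor]
        truth.contamination.append((target, donor, fraction))

    alt_reads = {
        sid: rng.binomial(depth[sid], p_alt[sid]) for sid in sample_ids
    }
    missing = {
        sid: (rng.random(n) < cfg.missing_rate) if cfg.missing_rate > 0
        else np.zeros(n, dtype=bool)
        for sid in sample_ids
    }

    sites: list[VariantSite] = []
    order = sorted(range(n), key=lambda i: (contigs[i], positions[i]))
    for i in order:
        calls: dict[str, GenotypeCall] = {}
        for sid in sample_ids:
            g = alleles[sid][i]
            dp = int(depth[sid][i])
            ad = (dp - int(alt_reads[sid][i]), int(alt_reads[sid][i]))
            gq = float(min(99, 3 * dp))
            if missing[sid][i]:
                tup: tuple[Optional[int], ...] = (None, None)
            elif g[1] == _HAPLOID:
                if cfg.diploid_male_x:
                    tup = (int(g[0]), int(g[0]))
                else:
                    tup = (int(g[0]),)
            else:
                a, b = sorted((int(g[0]), int(g[1])))
                tup = (a, b)
            calls[sid] = GenotypeCall(
                alleles=tup, depth=dp, allele_depths=ad, quality=gq
            )
        sites.append(VariantSite(contigs[i], positions[i], refs[i], (alts[i],),
                                 calls=calls))

    cohort = Cohort(sample_ids=sample_ids, sites=sites,
                    site_afs=afs[np.array(order)])
    for a, b in cfg.swap_pairs:
        inject_swap(cohort, a, b, truth)
    return cohort, truth


def inject_swap(cohort: Cohort, sample_a: str, sample_b: str,
                truth: Optional[SimTruth] = None) -> None:
    """Exchange two samples' genotype columns; header names stay put.

    Swapping a sample with itself is the identity; swapping twice restores
    the original columns.
    """
    for sid in (sample_a, sample_b):
        if sid not in cohort.sample_ids:
            raise ValueError(f"unknown sample {sid!r}")
    if sample_a == sample_b:
        return
    for site in cohort.sites:
        ca, cb = site.calls.get(sample_a), site.calls.get(sample_b)
        if ca is not None:
            site.calls[sample_b] = ca
        else:
            site.calls.pop(sample_b, None)
        if cb is not None:
            site.calls[sample_a] = cb
        else:
            site.calls.pop(sample_a, None)
    if truth is not None:
        truth.swaps.append((sample_a, sample_b))


def inject_roh(cohort: Cohort, sample_id: str, interval: Interval,
               seed: int = 0) -> int:
    """Render a sample homozygous across an interval (run of homozygosity).

    Emulates consanguinity: every het call inside the interval collapses to
    a homozygote, alt with probability equal to the site's population allele
    frequency (the shared haplotype carries either allele at its frequency).
    Returns the number of converted calls.
    """
    if sample_id not in cohort.sample_ids:
        raise ValueError(f"unknown sample {sample_id!r}")
    rng = np.random.default_rng(seed)
    converted = 0
    for i, site in enumerate(cohort.sites):
        if not interval.contains(site.contig, site.position):
            continue
        call = site.calls[sample_id]
        if len(call.alleles) != 2 or call.alleles[0] == call.alleles[1]:
            continue
        if None in call.alleles:
            continue
        p = float(cohort.site_afs[i])
        allele = 1 if rng.random() < p else 0
        dp = call.depth or 0
        ad = (0, dp) if allele == 1 else (dp, 0)
        site.calls[sample_id] = GenotypeCall(
            alleles=(allele, allele), depth=call.depth, allele_depths=ad,
            quality=call.quality,
        )
        converted += 1
    return converted


def _format_call(call: GenotypeCall) -> str:
    sep = "|" if call.phased else "/"
    gt = sep.join("." if a is None else str(a) for a in call.alleles)
    ad = ",".join(str(x) for x in call.allele_depths) if call.allele_depths else "."
    dp = "." if call.depth is None else str(call.depth)
    gq = "." if call.quality is None else str(int(call.quality))
    return f"{gt}:{ad}:{dp}:{gq}"


def write_cohort_vcf(cohort: Cohort, path: str) -> None:
    """Emit the cohort as a multi-sample VCF with GT:AD:DP:GQ."""
    contigs: list[str] = []
    for s in cohort.sites:
        if s.contig not in contigs:
            contigs.append(s.contig)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=xhetkin-simulate\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.sample_ids) + "\n")
        for s in cohort.sites:
            cols = "\t".join(_format_call(s.calls[sid]) for sid in cohort.sample_ids)
            fh.write(f"{s.contig}\t{s.position}\t.\t{s.ref}\t{','.join(s.alts)}"
                     f"\t.\t.\t.\tGT:AD:DP:GQ\t{cols}\n")


def write_truth_tables(truth: SimTruth, prefix: str) -> None:
    """Plain-TSV ground truth: sexes, pedigree, injections (+ trap BED)."""
    with open(f"{prefix}.sexes.tsv", "w") as fh:
        fh.write("sample\tsex\n")
        for sid in sorted(truth.sexes):
            fh.write(f"{sid}\t{truth.sexes[sid]}\n")
    with open(f"{prefix}.pedigree.tsv", "w") as fh:
        fh.write("sample\tfather\tmother\n")
        for sid, fa, mo in truth.pedigree:
            fh.write(f"{sid}\t{fa or '.'}\t{mo or '.'}\n")
    with open(f"{prefix}.injections.tsv", "w") as fh:
        fh.write("kind\tdetail\n")
        for a, b in truth.swaps:
            fh.write(f"swap\t{a}<->{b}\n")
        for t, d, f in truth.contamination:
            fh.write(f"contamination\t{t}<-{d}@{f}\n")
        for sid, c, p in truth.pseudo_het_calls:
            fh.write(f"pseudo_het\t{sid}@{c}:{p}\n")
    if truth.trap_regions is not None:
        from .xregion import write_bed

        write_bed(truth.trap_regions, f"{prefix}.traps.bed")
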