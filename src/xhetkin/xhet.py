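"""The Xhet statistic: per-sample heterozygosity on non-PAR chromosome X.

Xhet is the proportion of heterozygous genotypes among the heterozygous and
homozygous-alternate genotypes a sample carries inside the non-PAR X
interval, after parametric call filters.  Hom-ref and missing genotypes are
excluded before the proportion is taken, so the denominator is
``n_het + n_homalt``.  XY samples are hemizygous on non-PAR X and score near
zero; XX samples score substantially positive (around 0.5 on
carrier-ascertained call sets).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .filters import FilterParams, passes_call_filters
from .vcf_model import HET, HOM_ALT, VariantSite, classify_genotype, read_vcf
from .xregion import Interval, in_region, nonpar_x_interval


@dataclass(frozen=True)
class XhetResult:
    sample_id: str
    n_het: int
    n_homalt: int
    params: FilterParams
    interval: Interval

    @property
    def xhet(self) -> Optional[float]:
        """n_het / (n_het + n_homalt); None when no qualifying genotype."""
        denom = self.n_het + self.n_homalt
        if denom == 0:
            return None
        return self.n_het / denom

    @property
    def defined(self) -> bool:
        return self.n_het + self.n_homalt > 0


def compute_xhet(n_het: int, n_homalt: int) -> Optional[float]:
    """The Xhet ratio from counts; None (undefined) on a zero denominator."""
    denom = n_het + n_homalt
    return None if denom == 0 else n_het / denom


def count_x_genotypes(
    sites: Iterable[VariantSite],
    sample_id: str,
    interval: Optional[Interval] = None,
    params: Optional[FilterParams] = None,
) -> tuple[int, int]:
    """Count het and hom-alt genotypes for one sample inside the interval.

    Only calls that pass the parametric filters and classify as het or
    hom-alt are counted; hom-ref and missing never contribute.  Raises
    ``KeyError`` if the sample is absent from the stream.
    """
    interval = interval or nonpar_x_interval()
    params = params or FilterParams()
    n_het = n_homalt = 0
    seen_sample = False
    for site in sites:
        call = site.calls.get(sample_id)
        if call is None:
            continue
        seen_sample = True
        if not in_region(site.contig, site.position, interval):
            continue
        if not passes_call_filters(call, params):
            continue
        cls = classify_genotype(call)
        if cls == HET:
            n_het += 1
        elif cls == HOM_ALT:
            n_homalt += 1
    if not seen_sample:
        raise KeyError(f"sample {sample_id!r} absent from input stream")
    return n_het, n_homalt


def xhet_from_sites(
    sites: Sequence[VariantSite],
    sample_ids: Sequence[str],
    interval: Optional[Interval] = None,
    params: Optional[FilterParams] = None,
) -> list[XhetResult]:
    """Per-sample Xhet over an in-memory site list, ordered by sample id."""
    interval = interval or nonpar_x_interval()
    params = params or FilterParams()
    counts = {sid: [0, 0] for sid in sample_ids}
    for site in sites:
        if not in_region(site.contig, site.position, interval):
            continue
        for sid in sample_ids:
            call = site.calls.get(sid)
            if call is None or not passes_call_filters(call, params):
                continue
            cls = classify_genotype(call)
            if cls == HET:
                counts[sid][0] += 1
            elif cls == HOM_ALT:
                counts[sid][1] += 1
    return [
        XhetResult(sid, counts[sid][0], counts[sid][1], params, interval)
        for sid in sorted(counts)
    ]


def xhet_batch(
    vcf_paths: Sequence[str],
    interval: Optional[Interval] = None,
    params: Optional[FilterParams] = None,
) -> list[XhetResult]:
    """Compute Xhet for every sample across one or more VCFs.

    Each VCF may be single- or multi-sample; an undefined Xhet (no
    qualifying genotype) is reported with its counts rather than raised, so
    one degenerate sample never aborts a batch.  Results are ordered by
    sample id.
    """
    interval = interval or nonpar_x_interval()
    params = params or FilterParams()
    results: list[XhetResult] = []
    for path in vcf_paths:
        samples, site_iter = read_vcf(path, region=interval)
        sites = list(site_iter)
        results.extend(xhet_from_sites(sites, samples, interval, params))
    return sorted(results, key=lambda r: r.sample_id)


def write_xhet_tsv(results: Sequence[XhetResult], path: str) -> None:
    """TSV with counts, the ratio, and every filter parameter for provenance."""
    with open(path, "w") as fh:
        fh.write(
            "sample\tn_het\tn_homalt\txhet\tinterval\t"
            "af_min\tdp_min\tgq_min\tmiss_max\tstrict\n"
        )
        for r in results:
            x = "" if r.xhet is None else f"{r.xhet:.6f}"
            p = r.params
            fh.write(
                f"{r.sample_id}\t{r.n_het}\t{r.n_homalt}\t{x}\t{r.interval}\t"
                f"{p.af_min}\t{p.dp_min}\t{p.gq_min}\t{p.miss_max}\t{p.strict}\n"
            )
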