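"""Pseudo-heterozygosity scan over hemizygous-expected (male) samples.

True heterozygosity is impossible on male non-PAR X, so recurrent het
calls there mark systematic artifacts: reads mis-mapped from paralogs,
processed pseudogenes or ampliconic duplications produce diploid-looking
allele fractions near 50%.  The scan restricts to exonic SNVs, applies one
or more inclusive VAF windows, and aggregates qualifying het calls per
position (samples with a het call), per gene, and per annotated region
(with per-Mb densities).

Two distinct tallies are computed because both are informative:
``unique_het_positions`` counts site keys with at least one qualifying het
call, while "genotype calls" are sample-summed (a position het in 30
samples contributes 30 calls but 1 position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .filters import VAF_WINDOWS, in_vaf_window
from .vcf_model import HET, VariantSite, allele_fraction, classify_genotype
from .xregion import RegionSet

SiteKey = tuple[str, int, str, tuple[str, ...]]


@dataclass
class HetScanTable:
    """Qualifying het-call tallies for one VAF window."""

    window: tuple[float, float]
    per_position: dict[SiteKey, int] = field(default_factory=dict)  # -> n samples het

    @property
    def unique_het_positions(self) -> int:
        return len(self.per_position)

    @property
    def total_calls(self) -> int:
        return sum(self.per_position.values())


def scan(
    sites: Iterable[VariantSite],
    male_ids: Sequence[str],
    exons: RegionSet,
    windows: Sequence[tuple[float, float]] = VAF_WINDOWS,
) -> dict[tuple[float, float], HetScanTable]:
    """Tally heterozygous exonic-SNV calls of the given samples per window.

    A call contributes iff its site is an SNV overlapping an exon interval,
    the genotype classifies het, and its allele fraction (from AD; calls
    without a fraction are rejected — a VAF window is meaningless without
    one) lies inside the inclusive window.
    """
    if len(exons) == 0:
        raise ValueError("exon region set is empty")
    tables = {w: HetScanTable(window=w) for w in windows}
    for site in sites:
        if not site.is_snv:
            continue
        if not exons.overlapping(site.contig, site.position):
            continue
        for sid in male_ids:
            call = site.calls.get(sid)
            if call is None or classify_genotype(call) != HET:
                continue
            if allele_fraction(call) is None:
                raise ValueError(
                    f"het call without AD/VAF at {site.contig}:{site.position} "
                    f"sample {sid}: VAF windows need an allele fraction"
                )
            for w in windows:
                if in_vaf_window(call, w):
                    tab = tables[w]
                    tab.per_position[site.key] = tab.per_position.get(site.key, 0) + 1
    return tables


def gene_counts(table: HetScanTable, genes: RegionSet) -> dict[str, int]:
    """Sample-summed het calls per gene label.

    A position inside several overlapping gene intervals is counted in each
    of them, so overlapping gene pairs each carry the full tally.
    """
    counts: dict[str, int] = {}
    for (contig, pos, _ref, _alts), n in table.per_position.items():
        for label in genes.overlapping(contig, pos):
            counts[label] = counts.get(label, 0) + n
    return counts


def top_genes(
    table: HetScanTable, genes: RegionSet, n: int = 20
) -> list[tuple[str, int]]:
    """Top-n genes by descending het-call count; ties broken by label."""
    counts = gene_counts(table, genes)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def region_density(
    table: HetScanTable, regions: RegionSet
) -> dict[str, tuple[int, float, float]]:
    """Per-region (het call count, span in Mb, calls per Mb).

    Nested or overlapping regions are tallied independently — one call may
    contribute to several.  Every label in the set is reported, including
    zero-count ones.
    """
    spans = regions.spans_bp()
    counts = {label: 0 for label in spans}
    for (contig, pos, _ref, _alts), n in table.per_position.items():
        for label in regions.overlapping(contig, pos):
            counts[label] += n
    out = {}
    for label, span_bp in spans.items():
        if span_bp <= 0:
            raise ValueError(f"region {label!r} has non-positive span")
        mb = span_bp / 1e6
        out[label] = (counts[label], mb, counts[label] / mb)
    return out


def write_hetscan_tsv(
    tables: dict[tuple[float, float], HetScanTable],
    path: str,
    genes: Optional[RegionSet] = None,
    regions: Optional[RegionSet] = None,
    top_n: int = 20,
) -> None:
    """Combined report: per-window totals, top genes, and region densities."""
    with open(path, "w") as fh:
        fh.write("section\twindow\tlabel\tvalue\textra\n")
        for w, tab in tables.items():
            wname = f"{w[0]:g}-{w[1]:g}"
            fh.write(f"total\t{wname}\tunique_het_positions\t{tab.unique_het_positions}\t\n")
            fh.write(f"total\t{wname}\thet_genotype_calls\t{tab.total_calls}\t\n")
            if genes is not None:
                for label, count in top_genes(tab, genes, n=top_n):
                    fh.write(f"gene\t{wname}\t{label}\t{count}\t\n")
            if regions is not None:
                for label, (count, mb, dens) in sorted(region_density(tab, regions).items()):
                    fh.write(f"region\t{wname}\t{label}\t{count}\t{dens:.3f}/Mb over {mb:.3f} Mb\n")
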