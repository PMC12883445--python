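"""Chromosome-X region model: non-PAR interval, membership tests, BED regions.

All intervals are 1-based with inclusive bounds on both ends (the convention
of region strings like ``chrX:2781479-153925834``).  BED input, which is
0-based half-open, is converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

# "X" and "chrX" style names are interchangeable across references.
_DEFAULT_ALIASES = {
    "chrX": "X", "X": "X",
    "chrY": "Y", "Y": "Y",
    "chrM": "MT", "chrMT": "MT", "MT": "MT", "M": "MT",
}


def normalize_contig(name: str, aliases: dict[str, str] | None = None) -> str:
    table = aliases or _DEFAULT_ALIASES
    if name in table:
        return table[name]
    if name.startswith("chr"):
        return name[3:]
    return name


def contig_matches(a: str, b: str, aliases: dict[str, str] | None = None) -> bool:
    return normalize_contig(a, aliases) == normalize_contig(b, aliases)


@dataclass(frozen=True)
class Interval:
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, contig: str, position: int) -> bool:
        return contig_matches(contig, self.contig) and self.start <= position <= self.end

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


# Smallest interval excluding PAR1 and PAR2 that is shared across the
# GRCh37/hg19, GRCh38/hg38 and T2T assemblies; by construction the same
# coordinates apply to every supported assembly label.
_NONPAR_X = (2_781_479, 153_925_834)
_SUPPORTED_ASSEMBLIES = ("default", "GRCh37", "hg19", "GRCh38", "hg38", "T2T", "chm13")


def nonpar_x_interval(assembly: str = "default") -> Interval:
    """The shared non-pseudoautosomal interval of chromosome X.

    Heterozygosity on this interval is the basis of the Xhet statistic:
    PAR1/PAR2 are diploid in all samples and must be excluded.
    """
    if assembly not in _SUPPORTED_ASSEMBLIES:
        raise ValueError(
            f"unknown assembly {assembly!r}; supported: {', '.join(_SUPPORTED_ASSEMBLIES)}"
        )
    return Interval("chrX", *_NONPAR_X)


def in_region(contig: str, position: int, interval: Interval) -> bool:
    """Inclusive membership test with contig-name aliasing."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    return interval.contains(contig, position)


class BedError(ValueError):
    pass


@dataclass
class RegionSet:
    """A named collection of labelled intervals (e.g. exons, genes, strata)."""

    name: str
    intervals: list[tuple[Interval, str]] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._rebuild()

    def _rebuild(self) -> None:
        self._trees = {}
        for iv, label in self.intervals:
            if not label:
                raise BedError(f"empty label in region set {self.name!r}")
            key = normalize_contig(iv.contig)
            # IntervalTree is half-open; store [start, end+1)
            self._trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end + 1, label)

    def __len__(self) -> int:
        return len(self.intervals)

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, label in self.intervals:
            seen.setdefault(label)
        return list(seen)

    def overlapping(self, contig: str, position: int) -> list[str]:
        """Labels of every interval containing the position (may be several)."""
        tree = self._trees.get(normalize_contig(contig))
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.at(position))

    def spans_bp(self) -> dict[str, int]:
        """Total span per label in bp (intervals of a label summed)."""
        spans: dict[str, int] = {}
        for iv, label in self.intervals:
            spans[label] = spans.get(label, 0) + iv.length
        return spans


def load_bed(path: str, name: str | None = None) -> RegionSet:
    """Load a 3+ column BED into a RegionSet.

    BED records are 0-based half-open; they become 1-based inclusive
    Intervals via (start+1, end), preserving length.  Records without a
    fourth column are labelled ``region<N>``.  Malformed lines raise
    :class:`BedError` with the line number.
    """
    intervals: list[tuple[Interval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedError(f"{path}:{lineno}: expected >=3 columns, got {len(cols)}")
            try:
                start0, end0 = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end0 < start0 or end0 <= 0:
                raise BedError(f"{path}:{lineno}: invalid interval [{start0}, {end0})")
            label = cols[3] if len(cols) >= 4 and cols[3] else f"region{lineno}"
            intervals.append((Interval(cols[0], start0 + 1, end0), label))
    return RegionSet(name=name or str(path), intervals=intervals)


def write_bed(regions: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for iv, label in regions.intervals:
            fh.write(f"{iv.contig}\t{iv.start - 1}\t{iv.end}\t{label}\n")
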