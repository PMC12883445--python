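"""Parametric genotype/variant filters shared by the kinship and Xhet branches.

The defaults encode the standard pre-filter: allele fraction strictly above
0.25, read depth strictly above 20, and exclusion of sites with strictly
more than 20% missing genotypes after merging.  VAF windows (used by the
pseudo-heterozygosity scan) are inclusive on both ends and expressed in
percent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .vcf_model import MISSING, GenotypeCall, GenotypeMatrix, allele_fraction


@dataclass(frozen=True)
class FilterParams:
    af_min: Optional[float] = 0.25  # strict >
    dp_min: Optional[int] = 20  # strict >
    gq_min: Optional[float] = None  # inclusive >=
    miss_max: float = 0.20  # sites with missing fraction strictly above are dropped
    vaf_window: Optional[tuple[float, float]] = None  # inclusive percent bounds
    strict: bool = False  # calls lacking AD/DP fail AF/DP filters when True

    def __post_init__(self) -> None:
        if self.af_min is not None and not 0 <= self.af_min <= 1:
            raise ValueError(f"af_min out of [0,1]: {self.af_min}")
        if self.dp_min is not None and self.dp_min < 0:
            raise ValueError(f"dp_min negative: {self.dp_min}")
        if not 0 <= self.miss_max <= 1:
            raise ValueError(f"miss_max out of [0,1]: {self.miss_max}")
        if self.vaf_window is not None:
            low, high = self.vaf_window
            if not 0 <= low <= high <= 100:
                raise ValueError(f"bad vaf_window {self.vaf_window}")

    def with_(self, **kwargs) -> "FilterParams":
        return replace(self, **kwargs)


#: The three inclusive VAF windows (percent) used by the het scan.
VAF_WINDOWS: tuple[tuple[float, float], ...] = ((25, 75), (33, 66), (45, 55))


def passes_call_filters(call: GenotypeCall, params: FilterParams) -> bool:
    """Apply AF/DP/GQ thresholds to a single call.

    Inequalities are exact: AF and DP strict ``>``, GQ inclusive ``>=``.
    In the default permissive mode a call with no AD (AF undefined) or no DP
    passes those filters; ``params.strict`` fails them instead.
    """
    if params.af_min is not None:
        af = allele_fraction(call)
        if af is None:
            if params.strict:
                return False
        elif not af > params.af_min:
            return False
    if params.dp_min is not None:
        if call.depth is None:
            if params.strict:
                return False
        elif not call.depth > params.dp_min:
            return False
    if params.gq_min is not None and call.quality is not None:
        if not call.quality >= params.gq_min:
            return False
    if params.gq_min is not None and call.quality is None and params.strict:
        return False
    return True


def missingness_filter(matrix: GenotypeMatrix, miss_max: float = 0.20) -> GenotypeMatrix:
    """Drop sites whose missing-genotype fraction is strictly above miss_max.

    A site with exactly the threshold fraction missing (e.g. 1 of 5 samples
    at miss_max=0.20) is retained.  Samples are never removed and retained
    codes are unchanged.
    """
    if matrix.n_sites == 0:
        return matrix
    miss_frac = (matrix.codes == MISSING).mean(axis=0)
    keep = ~(miss_frac > miss_max)
    return GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        site_keys=[k for k, f in zip(matrix.site_keys, keep) if f],
        codes=matrix.codes[:, keep].copy(),
    )


def in_vaf_window(call: GenotypeCall, window: tuple[float, float]) -> bool:
    """True iff the call's allele fraction lies inside the inclusive window.

    The window is in percent (e.g. ``(25, 75)``); an undefined fraction is
    never inside any window.
    """
    af = allele_fraction(call)
    if af is None:
        return False
    low, high = window
    return low / 100.0 <= af <= high / 100.0
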