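"""KING-robust pairwise kinship from genotype-class codes.

For a sample pair (i, j) the estimator uses only sites where both
genotypes are observed:

    phi = (N_Aa,Aa - 2 * N_AA,aa) / (N_Aa,i + N_Aa,j)

where N_Aa,Aa counts sites with both samples heterozygous, N_AA,aa counts
opposite homozygotes, and N_Aa,i / N_Aa,j are the per-sample heterozygote
counts over the jointly observed sites.  The estimator is robust to
population structure and needs no allele frequencies.  Expected values:
0.5 for duplicates/MZ twins, 0.25 for parent-offspring and full sibs,
0.125 for second-degree, 0 for unrelated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .vcf_model import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix

DEGREE_DUPLICATE = "duplicate/MZ"
DEGREE_FIRST = "first"
DEGREE_SECOND = "second"
DEGREE_THIRD = "third"
DEGREE_UNRELATED = "unrelated"
DEGREE_UNDEFINED = "undefined"

# Standard powers-of-two kinship cutoffs: 1/2^(3/2), 1/2^(5/2), ...
_CUTOFFS = (0.354, 0.177, 0.0884, 0.0442)


@dataclass(frozen=True)
class PairCounts:
    n_AaAa: int  # both heterozygous
    n_AAaa: int  # opposite homozygotes
    n_Aa_i: int  # het count of sample i over jointly observed sites
    n_Aa_j: int
    n_obs: int  # jointly non-missing sites

    def __post_init__(self) -> None:
        if min(self.n_AaAa, self.n_AAaa, self.n_Aa_i, self.n_Aa_j, self.n_obs) < 0:
            raise ValueError("negative count")
        if self.n_AaAa > min(self.n_Aa_i, self.n_Aa_j):
            raise ValueError("n_AaAa exceeds a per-sample het count")
        if max(self.n_AaAa, self.n_AAaa, self.n_Aa_i, self.n_Aa_j) > self.n_obs:
            raise ValueError("count exceeds n_obs")


@dataclass(frozen=True)
class KinshipResult:
    pair: tuple[str, str]
    counts: PairCounts
    phi: Optional[float]
    degree: str


def pair_counts(codes_i: np.ndarray, codes_j: np.ndarray) -> PairCounts:
    """Accumulate KING counts over positions where both codes are non-missing."""
    codes_i = np.asarray(codes_i)
    codes_j = np.asarray(codes_j)
    if codes_i.shape != codes_j.shape:
        raise ValueError(f"length mismatch: {codes_i.shape} vs {codes_j.shape}")
    both = (codes_i != MISSING) & (codes_j != MISSING)
    a, b = codes_i[both], codes_j[both]
    het_i = a == HET
    het_j = b == HET
    opp = ((a == HOM_REF) & (b == HOM_ALT)) | ((a == HOM_ALT) & (b == HOM_REF))
    return PairCounts(
        n_AaAa=int((het_i & het_j).sum()),
        n_AAaa=int(opp.sum()),
        n_Aa_i=int(het_i.sum()),
        n_Aa_j=int(het_j.sum()),
        n_obs=int(both.sum()),
    )


def king_phi(counts: PairCounts) -> Optional[float]:
    """The robust kinship estimate; None when neither sample has a het call."""
    denom = counts.n_Aa_i + counts.n_Aa_j
    if denom == 0:
        return None
    return (counts.n_AaAa - 2 * counts.n_AAaa) / denom


def classify_degree(phi: Optional[float]) -> str:
    """Bin phi into relationship degrees at powers-of-two cutoffs."""
    if phi is None:
        return DEGREE_UNDEFINED
    if phi > _CUTOFFS[0]:
        return DEGREE_DUPLICATE
    if phi > _CUTOFFS[1]:
        return DEGREE_FIRST
    if phi > _CUTOFFS[2]:
        return DEGREE_SECOND
    if phi > _CUTOFFS[3]:
        return DEGREE_THIRD
    return DEGREE_UNRELATED


def kinship_pair(matrix: GenotypeMatrix, sid_i: str, sid_j: str) -> KinshipResult:
    counts = pair_counts(matrix.row(sid_i), matrix.row(sid_j))
    phi = king_phi(counts)
    return KinshipResult(pair=(sid_i, sid_j), counts=counts, phi=phi,
                         degree=classify_degree(phi))


def kinship_matrix(
    matrix: GenotypeMatrix, autosomes_only: bool = False
) -> list[KinshipResult]:
    """All unordered pairs plus the self-kinship diagonal, in id order.

    ``autosomes_only`` drops sex chromosomes and mitochondria before
    counting (hemizygous male X would otherwise deflate het counts).
    """
    if matrix.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    if autosomes_only:
        from .xregion import normalize_contig

        keep = np.array(
            [normalize_contig(k[0]) not in ("X", "Y", "MT") for k in matrix.site_keys]
        )
        matrix = GenotypeMatrix(
            sample_ids=list(matrix.sample_ids),
            site_keys=[k for k, f in zip(matrix.site_keys, keep) if f],
            codes=matrix.codes[:, keep].copy(),
        )
    ids = sorted(matrix.sample_ids)
    results = []
    for a in range(len(ids)):
        for b in range(a, len(ids)):
            results.append(kinship_pair(matrix, ids[a], ids[b]))
    return results


def phi_square_table(results: list[KinshipResult]) -> "pd.DataFrame":
    """Square phi matrix (pandas) for heatmap output; NaN where undefined."""
    import pandas as pd

    ids = sorted({s for r in results for s in r.pair})
    table = pd.DataFrame(np.nan, index=ids, columns=ids)
    for r in results:
        i, j = r.pair
        val = np.nan if r.phi is None else r.phi
        table.loc[i, j] = val
        table.loc[j, i] = val
    return table


def write_kinship_tsv(results: list[KinshipResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_i\tsample_j\tn_obs\tn_AaAa\tn_AAaa\tn_Aa_i\tn_Aa_j\tphi\tdegree\n"
        )
        for r in results:
            c = r.counts
            phi = "" if r.phi is None else f"{r.phi:.6f}"
            fh.write(
                f"{r.pair[0]}\t{r.pair[1]}\t{c.n_obs}\t{c.n_AaAa}\t{c.n_AAaa}\t"
                f"{c.n_Aa_i}\t{c.n_Aa_j}\t{phi}\t{r.degree}\n"
            )
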