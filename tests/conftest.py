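import importlib.resources as ir

import numpy as np
import pytest

from xhetkin.vcf_model import MISSING, GenotypeCall


@pytest.fixture(scope="session")
def toy12_path() -> str:
    """The 12-variant single-sample chrX fixture shipped with the package."""
    return str(ir.files("xhetkin.data") / "toy12.vcf")


def make_call(a, b=..., ad=None, dp=None, gq=None, phased=False, vaf=None):
    """Terse GenotypeCall builder: make_call(0, 1, ad=(10, 10), dp=20)."""
    alleles = (a,) if b is ... else (a, b)
    return GenotypeCall(alleles=alleles, phased=phased, depth=dp,
                        allele_depths=tuple(ad) if ad else None,
                        quality=gq, vaf=vaf)


def brute_force_king(codes_i, codes_j):
    """Independent per-site loop for the robust kinship estimator.

    Returns (n_AaAa, n_AAaa, n_Aa_i, n_Aa_j, n_obs, phi) using only scalar
    arithmetic; the implementation under test is vectorized.
    """
    n_AaAa = n_AAaa = het_i = het_j = n_obs = 0
    for a, b in zip(codes_i, codes_j):
        if a == MISSING or b == MISSING:
            continue
        n_obs += 1
        if a == 1:
            het_i += 1
        if b == 1:
            het_j += 1
        if a == 1 and b == 1:
            n_AaAa += 1
        if (a == 0 and b == 2) or (a == 2 and b == 0):
            n_AAaa += 1
    denom = het_i + het_j
    phi = None if denom == 0 else (n_AaAa - 2 * n_AAaa) / denom
    return n_AaAa, n_AAaa, het_i, het_j, n_obs, phi


def random_code_matrix(rng: np.random.Generator, n_samples: int, n_sites: int,
                       miss_rate: float = 0.1) -> np.ndarray:
    codes = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    codes[rng.random((n_samples, n_sites)) < miss_rate] = MISSING
    return codes
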