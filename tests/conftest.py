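"""Shared fixtures: simulated herds at two scales, reused across modules.

The session-scoped "study" fixture is the workhorse: ~300 genotyped animals
in 11 half-sib sire families with a realized 5,000-SNP GRM, large enough
for variance-component estimation to be informative while staying fast.
"""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings

from rumherit.greml import eigen_prepare
from rumherit.grm import compute_grm
from rumherit.plink import GenotypeMatrix, SNPRecord
from rumherit.simulate import HerdDesign, simulate_genotypes

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """297 genotyped animals, 11 half-sib families of 27, 5,000 SNPs."""
    fams = tuple((f"F{i:02d}", 27) for i in range(11))
    design = HerdDesign(
        n_animals=297, n_genotyped=297, families=fams, n_snps=5000,
        missing_rate=0.0, seed=11,
    )
    g, pedigree = simulate_genotypes(design)
    grm = compute_grm(g)
    return SimpleNamespace(
        design=design, genotypes=g, pedigree=pedigree, grm=grm,
        eig=eigen_prepare(grm),
    )


@pytest.fixture(scope="session")
def herd100():
    """100 genotyped animals with a few families — for mid-size checks."""
    fams = (("F1", 10), ("F2", 8), ("F3", 6), ("F4", 4))
    design = HerdDesign(
        n_animals=100, n_genotyped=100, families=fams, n_snps=3000,
        missing_rate=0.0, seed=5,
    )
    g, pedigree = simulate_genotypes(design)
    grm = compute_grm(g)
    return SimpleNamespace(
        design=design, genotypes=g, pedigree=pedigree, grm=grm,
        eig=eigen_prepare(grm),
    )


def make_genotypes(calls, prefix="a"):
    """GenotypeMatrix from a raw int call array (helper for hand fixtures)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        [f"F{i}" for i in range(n)],
        [f"{prefix}{i}" for i in range(n)],
        [("0", "0", "2", "-9")] * n,
        [SNPRecord(f"s{i + 1}", "1", 0.0, 1000 * (i + 1)) for i in range(m)],
        calls,
    )


@pytest.fixture
def geno_builder():
    return make_genotypes
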