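from __future__ import annotations

import numpy as np
import pytest

from runscan.genotype import MISSING, GenotypeMatrix, SnpRecord


def make_gm(
    dosage,
    positions=None,
    chromosome="1",
    population="POP",
    spacing_bp=50_000,
    chromosomes=None,
):
    """Build a small GenotypeMatrix from a dosage array.

    ``dosage`` is (n_individuals, n_snps); positions default to a regular
    grid.  ``chromosomes`` optionally gives a per-SNP chromosome label list.
    """
    dosage = np.asarray(dosage, dtype=np.int8)
    if dosage.ndim == 1:
        dosage = dosage[None, :]
    n_ind, n_snps = dosage.shape
    if chromosomes is None:
        chromosomes = [chromosome] * n_snps
    if positions is None:
        positions = []
        counters: dict[str, int] = {}
        for c in chromosomes:
            counters[c] = counters.get(c, 0) + 1
            positions.append(counters[c] * spacing_bp)
    snps = [
        SnpRecord(chromosome=str(c), snp_id=f"snp_{c}_{p}", position_bp=int(p))
        for c, p in zip(chromosomes, positions)
    ]
    return GenotypeMatrix(
        individual_ids=[f"ind{i}" for i in range(n_ind)],
        population_labels=[population] * n_ind,
        snps=snps,
        dosage=dosage,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_gm(rng):
    """50 x 100 random panel with all dosage states present per SNP."""
    while True:
        dosage = rng.integers(-1, 3, size=(50, 100)).astype(np.int8)
        # ensure both alleles observed at every SNP so PLINK round-trip is exact
        ok = all(
            (dosage[:, j] == 0).any() or (dosage[:, j] == 1).any()
            for j in range(100)
        ) and all(
            (dosage[:, j] == 2).any() or (dosage[:, j] == 1).any()
            for j in range(100)
        )
        if ok:
            break
    chromosomes = ["1"] * 50 + ["2"] * 50
    return make_gm(dosage, chromosomes=chromosomes, population="POPX")
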