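"""Shared fixtures: a hand-checkable painting example, a random-dataset
builder, and an independent brute-force painter used as the oracle."""

from __future__ import annotations

import numpy as np
import pytest

from radpaint import HaplotypeDataset, Locus

BASES = "ACGT"


@pytest.fixture
def four_diploids() -> HaplotypeDataset:
    """Four diploid individuals at one 4-SNP locus.

    ind1 carries {ACTG, ATTT}; ind2 {ACTG, ATTG}; ind3 {ATTT, ACTT};
    ind4 {ATTT, CCTT}.  Every nearest-neighbour relationship is checkable
    by hand: ind1's ACTG has the unique identical donor ind2; ind1's ATTT
    has two identical donors (ind3, ind4); ind2's ATTG has no identical
    relative and ties with the four alleles one SNP away (two of which
    belong to ind1); CCTT in ind4 is an outlier haplotype.
    """
    cells = (
        ("ACTG", "ATTT"),
        ("ACTG", "ATTG"),
        ("ATTT", "ACTT"),
        ("ATTT", "CCTT"),
    )
    return HaplotypeDataset(
        ["ind1", "ind2", "ind3", "ind4"], [Locus("L1", cells)]
    )


def random_dataset(
    rng: np.random.Generator,
    n_individuals: int = 5,
    n_loci: int = 6,
    max_snps: int = 5,
    max_ploidy: int = 2,
    missing_rate: float = 0.0,
    n_rate: float = 0.0,
) -> HaplotypeDataset:
    """Random dataset with per-individual ploidy and optional missing/N data.

    Guarantees every locus keeps at least one non-missing cell and every
    individual at least one non-missing locus.
    """
    ploidy = [int(rng.integers(1, max_ploidy + 1)) for _ in range(n_individuals)]
    loci = []
    for l in range(n_loci):
        snps = int(rng.integers(1, max_snps + 1))
        while True:
            cells = []
            for k in range(n_individuals):
                if rng.random() < missing_rate:
                    cells.append(None)
                    continue
                alleles = []
                for _ in range(ploidy[k]):
                    seq = "".join(
                        "N" if rng.random() < n_rate
                        else BASES[rng.integers(0, 4)]
                        for _ in range(snps)
                    )
                    alleles.append(seq)
                cells.append(tuple(alleles))
            if any(c is not None for c in cells):
                break
        loci.append(Locus(f"L{l + 1}", tuple(cells)))
    # ensure nobody is missing everywhere: give such individuals locus 0
    for k in range(n_individuals):
        if all(locus.cells[k] is None for locus in loci):
            cells = list(loci[0].cells)
            snps = loci[0].snp_count
            cells[k] = tuple(
                "".join(BASES[rng.integers(0, 4)] for _ in range(snps))
                for _ in range(ploidy[k])
            )
            loci[0] = Locus(loci[0].locus_id, tuple(cells))
    return HaplotypeDataset(
        [f"i{k + 1}" for k in range(n_individuals)], loci, ploidy
    )


def oracle_paint(dataset: HaplotypeDataset) -> np.ndarray:
    """Brute-force nearest-neighbour painting, written independently.

    Enumerates every recipient-allele / donor-allele pair with plain
    Python loops, splits ties equally, applies the pairwise co-presence
    rate rule for missing data (with pool-size normalisation), and scales
    rows to sum to the number of loci.
    """
    n = dataset.n_individuals
    L = dataset.n_loci
    weight_sum = [[0.0] * n for _ in range(n)]
    overlap = [[0] * n for _ in range(n)]

    for locus in dataset.loci:
        present = []
        for k, cell in enumerate(locus.cells):
            if cell is None:
                continue
            if all(all(ch == "N" for ch in a) for a in cell):
                continue
            present.append(k)
        for rec in present:
            # usable recipient alleles: at least one comparable donor allele
            usable = []
            for allele in locus.cells[rec]:
                found = False
                for don in present:
                    if don == rec:
                        continue
                    for dallele in locus.cells[don]:
                        comp = sum(
                            1
                            for a, b in zip(allele, dallele)
                            if a != "N" and b != "N"
                        )
                        if comp >= 1:
                            found = True
                if found:
                    usable.append(allele)
            if not usable:
                continue
            pool = len(present) - 1
            for j in present:
                if j != rec:
                    overlap[rec][j] += 1
            for allele in usable:
                dists = {}
                for don in present:
                    if don == rec:
                        continue
                    for di, dallele in enumerate(locus.cells[don]):
                        comp = diff = 0
                        for a, b in zip(allele, dallele):
                            if a != "N" and b != "N":
                                comp += 1
                                if a != b:
                                    diff += 1
                        if comp >= 1:
                            dists[(don, di)] = diff
                if not dists:
                    continue
                best = min(dists.values())
                tied = [key for key, d in dists.items() if d == best]
                for don, _ in tied:
                    weight_sum[rec][don] += (
                        pool / (len(usable) * len(tied))
                    )

    rates = [
        [
            weight_sum[i][j] / overlap[i][j] if overlap[i][j] else 0.0
            for j in range(n)
        ]
        for i in range(n)
    ]
    x = np.zeros((n, n))
    for i in range(n):
        total = sum(rates[i])
        if total <= 0:
            raise ValueError(f"individual {i} unpaintable everywhere")
        for j in range(n):
            x[i, j] = L * rates[i][j] / total
    return x
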