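"""Synthetic RAD haplotype datasets with known population structure.

The generative model is a two-level star phylogeny per locus: a random
root haplotype mutates once per population (at the between-population
divergence rate) and each allele copy of each individual mutates from its
population's haplotype (at the within-population diversity rate).  Every
locus draws independently, so the simulated loci are statistically
independent — linkage is introduced only explicitly, by duplicating loci.

Three missingness mechanisms, separately switchable, emulate the failure
modes of real reduced-representation data:

* ``missing_rate`` — uniform random cell dropout (sequencing depth);
* batch structure — each library batch fails to recover its own set of
  loci (the size-selection batch effect of ddRAD data);
* ``dropout_rate`` — population-correlated whole-population locus loss
  (allele dropout from restriction-site polymorphism).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import HaplotypeDataset, Locus

__all__ = ["SimConfig", "simulate", "duplicate_and_shuffle"]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the island-model haplotype simulator.

    Rates are per-site substitution probabilities; all rates live in
    [0, 1].  ``n_batches > 0`` splits individuals round-robin into
    library batches, each of which loses a disjoint random fraction
    ``batch_missing_frac`` of loci entirely.  ``seed`` is mandatory —
    every simulation is reproducible.
    """

    n_pops: int = 2
    n_per_pop: int = 10
    n_loci: int = 1000
    snps_per_locus: int = 5
    divergence: float = 0.1
    diversity: float = 0.2
    ploidy: int = 2
    missing_rate: float = 0.0
    n_batches: int = 0
    batch_missing_frac: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pops < 1 or self.n_per_pop < 1 or self.n_loci < 1:
            raise ValueError("counts must be positive")
        if self.snps_per_locus < 1 or self.ploidy < 1:
            raise ValueError("snps_per_locus and ploidy must be >= 1")
        for name in (
            "divergence",
            "diversity",
            "missing_rate",
            "batch_missing_frac",
            "dropout_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_batches < 0:
            raise ValueError("n_batches must be >= 0")
        if self.n_batches * self.batch_missing_frac > 1.0:
            raise ValueError(
                "disjoint batch locus sets need "
                "n_batches * batch_missing_frac <= 1"
            )


def _mutate(hap: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    out = hap.copy()
    hit = rng.random(hap.shape) < rate
    if hit.any():
        # uniform among the three other bases via an offset of 1..3 mod 4
        offsets = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + offsets) % 4
    return out


def simulate(config: SimConfig) -> tuple[HaplotypeDataset, list[int]]:
    """Draw a dataset; returns it with the true population label of each
    individual (labels ``0 .. n_pops-1`` in individual order)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pops * config.n_per_pop
    truth = [k // config.n_per_pop for k in range(n)]
    ids = [
        f"pop{truth[k] + 1}_ind{k % config.n_per_pop + 1}" for k in range(n)
    ]

    # batch membership (round-robin, cross-cutting populations) and the
    # disjoint locus set each batch fails to recover
    batch_of = None
    batch_loci: list[set[int]] = []
    if config.n_batches > 0 and config.batch_missing_frac > 0.0:
        batch_of = [k % config.n_batches for k in range(n)]
        per_batch = int(round(config.batch_missing_frac * config.n_loci))
        pool = rng.permutation(config.n_loci)
        for b in range(config.n_batches):
            batch_loci.append(set(pool[b * per_batch : (b + 1) * per_batch]))

    loci: list[Locus] = []
    for l in range(config.n_loci):
        root = rng.integers(0, 4, size=config.snps_per_locus)
        pop_haps = [
            _mutate(root, config.divergence, rng) for _ in range(config.n_pops)
        ]
        dropped_pops = set(
            np.nonzero(rng.random(config.n_pops) < config.dropout_rate)[0]
        )
        cells: list[tuple[str, ...] | None] = []
        for k in range(n):
            pop = truth[k]
            alleles = tuple(
                "".join(_BASES[_mutate(pop_haps[pop], config.diversity, rng)])
                for _ in range(config.ploidy)
            )
            cell: tuple[str, ...] | None = alleles
            if pop in dropped_pops:
                cell = None
            if batch_of is not None and l in batch_loci[batch_of[k]]:
                cell = None
            if cell is not None and rng.random() < config.missing_rate:
                cell = None
            cells.append(cell)
        if all(c is None for c in cells):
            continue  # a locus nobody recovered would never be in the table
        loci.append(Locus(f"L{l + 1}", tuple(cells)))

    dataset = HaplotypeDataset(ids, loci, [config.ploidy] * n)
    return dataset, truth


def duplicate_and_shuffle(
    dataset: HaplotypeDataset, seed: int
) -> HaplotypeDataset:
    """Duplicate every locus and scatter the copies at random positions.

    The result has ``2 L`` loci: the originals in their original relative
    order, plus one exact copy of each (id suffixed ``_dup``) inserted at a
    uniformly random position.  Painting is locus-order invariant, so the
    painting of the result is exactly twice that of the input; only the
    jackknife (and hence c) reacts to where the copies land.
    """
    rng = np.random.default_rng(seed)
    out: list[Locus] = list(dataset.loci)
    for locus in dataset.loci:
        copy = Locus(locus.locus_id + "_dup", locus.cells)
        pos = int(rng.integers(0, len(out) + 1))
        out.insert(pos, copy)
    return HaplotypeDataset(
        list(dataset.individual_ids), out, list(dataset.ploidy)
    )
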