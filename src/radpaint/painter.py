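"""Nearest-neighbour haplotype coancestry painting.

For every locus and every individual (the *recipient*), each of the
recipient's alleles looks for its closest relatives among the alleles of
all other individuals: the candidate donor allele(s) with the fewest
sequence differences.  One unit of coancestry per locus is shared out as

* ``1 / ploidy`` per recipient allele (coancestry is averaged across the
  allele copies an individual carries), and
* an equal fraction of that mass to each equally-distant nearest
  neighbour allele, accumulated onto the *individual* carrying it.

Summing over loci gives the coancestry matrix ``x``: ``x[i, j]`` is the
amount of nearest-neighbour coancestry recipient ``i`` received from
donor ``j``.  Missing data are handled pairwise: the coancestry of a
pair at loci where either member is missing is taken to be proportional
to the coancestry observed between them at the loci where both are
present.  Concretely, each pair's summed weight is converted to a rate
per co-present locus, and each recipient row of rates is then scaled to
sum to the total number of loci.  With no missing data this reduces to
the plain sum; with batch-structured missingness it avoids crediting
same-batch donors merely for being co-observed more often.  The matrix
is generally asymmetric — row sums are fixed by construction, column
sums measure how often an individual is anyone's closest relative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import HaplotypeDataset, Locus

__all__ = [
    "CoancestryMatrix",
    "RECIPIENT_MISSING",
    "hamming_excluding_N",
    "paint_locus",
    "paint",
    "paint_contributions",
    "read_chunks",
]

#: Returned by :func:`paint_locus` when the recipient has no usable allele
#: or no comparable donor at the locus.
RECIPIENT_MISSING = None

_BASE_N = ord("N")


@dataclass
class CoancestryMatrix:
    """Recipient-by-donor coancestry counts.

    Attributes
    ----------
    individual_ids
        Names, in matrix order (rows = recipients, columns = donors).
    x
        Square non-negative array; ``x[i, j]`` is coancestry received by
        ``i`` from ``j``.  The diagonal is structurally zero and every row
        sums to ``n_loci``.
    n_loci
        Number of loci painted (the row total, N).
    missing_counts
        Per recipient, the number of loci that contributed nothing
        directly (missing recipient cell or no comparable donor) and whose
        share was redistributed proportionally.
    """

    individual_ids: list[str]
    x: np.ndarray
    n_loci: int
    missing_counts: np.ndarray

    @property
    def p(self) -> np.ndarray:
        """Empirical nearest-neighbour probabilities ``x / n_loci``."""
        return self.x / self.n_loci

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.x, index=self.individual_ids, columns=self.individual_ids
        )

    def write_chunks(self, path: str | Path, c: float | None = None) -> None:
        """Write the tab-separated "chunks" file, optionally with a
        ``#Cfactor`` header carrying the variance-normalisation constant."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as out:
            if c is not None:
                out.write(f"#Cfactor {c:.6f}\n")
            out.write("Recipient\t" + "\t".join(self.individual_ids) + "\n")
            for name, row in zip(self.individual_ids, self.x):
                out.write(
                    name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n"
                )


def read_chunks(path: str | Path) -> tuple[CoancestryMatrix, float | None]:
    """Read a chunks file back; returns the matrix and the stored c (if any)."""
    path = Path(path)
    c: float | None = None
    with path.open("r", encoding="utf-8") as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if lines and lines[0].startswith("#Cfactor"):
        c = float(lines[0].split()[1])
        lines = lines[1:]
    header = lines[0].split("\t")
    ids = header[1:]
    x = np.array(
        [[float(v) for v in ln.split("\t")[1:]] for ln in lines[1:]]
    )
    n_loci = int(round(x.sum(axis=1).mean()))
    return (
        CoancestryMatrix(ids, x, n_loci, np.zeros(len(ids), dtype=int)),
        c,
    )


def hamming_excluding_N(a: str, b: str) -> tuple[int, int]:
    """Count differences between equal-length alleles, skipping N positions.

    Returns ``(diff_count, compared_sites)``: the number of positions where
    the alleles disagree and neither is ``N``, and the number of positions
    where neither is ``N`` at all.
    """
    if len(a) != len(b):
        raise ValueError(
            f"allele length mismatch: {len(a)} vs {len(b)}"
        )
    diff = comp = 0
    for ca, cb in zip(a, b):
        if ca == "N" or cb == "N":
            continue
        comp += 1
        if ca != cb:
            diff += 1
    return diff, comp


def _locus_arrays(locus: Locus) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a locus into (sequence bytes, N-mask, owner index) arrays."""
    seqs: list[str] = []
    owners: list[int] = []
    for k, cell in enumerate(locus.cells):
        if cell is None:
            continue
        for allele in cell:
            seqs.append(allele)
            owners.append(k)
    if not seqs:
        return (
            np.empty((0, 0), dtype=np.uint8),
            np.empty((0, 0), dtype=bool),
            np.empty(0, dtype=np.intp),
        )
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(seqs), -1)
    mask = arr != _BASE_N
    return arr, mask, np.asarray(owners, dtype=np.intp)


def _paint_locus_all(locus: Locus, n_individuals: int) -> tuple[np.ndarray, np.ndarray]:
    """Paint one locus for every recipient at once.

    Returns ``(W, missing)``: ``W`` is an ``n x n`` array of donor weights
    (each non-missing recipient row sums to 1, diagonal 0) and ``missing``
    flags recipients that could not be painted at this locus.
    """
    arr, mask, owners = _locus_arrays(locus)
    n = n_individuals
    A = owners.size
    W = np.zeros((n, n))
    missing = np.ones(n, dtype=bool)
    if A == 0:
        return W, missing

    # pairwise allele distances with N positions ignored
    both = mask[:, None, :] & mask[None, :, :]
    diff = ((arr[:, None, :] != arr[None, :, :]) & both).sum(axis=2)
    comp = both.sum(axis=2)

    # candidate donors: alleles of other individuals with >=1 comparable site
    cand = (owners[:, None] != owners[None, :]) & (comp >= 1)
    big = arr.shape[1] + 1  # larger than any real distance
    d = np.where(cand, diff, big)
    best = d.min(axis=1)
    usable = best < big  # allele has at least one comparable donor

    # an unusable allele (all-N, or nothing comparable) passes its share to
    # the recipient's remaining usable alleles: weight 1/n_usable each
    n_usable = np.bincount(owners[usable], minlength=n)
    missing = n_usable == 0
    share = np.zeros(A)
    share[usable] = 1.0 / n_usable[owners[usable]]

    tied = (d == best[:, None]) & cand
    tcount = tied.sum(axis=1)
    tcount[~usable] = 1  # avoid division by zero; share is 0 there anyway
    M = tied * (share / tcount)[:, None]

    onehot = np.zeros((A, n))
    onehot[np.arange(A), owners] = 1.0
    W = onehot.T @ M @ onehot
    return W, missing


def paint_locus(
    locus: Locus, recipient: int, n_individuals: int | None = None
):
    """Donor weights for one recipient at one locus.

    Returns a length-``n`` weight vector summing to 1, or
    :data:`RECIPIENT_MISSING` when the recipient's cell is missing, all its
    alleles are uninformative (all-N), or no other individual carries a
    comparable allele.  Recipient alleles that cannot be compared to any
    candidate pass their share to the recipient's remaining alleles, so the
    weight of each usable allele is ``1 / n_usable``.
    """
    if n_individuals is None:
        n_individuals = len(locus.cells)
    if locus.cells[recipient] is None:
        return RECIPIENT_MISSING
    W, missing = _paint_locus_all(locus, n_individuals)
    if missing[recipient]:
        return RECIPIENT_MISSING
    return W[recipient]


def paint_contributions(
    dataset: HaplotypeDataset,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus painting contributions, before any missing-data handling.

    Returns ``(C, copresent, missing)``: ``C`` has shape ``(n_loci, n, n)``
    and holds, per locus, each recipient's donor weights multiplied by the
    number of candidate donors available to that recipient at that locus —
    i.e. the *enrichment* of each donor over the uniform expectation given
    the locus's donor pool.  With complete data the pool is constant and
    the factor cancels in the final row normalisation; at loci with absent
    donors it stops the shrunken pool from inflating the apparent rates of
    the pairs that remain.  ``copresent`` (same shape, boolean) marks, per
    locus, the recipient/donor pairs where the recipient was paintable and
    the donor carried at least one usable allele; ``missing`` has shape
    ``(n_loci, n)``.  :func:`paint` and the block jackknife both consume
    this, so leave-block-out matrices never require re-painting.
    """
    n = dataset.n_individuals
    L = dataset.n_loci
    C = np.zeros((L, n, n))
    copresent = np.zeros((L, n, n), dtype=bool)
    missing = np.zeros((L, n), dtype=bool)
    diag = np.eye(n, dtype=bool)
    for l, locus in enumerate(dataset.loci):
        W, miss = _paint_locus_all(locus, n)
        present = np.zeros(n, dtype=bool)
        for k, cell in enumerate(locus.cells):
            if cell is not None and any(set(a) != {"N"} for a in cell):
                present[k] = True
        # candidate-donor pool size seen by each recipient at this locus
        pool = present.sum() - present.astype(int)
        C[l] = W * pool[:, None]
        missing[l] = miss
        copresent[l] = (~miss)[:, None] & present[None, :] & ~diag
    return C, copresent, missing


def _assemble(
    C_sum: np.ndarray,
    overlap: np.ndarray,
    miss_counts: np.ndarray,
    n_loci: int,
    ids: list[str],
) -> CoancestryMatrix:
    """Pairwise-rate missing-data correction, then rows scaled to ``n_loci``.

    ``overlap[i, j]`` counts loci at which the pair was co-observed; the
    coancestry rate per co-present locus is extrapolated to the full locus
    set and each row normalised to sum to ``n_loci``, so a pair's unseen
    loci are credited in proportion to what was observed between them.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(overlap > 0, C_sum / np.maximum(overlap, 1), 0.0)
    np.fill_diagonal(rate, 0.0)
    row = rate.sum(axis=1)
    if np.any(row <= 0):
        bad = [ids[k] for k in np.nonzero(row <= 0)[0]]
        raise ValueError(
            f"individual(s) {bad} unpaintable at every locus; cannot "
            "redistribute missing coancestry"
        )
    x = n_loci * rate / row[:, None]
    return CoancestryMatrix(list(ids), x, n_loci, miss_counts.copy())


def paint(dataset: HaplotypeDataset) -> CoancestryMatrix:
    """Compute the coancestry matrix for a dataset.

    Missing data are credited pairwise, in proportion to the coancestry
    observed between the pair at their co-present loci; every row of the
    result sums to the number of loci exactly.  Raises if some individual
    is unpaintable at every locus.
    """
    if dataset.n_individuals < 2:
        raise ValueError("painting needs at least two individuals")
    if dataset.n_loci < 1:
        raise ValueError("painting needs at least one locus")
    C, copresent, missing = paint_contributions(dataset)
    return _assemble(
        C.sum(axis=0),
        copresent.sum(axis=0),
        missing.sum(axis=0),
        dataset.n_loci,
        dataset.individual_ids,
    )
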