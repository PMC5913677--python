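"""Variance-normalisation constant *c* via a delete-block jackknife.

Treating each locus as an independent draw, an entry of the coancestry
matrix would follow ``x_ij ~ Binomial(N, p_ij)`` with ``p_ij = x_ij / N``,
giving theoretical variance ``N * p_ij * (1 - p_ij)``.  Real data deviate
in both directions: linkage between nearby loci inflates the true
sampling variance, while tie-splitting and the averaging of coancestry
across allele copies deflate it.  The constant

    c = mean over off-diagonal entries of  VE_ij / Vtheory_ij

where VE is the empirical variance from a delete-block jackknife over
consecutive loci (default block of 100), rescales the matrix before
clustering so that the multinomial likelihood sees ``N / c`` effectively
independent loci.  When loci in strong LD are scattered rather than
adjacent the jackknife cannot see the correlation and *c* comes out too
small — hence the LD reordering step for unmapped data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HaplotypeDataset
from .painter import paint_contributions

__all__ = ["CValueReport", "jackknife_variance", "estimate_c"]


@dataclass
class CValueReport:
    """Result of estimating c for one dataset."""

    c: float
    block_size: int
    n_blocks: int
    VE: np.ndarray
    Vtheory: np.ndarray
    entries_used: int
    x: np.ndarray
    n_loci: int
    summary: str = "mean"

    @property
    def n_effective(self) -> float:
        """Effective number of independent loci, N / c."""
        return self.n_loci / self.c


def _blocks(n_loci: int, block_size: int) -> list[np.ndarray]:
    edges = list(range(0, n_loci, block_size)) + [n_loci]
    return [np.arange(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _leave_block_out_matrices(
    C: np.ndarray, copresent: np.ndarray, block_size: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """All leave-one-block-out coancestry matrices, rescaled to full-N rows.

    Returns ``(X, weights, n_blocks)`` where ``X[b]`` is the painting of
    all loci outside block ``b`` brought back onto the full-``N`` row
    scale (same pairwise missing-data handling as the full painting), and
    ``weights`` are jackknife weights proportional to block size and
    normalised to sum to ``n_blocks``.
    """
    from .painter import _assemble

    L, n, _ = C.shape
    blocks = _blocks(L, block_size)
    n_blocks = len(blocks)
    if n_blocks < 2:
        raise ValueError(
            f"only {n_blocks} jackknife block(s) for {L} loci at block size "
            f"{block_size}; use a smaller block size"
        )
    total = C.sum(axis=0)
    overlap_total = copresent.sum(axis=0)
    X = np.empty((n_blocks, n, n))
    sizes = np.array([len(b) for b in blocks], dtype=float)
    ids = [str(k) for k in range(n)]
    for bi, block in enumerate(blocks):
        part = total - C[block].sum(axis=0)
        overlap = overlap_total - copresent[block].sum(axis=0)
        X[bi] = _assemble(
            part, overlap, np.zeros(n, dtype=int), L, ids
        ).x
    weights = n_blocks * sizes / sizes.sum()
    return X, weights, n_blocks


def _jackknife_ve(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    n_blocks = X.shape[0]
    mean = np.tensordot(weights, X, axes=1) / n_blocks
    dev2 = (X - mean) ** 2
    return (n_blocks - 1) / n_blocks * np.tensordot(weights, dev2, axes=1)


def jackknife_variance(
    dataset: HaplotypeDataset, block_size: int = 100
) -> tuple[np.ndarray, int]:
    """Empirical per-entry variance of the coancestry matrix.

    Loci are split, in their current order, into consecutive blocks of
    ``block_size`` (a short final block is kept and weighted by its size).
    Each leave-block-out painting is rescaled to full-``N`` rows and

        VE = (n_b - 1) / n_b * sum_b w_b * (x^(-b) - x_bar)^2

    with weights ``w_b`` proportional to block size (sum ``n_b``).
    """
    C, copresent, _ = paint_contributions(dataset)
    X, weights, n_blocks = _leave_block_out_matrices(C, copresent, block_size)
    return _jackknife_ve(X, weights), n_blocks


def estimate_c(
    dataset: HaplotypeDataset,
    block_size: int = 100,
    summary: str = "mean",
) -> CValueReport:
    """Estimate the variance-normalisation constant c.

    ``summary`` pools the per-entry ratios ``VE / Vtheory`` over
    off-diagonal entries with ``0 < p_ij < 1``; ``"mean"`` (default) or
    ``"median"``.
    """
    C, copresent, missing = paint_contributions(dataset)
    return _estimate_c_from_contributions(
        C, copresent, missing, dataset.n_loci, block_size, summary
    )


def _estimate_c_from_contributions(
    C: np.ndarray,
    copresent: np.ndarray,
    missing: np.ndarray,
    n_loci: int,
    block_size: int = 100,
    summary: str = "mean",
) -> CValueReport:
    from .painter import _assemble

    if summary not in {"mean", "median"}:
        raise ValueError("summary must be 'mean' or 'median'")
    X, weights, n_blocks = _leave_block_out_matrices(C, copresent, block_size)
    VE = _jackknife_ve(X, weights)

    n = C.shape[1]
    x = _assemble(
        C.sum(axis=0), copresent.sum(axis=0), missing.sum(axis=0),
        n_loci, [str(k) for k in range(n)],
    ).x

    p = x / n_loci
    Vtheory = n_loci * p * (1.0 - p)
    offdiag = ~np.eye(n, dtype=bool)
    use = offdiag & (Vtheory > 0.0)
    if not use.any():
        raise RuntimeError(
            "no off-diagonal entries with 0 < p < 1; cannot estimate c"
        )
    ratios = VE[use] / Vtheory[use]
    c = float(np.mean(ratios) if summary == "mean" else np.median(ratios))
    return CValueReport(
        c=c,
        block_size=block_size,
        n_blocks=n_blocks,
        VE=VE,
        Vtheory=Vtheory,
        entries_used=int(use.sum()),
        x=x,
        n_loci=n_loci,
        summary=summary,
    )
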