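"""Reading, writing and filtering of RAD haplotype matrices.

The canonical on-disk format is a flat, tab-separated text file:

* line 1: individual names (one column per individual);
* every further line: a locus identifier followed by one cell per
  individual; within a cell the individual's alleles (one per haploid
  genome copy) are joined by ``/``; an empty cell means the locus was
  not recovered in that individual.

Each allele is the concatenation of the bases observed at the variable
sites (SNPs) of the locus, so all alleles at one locus share a common
length, the locus's SNP count.  ``N`` marks an unknown base within an
otherwise called allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "HaplotypeDataset",
    "MissingnessReport",
    "ConversionLog",
    "HaplotypeFormatError",
    "read_haplotype_matrix",
    "write_haplotype_matrix",
    "convert_stacks",
    "missingness",
    "missingness_pca",
]

_ALPHABET = frozenset("ACGTN")
_MISSING_TOKENS = frozenset({"", "-", "."})


class HaplotypeFormatError(ValueError):
    """Raised when an input table violates the haplotype-matrix format."""


@dataclass(frozen=True)
class Locus:
    """One RAD locus: an id plus one allele list (or ``None``) per individual."""

    locus_id: str
    cells: tuple[tuple[str, ...] | None, ...]

    @property
    def snp_count(self) -> int:
        for cell in self.cells:
            if cell is not None:
                return len(cell[0])
        raise HaplotypeFormatError(
            f"locus {self.locus_id!r} has no non-missing cell"
        )


@dataclass
class HaplotypeDataset:
    """An ordered collection of RAD loci typed in a fixed panel of individuals.

    ``ploidy[k]`` is the number of allele copies individual ``k`` carries in
    every non-missing cell; ploidy may differ between individuals but is
    constant across loci within an individual.
    """

    individual_ids: list[str]
    loci: list[Locus]
    ploidy: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ploidy:
            self.ploidy = _infer_ploidy(self.individual_ids, self.loci)
        self.validate()

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def validate(self) -> None:
        n = self.n_individuals
        if len(set(self.individual_ids)) != n:
            raise HaplotypeFormatError("duplicate individual names")
        for locus in self.loci:
            if len(locus.cells) != n:
                raise HaplotypeFormatError(
                    f"locus {locus.locus_id!r} has {len(locus.cells)} cells "
                    f"for {n} individuals"
                )
            length = None
            for k, cell in enumerate(locus.cells):
                if cell is None:
                    continue
                for allele in cell:
                    if length is None:
                        length = len(allele)
                    if len(allele) != length:
                        raise HaplotypeFormatError(
                            f"locus {locus.locus_id!r}: alleles of unequal "
                            f"length in or across cells"
                        )
                    if not set(allele) <= _ALPHABET:
                        bad = sorted(set(allele) - _ALPHABET)
                        raise HaplotypeFormatError(
                            f"locus {locus.locus_id!r}: characters {bad} "
                            "outside the A/C/G/T/N alphabet"
                        )
                if len(cell) != self.ploidy[k]:
                    raise HaplotypeFormatError(
                        f"locus {locus.locus_id!r}: individual "
                        f"{self.individual_ids[k]!r} has {len(cell)} alleles, "
                        f"expected ploidy {self.ploidy[k]}"
                    )
            if length is None:
                raise HaplotypeFormatError(
                    f"locus {locus.locus_id!r} is missing in every individual"
                )

    def subset_loci(self, indices: Sequence[int]) -> "HaplotypeDataset":
        """New dataset restricted to (and reordered by) ``indices``."""
        return HaplotypeDataset(
            individual_ids=list(self.individual_ids),
            loci=[self.loci[i] for i in indices],
            ploidy=list(self.ploidy),
        )

    def subset_individuals(self, keep: Sequence[int]) -> "HaplotypeDataset":
        loci = [
            Locus(l.locus_id, tuple(l.cells[k] for k in keep)) for l in self.loci
        ]
        return HaplotypeDataset(
            individual_ids=[self.individual_ids[k] for k in keep],
            loci=loci,
            ploidy=[self.ploidy[k] for k in keep],
        )


def _infer_ploidy(ids: Sequence[str], loci: Sequence[Locus]) -> list[int]:
    ploidy = [0] * len(ids)
    for locus in loci:
        for k, cell in enumerate(locus.cells):
            if cell is not None and ploidy[k] == 0:
                ploidy[k] = len(cell)
    for k, p in enumerate(ploidy):
        if p == 0:
            # individual missing everywhere; ploidy undefined, painter rejects
            ploidy[k] = 1
    return ploidy


@dataclass(frozen=True)
class MissingnessReport:
    """Fraction of missing cells per individual and per locus."""

    per_individual: pd.Series
    per_locus: pd.Series


@dataclass(frozen=True)
class ConversionLog:
    """Record of what a Stacks conversion removed."""

    removed_samples: list[str]
    removed_loci: list[str]
    dropped_invariant: list[str]


# ---------------------------------------------------------------------------
# flat matrix format


# sentinel cell used by Stacks exports for loci with no variable sites
_CONSENSUS: tuple[str, ...] = ("__CONSENSUS__",)


def _parse_cell(token: str, where: str) -> tuple[str, ...] | None:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    if token.lower() == "consensus":
        return _CONSENSUS
    alleles = tuple(a.upper() for a in token.split("/"))
    for allele in alleles:
        if not allele or not set(allele) <= _ALPHABET:
            raise HaplotypeFormatError(
                f"{where}: cell {token!r} contains characters outside "
                "A/C/G/T/N or an empty allele"
            )
    if len({len(a) for a in alleles}) != 1:
        raise HaplotypeFormatError(
            f"{where}: alleles of unequal length within cell {token!r}"
        )
    return alleles


def _parse_table(
    path: str | Path,
) -> tuple[list[str], list[tuple[str, tuple[tuple[str, ...] | None, ...]]]]:
    """Parse the flat table into (individual names, raw locus rows)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise HaplotypeFormatError(f"{path}: empty file")
    individual_ids = [t.strip() for t in lines[0].split("\t")]
    n = len(individual_ids)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n + 1:
            raise HaplotypeFormatError(
                f"{path}:{lineno}: expected {n + 1} columns, found {len(parts)}"
            )
        locus_id = parts[0].strip()
        where = f"{path}:{lineno} (locus {locus_id!r})"
        cells = tuple(_parse_cell(tok, where) for tok in parts[1:])
        rows.append((locus_id, cells))
    return individual_ids, rows


def read_haplotype_matrix(path: str | Path) -> HaplotypeDataset:
    """Read the flat haplotype-matrix format.

    Empty cells, ``-`` and ``.`` are all accepted as missing so that minor
    dialect drift between exporters is tolerated; lower-case bases are
    upcased.  Raises :class:`HaplotypeFormatError`, naming the offending
    line, on ragged rows, mixed allele lengths or foreign characters.
    """
    individual_ids, rows = _parse_table(path)
    for locus_id, cells in rows:
        if any(cell is _CONSENSUS for cell in cells):
            raise HaplotypeFormatError(
                f"locus {locus_id!r}: 'consensus' calls are a Stacks export "
                "artefact; run convert_stacks instead"
            )
    loci = [Locus(locus_id, cells) for locus_id, cells in rows]
    return HaplotypeDataset(individual_ids=individual_ids, loci=loci)


def write_haplotype_matrix(dataset: HaplotypeDataset, path: str | Path) -> None:
    """Write the canonical flat format (missing cells as empty strings)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as out:
        out.write("\t".join(dataset.individual_ids) + "\n")
        for locus in dataset.loci:
            row = [locus.locus_id]
            for cell in locus.cells:
                row.append("" if cell is None else "/".join(cell))
            out.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Stacks conversion and filtering


def convert_stacks(
    path: str | Path,
    max_sample_missing: float = 0.20,
    max_snps: int = 5,
) -> tuple[HaplotypeDataset, ConversionLog]:
    """Convert a Stacks-style haplotype export and apply the standard filters.

    The input is a tab table of locus rows by sample columns where ``-``,
    ``.`` or an empty cell marks a missing call and ``consensus`` marks an
    invariant locus.  Processing order:

    1. invariant loci (``consensus`` calls, or a single allele sequence
       shared by every non-missing cell) are dropped with a warning —
       they carry no nearest-neighbour information;
    2. samples whose missing fraction is *strictly* greater than
       ``max_sample_missing`` are removed;
    3. missingness is recounted and loci with more than ``max_snps``
       variable sites are removed.

    Homozygous calls exported as a lone haplotype are expanded to the
    sample's full allele count (e.g. ``ACTG`` becomes ``ACTG/ACTG`` for a
    diploid), matching the usual convention of Stacks exports.
    """
    individual_ids, rows = _parse_table(path)

    invariant: list[str] = []
    kept_rows = []
    for locus_id, cells in rows:
        present = [c for c in cells if c is not None]
        alleles = {a for cell in present if cell is not _CONSENSUS for a in cell}
        if (
            not present
            or any(c is _CONSENSUS for c in cells)
            or len(alleles) <= 1
        ):
            invariant.append(locus_id)
        else:
            kept_rows.append((locus_id, cells))
    if invariant:
        warnings.warn(
            f"dropped {len(invariant)} invariant or empty locus/loci: "
            + ", ".join(invariant[:10]),
            stacklevel=2,
        )
    if not kept_rows:
        raise HaplotypeFormatError("no variable loci found in the table")
    data = _expand_homozygotes(individual_ids, kept_rows)

    report = missingness(data)
    keep = [
        k
        for k, name in enumerate(data.individual_ids)
        if report.per_individual[name] <= max_sample_missing
    ]
    removed_samples = [
        name for name in data.individual_ids
        if report.per_individual[name] > max_sample_missing
    ]
    if not keep:
        raise HaplotypeFormatError(
            "all samples exceed the missingness threshold; nothing left"
        )

    removed_loci = []
    kept_loci: list[Locus] = []
    for locus in data.loci:
        cells = tuple(locus.cells[k] for k in keep)
        if locus.snp_count > max_snps:
            removed_loci.append(locus.locus_id)
        elif all(c is None for c in cells):
            invariant.append(locus.locus_id)  # emptied by sample removal
        else:
            kept_loci.append(Locus(locus.locus_id, cells))
    if not kept_loci:
        raise HaplotypeFormatError("locus filtering removed every locus")
    data = HaplotypeDataset(
        [data.individual_ids[k] for k in keep],
        kept_loci,
        [data.ploidy[k] for k in keep],
    )
    return data, ConversionLog(removed_samples, removed_loci, invariant)


def _expand_homozygotes(
    individual_ids: list[str],
    rows: list[tuple[str, tuple[tuple[str, ...] | None, ...]]],
) -> HaplotypeDataset:
    """Replicate lone alleles up to each individual's maximal allele count."""
    target = [1] * len(individual_ids)
    for _, cells in rows:
        for k, cell in enumerate(cells):
            if cell is not None:
                target[k] = max(target[k], len(cell))
    loci = []
    for locus_id, cells in rows:
        fixed = []
        for k, cell in enumerate(cells):
            if cell is not None and len(cell) == 1 and target[k] > 1:
                cell = cell * target[k]
            fixed.append(cell)
        loci.append(Locus(locus_id, tuple(fixed)))
    return HaplotypeDataset(list(individual_ids), loci, target)


# ---------------------------------------------------------------------------
# missingness diagnostics


def missingness(dataset: HaplotypeDataset) -> MissingnessReport:
    """Per-individual and per-locus fractions of missing cells."""
    miss = np.array(
        [[cell is None for cell in locus.cells] for locus in dataset.loci],
        dtype=bool,
    )
    per_ind = pd.Series(
        miss.mean(axis=0), index=dataset.individual_ids, name="missing_fraction"
    )
    per_locus = pd.Series(
        miss.mean(axis=1),
        index=[l.locus_id for l in dataset.loci],
        name="missing_fraction",
    )
    return MissingnessReport(per_individual=per_ind, per_locus=per_locus)


def missingness_pca(dataset: HaplotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Ordination of individuals by their locus presence/absence profile.

    The loci x individuals table is collapsed to a 0/1 presence matrix
    (1 = genotype called, 0 = missing) and a PCA is run with individuals as
    observations.  Returns ``(scores, explained_variance_ratio)`` where
    ``scores`` is ``(n_individuals, 2)``.  Batch effects — groups of samples
    sharing which loci were recovered — show up as separated clusters here
    even when the genetic signal is unaffected.
    """
    if dataset.n_individuals < 3 or dataset.n_loci < 2:
        raise ValueError("missingness PCA needs >=3 individuals and >=2 loci")
    presence = np.array(
        [[cell is not None for cell in locus.cells] for locus in dataset.loci],
        dtype=float,
    ).T  # individuals x loci
    if presence.all() or not presence.any():
        warnings.warn(
            "presence/absence matrix is constant (no missing data); "
            "all PCA scores are zero",
            stacklevel=2,
        )
        return np.zeros((dataset.n_individuals, 2)), np.zeros(2)
    from sklearn.decomposition import PCA

    n_comp = min(2, dataset.n_individuals - 1)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(presence)
    evr = pca.explained_variance_ratio_
    if n_comp < 2:  # pad to the documented 2-D shape
        scores = np.column_stack([scores, np.zeros(len(scores))])
        evr = np.append(evr, 0.0)
    # a constant-after-centering matrix yields numerically tiny scores
    if np.allclose(scores, 0.0):
        scores = np.zeros_like(scores)
    return scores, evr
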