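"""Cohort-labelled diploid biallelic genotype matrices.

The central in-memory container is :class:`GenotypeMatrix`: an
``(n_samples, n_loci)`` matrix of alternative-allele dosages (0, 1, 2) with
``-1`` encoding a missing genotype, plus sample names, cohort labels and locus
positions. All estimators in :mod:`cgpatch.kinship` and
:mod:`cgpatch.popstats` operate on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a set of cohort-labelled samples.

    Parameters
    ----------
    dosages
        ``(n_samples, n_loci)`` int8 array of alt-allele dosages; -1 = missing.
    samples
        Sample identifiers, one per row.
    cohorts
        Cohort label per sample, aligned with ``samples``.
    positions
        1-based locus positions on the (single, synthetic) contig.
    contig
        Contig name used when writing VCF.
    """

    dosages: np.ndarray
    samples: list[str]
    cohorts: np.ndarray
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]
    contig: str = "chrS"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D (samples x loci) array")
        if len(self.samples) != self.dosages.shape[0]:
            raise DataError("sample list length does not match dosage rows")
        self.cohorts = np.asarray(self.cohorts, dtype=object)
        if self.cohorts.shape[0] != self.dosages.shape[0]:
            raise DataError("cohort labels do not match dosage rows")
        if self.positions is None:
            self.positions = np.arange(1, self.n_loci + 1, dtype=np.int64)
        else:
            self.positions = np.asarray(self.positions, dtype=np.int64)
        bad = (self.dosages > 2) | (self.dosages < MISSING)
        if bad.any():
            raise DataError("dosages must be in {0,1,2} or -1 for missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def cohort_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cohorts:
            seen.setdefault(str(c))
        return list(seen)

    def cohort_indices(self, cohort: str) -> np.ndarray:
        idx = np.flatnonzero(self.cohorts == cohort)
        if idx.size == 0:
            raise DataError(f"unknown cohort: {cohort!r}")
        return idx

    def cohort_dosages(self, cohort: str) -> np.ndarray:
        return self.dosages[self.cohort_indices(cohort)]

    def allele_frequencies(self) -> np.ndarray:
        """Pooled alt-allele frequency per locus over all non-missing genotypes.

        Loci with no called genotypes get frequency ``nan``.
        """
        called = self.dosages >= 0
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        n = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, mask],
            samples=list(self.samples),
            cohorts=self.cohorts.copy(),
            positions=self.positions[mask],
            contig=self.contig,
        )
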