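"""Site-frequency-spectrum containers shared by the empirical and coalescent sides."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


def fold(x: np.ndarray) -> np.ndarray:
    """Fold an unfolded spectrum over classes 1..n-1 into classes 1..floor(n/2).

    ``Y_j = X_j + X_{n-j}`` for j < n/2 and ``Y_{n/2} = X_{n/2}`` for even n.
    """
    x = np.asarray(x, dtype=float)
    n = x.size + 1
    half = n // 2
    y = np.empty(half)
    for j in range(1, half + 1):
        y[j - 1] = x[j - 1] if 2 * j == n else x[j - 1] + x[n - j - 1]
    return y


@dataclass
class SpectrumCounts:
    """Observed site-frequency spectrum of one cohort.

    ``n`` is the number of sequences (2 x diploid individuals); ``Y`` the folded
    counts over minor-allele classes 1..floor(n/2); ``Z`` the normalized folded
    spectrum; ``X`` the unfolded counts when derived states are known (absent
    for the default minor-allele pathway).
    """

    n: int
    Y: np.ndarray
    X: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.size != self.n // 2:
            raise DataError("folded spectrum must have floor(n/2) classes")
        if (self.Y < 0).any():
            raise DataError("spectrum counts must be non-negative")

    @property
    def total_segregating(self) -> float:
        return float(self.Y.sum())

    @property
    def Z(self) -> np.ndarray:
        total = self.Y.sum()
        if total == 0:
            raise DataError("no segregating sites: normalized spectrum undefined")
        return self.Y / total


@dataclass
class BranchSpectrum:
    """Expected branch-length spectrum of a coalescent model.

    ``B[i-1]`` is E[B_i(n)], the expected total length of branches supporting
    ``i`` of the ``n`` leaves; ``normalized_folded`` is the model's prediction
    for the normalized folded site-frequency spectrum E[B_i]/E[B] (theta
    cancels); ``mc_se`` carries Monte-Carlo standard errors per folded class
    (zeros for closed-form / exact spectra).
    """

    n: int
    B: np.ndarray
    mc_se: np.ndarray = field(default=None)  # type: ignore[assignment]
    replicates: int = 0

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.size != self.n - 1:
            raise DataError("branch spectrum must have n-1 classes")
        if self.mc_se is None:
            self.mc_se = np.zeros(self.n // 2)
        self.mc_se = np.asarray(self.mc_se, dtype=float)

    @property
    def B_total(self) -> float:
        return float(self.B.sum())

    @property
    def normalized(self) -> np.ndarray:
        return self.B / self.B_total

    @property
    def normalized_folded(self) -> np.ndarray:
        return fold(self.B) / self.B_total
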