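"""Resolution-weight kernels for the simple entropy.

The simple entropy of a word of length L averages the counts of its
suffixes of length k = 1..L with weights a_k.  Two families are provided:

* Gaussian, a_k = exp(-(L-k)^2 / (2 sigma^2)), centred at k = L.  Large
  sigma lets short suffixes contribute; sigma -> 0 collapses the statistic
  to the plain L-mer count (single resolution).
* Geometric, a_k = (4 phi)^k, the weighting used by the per-position
  entropic profile.

Weights are never normalised here: the entropy formula itself divides by
the weight sum, so both families share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class WeightScheme:
    """Per-resolution weights a_1..a_L."""

    L: int
    values: np.ndarray  # shape (L,), non-negative
    kind: str = "custom"
    param: float = float("nan")

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.L,):
            raise ValueError(f"expected {self.L} weights, got shape {values.shape}")
        if np.any(values < 0):
            raise ValueError("weights must be non-negative")
        if values.sum() <= 0:
            raise ValueError("at least one weight must be positive")
        object.__setattr__(self, "values", values)

    @property
    def total(self) -> float:
        return float(self.values.sum())


def gaussian_weights(L: int, sigma: float) -> WeightScheme:
    """Gaussian kernel a_k = exp(-(L-k)^2 / (2 sigma^2)), k = 1..L."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    k = np.arange(1, L + 1, dtype=float)
    values = np.exp(-((L - k) ** 2) / (2.0 * sigma**2))
    return WeightScheme(L=L, values=values, kind="gaussian", param=float(sigma))


def geometric_weights(L: int, phi: float) -> WeightScheme:
    """Geometric weights a_k = (4 phi)^k used by the position profile."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if phi <= 0:
        raise ValueError(f"phi must be positive, got {phi}")
    k = np.arange(1, L + 1, dtype=float)
    values = (4.0 * phi) ** k
    return WeightScheme(L=L, values=values, kind="geometric", param=float(phi))
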