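"""Binned residue-pair distance distributions.

The AF2 error head emits, for every residue pair (i, j), a probability
vector over distance bins: the full distribution of the predicted
aligned error.  The distogram head emits the analogous distribution of
the predicted Cβ–Cβ distance (Cα for glycine).  Both are carried here as
an N x N x B tensor plus its bin edges.

When a file does not carry edges we default to 64 uniform half-ångström
bins spanning [0, 32) Å; files that carry edges override the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Default error-bin edges: 64 uniform 0.5 Å bins on [0, 32).
DEFAULT_ERROR_BIN_EDGES: np.ndarray = np.linspace(0.0, 32.0, 65)

#: A pair slice whose probabilities sum within this of 1 is renormalized
#: silently; a larger deviation is a hard error (corrupt data).
NORMALIZATION_TOL = 1e-5


def _validate_probs(probs: np.ndarray, bin_edges: np.ndarray, what: str) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    if probs.ndim != 3 or probs.shape[0] != probs.shape[1]:
        raise ValidationError(f"{what}: expected an N x N x B tensor, got {probs.shape}")
    if bin_edges.ndim != 1 or bin_edges.size != probs.shape[2] + 1:
        raise ValidationError(
            f"{what}: need {probs.shape[2] + 1} bin edges, got {bin_edges.size}"
        )
    if np.any(np.diff(bin_edges) <= 0):
        raise ValidationError(f"{what}: bin edges must be strictly increasing")
    if np.any(probs < 0):
        i, j, _ = np.unravel_index(int(np.argmin(probs)), probs.shape)
        raise ValidationError(f"{what}: negative probability at pair ({i}, {j})")
    sums = probs.sum(axis=2)
    off = np.abs(sums - 1.0)
    worst = np.unravel_index(int(np.argmax(off)), off.shape)
    if off[worst] > NORMALIZATION_TOL:
        raise ValidationError(
            f"{what}: probability slice at pair {tuple(int(k) for k in worst)} "
            f"sums to {sums[worst]:.6g}, beyond tolerance {NORMALIZATION_TOL:g}"
        )
    if off[worst] <= 1e-12:  # already normalized; keep bits stable on round-trips
        return probs
    return probs / sums[:, :, None]


@dataclass(frozen=True)
class BinnedErrorDistribution:
    """Full predicted-aligned-error distribution, N x N x B.

    ``probs[i, j]`` is the probability vector of the aligned error of
    residue j when the model is aligned on residue i; rows are alignment
    frames, so the tensor need not be symmetric.
    """

    probs: np.ndarray
    bin_edges: np.ndarray = field(default_factory=lambda: DEFAULT_ERROR_BIN_EDGES.copy())

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(
            self, "probs", _validate_probs(self.probs, edges, type(self).__name__)
        )

    @property
    def N(self) -> int:
        return int(self.probs.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.probs.shape[2])

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def expected_value(self) -> np.ndarray:
        """N x N matrix of expected distances (the flat PAE matrix for an
        error distribution)."""
        return self.probs @ self.bin_midpoints

    def restrict(self, idx: np.ndarray) -> "BinnedErrorDistribution":
        return type(self)(self.probs[np.ix_(idx, idx)], self.bin_edges)


@dataclass(frozen=True)
class DistogramDistribution(BinnedErrorDistribution):
    """Predicted Cβ–Cβ distance distribution (Cα for glycine), N x N x B."""

    #: Records the atom convention of the distances; informational.
    atom_convention: str = "CB (CA for glycine)"

    def restrict(self, idx: np.ndarray) -> "DistogramDistribution":
        return type(self)(self.probs[np.ix_(idx, idx)], self.bin_edges, self.atom_convention)
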