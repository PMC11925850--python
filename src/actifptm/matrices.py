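"""Derived pairwise matrices: contact probabilities, expected TM
contributions, and the residue-weight matrices of the TM-family scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class ContactMap:
    """q[i, j] = P(distance(i, j) < threshold).

    Symmetrized on construction by averaging with the transpose: the
    heads may be numerically asymmetric but contact is a property of the
    unordered pair.  The diagonal is ignored by all consumers.
    """

    q: np.ndarray
    threshold: float = 8.0

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=np.float64)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValidationError(f"contact map must be square, got {q.shape}")
        if np.any(q < -1e-12) or np.any(q > 1 + 1e-12):
            raise ValidationError("contact probabilities must lie in [0, 1]")
        q = np.clip(0.5 * (q + q.T), 0.0, 1.0)
        object.__setattr__(self, "q", q)

    @property
    def N(self) -> int:
        return int(self.q.shape[0])

    def restrict(self, idx: np.ndarray) -> "ContactMap":
        return ContactMap(self.q[np.ix_(idx, idx)], self.threshold)


@dataclass(frozen=True)
class PairTMMatrix:
    """g[i, j]: expected TM contribution of pair (i, j).

    Each entry is the TM kernel 1/(1+(d/d0)^2) averaged over the
    predicted error distribution of the pair, hence a convex combination
    of per-bin kernel values and itself in (0, 1].
    """

    g: np.ndarray
    d0: float
    L_norm: int

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=np.float64)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValidationError(f"pair TM matrix must be square, got {g.shape}")
        if self.d0 <= 0:
            raise ValidationError("d0 must be positive")
        if np.any(g <= 0) or np.any(g > 1 + 1e-12):
            raise ValidationError("expected TM contributions must lie in (0, 1]")
        object.__setattr__(self, "g", g)

    @property
    def N(self) -> int:
        return int(self.g.shape[0])


@dataclass(frozen=True)
class WeightMatrix:
    """Row-normalized residue-pair weights of one TM-family score.

    mask_kind records which score the weights implement: ``all`` (pTM:
    every pair, uniform), ``interchain`` (ipTM: 1 on interchain pairs),
    ``contact_weighted`` (actifpTM: contact probability on interchain
    pairs).  Every row with any unmasked weight sums to 1; rows with all
    pairs masked are all-zero.
    """

    w: np.ndarray
    mask_kind: str

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"weight matrix must be square, got {w.shape}")
        if np.any(w < 0):
            raise ValidationError("weights must be nonnegative")
        if self.mask_kind not in ("all", "interchain", "contact_weighted"):
            raise ValidationError(f"unknown mask_kind {self.mask_kind!r}")
        object.__setattr__(self, "w", w)

    @property
    def nonzero_rows(self) -> np.ndarray:
        return self.w.sum(axis=1) > 0

    @classmethod
    def from_raw(cls, raw: np.ndarray, mask_kind: str) -> "WeightMatrix":
        """Row-normalize raw nonnegative weights; all-zero rows stay zero."""
        raw = np.asarray(raw, dtype=np.float64)
        sums = raw.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(sums > 0, raw / np.where(sums > 0, sums, 1.0), 0.0)
        return cls(w, mask_kind)
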