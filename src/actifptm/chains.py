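"""Chain partition of a concatenated multimer.

All matrices in this package use a single global residue index:
0-based, contiguous per chain, chains concatenated in ``chain_order``.
The partition records which global index belongs to which chain and is
the source of the interchain masks used by ipTM and actifpTM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

_DEFAULT_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class ChainPartition:
    """Per-residue chain labels for a complex of N residues.

    Parameters
    ----------
    asym_id
        Length-N sequence of chain labels (strings).  Residues of one
        chain must occupy a contiguous index range unless
        ``allow_noncontiguous`` is set at construction.
    chain_order
        Ordered unique labels.  Derived from ``asym_id`` (order of first
        appearance) when omitted.
    """

    asym_id: np.ndarray
    chain_order: tuple[str, ...] = ()
    allow_noncontiguous: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        ids = np.asarray([str(a) for a in self.asym_id], dtype=object)
        object.__setattr__(self, "asym_id", ids)
        if ids.size == 0:
            raise ValidationError("chain partition must cover at least one residue")
        seen: list[str] = []
        for a in ids:
            if a not in seen:
                seen.append(a)
        if not self.chain_order:
            object.__setattr__(self, "chain_order", tuple(seen))
        else:
            order = tuple(str(c) for c in self.chain_order)
            object.__setattr__(self, "chain_order", order)
            if set(seen) - set(order):
                raise ValidationError(
                    f"labels {sorted(set(seen) - set(order))} appear in asym_id "
                    "but not in chain_order"
                )
        if not self.allow_noncontiguous:
            for label in self.chain_order:
                idx = np.flatnonzero(ids == label)
                if idx.size and not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                    raise ValidationError(
                        f"chain {label!r} is not contiguous; pass "
                        "allow_noncontiguous=True to override"
                    )

    @classmethod
    def from_lengths(
        cls, lengths: "list[int] | tuple[int, ...]", labels: "tuple[str, ...] | None" = None
    ) -> "ChainPartition":
        """Build a partition from per-chain residue counts.

        Labels default to A, B, C, ... in order.
        """
        lengths = [int(n) for n in lengths]
        if not lengths or any(n < 1 for n in lengths):
            raise ValidationError(f"chain lengths must be positive, got {lengths}")
        if labels is None:
            if len(lengths) > len(_DEFAULT_LABELS):
                raise ValidationError("too many chains for default labels")
            labels = tuple(_DEFAULT_LABELS[: len(lengths)])
        if len(labels) != len(lengths):
            raise ValidationError("labels and lengths differ in count")
        ids = list(
            itertools.chain.from_iterable([lab] * n for lab, n in zip(labels, lengths))
        )
        return cls(np.asarray(ids, dtype=object), tuple(labels))

    @property
    def N(self) -> int:
        return int(self.asym_id.size)

    @property
    def n_chains(self) -> int:
        return len(self.chain_order)

    def length_of(self, label: str) -> int:
        return int(np.count_nonzero(self.asym_id == label))

    def indices(self, label: str) -> np.ndarray:
        """Global indices of one chain's residues, ascending."""
        if label not in self.chain_order:
            raise ValidationError(f"unknown chain label {label!r}")
        return np.flatnonzero(self.asym_id == label)

    def interchain_mask(self) -> np.ndarray:
        """Boolean N x N matrix, True where residues i, j sit on different chains."""
        return self.asym_id[:, None] != self.asym_id[None, :]

    def chain_pairs(self) -> "list[tuple[str, str]]":
        """Unordered chain pairs in chain_order, as ordered tuples."""
        return list(itertools.combinations(self.chain_order, 2))

    def restrict(self, labels: "tuple[str, ...]") -> "tuple[np.ndarray, ChainPartition]":
        """Global indices of the union of ``labels`` plus the induced sub-partition."""
        idx = np.concatenate([self.indices(lab) for lab in labels])
        sub = ChainPartition(self.asym_id[idx], tuple(labels))
        return idx, sub
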