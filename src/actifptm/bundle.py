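"""PredictionBundle: the canonical in-memory form of one prediction's
confidence outputs.

A bundle aggregates whatever confidence components a prediction run
exported — the binned error tensor and/or the flat PAE matrix, the
distogram and/or a precomputed contact map, per-residue pLDDT — together
with the chain partition.  Missing components are recorded as absent,
never fabricated; each score declares what it needs and raises
:class:`~actifptm.errors.MissingComponentError` when that is not there.

The flat PAE matrix is derivable from the error tensor (its expectation)
and the contact map from the distogram (its mass below the contact
threshold), but not the other way round: the inversions are ill-posed
and are never attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chains import ChainPartition
from .distributions import BinnedErrorDistribution, DistogramDistribution
from .errors import MissingComponentError, ValidationError
from .matrices import ContactMap


@dataclass
class PredictionBundle:
    chains: ChainPartition
    plddt: np.ndarray
    error_dist: "BinnedErrorDistribution | None" = None
    pae: "np.ndarray | None" = None
    distogram: "DistogramDistribution | None" = None
    contact_map: "ContactMap | None" = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        N = self.chains.N
        self.plddt = np.asarray(self.plddt, dtype=np.float64)
        if self.plddt.shape != (N,):
            raise ValidationError(
                f"plddt has shape {self.plddt.shape}, expected ({N},)"
            )
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValidationError("plddt values must lie in [0, 100]")
        for name in ("error_dist", "distogram", "contact_map"):
            comp = getattr(self, name)
            if comp is not None and comp.N != N:
                raise ValidationError(
                    f"{name} covers {comp.N} residues, chain partition covers {N}"
                )
        if self.pae is not None:
            self.pae = np.asarray(self.pae, dtype=np.float64)
            if self.pae.shape != (N, N):
                raise ValidationError(
                    f"pae has shape {self.pae.shape}, expected ({N}, {N})"
                )
            if np.any(self.pae < 0):
                raise ValidationError("pae entries must be nonnegative")
        if (
            self.error_dist is None
            and self.pae is None
            and self.distogram is None
            and self.contact_map is None
        ):
            raise ValidationError("bundle carries no scoring input at all")

    @property
    def N(self) -> int:
        return self.chains.N

    def require_error_dist(self) -> BinnedErrorDistribution:
        if self.error_dist is None:
            raise MissingComponentError(
                "this score needs the binned error tensor, which the input "
                "did not provide (a flat PAE matrix is not sufficient)"
            )
        return self.error_dist

    def get_pae(self) -> np.ndarray:
        """The flat PAE matrix: as stored, else the error tensor's expectation."""
        if self.pae is not None:
            return self.pae
        if self.error_dist is not None:
            return self.error_dist.expected_value()
        raise MissingComponentError(
            "no PAE matrix and no error tensor to derive it from"
        )

    def get_contact_map(self, threshold: float = 8.0) -> ContactMap:
        """The contact map: as stored, else collapsed from the distogram.

        A stored map is returned as-is even if its threshold differs
        from the requested one (it cannot be recomputed); the mismatch
        is the caller's to notice via ``ContactMap.threshold``.
        """
        if self.contact_map is not None:
            return self.contact_map
        if self.distogram is not None:
            from .scoring import contact_probs

            return contact_probs(self.distogram, threshold)
        raise MissingComponentError(
            "no contact map and no distogram to derive it from"
        )

    def restrict(self, labels: tuple) -> "PredictionBundle":
        """Sub-bundle over the residues of the given chains."""
        idx, sub_chains = self.chains.restrict(labels)
        return PredictionBundle(
            chains=sub_chains,
            plddt=self.plddt[idx],
            error_dist=None if self.error_dist is None else self.error_dist.restrict(idx),
            pae=None if self.pae is None else self.pae[np.ix_(idx, idx)],
            distogram=None if self.distogram is None else self.distogram.restrict(idx),
            contact_map=None if self.contact_map is None else self.contact_map.restrict(idx),
            metadata=dict(self.metadata),
        )
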