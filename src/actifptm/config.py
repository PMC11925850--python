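"""Scoring configuration.

One object carries every tunable of the scoring pipeline so a run is
reproducible from its JSON serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .errors import ValidationError

#: Success thresholds; every comparison is a strict inequality.
#: ipae is an upper bound (smaller is better), the rest are lower bounds.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "interface_plddt": 85.0,
    "ipae": 5.0,
    "iptm": 0.85,
    "confidence": 0.85,
    "actifptm": 0.85,
}

#: Metrics for which success means falling *below* the threshold.
LOWER_IS_BETTER = frozenset({"ipae"})


@dataclass(frozen=True)
class ScoringConfig:
    """Tunables of the scoring pipeline.

    Parameters
    ----------
    d0_mode
        ``"full_length"`` (default): the TM normalization distance d0 is
        recomputed from the residue count of whatever is being scored
        (the full complex for global scores, |A|+|B| for a chain pair,
        |A| for per-chain pTM).  A float fixes d0 at that value
        everywhere, which makes actifpTM exactly invariant to appended
        non-contacting residues.
    contact_threshold
        Distance (Å) below which a residue pair counts as a contact when
        collapsing a distogram into contact probabilities.
    contact_call_threshold
        Contact probability at or above which a pair is *called* a
        contact when building the interface mask for ipAE and interface
        pLDDT.
    focus_chain
        Chain whose residues define "peptide interface pLDDT".  None
        selects the shortest chain (first in chain order on ties).
    thresholds
        Success thresholds, overriding :data:`DEFAULT_THRESHOLDS`.
    calc_pairwise
        Whether to compute per-chain-pair scores.
    """

    d0_mode: "str | float" = "full_length"
    contact_threshold: float = 8.0
    contact_call_threshold: float = 0.5
    focus_chain: "str | None" = None
    thresholds: dict = field(default_factory=dict)
    calc_pairwise: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.d0_mode, str):
            if self.d0_mode != "full_length":
                raise ValidationError(
                    f"d0_mode must be 'full_length' or a fixed value, got {self.d0_mode!r}"
                )
        else:
            if not float(self.d0_mode) > 0:
                raise ValidationError("fixed d0 must be positive")
            object.__setattr__(self, "d0_mode", float(self.d0_mode))
        if not 0 <= self.contact_call_threshold <= 1:
            raise ValidationError("contact_call_threshold must lie in [0, 1]")
        if self.contact_threshold <= 0:
            raise ValidationError("contact_threshold must be positive")
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")

    @property
    def effective_thresholds(self) -> dict:
        return {**DEFAULT_THRESHOLDS, **self.thresholds}

    def fixed_d0(self) -> "float | None":
        """The fixed d0 value, or None when d0 follows the scored length."""
        return None if self.d0_mode == "full_length" else float(self.d0_mode)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ScoringConfig":
        return cls(**json.loads(s))
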