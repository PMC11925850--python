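"""Score report: every scalar and per-chain quantity one scoring run produces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def pair_key(a: str, b: str) -> str:
    """Canonical dictionary key for an unordered chain pair."""
    return f"{a}:{b}"


@dataclass
class ScoreReport:
    """All confidence scores computed from one prediction.

    Scalars that could not be computed (missing component, no interface)
    are None and are simply absent from success classification.
    ``per_residue_rowsums`` holds the per-residue weighted score vector
    whose maximum is the actifpTM value; ``per_residue_argmax`` is the
    lowest index attaining it.
    """

    ptm: "float | None" = None
    iptm: "float | None" = None
    actifptm: "float | None" = None
    confidence: "float | None" = None
    ipae: "float | None" = None
    interface_plddt: "float | None" = None
    per_chain_ptm: dict = field(default_factory=dict)
    pairwise_actifptm: dict = field(default_factory=dict)
    pairwise_iptm: dict = field(default_factory=dict)
    per_residue_rowsums: "np.ndarray | None" = None
    per_residue_argmax: "int | None" = None
    no_interface: bool = False
    pairwise_no_interface: dict = field(default_factory=dict)
    success_flags: dict = field(default_factory=dict)
    focus_chain: "str | None" = None
    chain_order: tuple = ()
    metadata: dict = field(default_factory=dict)

    def scalars(self) -> dict:
        return {
            "ptm": self.ptm,
            "iptm": self.iptm,
            "actifptm": self.actifptm,
            "confidence": self.confidence,
            "ipae": self.ipae,
            "interface_plddt": self.interface_plddt,
        }

    def to_dict(self) -> dict:
        """JSON-ready representation (schema used by write_report)."""
        rowsums = (
            None
            if self.per_residue_rowsums is None
            else [float(x) for x in self.per_residue_rowsums]
        )
        return {
            "scalars": {k: v for k, v in self.scalars().items()},
            "per_chain_ptm": dict(self.per_chain_ptm),
            "pairwise": {
                "actifptm": dict(self.pairwise_actifptm),
                "iptm": dict(self.pairwise_iptm),
            },
            "per_residue": {
                "actifptm_rowsums": rowsums,
                "argmax": self.per_residue_argmax,
            },
            "flags": {
                "no_interface": self.no_interface,
                "pairwise_no_interface": dict(self.pairwise_no_interface),
            },
            "success": dict(self.success_flags),
            "focus_chain": self.focus_chain,
            "chain_order": list(self.chain_order),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreReport":
        per_res = d.get("per_residue", {})
        rowsums = per_res.get("actifptm_rowsums")
        return cls(
            **d.get("scalars", {}),
            per_chain_ptm=dict(d.get("per_chain_ptm", {})),
            pairwise_actifptm=dict(d.get("pairwise", {}).get("actifptm", {})),
            pairwise_iptm=dict(d.get("pairwise", {}).get("iptm", {})),
            per_residue_rowsums=None if rowsums is None else np.asarray(rowsums),
            per_residue_argmax=per_res.get("argmax"),
            no_interface=d.get("flags", {}).get("no_interface", False),
            pairwise_no_interface=dict(
                d.get("flags", {}).get("pairwise_no_interface", {})
            ),
            success_flags=dict(d.get("success", {})),
            focus_chain=d.get("focus_chain"),
            chain_order=tuple(d.get("chain_order", ())),
            metadata=dict(d.get("metadata", {})),
        )

    def summary_line(self) -> str:
        def fmt(x: "float | None") -> str:
            return "n/a" if x is None else f"{x:.4f}"

        return (
            f"actifpTM={fmt(self.actifptm)} ipTM={fmt(self.iptm)} "
            f"pTM={fmt(self.ptm)} confidence={fmt(self.confidence)}"
        )
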