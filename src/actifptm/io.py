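"""Readers and writers for AF2/ColabFold-style confidence outputs.

Three dialects are supported:

``colabfold_json``
    The ColabFold score-file dialect: ``pae`` or
    ``predicted_aligned_error`` (N x N floats), ``plddt`` (N floats) and
    optional ``ptm``/``iptm`` scalars.  The scalars are kept as metadata
    for cross-checks only — they never enter any computation.  The flat
    dialect cannot carry binned tensors; an optional NPZ *sidecar* (same
    keys as the npz dialect) supplies them.

``npz_archive`` / ``pickle_archive``
    Key-value archives with keys ``error_bin_probs``, ``error_bin_edges``,
    ``distogram_probs``, ``distogram_edges``, ``contact_probs``, ``pae``,
    ``plddt``, ``asym_id`` — all optional except at least one scoring
    input.

Chain identity comes from the archive's ``asym_id`` when present,
otherwise from the caller (a ChainPartition or a list of chain lengths).
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import PredictionBundle
from .chains import ChainPartition
from .distributions import BinnedErrorDistribution, DistogramDistribution
from .errors import DialectError, ValidationError
from .matrices import ContactMap
from .report import ScoreReport

DIALECTS = ("auto", "colabfold_json", "npz_archive", "pickle_archive")

_EXTENSION_DIALECTS = {
    ".json": "colabfold_json",
    ".npz": "npz_archive",
    ".pkl": "pickle_archive",
    ".pickle": "pickle_archive",
}

ARCHIVE_KEYS = (
    "error_bin_probs",
    "error_bin_edges",
    "distogram_probs",
    "distogram_edges",
    "contact_probs",
    "pae",
    "plddt",
    "asym_id",
)


def detect_dialect(path: "str | Path") -> str:
    ext = Path(path).suffix.lower()
    try:
        return _EXTENSION_DIALECTS[ext]
    except KeyError:
        raise DialectError(
            f"cannot detect dialect from extension {ext!r} of {path}; "
            f"pass one of {DIALECTS[1:]}"
        ) from None


def _resolve_chains(
    chain_spec, asym_id: "np.ndarray | None", allow_noncontiguous: bool
) -> ChainPartition:
    if isinstance(chain_spec, ChainPartition):
        return chain_spec
    if chain_spec is not None:
        return ChainPartition.from_lengths(list(chain_spec))
    if asym_id is not None:
        return ChainPartition(
            np.asarray(asym_id), allow_noncontiguous=allow_noncontiguous
        )
    raise ValidationError(
        "no chain information: the file carries no asym_id and no "
        "chain_spec was given"
    )


def _bundle_from_mapping(
    data: dict, chain_spec, source: str, allow_noncontiguous: bool
) -> PredictionBundle:
    chains = _resolve_chains(chain_spec, data.get("asym_id"), allow_noncontiguous)
    error_dist = None
    if data.get("error_bin_probs") is not None:
        probs = np.asarray(data["error_bin_probs"], dtype=np.float64)
        edges = data.get("error_bin_edges")
        if edges is None:
            error_dist = BinnedErrorDistribution(probs)
        else:
            error_dist = BinnedErrorDistribution(probs, np.asarray(edges))
    distogram = None
    if data.get("distogram_probs") is not None:
        probs = np.asarray(data["distogram_probs"], dtype=np.float64)
        edges = data.get("distogram_edges")
        if edges is None:
            distogram = DistogramDistribution(probs)
        else:
            distogram = DistogramDistribution(probs, np.asarray(edges))
    contact_map = None
    if data.get("contact_probs") is not None:
        contact_map = ContactMap(np.asarray(data["contact_probs"], dtype=np.float64))
    pae = data.get("pae")
    plddt = data.get("plddt")
    if plddt is None:
        raise ValidationError(f"{source}: no plddt vector")
    metadata = dict(data.get("metadata") or {})
    metadata["source"] = source
    return PredictionBundle(
        chains=chains,
        plddt=np.asarray(plddt, dtype=np.float64),
        error_dist=error_dist,
        pae=None if pae is None else np.asarray(pae, dtype=np.float64),
        distogram=distogram,
        contact_map=contact_map,
        metadata=metadata,
    )


def _read_archive_mapping(path: Path, dialect: str) -> dict:
    if dialect == "npz_archive":
        with np.load(path, allow_pickle=False) as npz:
            return {k: npz[k] for k in npz.files}
    with open(path, "rb") as fh:
        data = pickle.load(fh)
    if not isinstance(data, dict):
        raise DialectError(f"{path}: pickle archive must hold a dict")
    return data


def read_bundle(
    path: "str | Path",
    chain_spec=None,
    dialect: str = "auto",
    sidecar: "str | Path | None" = None,
    allow_noncontiguous: bool = False,
) -> PredictionBundle:
    """Read one prediction's confidence outputs into a validated bundle.

    ``chain_spec`` is a ChainPartition, a list of chain lengths, or None
    (archive must then carry ``asym_id``).  ``sidecar`` attaches an NPZ
    archive of binned tensors to a flat colabfold_json file.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = detect_dialect(path)

    if dialect == "colabfold_json":
        with open(path) as fh:
            raw = json.load(fh)
        pae = raw.get("pae", raw.get("predicted_aligned_error"))
        data: dict = {
            "pae": None if pae is None else np.asarray(pae, dtype=np.float64),
            "plddt": raw.get("plddt"),
        }
        if sidecar is not None:
            side = _read_archive_mapping(Path(sidecar), "npz_archive")
            for key in ARCHIVE_KEYS:
                if key in side and data.get(key) is None:
                    data[key] = side[key]
        bundle = _bundle_from_mapping(
            data, chain_spec, str(path), allow_noncontiguous
        )
        for key in ("ptm", "iptm"):
            if key in raw:
                bundle.metadata[f"file_{key}"] = float(raw[key])
        return bundle

    data = _read_archive_mapping(path, dialect)
    unknown = set(data) - set(ARCHIVE_KEYS) - {"metadata"}
    if unknown:
        raise DialectError(f"{path}: unrecognized archive keys {sorted(unknown)}")
    return _bundle_from_mapping(data, chain_spec, str(path), allow_noncontiguous)


def _bundle_to_mapping(bundle: PredictionBundle) -> dict:
    data: dict = {"plddt": bundle.plddt, "asym_id": np.asarray(bundle.chains.asym_id, dtype=str)}
    if bundle.error_dist is not None:
        data["error_bin_probs"] = bundle.error_dist.probs
        data["error_bin_edges"] = bundle.error_dist.bin_edges
    if bundle.distogram is not None:
        data["distogram_probs"] = bundle.distogram.probs
        data["distogram_edges"] = bundle.distogram.bin_edges
    if bundle.contact_map is not None:
        data["contact_probs"] = bundle.contact_map.q
    if bundle.pae is not None:
        data["pae"] = bundle.pae
    return data


def write_bundle(
    bundle: PredictionBundle,
    path: "str | Path",
    dialect: str = "auto",
    sidecar: "str | Path | None" = None,
) -> None:
    """Serialize a bundle in any supported dialect.

    For ``colabfold_json`` only the flat components (PAE, pLDDT) fit in
    the JSON file itself; pass ``sidecar`` to also write an NPZ archive
    holding the binned tensors, readable back via the same argument.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = detect_dialect(path)
    if dialect == "npz_archive":
        np.savez(path, **_bundle_to_mapping(bundle))
    elif dialect == "pickle_archive":
        with open(path, "wb") as fh:
            pickle.dump(_bundle_to_mapping(bundle), fh)
    elif dialect == "colabfold_json":
        payload = {
            "pae": [[float(x) for x in row] for row in bundle.get_pae()],
            "plddt": [float(x) for x in bundle.plddt],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        if sidecar is not None:
            side = _bundle_to_mapping(bundle)
            side.pop("pae", None)
            np.savez(Path(sidecar), **side)
    else:
        raise DialectError(f"unknown dialect {dialect!r}")


def write_report(report: ScoreReport, path: "str | Path", format: str = "json") -> None:
    """Write a score report as JSON (full schema) or CSV (flat).

    The CSV has one row per chain pair, carrying that pair's scores next
    to the (repeated) global scalars.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
    elif format == "csv":
        rows = []
        pairs = sorted(set(report.pairwise_iptm) | set(report.pairwise_actifptm))
        for key in pairs:
            rows.append(
                {
                    "chain_pair": key,
                    "pairwise_actifptm": report.pairwise_actifptm.get(key),
                    "pairwise_iptm": report.pairwise_iptm.get(key),
                    **report.scalars(),
                }
            )
        if not rows:  # no pairwise map computed; still emit the scalars
            rows.append({"chain_pair": None, **report.scalars()})
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_report(path: "str | Path") -> ScoreReport:
    with open(path) as fh:
        return ScoreReport.from_dict(json.load(fh))
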