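"""TM-family confidence scores from binned error distributions.

All scores here descend from the TM-score kernel 1/(1 + (d/d0)^2).
The error head's per-pair distance distribution turns the kernel into an
expected per-pair TM contribution g[i, j]; a score is then a weighted
per-row (per alignment frame) sum of g, maximized over frames —
emulating superposition on every residue and reporting the best.

The three family members differ only in the residue-pair weights:

* pTM       — every pair, uniform weight 1/N per row;
* ipTM      — weight 1 on interchain pairs, row-normalized;
* actifpTM  — weight = contact probability on interchain pairs,
              row-normalized, so residue pairs the model does not
              predict to touch (flexible flanks) carry no weight.

ipAE (median PAE over called interface pairs), interface pLDDT (mean
pLDDT of focus-chain residues with an interchain contact call), the
AF2-multimer model confidence 0.8·ipTM + 0.2·pTM, and threshold-based
success classification round out the set.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .bundle import PredictionBundle
from .chains import ChainPartition
from .config import LOWER_IS_BETTER, ScoringConfig
from .distributions import BinnedErrorDistribution, DistogramDistribution
from .errors import (
    MissingComponentError,
    NoInterfaceError,
    SingleChainError,
    ValidationError,
)
from .matrices import ContactMap, PairTMMatrix, WeightMatrix
from .report import ScoreReport, pair_key

__all__ = [
    "d0_of",
    "tm_kernel",
    "expected_pair_tm",
    "ptm_score",
    "iptm_score",
    "contact_probs",
    "actifptm_score",
    "pairwise_chain_scores",
    "ipae_score",
    "interface_plddt",
    "interface_mask_from_contacts",
    "model_confidence",
    "classify_success",
    "score_bundle",
]


def d0_of(L_norm: int) -> float:
    """TM-score normalization distance for a target of ``L_norm`` residues.

    d0 = 1.24 * (max(L, 19) - 15)^(1/3) - 1.8, the standard TM-score
    length scaling with the usual clamp that keeps d0 positive for short
    targets.  Monotone nondecreasing in L.
    """
    L = int(L_norm)
    if L < 1:
        raise ValidationError(f"L_norm must be >= 1, got {L_norm}")
    return 1.24 * (max(L, 19) - 15.0) ** (1.0 / 3.0) - 1.8


def tm_kernel(d, d0: float):
    """TM-score distance kernel 1/(1 + (d/d0)^2); in (0, 1], decreasing in d."""
    if d0 <= 0:
        raise ValidationError(f"d0 must be positive, got {d0}")
    d = np.asarray(d, dtype=np.float64)
    out = 1.0 / (1.0 + (d / d0) ** 2)
    return float(out) if out.ndim == 0 else out


def expected_pair_tm(
    error_dist: BinnedErrorDistribution,
    L_norm: "int | None" = None,
    d0: "float | None" = None,
) -> PairTMMatrix:
    """Expected TM contribution of every residue pair.

    g[i, j] = sum_b p_ij(b) * tm_kernel(midpoint_b, d0): the per-bin
    maximum theoretical TM-score, weighted by the bin probabilities.
    Exactly one of ``L_norm`` (d0 recomputed from it) or ``d0`` (fixed)
    selects the normalization.
    """
    if (L_norm is None) == (d0 is None):
        raise ValidationError("pass exactly one of L_norm or d0")
    if d0 is None:
        d0 = d0_of(L_norm)
    kernel = tm_kernel(error_dist.bin_midpoints, d0)
    g = error_dist.probs @ kernel
    return PairTMMatrix(g, d0=float(d0), L_norm=int(L_norm or 0) or error_dist.N)


def _max_weighted_rowsum(g: PairTMMatrix, weights: WeightMatrix):
    """Per-frame weighted sums and their max over frames with any weight."""
    rowsums = (weights.w * g.g).sum(axis=1)
    alive = weights.nonzero_rows
    if not np.any(alive):
        return 0.0, rowsums, None
    masked = np.where(alive, rowsums, -np.inf)
    argmax = int(np.argmax(masked))  # lowest index on ties
    return float(rowsums[argmax]), rowsums, argmax


def ptm_score(g: PairTMMatrix) -> float:
    """pTM: max over frames i of the plain row mean of g (diagonal included).

    Uses the AF2 convention L_common = L_target = total length, so the
    row weight is uniformly 1/N.
    """
    return float(np.max(g.g.mean(axis=1)))


def _interchain_weights(chains: ChainPartition) -> WeightMatrix:
    if chains.n_chains < 2:
        raise SingleChainError("interface scores undefined for single chain")
    return WeightMatrix.from_raw(
        chains.interchain_mask().astype(np.float64), "interchain"
    )


def iptm_score(g: PairTMMatrix, chains: ChainPartition) -> float:
    """ipTM: interchain pairs get weight 1, rows are normalized, and the
    best per-frame weighted sum is returned."""
    score, _, _ = _max_weighted_rowsum(g, _interchain_weights(chains))
    return score


def contact_probs(distogram: DistogramDistribution, threshold: float = 8.0) -> ContactMap:
    """Collapse a distogram into P(distance < threshold) per pair.

    Bins entirely below the threshold contribute their full mass; the
    bin straddling the threshold contributes linearly interpolated
    partial mass.  The result is symmetrized.
    """
    edges = distogram.bin_edges
    if not (edges[0] <= threshold <= edges[-1]):
        raise ValidationError(
            f"contact threshold {threshold} outside bin support "
            f"[{edges[0]}, {edges[-1]}]"
        )
    frac = np.clip((threshold - edges[:-1]) / np.diff(edges), 0.0, 1.0)
    q = distogram.probs @ frac
    return ContactMap(np.clip(q, 0.0, 1.0), threshold=float(threshold))


class _ActifptmDetails(NamedTuple):
    score: float
    rowsums: np.ndarray
    argmax: "int | None"
    no_interface: bool


def _actifptm_details(
    g: PairTMMatrix, contacts: ContactMap, chains: ChainPartition
) -> _ActifptmDetails:
    if chains.n_chains < 2:
        raise SingleChainError("interface scores undefined for single chain")
    raw = contacts.q * chains.interchain_mask()
    weights = WeightMatrix.from_raw(raw, "contact_weighted")
    score, rowsums, argmax = _max_weighted_rowsum(g, weights)
    return _ActifptmDetails(score, rowsums, argmax, argmax is None)


def actifptm_score(
    g: PairTMMatrix, contacts: ContactMap, chains: ChainPartition
) -> float:
    """actifpTM: ipTM with interchain weights equal to contact probabilities.

    Raw weight q[i, j] on interchain pairs, 0 on intrachain pairs; rows
    with any weight are normalized to sum 1 and only those rows compete
    in the final max.  If no interchain pair has positive contact
    probability anywhere, the complex has no predicted interface and the
    score is 0 (see ``score_bundle`` for the accompanying flag).
    """
    return _actifptm_details(g, contacts, chains).score


class PairwiseChainScores(NamedTuple):
    pairwise_actifptm: dict
    pairwise_iptm: dict
    per_chain_ptm: dict
    pairwise_no_interface: dict


def pairwise_chain_scores(
    bundle: PredictionBundle, config: "ScoringConfig | None" = None
) -> PairwiseChainScores:
    """Interface scores for every chain pair plus per-chain pTM.

    Each unordered pair (A, B) is scored on the restriction of every
    matrix to the residues of A ∪ B, with d0 recomputed from |A| + |B|
    (unless a fixed d0 is configured); per-chain pTM likewise uses the
    A x A restriction and |A|.  Unlike the single global ipTM this makes
    weak or absent interfaces between individual chain pairs visible.
    """
    config = config or ScoringConfig()
    chains = bundle.chains
    error_dist = bundle.require_error_dist()
    fixed = config.fixed_d0()
    try:
        contacts = bundle.get_contact_map(config.contact_threshold)
    except MissingComponentError:
        contacts = None

    pw_actif: dict = {}
    pw_iptm: dict = {}
    pw_flag: dict = {}
    for a, b in chains.chain_pairs():
        idx, sub_chains = chains.restrict((a, b))
        sub_err = error_dist.restrict(idx)
        if fixed is None:
            g = expected_pair_tm(sub_err, L_norm=idx.size)
        else:
            g = expected_pair_tm(sub_err, d0=fixed)
        key = pair_key(a, b)
        pw_iptm[key] = iptm_score(g, sub_chains)
        if contacts is not None:
            det = _actifptm_details(g, contacts.restrict(idx), sub_chains)
            pw_actif[key] = det.score
            pw_flag[key] = det.no_interface

    per_chain: dict = {}
    for label in chains.chain_order:
        idx = chains.indices(label)
        sub_err = error_dist.restrict(idx)
        if fixed is None:
            g = expected_pair_tm(sub_err, L_norm=idx.size)
        else:
            g = expected_pair_tm(sub_err, d0=fixed)
        per_chain[label] = ptm_score(g)

    return PairwiseChainScores(pw_actif, pw_iptm, per_chain, pw_flag)


def interface_mask_from_contacts(
    contacts: ContactMap, chains: ChainPartition, call_threshold: float = 0.5
) -> np.ndarray:
    """Boolean mask of called interface pairs: interchain and
    contact probability >= call_threshold."""
    return (contacts.q >= call_threshold) & chains.interchain_mask()


def ipae_score(pae: np.ndarray, interface_mask: np.ndarray) -> float:
    """Median PAE over interface residue pairs, in Å.

    Both orientations (i, j) and (j, i) of every called pair enter the
    median, since PAE is frame-dependent.  Even counts use the
    mean-of-middle-two convention.
    """
    pae = np.asarray(pae, dtype=np.float64)
    mask = np.asarray(interface_mask, dtype=bool)
    if pae.shape != mask.shape:
        raise ValidationError("pae and interface mask shapes differ")
    both = mask | mask.T
    if not np.any(both):
        raise NoInterfaceError("no residue pair is called as interface")
    return float(np.median(pae[both]))


def interface_plddt(
    plddt: np.ndarray,
    chains: ChainPartition,
    contacts: ContactMap,
    focus_chain: str,
    call_threshold: float = 0.5,
) -> float:
    """Mean pLDDT of focus-chain residues with >= 1 interchain contact call."""
    mask = interface_mask_from_contacts(contacts, chains, call_threshold)
    idx = chains.indices(focus_chain)
    has_contact = mask[idx].any(axis=1)
    if not np.any(has_contact):
        raise NoInterfaceError(
            f"chain {focus_chain!r} has no called interface residue"
        )
    return float(np.mean(np.asarray(plddt, dtype=np.float64)[idx][has_contact]))


def model_confidence(ptm: float, iptm: float) -> float:
    """AF2-multimer ranking confidence: 0.8 * ipTM + 0.2 * pTM."""
    return 0.8 * iptm + 0.2 * ptm


def classify_success(
    report: ScoreReport, thresholds: "dict | None" = None
) -> dict:
    """Strict-inequality success call per metric.

    A metric whose scalar is absent from the report yields no flag at
    all (absent, not False).  ``ipae`` succeeds below its threshold; all
    other metrics succeed above theirs.
    """
    from .config import DEFAULT_THRESHOLDS

    cuts = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    scalars = report.scalars()
    flags: dict = {}
    for metric, cut in cuts.items():
        value = scalars.get(metric)
        if value is None:
            continue
        if metric in LOWER_IS_BETTER:
            flags[metric] = bool(value < cut)
        else:
            flags[metric] = bool(value > cut)
    return flags


def _default_focus_chain(chains: ChainPartition) -> str:
    lengths = {lab: chains.length_of(lab) for lab in chains.chain_order}
    return min(chains.chain_order, key=lambda lab: (lengths[lab], chains.chain_order.index(lab)))


def score_bundle(
    bundle: PredictionBundle, config: "ScoringConfig | None" = None
) -> ScoreReport:
    """Run the full scoring pipeline on one prediction.

    Computes every score the bundle's components allow and leaves the
    rest absent.  Requires >= 2 chains: the pipeline exists to judge
    interfaces.
    """
    config = config or ScoringConfig()
    chains = bundle.chains
    if chains.n_chains < 2:
        raise SingleChainError("interface scores undefined for single chain")

    report = ScoreReport(chain_order=chains.chain_order, metadata=dict(bundle.metadata))

    try:
        contacts = bundle.get_contact_map(config.contact_threshold)
    except MissingComponentError:
        contacts = None

    if bundle.error_dist is not None:
        fixed = config.fixed_d0()
        if fixed is None:
            g = expected_pair_tm(bundle.error_dist, L_norm=bundle.N)
        else:
            g = expected_pair_tm(bundle.error_dist, d0=fixed)
        report.ptm = ptm_score(g)
        report.iptm = iptm_score(g, chains)
        report.confidence = model_confidence(report.ptm, report.iptm)
        if contacts is not None:
            det = _actifptm_details(g, contacts, chains)
            report.actifptm = det.score
            report.per_residue_rowsums = det.rowsums
            report.per_residue_argmax = det.argmax
            report.no_interface = det.no_interface
        if config.calc_pairwise:
            pw = pairwise_chain_scores(bundle, config)
            report.pairwise_actifptm = pw.pairwise_actifptm
            report.pairwise_iptm = pw.pairwise_iptm
            report.per_chain_ptm = pw.per_chain_ptm
            report.pairwise_no_interface = pw.pairwise_no_interface

    if contacts is not None:
        try:
            pae = bundle.get_pae()
        except MissingComponentError:
            pae = None
        mask = interface_mask_from_contacts(
            contacts, chains, config.contact_call_threshold
        )
        if pae is not None:
            try:
                report.ipae = ipae_score(pae, mask)
            except NoInterfaceError:
                report.ipae = None
        focus = config.focus_chain or _default_focus_chain(chains)
        report.focus_chain = focus
        try:
            report.interface_plddt = interface_plddt(
                bundle.plddt, chains, contacts, focus, config.contact_call_threshold
            )
        except NoInterfaceError:
            report.interface_plddt = None

    report.success_flags = classify_success(report, config.thresholds)
    return report
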