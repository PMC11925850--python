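"""Seeded synthetic prediction bundles with controlled structure.

Three generators cover the testing needs of the scoring stack without
ever running AlphaFold2:

* :func:`make_point_mass_bundle` — a bundle whose error and distance
  distributions are point masses derived from a toy distance matrix, so
  pTM collapses to the direct geometric TM-score formula;
* :func:`make_flank_scenario` — a receptor–peptide complex with a
  confident interface block and growing flexible flanks, the situation
  that biases ipTM and that actifpTM is designed to ignore;
* :func:`make_random_bundle` — fully random but valid bundles for
  property tests.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; equal seeds give bit-identical bundles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bundle import PredictionBundle
from .chains import ChainPartition
from .distributions import (
    DEFAULT_ERROR_BIN_EDGES,
    BinnedErrorDistribution,
    DistogramDistribution,
)
from .errors import ValidationError
from .matrices import ContactMap
from .scoring import d0_of

__all__ = [
    "FlankScenarioSpec",
    "make_point_mass_bundle",
    "make_flank_scenario",
    "make_random_bundle",
    "snap_to_bin_midpoints",
]


def _bin_of(d: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Index of the bin containing each distance; distances at or beyond
    the last edge land in the last bin (with a warning from callers)."""
    idx = np.searchsorted(edges, d, side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


def snap_to_bin_midpoints(dist_matrix: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Replace each distance with the midpoint of its containing bin.

    This is the distance matrix a binned point-mass bundle actually
    represents; oracles comparing against the direct TM formula must use
    the snapped matrix for exact agreement.
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    mid = 0.5 * (edges[:-1] + edges[1:])
    return mid[_bin_of(np.asarray(dist_matrix, dtype=np.float64), edges)]


def make_point_mass_bundle(
    dist_matrix: np.ndarray,
    chains: ChainPartition,
    bin_edges: "np.ndarray | None" = None,
    plddt_value: float = 95.0,
) -> PredictionBundle:
    """Bundle whose error and distogram slices are point masses at the
    bin containing each pairwise distance.

    The matrix must be symmetric and nonnegative with a zero diagonal.
    Distances beyond the last bin edge are placed in the last bin and a
    warning is recorded.
    """
    D = np.asarray(dist_matrix, dtype=np.float64)
    edges = (
        DEFAULT_ERROR_BIN_EDGES.copy() if bin_edges is None else np.asarray(bin_edges)
    )
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError(f"distance matrix must be square, got {D.shape}")
    if not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(D < 0) or np.any(np.diag(D) != 0):
        raise ValidationError("distances must be nonnegative with zero diagonal")
    if D.shape[0] != chains.N:
        raise ValidationError("distance matrix and chain partition disagree on N")
    if np.any(D >= edges[-1]):
        warnings.warn(
            "distances beyond the last bin edge were clipped into the last bin",
            stacklevel=2,
        )
    N, B = D.shape[0], edges.size - 1
    probs = np.zeros((N, N, B))
    ii, jj = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    probs[ii, jj, _bin_of(D, edges)] = 1.0
    return PredictionBundle(
        chains=chains,
        plddt=np.full(N, float(plddt_value)),
        error_dist=BinnedErrorDistribution(probs, edges),
        distogram=DistogramDistribution(probs.copy(), edges),
        metadata={"generator": "point_mass"},
    )


def _triangular_bump(center_distance: float, edges: np.ndarray) -> np.ndarray:
    """Probability vector with a triangular bump (weights 1,2,3,2,1) over
    the bin containing ``center_distance`` +/- 2 bins, clipped at the
    support boundaries and renormalized."""
    B = edges.size - 1
    c = int(_bin_of(np.asarray(center_distance), edges))
    vec = np.zeros(B)
    for offset, weight in zip((-2, -1, 0, 1, 2), (1.0, 2.0, 3.0, 2.0, 1.0)):
        b = c + offset
        if 0 <= b < B:
            vec[b] = weight
    return vec / vec.sum()


def _kernel_inverse(g: float, d0: float) -> float:
    """Distance at which the TM kernel equals g (g in (0, 1])."""
    if not 0 < g <= 1:
        raise ValidationError(f"target expected-TM level must lie in (0, 1], got {g}")
    return d0 * float(np.sqrt(1.0 / g - 1.0))


@dataclass(frozen=True)
class FlankScenarioSpec:
    """Parameters of the receptor–peptide flank scenario.

    The complex is chain A (receptor, ``receptor_len`` residues) plus
    chain B (peptide): ``flank | motif | flank``.  The three bundles the
    generator returns differ only in flank length per side: 0,
    ``flank_len``, and ``2 * flank_len`` — emulating predictions of the
    bare motif and of extensions by one or two motif-lengths of
    flexible sequence.

    Confidence structure: all pairs within the core (receptor + motif)
    carry low predicted error (``pae_core``), except rows anchored on
    peptide residues, which carry moderately higher error
    (``pae_core_peptide_frame``) — alignment frames on a short peptide
    are less reliable than frames on the folded receptor, the asymmetry
    real PAE matrices show for peptide–receptor complexes.  Any pair
    involving a flank residue carries high error (``pae_flank``).
    ``g_core`` / ``g_flank``, when given, override the corresponding
    error-bump centres via the inverse TM kernel at the reference d0
    (the d0 of the flankless complex).

    The contact map is ``q_core`` on ``interface_size`` randomly placed
    receptor x motif pairs, ``q_flank`` on every interchain pair
    involving a flank residue (default 0: flanks predicted not to
    touch), and 0 on the remaining interchain pairs.
    """

    receptor_len: int = 60
    motif_len: int = 10
    flank_len: int = 10
    interface_size: "int | None" = None
    g_core: "float | None" = None
    g_flank: "float | None" = None
    q_core: float = 1.0
    q_flank: float = 0.0
    pae_core: float = 0.8
    pae_core_peptide_frame: float = 6.2
    pae_flank: float = 25.0
    plddt_core: float = 92.0
    plddt_flank: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.receptor_len, self.motif_len) < 1 or self.flank_len < 1:
            raise ValidationError("receptor, motif and flank lengths must be positive")
        if not (0 <= self.q_flank <= 1 and 0 < self.q_core <= 1):
            raise ValidationError("contact levels must lie in [0, 1], q_core > 0")
        n_pairs = self.receptor_len * self.motif_len
        size = self.interface_size
        if size is None:
            size = min(4 * self.motif_len, n_pairs)
            object.__setattr__(self, "interface_size", size)
        if not 1 <= size <= n_pairs:
            raise ValidationError(
                f"interface_size must lie in [1, {n_pairs}], got {size}"
            )


def _build_flank_bundle(
    spec: FlankScenarioSpec,
    flank: int,
    interface_pairs: np.ndarray,
    variant: str,
) -> PredictionBundle:
    R, M = spec.receptor_len, spec.motif_len
    N = R + M + 2 * flank
    edges = DEFAULT_ERROR_BIN_EDGES
    chains = ChainPartition.from_lengths([R, M + 2 * flank], ("A", "B"))

    d0_ref = d0_of(R + M)
    pae_core = (
        spec.pae_core if spec.g_core is None else _kernel_inverse(spec.g_core, d0_ref)
    )
    pae_flank = (
        spec.pae_flank if spec.g_flank is None else _kernel_inverse(spec.g_flank, d0_ref)
    )

    is_receptor = np.arange(N) < R
    motif_idx = np.arange(R + flank, R + flank + M)
    is_motif = np.zeros(N, dtype=bool)
    is_motif[motif_idx] = True
    is_core = is_receptor | is_motif
    is_flank = ~is_core

    bump_core = _triangular_bump(pae_core, edges)
    bump_pep = _triangular_bump(spec.pae_core_peptide_frame, edges)
    bump_flank = _triangular_bump(pae_flank, edges)
    bump_self = _triangular_bump(0.0, edges)

    probs = np.empty((N, N, edges.size - 1))
    pae = np.empty((N, N))
    # frame i on rows: peptide-anchored frames see the receptor with
    # higher error than receptor-anchored frames see the peptide
    core_pair = is_core[:, None] & is_core[None, :]
    pep_frame = core_pair & is_motif[:, None] & is_receptor[None, :]
    core_rest = core_pair & ~pep_frame
    flank_pair = ~core_pair
    probs[core_rest] = bump_core
    pae[core_rest] = pae_core
    probs[pep_frame] = bump_pep
    pae[pep_frame] = spec.pae_core_peptide_frame
    probs[flank_pair] = bump_flank
    pae[flank_pair] = pae_flank
    di = np.diag_indices(N)
    probs[di] = bump_self
    pae[di] = 0.0

    q = np.zeros((N, N))
    band = np.abs(np.arange(N)[:, None] - np.arange(N)[None, :]) <= 4
    intrachain = ~chains.interchain_mask()
    q[band & intrachain] = 1.0
    if spec.q_flank > 0:
        fl_inter = (is_flank[:, None] | is_flank[None, :]) & ~intrachain
        q[fl_inter] = spec.q_flank
    r_idx = interface_pairs[:, 0]
    m_idx = motif_idx[interface_pairs[:, 1]]
    q[r_idx, m_idx] = spec.q_core
    q[m_idx, r_idx] = spec.q_core
    np.fill_diagonal(q, 1.0)

    plddt = np.where(is_core, spec.plddt_core, spec.plddt_flank).astype(float)

    return PredictionBundle(
        chains=chains,
        plddt=plddt,
        error_dist=BinnedErrorDistribution(probs, edges),
        pae=pae,
        contact_map=ContactMap(q, threshold=8.0),
        metadata={
            "generator": "flank_scenario",
            "variant": variant,
            "seed": spec.seed,
            "d0_ref": d0_ref,
        },
    )


def make_flank_scenario(
    spec: "FlankScenarioSpec | None" = None,
) -> "tuple[PredictionBundle, PredictionBundle, PredictionBundle]":
    """Three bundles — flankless, short flanks, long flanks — sharing
    bit-identical receptor and motif sub-tensors.

    Holding d0 fixed at the reference value (``d0_of(receptor + motif)``,
    stored in each bundle's metadata), actifpTM is exactly invariant
    across the three when ``q_flank`` is 0, while ipTM decreases
    strictly as flanks grow.
    """
    spec = spec or FlankScenarioSpec()
    rng = np.random.default_rng(spec.seed)
    n_pairs = spec.receptor_len * spec.motif_len
    flat = rng.choice(n_pairs, size=spec.interface_size, replace=False)
    interface_pairs = np.stack(
        [flat // spec.motif_len, flat % spec.motif_len], axis=1
    )
    return tuple(
        _build_flank_bundle(spec, flank, interface_pairs, variant)
        for flank, variant in ((0, "none"), (spec.flank_len, "short"), (2 * spec.flank_len, "long"))
    )


def make_random_bundle(
    N: int,
    n_chains: int,
    seed: int,
    n_bins: int = 64,
    alpha: float = 1.0,
) -> PredictionBundle:
    """Fully random but valid bundle: Dirichlet(alpha) probability slices
    for error and distance distributions, a random contiguous chain
    partition, and uniform random pLDDT.  Deterministic per seed."""
    if not 1 <= n_chains <= N:
        raise ValidationError("need N >= n_chains >= 1")
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, 32.0, n_bins + 1)
    if n_chains > 1:
        cuts = np.sort(rng.choice(np.arange(1, N), size=n_chains - 1, replace=False))
        lengths = np.diff(np.concatenate(([0], cuts, [N])))
    else:
        lengths = np.array([N])
    chains = ChainPartition.from_lengths(lengths.tolist())

    def dirichlet_slices() -> np.ndarray:
        raw = rng.standard_gamma(alpha, size=(N, N, n_bins))
        return raw / raw.sum(axis=2, keepdims=True)

    return PredictionBundle(
        chains=chains,
        plddt=rng.uniform(30.0, 100.0, size=N),
        error_dist=BinnedErrorDistribution(dirichlet_slices(), edges),
        distogram=DistogramDistribution(dirichlet_slices(), edges),
        metadata={"generator": "random", "seed": seed},
    )
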