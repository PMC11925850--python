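# Methods

## Scores

All TM-family scores are expectations of the TM-score kernel
k(d) = 1/(1 + (d/d0)²) under the model's own predicted-error
distributions, aggregated the way the TM-score itself aggregates:
per alignment frame, then maximized over frames. The inputs are the
error head's N×N×B probability tensor p_ij(b) (frame i, residue j,
distance bin b), the distogram (same shape, Cβ–Cβ distances, Cα for
glycine), and per-residue pLDDT. Nothing here requires model
coordinates.

Per-pair expected TM contribution:
g_ij = Σ_b p_ij(b)·k(mid_b), with mid_b the bin midpoint. Since each
p_ij(·) is a probability vector, g_ij is a convex combination of kernel
values and lies in (0, 1]; moving mass from a higher bin to a lower bin
can only raise it (the kernel is decreasing), which is the monotonicity
the property tests assert.

- **pTM** = max_i (1/N) Σ_j g_ij. The diagonal is included: the score
  uses the convention L_common = L_target = N (total concatenated
  length), and g_ii (self-error near zero) is part of that row mean.
- **ipTM**: raw weights 1 on interchain pairs, 0 intrachain and on the
  diagonal; each row is normalized over its unmasked pairs (so weights
  sum to 1 per row); score = max over rows of Σ_j w̃_ij·g_ij.
- **actifpTM**: identical, except the raw interchain weight is the
  contact probability q_ij. Rows whose raw weights are all zero are
  excluded from the max — a residue with no interface evidence should
  not define the complex score. If *every* row is zero the complex has
  no predicted interface: the score is 0 and a `no_interface` flag is
  set, rather than an error.

When q is constant on interchain pairs the row normalization cancels it
and actifpTM equals ipTM exactly; this identity is tested to 1e-12.

Contact probabilities come from the distogram as the mass below the
contact threshold (default 8 Å), with the straddling bin contributing a
linearly interpolated fraction — deterministic and stable when the
threshold lands on or near a bin edge. The map is symmetrized by
averaging with its transpose, since contact is a property of the
unordered pair while the heads may be numerically asymmetric.

## Normalization length d0

d0(L) = 1.24·(max(L, 19) − 15)^⅓ − 1.8 (the clamp keeps d0 ≈ 0.17 Å
positive for short targets). Global scores use L = N; pairwise-chain
scores use L = |A|+|B|; per-chain pTM uses L = |A|. `ScoringConfig`
also accepts a fixed d0 (`d0_mode=<value>`). The fixed mode exists
because appending residues changes d0 even when they carry zero contact
weight: with d0 fixed, actifpTM is *exactly* invariant to such
padding; with d0 recomputed from the grown length, it moves only
through d0, upward (a larger d0 flattens the kernel, raising every
g_ij). Both behaviours are asserted in the tests. Which length the
reference pipeline uses for actifpTM's d0 is not nailed down anywhere
authoritative; full-length is the parent metric's convention and is the
default here.

## Interface statistics

Interface pairs for ipAE and interface pLDDT are *called* from the
contact map: interchain and q_ij ≥ 0.5 by default
(`contact_call_threshold`). A caller-supplied boolean mask is accepted
wherever a coordinate-derived interface is available; this package
deliberately parses no structures. ipAE is the median PAE over called
pairs using both orientations (PAE is frame-dependent), mean-of-middle
on even counts. Interface pLDDT averages pLDDT over focus-chain
residues with at least one call; the focus chain defaults to the
shortest chain (the peptide in peptide–receptor work), first in chain
order on ties. Model confidence is 0.8·ipTM + 0.2·pTM exactly. Success
flags use strict inequalities (defaults: interface pLDDT > 85,
ipAE < 5.0 Å, ipTM > 0.85, confidence > 0.85, actifpTM > 0.85); a
metric that could not be computed yields no flag rather than `False`.

## Error-bin convention

64 uniform 0.5 Å bins on [0, 32) by default. Published half-Å
enumerations of the error binning are internally inconsistent (62 vs 64
bins), so the default is a documented choice, and edges carried by an
input file always override it.

## Synthetic fixtures

`make_random_bundle` draws Dirichlet(α) probability slices (α = 1
default; smaller α gives spiky distributions so contact calls at
q ≥ 0.5 actually occur), a random contiguous chain partition, and
uniform pLDDT in [30, 100]. One `numpy.random.default_rng(seed)` per
call; equal seeds give bit-identical bundles (asserted on the pickle
serialization; NPZ containers embed timestamps and are compared
array-wise).

`make_point_mass_bundle` turns a toy distance matrix into one-hot bin
distributions, making pTM collapse to the direct geometric TM formula.
A binned point mass can only represent a bin midpoint, so exact
agreement is asserted on midpoint-valued distance matrices, with the
diagonal zeros snapped to the first midpoint by the exposed
`snap_to_bin_midpoints` helper that the comparison oracle shares.
Distances beyond the last edge land in the last bin with a warning.

`make_flank_scenario` builds three receptor–peptide bundles — bare
motif, flanks of one motif-length per side, flanks of two motif-lengths
per side (the standard extension protocol for motif predictions) — with
bit-identical receptor and motif sub-tensors. Defaults: 60-residue
receptor, 10-residue motif, 10-residue flank unit, 40 interface pairs
placed at seeded random among receptor×motif pairs with contact
probability q_core = 1, flank interchain contacts q_flank = 0, core
error bumps at 0.8 Å, flank bumps at 25 Å, pLDDT 92 (core) / 35
(flank). Error distributions are triangular bumps (weights 1-2-3-2-1
over the centre bin ± 2) rather than point masses, so the bin-summation
path is exercised. `g_core`/`g_flank`, when given, re-derive the bump
centres from target expected-TM levels via the inverse kernel at the
scenario reference d0 = d0(receptor + motif).

One generator choice deserves emphasis: the error tensor is
**frame-asymmetric** — rows anchored on peptide residues see the
receptor with a higher error bump (`pae_core_peptide_frame`, default
6.2 Å) than rows anchored on receptor residues see the peptide
(0.8 Å). Real PAE matrices show exactly this asymmetry for short
peptides bound to folded receptors. It is also load-bearing: the final
max-over-frames means peptide-frame rows, whose interchain set (the
receptor) never grows, would otherwise pin ipTM at its flankless value
no matter how many flanks are added. With the asymmetry, the flankless
ipTM is carried by receptor frames, flanks dilute those frames' row
averages, and ipTM falls to the (lower) peptide-frame level — the
qualitative signature the scenario exists to reproduce (ipTM drops by
≈ 0.7 at fixed d0 while actifpTM is constant to 1e-12) — without
touching any core entry.

What the generator does *not* emulate: sequence-conditioned confidence,
correlated errors between neighbouring pairs, realistic pLDDT profiles,
or distogram–error-head consistency (the scenario plants its PAE matrix
and contact map directly). Passing tests therefore demonstrate the
*algebra* of the scores on controlled inputs, not predictive validity
on real AF2 outputs.

## Numerical choices

- Probability slices summing to 1 within 1e-5 are renormalized (slices
  already within 1e-12 are left untouched so serialization round-trips
  are bit-stable); larger deviations are hard errors naming the pair.
- Ties in the per-frame max report the lowest frame index.
- Scores are computed in float64 throughout; the oracle-equivalence
  tests bound the vectorized-vs-naive gap by 1e-10 on complexes up to
  N = 40 with 2–4 chains (100 bundles), and the exact identities
  (uniform-contact, flank invariance) by 1e-12.
- Problem sizes in the test-suite and acceptance script (N ≤ 40,
  25–100 replicates) keep the naive nested-loop references cheap while
  covering multiple chain counts; the vectorized path itself handles
  realistic complex sizes.

## Limitations

- A flat PAE matrix alone cannot yield any TM-family score: the binned
  tensor is required and is never reconstructed from PAE (the
  deconvolution is ill-posed). ColabFold JSON therefore needs the NPZ
  sidecar for pTM/ipTM/actifpTM.
- Contact calls from the distogram stand in for coordinate-derived
  interfaces in ipAE/interface pLDDT; with poorly calibrated
  distograms the call threshold (0.5) matters, and a coordinate-based
  mask should be supplied instead.
- Chain labels must partition contiguous index ranges unless explicitly
  overridden; per-residue reordering is out of scope.
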