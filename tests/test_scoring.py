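import numpy as np
import pytest

import naive_reference as ref
from actifptm import (
    BinnedErrorDistribution,
    ChainPartition,
    ContactMap,
    DistogramDistribution,
    NoInterfaceError,
    ScoreReport,
    SingleChainError,
    ValidationError,
    actifptm_score,
    classify_success,
    contact_probs,
    d0_of,
    expected_pair_tm,
    interface_mask_from_contacts,
    interface_plddt,
    ipae_score,
    iptm_score,
    make_random_bundle,
    model_confidence,
    pairwise_chain_scores,
    ptm_score,
    score_bundle,
    tm_kernel,
)
from actifptm.scoring import _interchain_weights


class TestD0:
    @pytest.mark.parametrize(
        "L, expected",
        [
            (19, 1.24 * 4 ** (1 / 3) - 1.8),  # ~0.16840
            (10, 1.24 * 4 ** (1 / 3) - 1.8),  # clamped to 19
            (100, 1.24 * 85 ** (1 / 3) - 1.8),
        ],
    )
    def test_closed_form_with_short_length_clamp(self, L, expected):
        assert d0_of(L) == pytest.approx(expected, abs=1e-12)

    def test_monotone_nondecreasing(self):
        vals = [d0_of(L) for L in range(1, 400)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert d0_of(115) > d0_of(114)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValidationError):
            d0_of(0)


class TestTMKernel:
    @pytest.mark.parametrize(
        "d, d0, expected", [(0.0, 3.0, 1.0), (3.0, 3.0, 0.5), (9.0, 3.0, 0.1)]
    )
    def test_reference_points(self, d, d0, expected):
        assert tm_kernel(d, d0) == pytest.approx(expected, abs=1e-15)

    def test_vectorized_decreasing_in_distance(self):
        d = np.linspace(0, 30, 100)
        k = tm_kernel(d, 2.5)
        assert np.all(np.diff(k) < 0) and k[0] == 1.0

    def test_rejects_nonpositive_d0(self):
        with pytest.raises(ValidationError):
            tm_kernel(1.0, 0.0)


class TestExpectedPairTM:
    def test_point_mass_in_lowest_bin_gives_uniform_kernel_value(self):
        probs = np.zeros((5, 5, 64))
        probs[..., 0] = 1.0
        dist = BinnedErrorDistribution(probs)
        g = expected_pair_tm(dist, L_norm=5)
        expected = tm_kernel(dist.bin_midpoints[0], d0_of(5))
        assert np.allclose(g.g, expected, atol=1e-15)

    def test_uniform_distribution_gives_mean_of_kernel_values(self):
        dist = BinnedErrorDistribution(np.full((20, 20, 64), 1 / 64))
        g = expected_pair_tm(dist, L_norm=20)
        expected = tm_kernel(dist.bin_midpoints, d0_of(20)).mean()
        assert np.allclose(g.g, expected, atol=1e-12)

    def test_matches_nested_loop_oracle(self, seed7_bundle):
        d0 = d0_of(seed7_bundle.N)
        g = expected_pair_tm(seed7_bundle.error_dist, L_norm=seed7_bundle.N)
        g_ref = ref.naive_pair_tm(
            seed7_bundle.error_dist.probs.tolist(),
            seed7_bundle.error_dist.bin_edges.tolist(),
            d0,
        )
        assert np.max(np.abs(g.g - np.asarray(g_ref))) < 1e-10

    def test_requires_exactly_one_normalization_argument(self):
        dist = BinnedErrorDistribution(np.full((2, 2, 64), 1 / 64))
        with pytest.raises(ValidationError):
            expected_pair_tm(dist)
        with pytest.raises(ValidationError):
            expected_pair_tm(dist, L_norm=2, d0=1.0)


def constant_g(N, value, L_norm=None):
    probs = np.zeros((N, N, 64))
    probs[..., 0] = 1.0
    dist = BinnedErrorDistribution(probs)
    # pick d0 so the kernel at the first midpoint equals `value`
    d0 = dist.bin_midpoints[0] / np.sqrt(1 / value - 1)
    return expected_pair_tm(dist, d0=d0)


class TestPtmIptm:
    def test_ptm_of_all_confident_pairs_is_one(self):
        from actifptm.matrices import PairTMMatrix

        g = PairTMMatrix(np.ones((4, 4)), d0=2.0, L_norm=4)
        assert ptm_score(g) == 1.0

    def test_ptm_is_max_over_row_means(self):
        from actifptm.matrices import PairTMMatrix

        mat = np.full((5, 5), 0.1)
        mat[2] = 0.9
        g = PairTMMatrix(mat, d0=2.0, L_norm=5)
        assert ptm_score(g) == pytest.approx(0.9)

    def test_iptm_of_constant_interchain_g_equals_the_constant(self):
        g = constant_g(8, 0.73)
        chains = ChainPartition.from_lengths([5, 3])
        assert iptm_score(g, chains) == pytest.approx(
            float(g.g[0, 0]), abs=1e-12
        )

    def test_iptm_matches_oracle_on_random_bundle(self, seed7_bundle):
        g = expected_pair_tm(seed7_bundle.error_dist, L_norm=seed7_bundle.N)
        expected = ref.naive_iptm(
            g.g.tolist(), list(seed7_bundle.chains.asym_id)
        )
        assert iptm_score(g, seed7_bundle.chains) == pytest.approx(
            expected, abs=1e-10
        )

    def test_iptm_undefined_for_single_chain(self):
        g = constant_g(6, 0.5)
        with pytest.raises(SingleChainError):
            iptm_score(g, ChainPartition.from_lengths([6]))

    def test_iptm_averages_over_noncontacting_chains_too(self):
        # the dilution bias actifpTM removes: a third chain with poor
        # interchain confidence drags every frame's interchain average down
        mat = np.full((9, 9), 0.05)
        chains = ChainPartition.from_lengths([3, 3, 3])
        inter = chains.interchain_mask()
        ab = np.zeros((9, 9), dtype=bool)
        ab[:3, 3:6] = ab[3:6, :3] = True
        mat[ab] = 0.9
        from actifptm.matrices import PairTMMatrix

        g = PairTMMatrix(mat, d0=2.0, L_norm=9)
        score = iptm_score(g, chains)
        assert score == pytest.approx((3 * 0.9 + 3 * 0.05) / 6)
        assert score < 0.9  # diluted below the A-B interface confidence

    def test_interchain_weight_rows_sum_to_one(self):
        w = _interchain_weights(ChainPartition.from_lengths([4, 2, 3]))
        assert np.allclose(w.w.sum(axis=1), 1.0, atol=1e-12)


class TestContactProbs:
    def test_all_mass_below_threshold_gives_one(self):
        probs = np.zeros((3, 3, 64))
        probs[..., 2] = 1.0  # 1.0-1.5 A, well below 8
        q = contact_probs(DistogramDistribution(probs), 8.0)
        assert np.allclose(q.q, 1.0)

    def test_all_mass_above_threshold_gives_zero(self):
        probs = np.zeros((3, 3, 64))
        probs[..., 40] = 1.0  # 20-20.5 A
        q = contact_probs(DistogramDistribution(probs), 8.0)
        assert np.allclose(q.q, 0.0)

    def test_threshold_on_exact_edge_takes_fraction_of_uniform_mass(self):
        probs = np.full((2, 2, 64), 1 / 64)
        q = contact_probs(DistogramDistribution(probs), 8.0)  # 16 of 64 bins
        assert np.allclose(q.q, 16 / 64, atol=1e-12)

    def test_straddling_bin_contributes_linear_fraction(self):
        probs = np.zeros((2, 2, 64))
        probs[..., 16] = 1.0  # bin [8.0, 8.5)
        q = contact_probs(DistogramDistribution(probs), 8.25)
        assert np.allclose(q.q, 0.5, atol=1e-12)

    def test_matches_nested_loop_oracle(self, seed7_bundle):
        q = contact_probs(seed7_bundle.distogram, 8.0)
        q_ref = ref.naive_contact_probs(
            seed7_bundle.distogram.probs.tolist(),
            seed7_bundle.distogram.bin_edges.tolist(),
            8.0,
        )
        assert np.max(np.abs(q.q - np.asarray(q_ref))) < 1e-12

    def test_threshold_outside_support_rejected(self):
        probs = np.full((2, 2, 64), 1 / 64)
        with pytest.raises(ValidationError):
            contact_probs(DistogramDistribution(probs), 40.0)


class TestActifptm:
    def test_constant_interchain_contacts_reduce_to_iptm(self, seed7_bundle):
        g = expected_pair_tm(seed7_bundle.error_dist, L_norm=seed7_bundle.N)
        chains = seed7_bundle.chains
        q = ContactMap(np.full((chains.N, chains.N), 0.37))
        assert abs(
            actifptm_score(g, q, chains) - iptm_score(g, chains)
        ) < 1e-12

    def test_matches_oracle_with_structured_contacts(self, seed7_bundle):
        g = expected_pair_tm(seed7_bundle.error_dist, L_norm=seed7_bundle.N)
        q = contact_probs(seed7_bundle.distogram, 8.0)
        expected, _ = ref.naive_actifptm(
            g.g.tolist(), q.q.tolist(), list(seed7_bundle.chains.asym_id)
        )
        assert actifptm_score(g, q, seed7_bundle.chains) == pytest.approx(
            expected, abs=1e-10
        )

    def test_zero_contacts_everywhere_scores_zero(self):
        g = constant_g(6, 0.8)
        chains = ChainPartition.from_lengths([3, 3])
        q = ContactMap(np.zeros((6, 6)))
        assert actifptm_score(g, q, chains) == 0.0

    def test_single_chain_rejected(self):
        g = constant_g(4, 0.5)
        with pytest.raises(SingleChainError):
            actifptm_score(g, ContactMap(np.ones((4, 4))), ChainPartition.from_lengths([4]))

    def test_flanks_with_zero_contact_probability_do_not_change_the_score(self):
        # confident interface block plus flanks: at fixed d0, scoring the
        # padded complex equals scoring the trimmed one
        rng = np.random.default_rng(5)
        B = 64

        def bundle_g(N):
            raw = rng.random((N, N, B))
            return raw / raw.sum(axis=2, keepdims=True)

        core = bundle_g(8)
        padded = np.empty((12, 12, B))
        padded[:8, :8] = core
        flank_slice = np.zeros(B)
        flank_slice[-1] = 1.0
        padded[8:, :] = flank_slice
        padded[:8, 8:] = flank_slice
        d0 = 2.0
        g_core = expected_pair_tm(BinnedErrorDistribution(core), d0=d0)
        g_pad = expected_pair_tm(BinnedErrorDistribution(padded), d0=d0)
        q_core = np.zeros((8, 8))
        q_core[:4, 4:] = 1.0
        q_pad = np.zeros((12, 12))
        q_pad[:8, :8] = q_core
        chains_core = ChainPartition.from_lengths([4, 4])
        chains_pad = ChainPartition.from_lengths([4, 8])
        s_core = actifptm_score(g_core, ContactMap(q_core), chains_core)
        s_pad = actifptm_score(g_pad, ContactMap(q_pad), chains_pad)
        assert s_pad == pytest.approx(s_core, abs=1e-12)


class TestPairwiseChainScores:
    def test_two_chain_pairwise_equals_global(self, seed7_bundle):
        pw = pairwise_chain_scores(seed7_bundle)
        g = expected_pair_tm(seed7_bundle.error_dist, L_norm=seed7_bundle.N)
        q = contact_probs(seed7_bundle.distogram, 8.0)
        key = "{}:{}".format(*seed7_bundle.chains.chain_order)
        assert pw.pairwise_iptm[key] == pytest.approx(
            iptm_score(g, seed7_bundle.chains), abs=1e-12
        )
        assert pw.pairwise_actifptm[key] == pytest.approx(
            actifptm_score(g, q, seed7_bundle.chains), abs=1e-12
        )

    def test_matches_oracle_on_three_chain_bundle(self):
        bundle = make_random_bundle(N=18, n_chains=3, seed=11)
        pw = pairwise_chain_scores(bundle)
        q = contact_probs(bundle.distogram, 8.0)
        ref_actif, ref_iptm, ref_ptm = ref.naive_pairwise(
            bundle.error_dist.probs.tolist(),
            bundle.error_dist.bin_edges.tolist(),
            q.q.tolist(),
            list(bundle.chains.asym_id),
        )
        for key in ref_iptm:
            assert pw.pairwise_iptm[key] == pytest.approx(ref_iptm[key], abs=1e-10)
            assert pw.pairwise_actifptm[key] == pytest.approx(ref_actif[key], abs=1e-10)
        for key in ref_ptm:
            assert pw.per_chain_ptm[key] == pytest.approx(ref_ptm[key], abs=1e-10)

    def test_noncontacting_pair_flagged_while_its_iptm_stays_positive(self):
        from actifptm import PredictionBundle

        N = 9
        chains = ChainPartition.from_lengths([3, 3, 3])
        probs = np.zeros((N, N, 64))
        probs[..., 4] = 1.0
        q = np.zeros((N, N))
        q[:3, 3:6] = q[3:6, :3] = 1.0  # only A-B touch
        bundle = PredictionBundle(
            chains=chains,
            plddt=np.full(N, 80.0),
            error_dist=BinnedErrorDistribution(probs),
            contact_map=ContactMap(q),
        )
        pw = pairwise_chain_scores(bundle)
        assert pw.pairwise_actifptm["B:C"] == 0.0
        assert pw.pairwise_no_interface["B:C"] is True
        assert pw.pairwise_iptm["B:C"] > 0.0
        assert pw.pairwise_no_interface["A:B"] is False

    def test_per_chain_ptm_of_fully_confident_chain_approaches_one(self):
        from actifptm import PredictionBundle

        N = 33  # chain A long enough that d0 is not clamped down
        probs = np.zeros((N, N, 64))
        probs[..., 0] = 1.0  # every error in the lowest bin
        bundle = PredictionBundle(
            chains=ChainPartition.from_lengths([30, 3]),
            plddt=np.full(N, 90.0),
            error_dist=BinnedErrorDistribution(probs),
            contact_map=ContactMap(np.ones((N, N))),
        )
        pw = pairwise_chain_scores(bundle)
        assert pw.per_chain_ptm["A"] > 0.9


class TestIpae:
    def test_constant_masked_values(self):
        pae = np.full((4, 4), 3.0)
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 2] = True
        assert ipae_score(pae, mask) == 3.0

    def test_even_count_uses_mean_of_middle_pair(self):
        pae = np.zeros((4, 4))
        pae[0, 2], pae[2, 0], pae[1, 3], pae[3, 1] = 2.0, 4.0, 6.0, 8.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 2] = mask[1, 3] = True  # transposes pulled in automatically
        assert ipae_score(pae, mask) == 5.0

    def test_planted_block_matches_oracle(self, flank_trio):
        bundle = flank_trio[0]
        mask = interface_mask_from_contacts(
            bundle.get_contact_map(), bundle.chains, 0.5
        )
        expected = ref.naive_ipae(
            bundle.pae.tolist(),
            ref.naive_interface_mask(
                bundle.get_contact_map().q.tolist(),
                list(bundle.chains.asym_id),
                0.5,
            ),
        )
        assert ipae_score(bundle.pae, mask) == pytest.approx(expected, abs=1e-12)

    def test_empty_mask_is_no_interface_error(self):
        with pytest.raises(NoInterfaceError):
            ipae_score(np.ones((3, 3)), np.zeros((3, 3), dtype=bool))


class TestInterfacePlddt:
    def _setup(self, plddt_b):
        chains = ChainPartition.from_lengths([3, 2])
        q = np.zeros((5, 5))
        q[0, 3] = q[3, 0] = 1.0
        q[1, 4] = q[4, 1] = 1.0
        plddt = np.array([70.0, 75.0, 60.0] + plddt_b)
        return plddt, chains, ContactMap(q)

    def test_uniform_interface_plddt(self):
        plddt, chains, q = self._setup([90.0, 90.0])
        assert interface_plddt(plddt, chains, q, "B") == 90.0

    def test_mean_of_two_interface_residues(self):
        plddt, chains, q = self._setup([80.0, 90.0])
        assert interface_plddt(plddt, chains, q, "B") == 85.0

    def test_only_called_residues_enter_the_mean(self):
        plddt, chains, q = self._setup([80.0, 90.0])
        assert interface_plddt(plddt, chains, q, "A") == pytest.approx(72.5)

    def test_focus_chain_without_interface_raises(self):
        chains = ChainPartition.from_lengths([2, 2])
        q = ContactMap(np.zeros((4, 4)))
        with pytest.raises(NoInterfaceError):
            interface_plddt(np.full(4, 90.0), chains, q, "B")

    def test_matches_oracle_on_flank_bundle(self, flank_trio):
        bundle = flank_trio[2]
        got = interface_plddt(
            bundle.plddt, bundle.chains, bundle.get_contact_map(), "B"
        )
        expected = ref.naive_interface_plddt(
            bundle.plddt.tolist(),
            bundle.get_contact_map().q.tolist(),
            list(bundle.chains.asym_id),
            "B",
            0.5,
        )
        assert got == pytest.approx(expected, abs=1e-12)


class TestConfidenceAndSuccess:
    @pytest.mark.parametrize(
        "ptm, iptm, expected",
        [(1.0, 1.0, 1.0), (0.5, 1.0, 0.9), (0.2, 0.85, 0.72)],
    )
    def test_model_confidence_is_fixed_mixture(self, ptm, iptm, expected):
        assert model_confidence(ptm, iptm) == pytest.approx(expected, abs=1e-12)

    def test_thresholds_are_strict_inequalities(self):
        report = ScoreReport(
            iptm=0.85, confidence=0.85, actifptm=0.85, ipae=5.0, interface_plddt=85.0
        )
        assert classify_success(report) == {
            "interface_plddt": False,
            "ipae": False,
            "iptm": False,
            "confidence": False,
            "actifptm": False,
        }
        report = ScoreReport(ipae=4.99, iptm=0.86)
        flags = classify_success(report)
        assert flags["ipae"] is True and flags["iptm"] is True

    def test_missing_scalars_yield_absent_flags_not_false(self):
        flags = classify_success(ScoreReport(iptm=0.9))
        assert flags == {"iptm": True}

    def test_threshold_overrides(self):
        flags = classify_success(ScoreReport(iptm=0.6), {"iptm": 0.5})
        assert flags == {"iptm": True}


class TestScoreBundle:
    def test_full_pipeline_produces_consistent_report(self, seed7_bundle):
        report = score_bundle(seed7_bundle)
        assert 0 < report.ptm <= 1 and 0 < report.iptm <= 1
        assert report.confidence == pytest.approx(
            0.8 * report.iptm + 0.2 * report.ptm, abs=1e-15
        )
        assert report.actifptm == pytest.approx(
            max(report.per_residue_rowsums), abs=1e-12
        )
        assert report.focus_chain == min(
            report.chain_order, key=seed7_bundle.chains.length_of
        )

    def test_single_chain_bundle_rejected(self):
        bundle = make_random_bundle(N=8, n_chains=1, seed=1)
        with pytest.raises(SingleChainError, match="single chain"):
            score_bundle(bundle)

    def test_pae_only_bundle_yields_no_tm_scores(self):
        from actifptm import PredictionBundle

        bundle = PredictionBundle(
            chains=ChainPartition.from_lengths([5, 5]),
            plddt=np.full(10, 70.0),
            pae=np.full((10, 10), 4.0),
        )
        report = score_bundle(bundle)
        assert report.ptm is None and report.iptm is None
        assert report.actifptm is None
        assert "iptm" not in report.success_flags
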