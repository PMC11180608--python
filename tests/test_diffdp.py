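"""Differentiable NW: oracle equivalence, derivative identities, limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alnvec.diffdp import (
    AlignmentPath,
    ScoreMatrices,
    SmoothingConfig,
    enumerate_paths_oracle,
    nw_alignment_grads,
    nw_directional,
    nw_expected_alignment,
    nw_forward,
    nw_forward_padded,
    nw_hard_decode,
    smooth_max,
    read_expected_tsv,
    write_expected_tsv,
)

BOTH_MODES = ["as_printed", "path_strict"]


def random_scores(rng, p, q):
    return ScoreMatrices(rng.normal(0.0, 1.5, (p, q)), rng.normal(-1.0, 1.0, (p, q)))


# ---------------------------------------------------------------------------
# smooth max
# ---------------------------------------------------------------------------


class TestSmoothMax:
    def test_symmetric_input_splits_weights_evenly(self):
        v, w = smooth_max([0.0, 0.0, 0.0])
        assert v == pytest.approx(math.log(3.0))
        np.testing.assert_allclose(w, [1 / 3] * 3)

    def test_low_temperature_approaches_hard_max(self):
        v, w = smooth_max([5.0, 0.0, 0.0], SmoothingConfig(temperature=1e-3))
        assert v == pytest.approx(5.0, abs=1e-6)
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0], atol=1e-6)

    def test_two_entry_value(self):
        v, _ = smooth_max([1.0, 2.0])
        assert v == pytest.approx(2.0 + math.log1p(math.exp(-1.0)))

    def test_neg_inf_entries_get_zero_weight(self):
        v, w = smooth_max([1.0, -np.inf])
        assert v == pytest.approx(1.0)
        assert w[1] == 0.0

    def test_all_neg_inf_signals_no_transition(self):
        with pytest.raises(ValueError, match="admissible"):
            smooth_max([-np.inf, -np.inf])

    @given(
        xs=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        tau=st.floats(0.05, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_normalization(self, xs, tau):
        v, w = smooth_max(xs, SmoothingConfig(temperature=tau))
        assert v >= max(xs) - 1e-9
        assert v - max(xs) <= tau * math.log(len(xs)) + 1e-9
        assert w.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# forward recursion
# ---------------------------------------------------------------------------


class TestForward:
    def test_single_cell_path_strict_forced_match(self):
        f = nw_forward(
            ScoreMatrices([[2.0]], [[-1.0]]), SmoothingConfig(border_mode="path_strict")
        )
        assert f.terminal == pytest.approx(2.0)
        np.testing.assert_allclose(f.weights[0, 0], [1.0, 0.0, 0.0])

    def test_two_by_two_zeros_path_strict_counts_three_paths(self):
        sm = ScoreMatrices(np.zeros((2, 2)), np.zeros((2, 2)))
        f = nw_forward(sm, SmoothingConfig(border_mode="path_strict"))
        assert f.terminal == pytest.approx(math.log(3.0))

    def test_single_cell_as_printed_boundary_weights(self):
        f = nw_forward(ScoreMatrices([[0.0]], [[0.0]]), SmoothingConfig())
        assert f.terminal == pytest.approx(math.log(math.e + 2.0))

    def test_weights_are_probability_triples(self):
        rng = np.random.default_rng(0)
        for mode in BOTH_MODES:
            f = nw_forward(random_scores(rng, 5, 4), SmoothingConfig(border_mode=mode))
            assert (f.weights >= 0).all()
            np.testing.assert_allclose(f.weights.sum(axis=2), 1.0, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ScoreMatrices(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            SmoothingConfig(temperature=0.0)

    def test_padded_batch_matches_individual_evaluation(self):
        rng = np.random.default_rng(3)
        shapes = [(3, 5), (2, 2), (4, 1)]
        P, Q = 5, 6
        mu = rng.normal(0, 1, (3, P, Q))
        gap = rng.normal(-1, 1, (3, P, Q))
        batch = nw_forward_padded(mu, gap, shapes)
        for b, (p, q) in enumerate(shapes):
            solo = nw_forward(ScoreMatrices(mu[b, :p, :q], gap[b, :p, :q]))
            assert np.array_equal(batch[b].value, solo.value)
            assert np.array_equal(batch[b].weights, solo.weights)
            # padding content must be irrelevant
            mu2 = mu.copy()
            mu2[b, p:, :] = 1e6
            again = nw_forward_padded(mu2, gap, shapes)
            assert np.array_equal(again[b].value, solo.value)


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------


class TestOracleEquivalence:
    def test_two_by_two_zeros_marginals(self):
        sm = ScoreMatrices(np.zeros((2, 2)), np.zeros((2, 2)))
        cfg = SmoothingConfig(border_mode="path_strict")
        orc = enumerate_paths_oracle(sm, cfg)
        assert orc.value == pytest.approx(math.log(3.0))
        np.testing.assert_allclose(
            orc.marginals, [[1.0, 1 / 3], [1 / 3, 1.0]], atol=1e-12
        )
        e = nw_expected_alignment(nw_forward(sm, cfg)).e
        np.testing.assert_allclose(e, orc.marginals, atol=1e-9)
        np.testing.assert_allclose(e, e.T, atol=1e-12)

    def test_single_cell_marginal_is_one(self):
        orc = enumerate_paths_oracle(
            ScoreMatrices([[0.7]], [[-0.3]]), SmoothingConfig(border_mode="path_strict")
        )
        assert orc.marginals[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", BOTH_MODES)
    @pytest.mark.parametrize("mu_on_gaps", [True, False])
    def test_forward_and_marginals_match_enumeration(self, mode, mu_on_gaps):
        rng = np.random.default_rng(42)
        cfg = SmoothingConfig(border_mode=mode, mu_on_gaps=mu_on_gaps)
        for _ in range(60):
            p, q = rng.integers(1, 7, size=2)
            sm = random_scores(rng, p, q)
            orc = enumerate_paths_oracle(sm, cfg)
            fwd = nw_forward(sm, cfg)
            assert fwd.terminal == pytest.approx(orc.value, abs=1e-8)
            e = nw_expected_alignment(fwd).e
            np.testing.assert_allclose(e, orc.marginals, atol=1e-8)
            assert (e >= -1e-9).all() and (e <= 1 + 1e-9).all()

    def test_temperature_scaling_agrees_with_oracle(self):
        rng = np.random.default_rng(5)
        sm = random_scores(rng, 3, 3)
        for tau in (0.3, 2.5):
            cfg = SmoothingConfig(temperature=tau, border_mode="path_strict")
            assert nw_forward(sm, cfg).terminal == pytest.approx(
                enumerate_paths_oracle(sm, cfg).value, abs=1e-8
            )

    def test_total_marginal_mass_matches_oracle(self):
        rng = np.random.default_rng(9)
        cfg = SmoothingConfig(border_mode="path_strict")
        sm = random_scores(rng, 4, 5)
        orc = enumerate_paths_oracle(sm, cfg)
        e = nw_expected_alignment(nw_forward(sm, cfg)).e
        assert e.sum() == pytest.approx(orc.marginals.sum(), abs=1e-8)

    def test_oracle_refuses_large_grids(self):
        with pytest.raises(ValueError, match="too large"):
            enumerate_paths_oracle(ScoreMatrices(np.zeros((7, 6)), np.zeros((7, 6))))


# ---------------------------------------------------------------------------
# derivative identities
# ---------------------------------------------------------------------------


def fd_value(sm, cfg, zmu, zg, h=1e-5):
    vp = nw_forward(ScoreMatrices(sm.mu + h * zmu, sm.gap + h * zg), cfg).terminal
    vm = nw_forward(ScoreMatrices(sm.mu - h * zmu, sm.gap - h * zg), cfg).terminal
    return (vp - vm) / (2 * h)


class TestDerivatives:
    @pytest.mark.parametrize("mode", BOTH_MODES)
    def test_expected_alignment_is_gradient_of_value(self, mode):
        rng = np.random.default_rng(17)
        cfg = SmoothingConfig(border_mode=mode)
        for _ in range(10):
            p, q = rng.integers(1, 6, size=2)
            sm = random_scores(rng, p, q)
            e = nw_expected_alignment(nw_forward(sm, cfg)).e
            for i in range(p):
                for j in range(q):
                    z = np.zeros((p, q))
                    z[i, j] = 1.0
                    fd = fd_value(sm, cfg, z, np.zeros_like(z))
                    assert e[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    @pytest.mark.parametrize("mode", BOTH_MODES)
    def test_directional_derivative_matches_finite_differences(self, mode):
        rng = np.random.default_rng(23)
        cfg = SmoothingConfig(border_mode=mode)
        for _ in range(15):
            p, q = rng.integers(2, 6, size=2)
            sm = random_scores(rng, p, q)
            z = (rng.normal(0, 1, (p, q)), rng.normal(0, 1, (p, q)))
            fwd = nw_forward(sm, cfg)
            d = nw_directional(sm, z, fwd)
            assert d.vdot == pytest.approx(fd_value(sm, cfg, *z), rel=1e-4, abs=1e-7)
            h = 1e-5
            ep = nw_expected_alignment(
                nw_forward(ScoreMatrices(sm.mu + h * z[0], sm.gap + h * z[1]), cfg)
            ).e
            em = nw_expected_alignment(
                nw_forward(ScoreMatrices(sm.mu - h * z[0], sm.gap - h * z[1]), cfg)
            ).e
            np.testing.assert_allclose(d.edot, (ep - em) / (2 * h), rtol=1e-3, atol=1e-6)

    def test_zero_perturbation_gives_zero_derivatives(self):
        sm = random_scores(np.random.default_rng(1), 3, 4)
        fwd = nw_forward(sm)
        d = nw_directional(sm, (np.zeros((3, 4)), np.zeros((3, 4))), fwd)
        assert d.vdot == 0.0
        assert np.all(d.edot == 0.0)

    def test_directional_derivative_is_linear_in_z(self):
        rng = np.random.default_rng(31)
        sm = random_scores(rng, 3, 3)
        fwd = nw_forward(sm)
        z1 = (rng.normal(0, 1, (3, 3)), rng.normal(0, 1, (3, 3)))
        z2 = (rng.normal(0, 1, (3, 3)), rng.normal(0, 1, (3, 3)))
        combo = (2 * z1[0] + 3 * z2[0], 2 * z1[1] + 3 * z2[1])
        dc = nw_directional(sm, combo, fwd)
        d1 = nw_directional(sm, z1, fwd)
        d2 = nw_directional(sm, z2, fwd)
        assert dc.vdot == pytest.approx(2 * d1.vdot + 3 * d2.vdot, abs=1e-8)
        np.testing.assert_allclose(dc.edot, 2 * d1.edot + 3 * d2.edot, atol=1e-8)

    def test_perturbation_shape_mismatch_rejected(self):
        sm = random_scores(np.random.default_rng(2), 3, 3)
        with pytest.raises(ValueError):
            nw_directional(sm, (np.zeros((2, 3)), np.zeros((2, 3))), nw_forward(sm))

    def test_reverse_mode_pullback_matches_finite_differences(self):
        """dL/dmu and dL/dgap for a loss on e, vs central differences."""
        rng = np.random.default_rng(77)
        cfg = SmoothingConfig()
        p, q = 4, 3
        sm = random_scores(rng, p, q)
        u = rng.normal(0, 1, (p, q))
        dmu, dgap, _ = nw_alignment_grads(sm, cfg, u)

        def scalar(mu, gap):
            e = nw_expected_alignment(nw_forward(ScoreMatrices(mu, gap), cfg)).e
            return float((u * e).sum())

        h = 1e-6
        for i in range(p):
            for j in range(q):
                mp, mm = sm.mu.copy(), sm.mu.copy()
                mp[i, j] += h
                mm[i, j] -= h
                assert dmu[i, j] == pytest.approx(
                    (scalar(mp, sm.gap) - scalar(mm, sm.gap)) / (2 * h), rel=1e-3, abs=1e-6
                )
                gp, gm = sm.gap.copy(), sm.gap.copy()
                gp[i, j] += h
                gm[i, j] -= h
                assert dgap[i, j] == pytest.approx(
                    (scalar(sm.mu, gp) - scalar(sm.mu, gm)) / (2 * h), rel=1e-3, abs=1e-6
                )


# ---------------------------------------------------------------------------
# hard decode & zero-temperature limit
# ---------------------------------------------------------------------------


class TestHardDecode:
    def test_diagonal_dominant_scores_decode_to_all_match(self):
        mu = np.where(np.eye(3, dtype=bool), 5.0, 0.1)
        score, path = nw_hard_decode(ScoreMatrices(mu, np.full((3, 3), -1.0)))
        assert path.states == "MMM"
        assert score == pytest.approx(15.0)

    def test_single_cell_is_always_a_match(self):
        _, path = nw_hard_decode(ScoreMatrices([[-(2.0)]], [[-5.0]]))
        assert path.states == "M"

    def test_replayed_path_score_equals_returned_score(self):
        rng = np.random.default_rng(13)
        cfg = SmoothingConfig(border_mode="path_strict")
        for _ in range(20):
            p, q = rng.integers(1, 7, size=2)
            sm = random_scores(rng, p, q)
            score, path = nw_hard_decode(sm)
            assert path.replay_score(sm, cfg) == pytest.approx(score, abs=1e-12)
            assert (path.p, path.q) == (p, q)

    def test_hard_decode_equals_enumeration_argmax(self):
        rng = np.random.default_rng(19)
        cfg = SmoothingConfig(border_mode="path_strict")
        for _ in range(25):
            p, q = rng.integers(1, 6, size=2)
            sm = random_scores(rng, p, q)
            score, path = nw_hard_decode(sm)
            orc = enumerate_paths_oracle(sm, cfg)
            assert score == pytest.approx(orc.best_score, abs=1e-10)
            assert path.states == orc.best_states

    def test_smoothed_value_decreases_to_hard_score_with_temperature(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            p, q = rng.integers(2, 6, size=2)
            sm = random_scores(rng, p, q)
            hard, _ = nw_hard_decode(sm)
            prev = np.inf
            for tau in (1.0, 0.1, 0.01):
                v = nw_forward(
                    sm, SmoothingConfig(temperature=tau, border_mode="path_strict")
                ).terminal
                assert hard - 1e-9 <= v <= prev + 1e-12
                assert v - hard <= tau * math.log(3.0 * p * q) + 1e-9
                prev = v


# ---------------------------------------------------------------------------
# AlignmentPath contract and serialization
# ---------------------------------------------------------------------------


class TestAlignmentPath:
    def test_replay_consumes_both_sequences(self):
        path = AlignmentPath("MXYMM")
        assert (path.p, path.q) == (4, 4)
        assert path.edges == {(1, 1), (3, 3), (4, 4)}

    def test_edges_strictly_increasing(self):
        with pytest.raises(ValueError):
            AlignmentPath.from_edges([(1, 2), (2, 2)], 3, 3)

    def test_from_edges_round_trip(self):
        path = AlignmentPath.from_edges([(2, 1), (4, 3)], 5, 4)
        assert AlignmentPath(path.states).edges == {(2, 1), (4, 3)}
        assert (path.p, path.q) == (5, 4)

    def test_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            AlignmentPath("MZM")

    def test_expected_alignment_tsv_round_trip(self, tmp_path):
        sm = random_scores(np.random.default_rng(4), 3, 5)
        exp = nw_expected_alignment(nw_forward(sm))
        f = tmp_path / "e.tsv"
        write_expected_tsv(f, exp)
        np.testing.assert_allclose(read_expected_tsv(f), exp.e, atol=1e-10)
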