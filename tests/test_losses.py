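"""Loss terms checked against naive loop oracles and closed forms."""

import numpy as np
import pytest

from dcseg import losses as L
from dcseg.nn import Tensor

from conftest import (oracle_avg, oracle_cr, oracle_hc, oracle_kl,
                      oracle_sup, oracle_urc, random_prob_maps)


# ---------------------------------------------------------------------------
# supervised loss
# ---------------------------------------------------------------------------

class TestSupervisedLoss:
    def test_perfect_onehot_prediction_is_numerically_zero(self, rng):
        mask = rng.integers(0, 2, (1, 8, 8))
        onehot = np.stack([(mask == c).astype(np.float32) for c in range(2)],
                          axis=1)
        val = L.supervised_loss([onehot] * 5, mask).item()
        assert val == pytest.approx(0.0, abs=1e-5)

    def test_uniform_prediction_ce_closed_form(self):
        # uniform over K=2: CE = ln 2 per level; 5 levels, 0.5 CE weight
        mask = np.zeros((1, 4, 4), dtype=int)
        uniform = np.full((1, 2, 4, 4), 0.5, dtype=np.float32)
        maps = [uniform] * 5
        val = L.supervised_loss(maps, mask).item()
        # Dice part: class0 ratio 2*8/(8+16)=2/3, class1 2*0/(8+0);
        # subtract it to isolate the CE contribution
        dice_per_level = 1.0 - 0.5 * (2 * 8 / (8 + 16) + 0.0)
        ce_part = val - 5 * 0.5 * dice_per_level
        assert ce_part == pytest.approx(5 * 0.5 * np.log(2), rel=1e-4)

    def test_alpha_linearity(self, rng):
        maps = random_prob_maps(rng, 3, 2, 6, 6)
        mask = rng.integers(0, 2, (1, 6, 6))
        one = L.supervised_loss(maps, mask, alpha=[1, 1, 1]).item()
        two = L.supervised_loss(maps, mask, alpha=[2, 2, 2]).item()
        assert two == pytest.approx(2 * one, rel=1e-5)

    def test_matches_loop_oracle(self, rng):
        for _ in range(5):
            s = int(rng.integers(2, 5))
            k = int(rng.integers(2, 4))
            maps = random_prob_maps(rng, s, k, 8, 8)
            mask = np.asarray(rng.integers(0, k, (1, 8, 8)))
            got = L.supervised_loss(maps, mask).item()
            want = oracle_sup(maps, mask)
            assert got == pytest.approx(want, abs=1e-5)

    def test_out_of_range_mask_raises(self, rng):
        maps = random_prob_maps(rng, 2, 2, 4, 4)
        with pytest.raises(ValueError, match="classes"):
            L.supervised_loss(maps, np.full((1, 4, 4), 7))

    def test_none_fine_map_is_skipped(self, rng):
        maps = random_prob_maps(rng, 3, 2, 4, 4)
        mask = np.asarray(rng.integers(0, 2, (1, 4, 4)))
        with_none = L.supervised_loss([None] + maps, mask).item()
        assert with_none == pytest.approx(
            L.supervised_loss(maps, mask).item(), rel=1e-6)


# ---------------------------------------------------------------------------
# consistency terms
# ---------------------------------------------------------------------------

class TestHierarchicalConsistency:
    def test_average_of_identical_maps_is_the_map(self, rng):
        m = random_prob_maps(rng, 1, 3, 4, 4)[0]
        avg = L.average_prediction([m, m, m])
        np.testing.assert_allclose(avg.data, m, atol=1e-6)

    def test_average_channel_sums_are_one(self, rng):
        maps = random_prob_maps(rng, 4, 3, 6, 6)
        avg = L.average_prediction(maps)
        np.testing.assert_allclose(avg.data.sum(axis=1), 1.0, atol=1e-6)

    def test_two_level_disagreement_pixel(self):
        p1 = np.zeros((1, 2, 1, 1), np.float32)
        p2 = np.zeros((1, 2, 1, 1), np.float32)
        p1[0, 0] = 1.0
        p2[0, 1] = 1.0
        avg = L.average_prediction([p1, p2])
        np.testing.assert_allclose(avg.data[0, :, 0, 0], [0.5, 0.5])

    def test_identical_levels_give_zero(self, rng):
        m = random_prob_maps(rng, 1, 2, 5, 5)[0]
        assert L.hierarchical_consistency([m, m, m]).item() == pytest.approx(0.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            s = int(rng.integers(2, 5))
            maps = random_prob_maps(rng, s, 2, 4, 4)
            got = L.hierarchical_consistency(maps).item()
            assert got == pytest.approx(oracle_hc(maps), abs=1e-6)

    def test_level_permutation_invariance(self, rng):
        maps = random_prob_maps(rng, 4, 3, 4, 4)
        a = L.hierarchical_consistency(maps).item()
        b = L.hierarchical_consistency(maps[::-1]).item()
        assert a == pytest.approx(b, rel=1e-6)


class TestUncertaintyMap:
    def test_identical_maps_give_zero_divergence_unit_weight(self, rng):
        m = random_prob_maps(rng, 1, 3, 4, 4)[0]
        um = L.uncertainty_map([m, m])
        np.testing.assert_allclose(um.d, 0.0, atol=1e-6)
        np.testing.assert_allclose(um.w, 1.0, atol=1e-6)

    def test_kl_nonnegative_and_weights_in_unit_interval(self, rng):
        for _ in range(10):
            maps = random_prob_maps(rng, 3, 3, 6, 6)
            um = L.uncertainty_map(maps)
            assert (um.d >= 0).all()
            assert (um.w > 0).all() and (um.w <= 1).all()

    def test_hand_computed_kl_value(self):
        # KL((0.9,0.1) || (0.5,0.5)) = 0.9 ln 1.8 + 0.1 ln 0.2
        p = np.array([0.9, 0.1], np.float32).reshape(1, 2, 1, 1)
        q = np.array([0.5, 0.5], np.float32).reshape(1, 2, 1, 1)
        um = L.uncertainty_map([p], p_avg=q)
        want = 0.9 * np.log(1.8) + 0.1 * np.log(0.2)
        assert um.d[0, 0, 0, 0] == pytest.approx(want, abs=1e-5)
        assert want == pytest.approx(0.3681, abs=1e-4)

    def test_matches_loop_oracle(self, rng):
        maps = random_prob_maps(rng, 3, 2, 4, 4)
        um = L.uncertainty_map(maps)
        np.testing.assert_allclose(um.d, oracle_kl(maps), atol=1e-5)


class TestRectifiedConsistency:
    def test_unit_weights_reduce_to_hierarchical(self, rng):
        maps = random_prob_maps(rng, 3, 2, 5, 5)
        um = L.UncertaintyMap(d=np.zeros((3, 1, 5, 5)),
                              w=np.ones((3, 1, 5, 5)))
        got = L.rectified_consistency(maps, umap=um).item()
        assert got == pytest.approx(
            L.hierarchical_consistency(maps).item(), abs=1e-6)

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            s = int(rng.integers(2, 5))
            maps = random_prob_maps(rng, s, 2, 4, 4)
            got = L.rectified_consistency(maps).item()
            assert got == pytest.approx(oracle_urc(maps), abs=1e-6)

    def test_raising_divergence_shrinks_pixel_contribution(self, rng):
        maps = random_prob_maps(rng, 2, 2, 4, 4)
        um = L.uncertainty_map(maps)
        base = L.rectified_consistency(maps, umap=um).item()
        # find the highest-discrepancy pixel of level 0 and inflate its d
        avg = oracle_avg(maps)
        sq = ((maps[0] - avg) ** 2).sum(axis=1)[0]
        i, j = np.unravel_index(sq.argmax(), sq.shape)
        d2 = um.d.copy()
        d2[0, 0, i, j] += 5.0
        um2 = L.UncertaintyMap(d=d2, w=np.exp(-d2))
        assert L.rectified_consistency(maps, umap=um2).item() < base

    def test_zero_weights_raise(self, rng):
        maps = random_prob_maps(rng, 2, 2, 3, 3)
        um = L.UncertaintyMap(d=np.zeros((2, 1, 3, 3)),
                              w=np.zeros((2, 1, 3, 3)))
        with pytest.raises(ValueError, match="zero"):
            L.rectified_consistency(maps, umap=um)


class TestCoarseFineConsistency:
    def test_identical_maps_give_zero(self, rng):
        m = random_prob_maps(rng, 1, 2, 4, 4)[0]
        assert L.cfgc_loss(m, m).item() == pytest.approx(0.0)

    def test_single_pixel_disagreement_value(self):
        # one differing pixel (1,0) vs (0,1) in a 2-channel 2x2 map -> 2/4
        p0 = np.zeros((1, 2, 2, 2), np.float32)
        p1 = np.zeros((1, 2, 2, 2), np.float32)
        p0[0, 0] = 1.0
        p1[0, 0] = 1.0
        p0[0, :, 0, 0] = [1, 0]
        p1[0, :, 0, 0] = [0, 1]
        assert L.cfgc_loss(p0, p1).item() == pytest.approx(2 / 4)

    def test_numerically_symmetric(self, rng):
        a, b = random_prob_maps(rng, 2, 3, 5, 5)
        assert L.cfgc_loss(a, b).item() == pytest.approx(
            L.cfgc_loss(b, a).item(), rel=1e-6)

    def test_matches_loop_oracle(self, rng):
        a, b = random_prob_maps(rng, 2, 2, 4, 4)
        assert L.cfgc_loss(a, b).item() == pytest.approx(
            oracle_cr(a, b), abs=1e-6)

    def test_shape_mismatch_raises(self, rng):
        a = random_prob_maps(rng, 1, 2, 4, 4)[0]
        b = random_prob_maps(rng, 1, 2, 5, 5)[0]
        with pytest.raises(ValueError, match="mismatch"):
            L.cfgc_loss(a, b)

    def test_gradient_blocked_on_fine_flows_through_coarse(self, rng):
        a = Tensor(random_prob_maps(rng, 1, 2, 4, 4)[0], requires_grad=True)
        b = Tensor(random_prob_maps(rng, 1, 2, 4, 4)[0], requires_grad=True)
        L.cfgc_loss(a, b).backward()
        assert a.grad is None
        assert b.grad is not None and np.abs(b.grad).max() > 0

    def test_symmetric_mode_propagates_both(self, rng):
        a = Tensor(random_prob_maps(rng, 1, 2, 4, 4)[0], requires_grad=True)
        b = Tensor(random_prob_maps(rng, 1, 2, 4, 4)[0], requires_grad=True)
        L.cfgc_loss(a, b, stop_gradient=False).backward()
        assert np.abs(a.grad).max() > 0 and np.abs(b.grad).max() > 0


# ---------------------------------------------------------------------------
# schedule and assembly
# ---------------------------------------------------------------------------

class TestSchedule:
    def test_endpoint_values(self):
        cfg = L.ScheduleConfig(k=0.1, total_iters=1000)
        assert L.lambda_schedule(1000, cfg) == pytest.approx(0.1)
        assert L.lambda_schedule(0, cfg) == pytest.approx(0.1 * np.exp(-5),
                                                          rel=1e-6)
        assert L.lambda_schedule(500, cfg) == pytest.approx(
            0.1 * np.exp(-1.25), rel=1e-6)

    def test_monotone_nondecreasing_and_clamped(self):
        cfg = L.ScheduleConfig(k=0.1, total_iters=777)
        ts = np.linspace(0, 777, 1000)
        vals = [L.lambda_schedule(t, cfg) for t in ts]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert L.lambda_schedule(5000, cfg) == pytest.approx(0.1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            L.ScheduleConfig(k=-1)
        with pytest.raises(ValueError):
            L.ScheduleConfig(beta=1.5)


class TestTotalLoss:
    def test_equal_terms_collapse_at_beta_half(self):
        cfg = L.ScheduleConfig(k=0.1, total_iters=10, beta=0.5)
        b = L.total_loss(1.0, 0.3, 0.3, t=10, cfg=cfg)
        assert b.l_unsup == pytest.approx(0.3)

    def test_beta_one_keeps_only_rectified_term(self):
        cfg = L.ScheduleConfig(k=0.1, total_iters=10, beta=1.0)
        b = L.total_loss(1.0, 0.3, 0.9, t=10, cfg=cfg)
        assert b.l_unsup == pytest.approx(0.3)

    def test_warmup_start_weight(self):
        cfg = L.ScheduleConfig(k=0.1, total_iters=10_000)
        b = L.total_loss(2.0, 1.0, 1.0, t=0, cfg=cfg)
        assert b.lam == pytest.approx(6.7379e-4, rel=1e-3)
        assert b.l_total == pytest.approx(2.0 + 6.7379e-4, rel=1e-4)

    def test_bundle_identities(self, rng):
        cfg = L.ScheduleConfig(k=0.1, total_iters=50, beta=0.5)
        for _ in range(10):
            s, u, c, t = rng.random(4)
            b = L.total_loss(s, u, c, t=t * 50, cfg=cfg)
            assert b.l_unsup == pytest.approx(0.5 * u + 0.5 * c, abs=1e-6)
            assert b.l_total == pytest.approx(b.l_sup + b.lam * b.l_unsup,
                                              abs=1e-6)
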