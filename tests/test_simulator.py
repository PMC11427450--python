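import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from mudrop.grid import default_grid, make_grid
from mudrop.simulator import (ActuationPattern, PhysicsParams, VirtualDevice,
                              VirtualDroplet, adjust_brightness, render_frame,
                              step_physics)
from mudrop.states import DropletState


# ---------------------------------------------------------------------------
# brightness
# ---------------------------------------------------------------------------

class TestAdjustBrightness:
    def test_identity_at_factor_one(self):
        img = np.arange(48, dtype=np.uint8).reshape(4, 4, 3)
        assert np.array_equal(adjust_brightness(img, 1.0), img)

    def test_scales_pixel_values(self):
        img = np.full((2, 2, 3), 100, dtype=np.uint8)
        assert np.all(adjust_brightness(img, 1.5) == 150)

    def test_saturates_at_channel_maximum(self):
        img = np.full((2, 2, 3), 200, dtype=np.uint8)
        assert np.all(adjust_brightness(img, 1.8) == 255)

    @pytest.mark.parametrize("factor", [0.0, -1.0])
    def test_nonpositive_factor_rejected(self, factor):
        with pytest.raises(ValueError):
            adjust_brightness(np.zeros((2, 2, 3), np.uint8), factor)

    @given(st.integers(0, 127), st.sampled_from([1.25, 1.5, 2.0]))
    @settings(max_examples=30, deadline=None)
    def test_involution_where_no_clipping(self, value, factor):
        img = np.full((2, 2, 3), value, dtype=np.uint8)
        up = adjust_brightness(img, factor)
        if up.max() < 255:   # no clipping occurred
            assert np.array_equal(adjust_brightness(up, 1.0 / factor), img)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

class TestRenderFrame:
    def test_single_unsplit_droplet_is_one_class1_region(self, grid):
        d = VirtualDroplet(0, 800.0, (64.0, 64.0))
        f = render_frame([d], grid)
        assert set(np.unique(f.mask)) == {0, 1}
        _, n = ndimage.label(f.mask == 1)
        assert n == 1

    def test_split_pair_far_apart_both_class3(self, grid):
        a = VirtualDroplet(0, 500.0, (64.0, 30.0), DropletState.SPLIT)
        b = VirtualDroplet(1, 500.0, (64.0, 98.0), DropletState.SPLIT)
        f = render_frame([a, b], grid)
        _, n = ndimage.label(f.mask == 3)
        assert n == 2
        assert set(np.unique(f.mask)) == {0, 3}

    def test_hourglass_neck_splits_under_erosion(self, grid):
        d = VirtualDroplet(0, 900.0, (64.0, 64.0), DropletState.SPLITTING,
                           neck_px=4.0, lobe_span=17.0)
        f = render_frame([d], grid)
        sil = f.mask == 2
        _, n = ndimage.label(sil)
        assert n == 1   # connected through the neck
        eroded = ndimage.binary_erosion(sil, iterations=2)
        _, n2 = ndimage.label(eroded)
        assert n2 == 2  # a 4-px neck vanishes under 2-px erosion

    def test_mask_pixels_match_rendered_droplet_footprint(self, grid):
        for color in ("red", "transparent"):
            d = VirtualDroplet(0, 800.0, (64.0, 64.0), color=color)
            f = render_frame([d], grid)
            clean = render_frame([], grid)
            changed = np.any(f.image != clean.image, axis=-1)
            assert np.array_equal(changed, f.mask == 1)

    def test_overlapping_incompatible_states_rejected(self, grid):
        a = VirtualDroplet(0, 800.0, (64.0, 64.0), DropletState.UNSPLIT)
        b = VirtualDroplet(1, 800.0, (64.0, 70.0), DropletState.MERGING)
        with pytest.raises(ValueError, match="ambiguous"):
            render_frame([a, b], grid)

    def test_droplet_off_canvas_rejected(self, grid):
        d = VirtualDroplet(0, 900.0, (4.0, 4.0))
        with pytest.raises(ValueError, match="fit"):
            render_frame([d], grid)

    def test_rendering_is_deterministic_per_seed(self, grid):
        d = VirtualDroplet(0, 800.0, (64.0, 64.0))
        f1 = render_frame([d], grid, rng=np.random.default_rng(5), noise_sd=2.0)
        f2 = render_frame([d], grid, rng=np.random.default_rng(5), noise_sd=2.0)
        assert np.array_equal(f1.image, f2.image)


# ---------------------------------------------------------------------------
# physics
# ---------------------------------------------------------------------------

def _strip_droplet(volume=900.0, at=2):
    g = make_grid(1, 5, 32, margin_px=20)
    return g, VirtualDroplet(0, volume, g.center(at))


class TestStepPhysics:
    def test_certain_move_lands_on_target_center(self):
        g, d = _strip_droplet()
        p = PhysicsParams(move_success_prob=1.0)
        out = step_physics([d], ActuationPattern(frozenset({3})), g, p,
                           np.random.default_rng(0))
        assert out[0].centroid == g.center(3)

    def test_noiseless_split_gives_exact_halves(self):
        g, d = _strip_droplet(volume=800.0)
        p = PhysicsParams(split_pull_prob=0.0, split_asymmetry_sd=0.0)
        rng = np.random.default_rng(0)
        pat = ActuationPattern(frozenset({1, 3}))
        mid = step_physics([d], pat, g, p, rng)
        assert mid[0].state is DropletState.SPLITTING
        out = step_physics(mid, pat, g, p, rng)
        assert [o.state for o in out] == [DropletState.SPLIT] * 2
        assert [o.volume for o in out] == [400.0, 400.0]

    def test_merge_conserves_volume(self):
        g = make_grid(1, 5, 32, margin_px=20)
        a = VirtualDroplet(0, 300.0, g.center(1))
        b = VirtualDroplet(1, 500.0, g.center(2))
        p = PhysicsParams(move_success_prob=1.0)
        rng = np.random.default_rng(0)
        drops = [a, b]
        for _ in range(4):
            drops = step_physics(drops, ActuationPattern(frozenset({2})), g,
                                 p, rng)
            if len(drops) == 1:
                break
        assert len(drops) == 1
        assert drops[0].state is DropletState.UNSPLIT
        assert drops[0].volume == pytest.approx(800.0)

    @given(st.integers(0, 2 ** 16))
    @settings(max_examples=25, deadline=None)
    def test_volume_conserved_under_random_actuation(self, seed):
        g, d = _strip_droplet()
        rng = np.random.default_rng(seed)
        params = PhysicsParams(seed=seed)
        drops = [d]
        total0 = sum(x.volume for x in drops)
        for _ in range(12):
            k = int(rng.integers(1, 3))
            pat = ActuationPattern(frozenset(
                int(e) for e in rng.choice(5, size=k, replace=False)))
            drops = step_physics(drops, pat, g, params, rng)
        assert sum(x.volume for x in drops) == pytest.approx(total0, abs=1e-6)

    def test_pattern_with_unknown_electrode_rejected(self):
        g, d = _strip_droplet()
        with pytest.raises(ValueError, match="nonexistent"):
            step_physics([d], ActuationPattern(frozenset({9})), g,
                         PhysicsParams(), np.random.default_rng(0))


class TestVirtualDevice:
    def test_identical_seed_gives_bit_identical_trajectories(self):
        g = make_grid(1, 5, 32, margin_px=20)

        def run():
            d = VirtualDroplet(0, 900.0, g.center(2))
            dev = VirtualDevice([d], g, PhysicsParams(seed=11), record=True)
            dev.actuate({1, 3}, 4)
            return dev

        a, b = run(), run()
        assert a.state_multiset() == b.state_multiset()
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.image, fb.image)
            assert np.array_equal(fa.mask, fb.mask)
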