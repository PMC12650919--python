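import numpy as np
import pytest

from sinusvol import (ErosionSequence, erode_layers, reconstruct_layers,
                      remove_hidden_connections, select_seed_component)
from conftest import diamond, disc, random_mask
from oracles import bfs_label, brute_constrained_dilate, brute_erode


class TestErodeLayers:
    def test_three_by_three_keeps_center_only(self):
        seq = erode_layers(np.ones((3, 3), dtype=np.uint8), 1)
        assert seq.deepest.sum() == 1 and seq.deepest[1, 1] == 1

    def test_thin_line_vanishes(self):
        line = np.zeros((5, 9), dtype=np.uint8)
        line[2, 1:8] = 1
        assert erode_layers(line, 1).deepest.sum() == 0

    def test_rectangle_interior_strip(self):
        rect = np.zeros((9, 7), dtype=np.uint8)
        rect[1:8, 1:6] = 1  # 7x5 solid block
        deepest = erode_layers(rect, 2).deepest
        expected = np.zeros_like(rect)
        expected[3:6, 3] = 1  # 3x1 interior strip
        assert np.array_equal(deepest, expected)

    def test_levels_nested_and_match_brute_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            mask = random_mask(rng)
            seq = erode_layers(mask, 3)
            assert len(seq.levels) == 4
            current = mask.astype(np.uint8)
            for level in seq.levels[1:]:
                assert np.all(level <= current)
                current = brute_erode(current)
                assert np.array_equal(level, current)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            erode_layers(np.ones((2, 2)), -1)

    def test_sequence_rejects_non_nested_levels(self):
        with pytest.raises(ValueError, match="nested"):
            ErosionSequence([np.zeros((2, 2)), np.ones((2, 2))])


class TestSelectSeedComponent:
    def _blobs(self):
        mask = np.zeros((7, 13), dtype=np.uint8)
        mask[2:5, 1:4] = 1   # blob A
        mask[2:5, 9:12] = 1  # blob B
        return mask

    def test_reference_inside_one_blob(self):
        mask = self._blobs()
        out = select_seed_component(mask, {(3, 2)})
        assert out[2:5, 1:4].all() and out.sum() == 9

    def test_reference_touching_both_blobs(self):
        mask = self._blobs()
        out = select_seed_component(mask, {(3, 2), (3, 8)})  # (3,8) at d1=1 from blob B
        assert out.sum() == 18

    def test_matches_flood_fill_from_references(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            mask = random_mask(rng, p=0.35)
            fg = np.argwhere(mask)
            if fg.size == 0:
                continue
            refs = {tuple(map(int, fg[i])) for i in rng.integers(len(fg), size=3)}
            out = select_seed_component(mask, refs)
            labels, _ = bfs_label(mask)
            keep = set()
            for r, c in refs:
                for dr, dc in ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] and labels[rr, cc]:
                        keep.add(labels[rr, cc])
            expected = np.isin(labels, sorted(keep)) if keep else np.zeros_like(mask, dtype=bool)
            assert np.array_equal(out.astype(bool), expected)

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            select_seed_component(self._blobs(), set())


class TestReconstructLayers:
    def test_depth_zero_is_identity(self):
        mask = disc((11, 11), (5, 5), 3.5)
        seq = erode_layers(mask, 0)
        assert np.array_equal(reconstruct_layers(mask, seq), mask)

    @pytest.mark.parametrize("radius", [3.5, 6.0])
    def test_disc_exactly_recovered(self, radius):
        mask = disc((17, 17), (8, 8), radius)
        seq = erode_layers(mask, 2)
        assert seq.deepest.any()
        assert np.array_equal(reconstruct_layers(seq.deepest, seq), mask)

    def test_matches_constrained_dilation_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            mask = random_mask(rng, p=0.6)
            l = int(rng.integers(1, 4))
            seq = erode_layers(mask, l)
            out = reconstruct_layers(seq.deepest, seq)
            assert np.array_equal(out, brute_constrained_dilate(seq.deepest, mask, l))
            # always bracketed: selection <= output <= original
            assert np.all(seq.deepest <= out) and np.all(out <= mask)

    def test_selection_outside_deepest_level_rejected(self):
        mask = np.ones((5, 5), dtype=np.uint8)
        seq = erode_layers(mask, 2)
        with pytest.raises(ValueError):
            reconstruct_layers(mask, seq)  # full mask is not within the core


class TestRemoveHiddenConnections:
    def test_identity_on_convex_blobs(self):
        # L1 diamonds of any radius > l are exactly recovered, as is the
        # 7-px disc; digital discs at some radii shed isolated boundary
        # pixels, which the 3D refinement sweep re-annexes in the pipeline
        for radius in range(3, 8):
            blob = diamond((19, 19), (9, 9), radius)
            out = remove_hidden_connections(blob, {(9, 9)}, 2)
            assert np.array_equal(out, blob)
        blob = disc((11, 11), (5, 5), 3.5)
        assert np.array_equal(remove_hidden_connections(blob, {(5, 5)}, 2), blob)

    def test_two_blob_channel_fixture(self, two_blob_channel):
        mask, blob_a, blob_b, ref = two_blob_channel
        out = remove_hidden_connections(mask, {ref}, 2).astype(bool)
        assert (out & blob_a).sum() == blob_a.sum()       # selected blob whole
        assert (out & blob_b).sum() == 0                  # far blob severed
        stub = out & ~blob_a & ~blob_b
        assert stub.sum() <= 2                            # at most an l-px stub
        # any stub pixel is adjacent to the selected blob side of the channel
        assert np.argwhere(stub)[:, 1].max(initial=0) <= 9

    def test_septum_property_random_families(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            h = int(rng.integers(11, 16))
            r = float(rng.uniform(3.4, 4.6))
            gap = int(rng.integers(6, 10))  # channel length > 2l
            width = int(rng.integers(1, 3))
            cy = h // 2
            ca, cb = 5, 5 + 2 * int(r) + gap
            shape = (h, cb + int(r) + 3)
            blob_a = disc(shape, (cy, ca), r).astype(bool)
            blob_b = disc(shape, (cy, cb), r).astype(bool)
            mask = (blob_a | blob_b).astype(np.uint8)
            row0 = cy - (width - 1) // 2
            mask[row0:row0 + width, ca:cb] = 1
            out = remove_hidden_connections(mask, {(cy, ca)}, 2).astype(bool)
            assert (out & blob_b & ~blob_a).sum() == 0

    def test_depth_exceeding_inradius_warns_and_passes_through(self):
        blob = disc((9, 9), (4, 4), 2.0)
        with pytest.warns(UserWarning, match="unprocessed"):
            out = remove_hidden_connections(blob, {(4, 4)}, 5)
        assert np.array_equal(out, blob)

    def test_reference_only_linked_through_channel_yields_empty(self):
        # reference sits on the channel; nothing of the eroded core is nearby
        mask = np.zeros((9, 21), dtype=np.uint8)
        mask[2:7, 14:19] = 1     # blob far from the reference
        mask[4, 0:14] = 1        # long 1-px channel
        out = remove_hidden_connections(mask, {(4, 0)}, 2)
        assert out.sum() == 0
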