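"""Image quantification: thresholds, colocalization, densities, Sholl, ratios."""

import numpy as np
import pytest

from synquant import puncta, synthgen
from synquant.puncta import (
    binarize,
    compute_threshold,
    max_project,
    normalize_densities,
    reporter_ratio,
    sholl_intersections,
    soma_segment,
    synapse_density,
    triple_colocalize,
)

import pandas as pd


class TestMaxProject:
    def test_single_slice_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(max_project([img]), img)

    def test_dominating_slice_wins(self):
        a = np.zeros((4, 4))
        np.testing.assert_array_equal(max_project([a, a + 1]), a + 1)

    def test_matches_per_pixel_brute_force(self):
        rng = np.random.default_rng(0)
        stack = [rng.random((5, 6)) for _ in range(4)]
        out = max_project(stack)
        for i in range(5):
            for j in range(6):
                assert out[i, j] == max(s[i, j] for s in stack)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            max_project([np.zeros((2, 2)), np.zeros((3, 3))])


class TestThresholdAndBinarize:
    def test_constant_image_threshold_equals_value(self):
        t = compute_threshold(np.full((8, 8), 100.0))
        assert t.mean == 100.0 and t.sd == 0.0 and t.threshold == 100.0

    def test_two_pixel_population_sd(self):
        t = compute_threshold(np.array([[0.0, 10.0]]))
        assert t.mean == 5.0 and t.sd == 5.0 and t.threshold == 10.0

    def test_threshold_at_max_gives_empty_mask(self):
        img = np.arange(9.0).reshape(3, 3)
        assert not binarize(img, img.max()).any()

    def test_negative_threshold_gives_full_mask(self):
        img = np.arange(9.0).reshape(3, 3)
        assert binarize(img, -1.0).all()

    def test_binarize_matches_brute_force(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 50, size=(6, 7)).astype(float)
        mask = binarize(img, 20.0)
        for i in range(6):
            for j in range(7):
                assert mask[i, j] == (img[i, j] > 20.0)

    def test_scale_invariance_of_mask_for_power_of_two(self):
        rng = np.random.default_rng(2)
        img = np.round(rng.normal(200, 40, size=(64, 64)))
        for c in (0.5, 2.0, 4.0):
            m1 = binarize(img, compute_threshold(img))
            m2 = binarize(c * img, compute_threshold(c * img))
            np.testing.assert_array_equal(m1, m2)


class TestTripleColocalize:
    def test_disjoint_masks_count_zero(self):
        a = np.zeros((5, 5), bool)
        b = a.copy()
        a[0, 0] = True
        b[4, 4] = True
        _, n = triple_colocalize(np.ones((5, 5), bool), a, b)
        assert n == 0

    def test_all_true_masks_single_component(self):
        m = np.ones((6, 6), bool)
        _, n = triple_colocalize(m, m, m)
        assert n == 1

    def test_single_pixel_regions_count(self):
        m = np.zeros((5, 5), bool)
        m[1, 1] = m[3, 3] = True  # diagonal -> 8-connected neighbors? no: gap
        _, n = triple_colocalize(np.ones((5, 5), bool), m, m)
        assert n == 2

    def test_connectivity_choice_changes_diagonal_touching(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        ones = np.ones((4, 4), bool)
        assert triple_colocalize(ones, m, m, connectivity=2)[1] == 1
        assert triple_colocalize(ones, m, m, connectivity=1)[1] == 2

    def test_recovers_planted_count_noise_free(self):
        field, truth = synthgen.gen_synapse_image(12, 3, 3, noise_sd=0.0,
                                                  psf_sigma_px=1.0, seed=5)
        rec, _ = puncta.quantify_field(field)
        assert rec.n_coloc == len(truth.coloc_centers) == 12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            triple_colocalize(np.ones((2, 2), bool), np.ones((3, 3), bool),
                              np.ones((2, 2), bool))


class TestSomaSegment:
    def test_recovers_disc_soma_and_excludes_dendrites(self):
        from skimage.morphology import dilation, disk

        _, truth = synthgen.gen_synapse_image(0, 0, 0, seed=8)
        soma = soma_segment(truth.neuron_mask, opening_radius_px=5)
        gt = truth.soma_mask
        assert (soma & gt).sum() >= 0.9 * gt.sum()
        # no dendrite pixels beyond the immediate soma junction (discrete
        # opening may keep 1-2 px of the dendrite root where it meets the disc)
        dendrites_away = truth.neuron_mask & ~dilation(gt, disk(2))
        assert not (soma & dendrites_away).any()

    def test_zero_radius_returns_mask(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        np.testing.assert_array_equal(soma_segment(mask, 0), mask)

    def test_single_disc_preserved(self):
        from skimage.draw import disk

        mask = np.zeros((40, 40), bool)
        rr, cc = disk((20, 20), 10)
        mask[rr, cc] = True
        soma = soma_segment(mask, 5)
        assert (soma & mask).sum() >= 0.9 * mask.sum()

    def test_overly_large_radius_raises(self):
        mask = np.zeros((20, 20), bool)
        mask[5:8, 5:8] = True
        with pytest.raises(ValueError, match="smaller"):
            soma_segment(mask, 8)


class TestDensity:
    def test_dendritic_hand_example(self):
        cell = np.zeros((20, 20), bool)
        cell.ravel()[:200] = True
        soma = np.zeros((20, 20), bool)
        soma.ravel()[:50] = True
        d = synapse_density(10, cell, soma, pixel_size_um=1.0, mode="dendritic")
        assert d == pytest.approx(10 / 150)

    def test_somatic_hand_example(self):
        cell = np.zeros((20, 20), bool)
        cell.ravel()[:200] = True
        soma = np.zeros((20, 20), bool)
        soma.ravel()[:50] = True
        assert synapse_density(10, cell, soma, 1.0, "somatic") == pytest.approx(0.2)

    def test_zero_count_zero_density(self):
        cell = np.ones((4, 4), bool)
        soma = np.zeros((4, 4), bool)
        assert synapse_density(0, cell, soma, 1.0) == 0.0

    def test_zero_area_raises(self):
        cell = np.ones((4, 4), bool)
        with pytest.raises(ValueError, match="zero"):
            synapse_density(1, cell, cell, 1.0, "dendritic")

    def test_pixel_size_scales_area(self):
        cell = np.ones((10, 10), bool)
        soma = np.zeros((10, 10), bool)
        d1 = synapse_density(5, cell, soma, 1.0)
        d2 = synapse_density(5, cell, soma, 0.5)
        assert d2 == pytest.approx(4 * d1)

    def test_split_field_pools_to_whole_field_density(self):
        # split through an empty column so no region is cut in two
        field, _ = synthgen.gen_synapse_image(10, 2, 2, noise_sd=0.0, seed=13)
        rec, thr = puncta.quantify_field(field)
        masks = {r: binarize(field.channels[r], thr[r]) for r in field.channels}
        overlap_cols = np.where(
            (masks["cellfill"] & masks["presynaptic"] & masks["postsynaptic"]).any(axis=0)
        )[0]
        split = None
        for c in range(30, 226):
            if c not in overlap_cols:
                split = c
                break
        assert split is not None
        counts, areas = [], []
        for sl in (np.s_[:, :split], np.s_[:, split:]):
            _, n = triple_colocalize(
                masks["cellfill"][sl], masks["presynaptic"][sl], masks["postsynaptic"][sl]
            )
            counts.append(n)
            areas.append(int(masks["cellfill"][sl].sum()))
        whole_density = rec.n_coloc / int(masks["cellfill"].sum())
        assert sum(counts) / sum(areas) == pytest.approx(whole_density)


class TestNormalization:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(
            rows, columns=["experiment_label", "condition_label",
                           "dendritic_density_per_um2"]
        )

    def test_simple_ratio(self):
        df = self._frame([("e1", "ctrl", 2.0), ("e1", "ctrl", 2.0),
                          ("e1", "cko", 4.0), ("e1", "cko", 4.0)])
        out = normalize_densities(df, "ctrl")
        vals = dict(zip(out["condition_label"], out["normalized"]))
        assert vals["ctrl"] == 1.0 and vals["cko"] == 2.0

    def test_identical_conditions_normalize_to_one(self):
        df = self._frame([("e1", "a", 3.0), ("e1", "b", 3.0)])
        out = normalize_densities(df, "a")
        assert (out["normalized"] == 1.0).all()

    def test_staining_scale_cancels_across_experiments(self):
        # same true ratio r=1.5, different absolute scales per experiment
        df = self._frame([("e1", "ctrl", 2.0), ("e1", "cko", 3.0),
                          ("e2", "ctrl", 8.0), ("e2", "cko", 12.0)])
        out = normalize_densities(df, "ctrl")
        cko = out[out["condition_label"] == "cko"]["normalized"]
        assert np.allclose(cko, 1.5)

    def test_missing_control_raises(self):
        df = self._frame([("e1", "cko", 3.0)])
        with pytest.raises(ValueError, match="no 'ctrl'"):
            normalize_densities(df, "ctrl")


class TestSholl:
    def test_single_radial_branch_crosses_every_circle_once(self):
        skel = np.zeros((300, 300), bool)
        skel[150, 150:285] = True  # straight branch along +x
        prof = sholl_intersections(skel, (150, 150), n_circles=11, spacing_um=10,
                                   pixel_size_um=1.0)
        assert prof.intersections == [1] * 11
        assert not prof.clipped

    def test_bifurcation_between_third_and_fourth_circle(self):
        # manual count on this fixture: 1 crossing for radii 10-30 um,
        # 2 crossings for radii 40-110 um
        skel = np.zeros((300, 300), bool)
        skel[150, 150:290] = True        # main branch along +x
        skel[40:151, 185] = True         # vertical daughter from (150, 185), r=35
        prof = sholl_intersections(skel, (150, 150))
        assert prof.intersections == [1, 1, 1] + [2] * 8

    def test_empty_skeleton_all_zero(self):
        prof = sholl_intersections(np.zeros((50, 50), bool), (25, 25),
                                   n_circles=3, spacing_um=5)
        assert prof.intersections == [0, 0, 0]

    def test_out_of_image_circles_flagged(self):
        skel = np.zeros((50, 50), bool)
        skel[25, 25:49] = True
        prof = sholl_intersections(skel, (25, 25), n_circles=5, spacing_um=10,
                                   pixel_size_um=1.0)
        assert prof.clipped

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            sholl_intersections(np.zeros((10, 10), bool), (20, 20))


class TestReporterRatio:
    def test_basic_and_identity(self):
        assert reporter_ratio(200.0, 100.0) == 2.0
        assert reporter_ratio(7.5, 7.5) == 1.0

    def test_batch_equals_elementwise(self):
        rng = np.random.default_rng(3)
        sig = rng.random(50) * 100
        ref = rng.random(50) * 10 + 1
        out = reporter_ratio(sig, ref)
        for i in range(50):
            assert out[i] == sig[i] / ref[i]

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            reporter_ratio(1.0, 0.0)


class TestPipelineDeterminism:
    def test_identical_field_and_config_give_identical_record(self):
        field, _ = synthgen.gen_synapse_image(9, 2, 2, noise_sd=30.0, seed=21)
        r1, _ = puncta.quantify_field(field)
        r2, _ = puncta.quantify_field(field)
        assert r1 == r2

    def test_channel_scaling_leaves_count_unchanged(self):
        field, _ = synthgen.gen_synapse_image(9, 2, 2, noise_sd=30.0, seed=22)
        rec, thr = puncta.quantify_field(field)
        masks = {r: binarize(2.0 * field.channels[r],
                             compute_threshold(2.0 * field.channels[r]))
                 for r in field.channels}
        _, n = triple_colocalize(masks["cellfill"], masks["presynaptic"],
                                 masks["postsynaptic"])
        assert n == rec.n_coloc
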