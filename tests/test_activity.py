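import copy

import numpy as np
import pytest

from bsamap.activity import (
    ActivityConfig,
    activity_map,
    bsa_series,
    component_contribution,
    roi_means,
    whole_brain_activity,
)
from bsamap.errors import ConfigError, DataError
from bsamap.io import LabelAtlas, VolumeGrid
from bsamap.labeling import NEURONAL, UNDEFINED, ComponentLabels


def brute_force_activity(series, dec, labels, cfg):
    """Literal per-voxel, per-component loop over the defining equations."""
    data = series.masked()
    out = np.zeros(data.shape[0])
    for i in range(data.shape[0]):
        total = 0.0
        for j in labels.neuronal_indices:
            nc = dec.spatial_maps[j, i]
            if cfg.clip_negative_nc:
                nc = max(nc, 0.0)
            total += component_contribution(data[i], dec.time_courses[j], nc, cfg)
        out[i] = total
    full = np.zeros(series.grid.shape)
    full[series.brain_mask] = out
    return full


class TestBsaSeries:
    def test_elementwise_product(self):
        np.testing.assert_array_equal(
            bsa_series([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]), [2.0, 4.0, 6.0]
        )

    def test_zero_weights_zero_output(self):
        assert np.all(bsa_series([5.0, -2.0, 8.0], np.zeros(3)) == 0.0)

    def test_signed_hand_example(self):
        np.testing.assert_array_equal(
            bsa_series([1.0, -1.0, 2.0], [3.0, 0.0, -1.0]), [3.0, 0.0, -2.0]
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            bsa_series([1.0, 2.0], [1.0, 2.0, 3.0])


class TestComponentContribution:
    def test_unit_sd_hand_example(self):
        s, w = np.array([1.0, 2.0, 3.0]), np.ones(3)
        for agg in ("sum_sd", "sum_sqrt_sd"):  # sqrt(1) == 1
            cfg = ActivityConfig(aggregation=agg)
            assert component_contribution(s, w, 1.0, cfg) == pytest.approx(1.0)

    def test_constant_bsa_contributes_zero(self):
        assert component_contribution(np.full(5, 4.0), np.ones(5), 2.0) == 0.0

    def test_population_sd_denominator(self):
        s = np.array([0.0, 2.0, 0.0, 2.0])
        cfg = ActivityConfig(sd_denominator="n")
        assert component_contribution(s, np.ones(4), 0.5, cfg) == pytest.approx(0.5)

    def test_two_component_sum_both_variants(self):
        # SD contributions 4 and 1 at NC weights 0.5 and 1.0
        s1, w1 = np.array([0.0, 8.0, 0.0, 8.0]), np.ones(4)  # SD(n)=4
        s2, w2 = np.array([0.0, 2.0, 0.0, 2.0]), np.ones(4)  # SD(n)=1
        cfg = ActivityConfig(sd_denominator="n")
        total = component_contribution(s1, w1, 0.5, cfg) + component_contribution(
            s2, w2, 1.0, cfg
        )
        assert total == pytest.approx(4 * 0.5 + 1 * 1)
        cfg_sqrt = ActivityConfig(aggregation="sum_sqrt_sd", sd_denominator="n")
        total_sqrt = component_contribution(s1, w1, 0.5, cfg_sqrt) + component_contribution(
            s2, w2, 1.0, cfg_sqrt
        )
        assert total_sqrt == pytest.approx(2 * 0.5 + 1 * 1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            ActivityConfig(aggregation="median")
        with pytest.raises(ConfigError):
            ActivityConfig(sd_denominator="n-2")


class TestActivityMap:
    @pytest.mark.parametrize("aggregation", ["sum_sd", "sum_sqrt_sd"])
    def test_matches_brute_force_oracle(self, preprocessed, decomposition,
                                        component_labels, aggregation):
        cfg = ActivityConfig(aggregation=aggregation)
        amap = activity_map(preprocessed, decomposition, component_labels, cfg)
        oracle = brute_force_activity(preprocessed, decomposition, component_labels, cfg)
        assert np.abs(amap.values - oracle).max() < 1e-10

    def test_k_zero_yields_zero_map(self, preprocessed, decomposition):
        n = decomposition.n_components
        labels = ComponentLabels(
            gof=np.zeros((n, 1)), assignment={},
            labels=np.array([UNDEFINED] * n, dtype=object), hf_fractions=np.zeros(n),
        )
        amap = activity_map(preprocessed, decomposition, labels)
        assert np.all(amap.values == 0.0) and amap.k_used == 0

    def test_permutation_invariance(self, preprocessed, decomposition, component_labels):
        perm = np.random.default_rng(3).permutation(decomposition.n_components)
        shuffled = copy.deepcopy(decomposition)
        shuffled.spatial_maps = decomposition.spatial_maps[perm]
        shuffled.raw_maps = decomposition.raw_maps[perm]
        shuffled.time_courses = decomposition.time_courses[perm]
        plabels = ComponentLabels(
            gof=component_labels.gof[perm],
            assignment=component_labels.assignment,
            labels=component_labels.labels[perm],
            hf_fractions=component_labels.hf_fractions[perm],
        )
        a = activity_map(preprocessed, decomposition, component_labels)
        b = activity_map(preprocessed, shuffled, plabels)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_zero_weight_component_changes_nothing(self, preprocessed, decomposition,
                                                   component_labels):
        base = activity_map(preprocessed, decomposition, component_labels)
        extended = copy.deepcopy(decomposition)
        extended.spatial_maps = np.vstack(
            [decomposition.spatial_maps, np.zeros((1, decomposition.spatial_maps.shape[1]))]
        )
        extended.raw_maps = np.vstack(
            [decomposition.raw_maps, np.zeros((1, decomposition.raw_maps.shape[1]))]
        )
        extended.time_courses = np.vstack(
            [decomposition.time_courses, np.ones((1, decomposition.n_volumes))]
        )
        elabels = ComponentLabels(
            gof=np.vstack([component_labels.gof, np.zeros((1, component_labels.gof.shape[1]))]),
            assignment=component_labels.assignment,
            labels=np.append(component_labels.labels, NEURONAL),
            hf_fractions=np.append(component_labels.hf_fractions, 0.0),
        )
        with_extra = activity_map(preprocessed, extended, elabels)
        np.testing.assert_allclose(with_extra.values, base.values, atol=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_homogeneity_in_series_scale(self, preprocessed, decomposition,
                                         component_labels, c):
        base_sd = activity_map(preprocessed, decomposition, component_labels,
                               ActivityConfig("sum_sd"))
        base_sqrt = activity_map(preprocessed, decomposition, component_labels,
                                 ActivityConfig("sum_sqrt_sd"))
        scaled = preprocessed.with_values(preprocessed.values * c)
        sd_scaled = activity_map(scaled, decomposition, component_labels,
                                 ActivityConfig("sum_sd"))
        sqrt_scaled = activity_map(scaled, decomposition, component_labels,
                                   ActivityConfig("sum_sqrt_sd"))
        np.testing.assert_allclose(sd_scaled.values, c * base_sd.values, rtol=1e-8)
        np.testing.assert_allclose(
            sqrt_scaled.values, np.sqrt(c) * base_sqrt.values, rtol=1e-8
        )

    def test_component_count_mismatch_rejected(self, preprocessed, decomposition,
                                               component_labels):
        bad = ComponentLabels(
            gof=component_labels.gof[:3],
            assignment={},
            labels=component_labels.labels[:3],
            hf_fractions=component_labels.hf_fractions[:3],
        )
        with pytest.raises(DataError, match="components"):
            activity_map(preprocessed, decomposition, bad)


class TestRoiSummaries:
    def make_atlas(self, shape, labels):
        g = VolumeGrid(shape, (1.0, 1.0, 1.0), np.eye(4))
        names = {int(i): f"r{i}" for i in np.unique(labels) if i != 0}
        return LabelAtlas(g, labels, names)

    def make_map(self, values, mask=None):
        from bsamap.activity import ActivityMap

        g = VolumeGrid(values.shape, (1.0, 1.0, 1.0), np.eye(4))
        mask = np.ones(values.shape, bool) if mask is None else mask
        return ActivityMap(g, mask, values, ActivityConfig(), 1)

    def test_uniform_region(self):
        vals = np.full((4, 4, 2), 3.0)
        labels = np.zeros((4, 4, 2), int)
        labels[:2] = 1
        table = roi_means(self.make_map(vals), self.make_atlas(vals.shape, labels))
        assert table.iloc[0]["mean"] == pytest.approx(3.0)
        assert table.iloc[0]["sd"] == pytest.approx(0.0)

    def test_two_voxel_region_hand_example(self):
        vals = np.zeros((4, 1, 1))
        vals[0, 0, 0], vals[1, 0, 0] = 1.0, 3.0
        labels = np.zeros((4, 1, 1), int)
        labels[:2, 0, 0] = 1
        table = roi_means(self.make_map(vals), self.make_atlas(vals.shape, labels))
        assert table.iloc[0]["mean"] == pytest.approx(2.0)
        assert table.iloc[0]["sd"] == pytest.approx(np.sqrt(2))

    def test_region_outside_mask_reported_empty(self):
        vals = np.ones((4, 4, 2))
        mask = np.zeros((4, 4, 2), bool)
        mask[2:] = True
        labels = np.zeros((4, 4, 2), int)
        labels[0] = 1
        table = roi_means(self.make_map(vals, mask), self.make_atlas(vals.shape, labels))
        assert table.iloc[0]["n_voxels"] == 0
        assert np.isnan(table.iloc[0]["mean"])


class TestWholeBrainActivity:
    def test_zero_map(self):
        amap = TestRoiSummaries().make_map(np.zeros((4, 4, 2)))
        assert whole_brain_activity(amap) == 0.0

    def test_uniform_map(self):
        amap = TestRoiSummaries().make_map(np.full((4, 4, 2), 2.5))
        assert whole_brain_activity(amap) == pytest.approx(2.5)

    def test_equals_masked_mean_oracle(self, preprocessed, decomposition, component_labels):
        amap = activity_map(preprocessed, decomposition, component_labels)
        oracle = float(amap.values[amap.mask].mean())
        assert whole_brain_activity(amap) == pytest.approx(oracle, abs=1e-12)
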