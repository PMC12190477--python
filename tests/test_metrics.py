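"""Pearson colocalization, positivity scoring, dispersion profiles and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import focusq
from focusq.metrics import (
    aggregate_dispersion,
    aggregate_pearson,
    dispersion_profile_cell,
    dispersion_profiles,
    pearson_per_cell,
    positivity_fractions,
    profile_peak_stats,
    score_structure_positivity,
)
from focusq.segmentation import StructureLabelMap

from conftest import analyze_scene


def _fov(primary, secondary=None, **kw):
    channels = {"primary": np.asarray(primary, dtype=float)}
    if secondary is not None:
        channels["secondary"] = np.asarray(secondary, dtype=float)
    return focusq.FieldOfView(channels=channels, **kw)


class TestPearson:
    def test_identical_channels_give_r_one(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (16, 16))
        cells = np.ones((16, 16), dtype=np.int32)
        rec = pearson_per_cell(_fov(img, img.copy()), cells)
        assert rec.loc[0, "r"] == pytest.approx(1.0)

    def test_inverted_channel_gives_r_minus_one(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 100, (16, 16))
        rec = pearson_per_cell(_fov(img, 200.0 - img), np.ones((16, 16), dtype=np.int32))
        assert rec.loc[0, "r"] == pytest.approx(-1.0)

    def test_four_pixel_worked_example(self):
        primary = np.array([[1.0, 2.0], [3.0, 4.0]])
        secondary = np.array([[1.0, 3.0], [2.0, 4.0]])
        rec = pearson_per_cell(_fov(primary, secondary), np.ones((2, 2), dtype=np.int32))
        assert rec.loc[0, "r"] == pytest.approx(0.8)
        assert rec.loc[0, "n_pixels"] == 4

    def test_constant_channel_cell_skipped(self):
        primary = np.ones((4, 4))
        secondary = np.arange(16, dtype=float).reshape(4, 4)
        rec = pearson_per_cell(_fov(primary, secondary), np.ones((4, 4), dtype=np.int32))
        assert rec.empty

    def test_missing_secondary_errors(self):
        with pytest.raises(ValueError, match="secondary"):
            pearson_per_cell(_fov(np.ones((4, 4))), np.ones((4, 4), dtype=np.int32))

    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_rescaling_invariance(self, a, b):
        rng = np.random.default_rng(42)
        primary = rng.uniform(0, 500, (12, 12))
        secondary = rng.uniform(0, 500, (12, 12))
        cells = np.ones((12, 12), dtype=np.int32)
        r0 = pearson_per_cell(_fov(primary, secondary), cells).loc[0, "r"]
        r1 = pearson_per_cell(_fov(primary, a * secondary + b), cells).loc[0, "r"]
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestAggregation:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["condition", "well", "site", "cell", "r", "n_pixels"])

    def test_single_cell_site_median_is_that_cell(self):
        rec = self._records([("c", "w1", "s1", 1, 0.42, 100)])
        well, cond = aggregate_pearson(rec)
        assert well.loc[0, "pearson_median"] == pytest.approx(0.42)
        assert np.isnan(cond.loc[0, "sd"])  # single well: SD undefined

    def test_well_median_of_site_medians(self):
        rows = [("c", "w1", s, 1, r, 10) for s, r in [("s1", 0.2), ("s2", 0.4), ("s3", 0.9)]]
        well, _ = aggregate_pearson(self._records(rows))
        assert well.loc[0, "pearson_median"] == pytest.approx(0.4)

    def test_condition_mean_and_sample_sd_over_wells(self):
        rows = [("c", w, "s1", 1, r, 10) for w, r in [("w1", 0.3), ("w2", 0.5), ("w3", 0.7)]]
        _, cond = aggregate_pearson(self._records(rows))
        assert cond.loc[0, "mean"] == pytest.approx(0.5)
        assert cond.loc[0, "sd"] == pytest.approx(0.2)
        assert cond.loc[0, "n_wells"] == 3

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        rows = [
            ("c", f"w{i%3}", f"s{i%2}", i, rng.uniform(-1, 1), 10) for i in range(24)
        ]
        rec = self._records(rows)
        shuffled = rec.sample(frac=1.0, random_state=7).reset_index(drop=True)
        w1, c1 = aggregate_pearson(rec)
        w2, c2 = aggregate_pearson(shuffled)
        pd.testing.assert_frame_equal(w1, w2)
        pd.testing.assert_frame_equal(c1, c2)


class TestPositivity:
    def _single_structure(self, structure_value, region_value):
        """One 3x3 structure centred in a cell of uniform secondary intensity."""
        primary = np.full((32, 32), 10.0)
        secondary = np.full((32, 32), region_value)
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[14:17, 14:17] = 1
        secondary[14:17, 14:17] = structure_value
        cells = np.ones((32, 32), dtype=np.int32)
        structures = StructureLabelMap(labels=labels, mode="punctum", cell_ids={1: 1})
        return _fov(primary, secondary), cells, structures

    def test_equal_means_ratio_one_not_positive(self):
        fov, cells, structures = self._single_structure(50.0, 50.0)
        tab = score_structure_positivity(fov, cells, structures)
        assert tab.loc[0, "ratio"] == pytest.approx(1.0)
        assert not tab.loc[0, "positive"]

    def test_ratio_exactly_at_threshold_is_negative(self):
        fov, cells, structures = self._single_structure(62.5, 50.0)
        tab = score_structure_positivity(fov, cells, structures)
        assert tab.loc[0, "ratio"] == pytest.approx(1.25)
        assert not tab.loc[0, "positive"]
        above = score_structure_positivity(fov, cells, structures, threshold=1.2499)
        assert above.loc[0, "positive"].item()

    def test_empty_region_flagged_unscorable(self):
        fov, cells, structures = self._single_structure(50.0, 50.0)
        tab = score_structure_positivity(fov, cells, structures, dilation_radius=0)
        assert not tab.loc[0, "scorable"]

    def test_fraction_recovery_on_synthetic_scene(self):
        spec = focusq.SceneSpec(coloc_fraction=0.5, seed=7)
        _, truth, sub, cells, structures = analyze_scene(spec, "punctum")
        tab = score_structure_positivity(sub, cells, structures)
        frac = tab[tab["scorable"]]["positive"].mean()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_structure_and_cell_fractions(self):
        rows = [
            dict(condition="c", well="w", site="s", cell=1, structure=i, mode="punctum",
                 area=9, structure_mean=1.0, region_mean=1.0, ratio=r, positive=p, scorable=True)
            for i, (r, p) in enumerate([(2.0, True), (1.0, False), (1.1, False)], start=1)
        ]
        site, cond = positivity_fractions(pd.DataFrame(rows))
        vals = site.set_index("statistic")["value"]
        assert vals["fraction_structures_positive"] == pytest.approx(1 / 3)
        assert vals["fraction_cells_positive"] == pytest.approx(1.0)

    def test_site_without_scorable_structures_excluded(self):
        rows = [
            dict(condition="c", well="w", site="s", cell=1, structure=1, mode="punctum",
                 area=9, structure_mean=np.nan, region_mean=np.nan, ratio=np.nan,
                 positive=False, scorable=False)
        ]
        site, cond = positivity_fractions(pd.DataFrame(rows))
        assert site.empty


def naive_dispersion_profile(channel, cell_mask):
    """Per-pixel reference implementation of the radial dispersion profile.

    Walks every in-cell pixel in row-major order, accumulates ring sums and
    counts in plain Python floats, and normalizes by the cell's mean
    intensity.
    """
    rows, cols = np.nonzero(cell_mask)
    weights = channel[cell_mask].astype(np.float64)
    total = 0.0
    sum_r = 0.0
    sum_c = 0.0
    for r, c, w in zip(rows, cols, weights):
        total += w
        sum_r += w * r
        sum_c += w * c
    cy, cx = sum_r / total, sum_c / total
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for r, c, w in zip(rows, cols, weights):
        ring = int(np.rint(np.hypot(r - cy, c - cx)))
        sums[ring] = sums.get(ring, 0.0) + w
        counts[ring] = counts.get(ring, 0) + 1
    mean = weights.mean()
    rings = sorted(sums)
    return pd.Series(
        [sums[k] / counts[k] / mean for k in rings], index=rings, name="value"
    ).rename_axis("distance")


class TestDispersion:
    def test_uniform_cell_profile_is_one_everywhere(self):
        rr, cc = np.mgrid[0:40, 0:40]
        cell = (rr - 20) ** 2 + (cc - 20) ** 2 <= 15**2
        channel = np.where(cell, 7.0, 0.0)
        profile = dispersion_profile_cell(channel, cell, cell, min_structure_pixels=1)
        np.testing.assert_allclose(profile.to_numpy(), 1.0, atol=1e-12)

    def test_point_mass_concentrates_at_ring_zero(self):
        rr, cc = np.mgrid[0:40, 0:40]
        cell = (rr - 20) ** 2 + (cc - 20) ** 2 <= 12**2
        channel = np.zeros((40, 40))
        channel[20, 20] = 100.0
        profile = dispersion_profile_cell(channel, cell, cell, min_structure_pixels=1)
        area = int(cell.sum())
        assert profile.loc[0] == pytest.approx(area)
        assert profile.drop(index=0).abs().max() == 0.0

    def test_cell_below_structure_pixel_minimum_skipped(self):
        cell = np.ones((10, 10), dtype=bool)
        structures = np.zeros((10, 10), dtype=bool)
        structures[5, 5] = True
        channel = np.random.default_rng(0).uniform(1, 2, (10, 10))
        assert dispersion_profile_cell(channel, cell, structures, min_structure_pixels=5) is None
        assert dispersion_profile_cell(channel, cell, structures, min_structure_pixels=1) is not None

    def test_matches_per_pixel_reference_on_synthetic_cells(self, dispersed_scene):
        _, _, sub, cells, structures = dispersed_scene
        checked = 0
        for lbl in range(1, int(cells.max()) + 1):
            mask = cells == lbl
            profile = dispersion_profile_cell(sub.primary, mask, structures.mask())
            if profile is None:
                continue
            reference = naive_dispersion_profile(sub.primary, mask)
            pd.testing.assert_series_equal(profile, reference, check_exact=True)
            checked += 1
        assert checked >= 3

    def test_normalization_identity(self, clustered_scene):
        """Ring values weighted by ring pixel counts average to exactly 1."""
        _, _, sub, cells, structures = clustered_scene
        for lbl in range(1, int(cells.max()) + 1):
            mask = cells == lbl
            profile = dispersion_profile_cell(sub.primary, mask, structures.mask())
            if profile is None:
                continue
            rr, cc = np.nonzero(mask)
            w = sub.primary[mask]
            total = w.sum()
            cy = (w * rr).sum() / total
            cx = (w * cc).sum() / total
            ring = np.rint(np.hypot(rr - cy, cc - cx)).astype(int)
            counts = pd.Series(ring).value_counts()
            weighted = (profile * counts.reindex(profile.index)).sum()
            assert weighted / mask.sum() == pytest.approx(1.0, abs=1e-9)

    def test_well_aggregation_is_ringwise_median(self):
        rows = []
        for cell, v in [(1, 0.5), (2, 1.0), (3, 4.0)]:
            rows.append(dict(condition="c", well="w", site="s", cell=cell, distance=3, value=v))
        well, cond = aggregate_dispersion(pd.DataFrame(rows))
        assert well.loc[0, "value"] == pytest.approx(1.0)

    def test_identical_profiles_aggregate_to_themselves(self):
        rows = [
            dict(condition="c", well="w", site="s", cell=cell, distance=d, value=v)
            for cell in (1, 2, 3)
            for d, v in [(0, 2.0), (1, 1.0), (2, 0.5)]
        ]
        well, cond = aggregate_dispersion(pd.DataFrame(rows))
        assert well.set_index("distance")["value"].to_dict() == {0: 2.0, 1: 1.0, 2: 0.5}
        assert cond.set_index("distance")["mean"].to_dict() == {0: 2.0, 1: 1.0, 2: 0.5}


class TestPeakStats:
    def test_flat_profile_tie_rule(self):
        peak, where, width = profile_peak_stats(pd.Series([1.0, 1.0, 1.0]))
        assert (peak, where, width) == (1.0, 0, 3)

    def test_single_peak(self):
        peak, where, width = profile_peak_stats(pd.Series([0.2, 3.0, 0.4]))
        assert (peak, where, width) == (3.0, 1, 1)

    def test_monotone_decreasing_peaks_at_ring_zero(self):
        peak, where, width = profile_peak_stats(pd.Series([5.0, 4.0, 3.0, 2.0, 1.0]))
        assert where == 0
        assert peak == 5.0
        assert width == 3  # rings 0..2 hold values >= 2.5

    def test_clustered_sharper_than_dispersed(self):
        clustered = analyze_scene(focusq.SceneSpec(pattern="clustered", seed=21), "focus")
        dispersed = analyze_scene(focusq.SceneSpec(pattern="dispersed", seed=21), "punctum")
        stats = {}
        for name, (_, _, sub, cells, structures) in {
            "clustered": clustered, "dispersed": dispersed
        }.items():
            profiles = dispersion_profiles(sub, cells, structures)
            _, cond = aggregate_dispersion(profiles)
            stats[name] = profile_peak_stats(cond.set_index("distance")["mean"])
        assert stats["clustered"][0] > stats["dispersed"][0]
        assert stats["clustered"][2] < stats["dispersed"][2]
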