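"""Clipping rules: thresholds, reasons, precedence, temporal windows."""
import numpy as np
import pytest
from shapely.geometry import box

import bmsom as bm
from bmsom.clipping import (
    REASON_ELEVATION,
    REASON_GEOGRAPHIC,
    REASON_NAMES,
    REASON_TEMPORAL,
)

from .conftest import disc_range, toy_sites


class TestDistanceClip:
    def test_boundary_retained(self):
        d = np.array([[400.0, 401.0, -50.0]])
        mask = bm.clip_by_distance(d, 400.0)
        assert mask.retained.tolist() == [[True, False, True]]
        assert mask.reason[0, 1] == REASON_GEOGRAPHIC
        assert mask.reason_counts() == {"geographic_distance": 1}

    def test_all_in_range_full_mask(self):
        d = -np.abs(np.random.default_rng(0).normal(100, 50, (4, 6)))
        mask = bm.clip_by_distance(d, 400.0)
        assert mask.retained.all()

    def test_monotone_in_threshold(self):
        d = np.random.default_rng(1).uniform(-500, 800, (5, 9))
        small = bm.clip_by_distance(d, 200.0)
        large = bm.clip_by_distance(d, 400.0)
        assert not np.any(small.retained & ~large.retained)

    def test_counts_partition(self):
        d = np.random.default_rng(2).uniform(-500, 800, (7, 11))
        m = bm.clip_by_distance(d, 300.0)
        assert m.n_retained + m.n_removed == 7 * 11


class TestElevationClip:
    def test_boundary_and_beyond(self):
        s = np.array([[3.0, 3.5, -3.0, -3.01, 0.0]])
        m = bm.clip_by_standardized_elevation(s)
        assert m.retained.tolist() == [[True, False, True, False, True]]
        assert m.reason[0, 1] == REASON_ELEVATION

    def test_species_without_limits_untouched(self, caplog):
        s = np.array([[5.0, -5.0], [np.nan, np.nan]])
        m = bm.clip_by_standardized_elevation(s)
        assert (~m.retained[0]).all()
        assert m.retained[1].all()


class TestTemporalClip:
    def _ranges(self, windows):
        out = []
        for i, w in enumerate(windows):
            r = disc_range(f"sp{i}", 50, 50, 30)
            if w is not None:
                r.season_start, r.season_end = w
            out.append(r)
        return out

    def test_resident_fully_retained(self):
        dates = np.array([[100.0, 150.0], [250.0, 300.0]])
        m = bm.clip_temporal(dates, self._ranges([None]))
        assert m.retained.all() and m.visit_mask.all()

    def test_plain_window_membership(self):
        dates = np.array([[150.0, 250.0]])
        m = bm.clip_temporal(dates, self._ranges([(100, 200)]))
        assert m.visit_mask[0, 0].tolist() == [True, False]
        assert m.retained[0, 0]  # one live visit keeps the cell

    def test_wraparound_against_brute_force(self):
        """Wrap-around window [300, 60]: compare against a day-by-day table."""
        member = np.zeros(367, bool)
        for day in range(1, 367):
            member[day] = (day >= 300) or (day <= 60)
        days = np.arange(1, 367, dtype=float).reshape(-1, 1)
        m = bm.clip_temporal(days, self._ranges([(300, 60)]))
        np.testing.assert_array_equal(m.visit_mask[0, :, 0], member[1:])
        assert m.visit_mask[0, 19, 0]  # day 20 retained

    def test_cell_removed_when_all_visits_removed(self):
        dates = np.array([[250.0, 260.0]])
        m = bm.clip_temporal(dates, self._ranges([(100, 200)]))
        assert not m.retained[0, 0]
        assert m.reason[0, 0] == REASON_TEMPORAL


class TestBarrierClip:
    def test_exclusion_polygon(self):
        sites = toy_sites(10, seed=3)
        ranges = [disc_range("spA", 50, 50, 40), disc_range("spB", 50, 50, 40)]
        barrier = box(0, 0, 100, 50)  # southern half excluded for spA only
        m = bm.clip_by_barrier(ranges, sites, {"spA": barrier})
        south = (sites["y_km"] < 50).to_numpy()
        np.testing.assert_array_equal(~m.retained[0], south)
        assert m.retained[1].all()


class TestCombine:
    def test_single_mask_identity(self):
        d = np.random.default_rng(0).uniform(-100, 600, (3, 5))
        m = bm.clip_by_distance(d, 300.0)
        c = bm.combine_masks([m])
        np.testing.assert_array_equal(c.retained, m.retained)
        np.testing.assert_array_equal(c.reason, m.reason)

    def test_union_of_disjoint_removals(self):
        a = bm.clip_by_distance(np.array([[500.0, 0.0]]), 300.0)
        s = np.array([[0.0, 4.0]])
        b = bm.clip_by_standardized_elevation(s)
        c = bm.combine_masks([a, b])
        assert (~c.retained).sum() == 2

    def test_precedence_geographic_over_elevation(self):
        a = bm.clip_by_distance(np.array([[500.0]]), 300.0)
        b = bm.clip_by_standardized_elevation(np.array([[4.0]]))
        c = bm.combine_masks([b, a])  # order of masks must not matter
        assert REASON_NAMES[int(c.reason[0, 0])] == "geographic_distance"

    def test_dimension_mismatch(self):
        a = bm.clip_by_distance(np.zeros((2, 3)), 1.0)
        b = bm.clip_by_distance(np.zeros((3, 2)), 1.0)
        with pytest.raises(ValueError, match="dimension"):
            bm.combine_masks([a, b])


class TestValidation:
    def test_detection_in_clipped_cell_listed(self, small_sim):
        hist = small_sim.history
        det = hist.detected_anywhere_by_cell()
        i, j = np.argwhere(det)[0]
        retained = np.ones(det.shape, bool)
        retained[i, j] = False
        mask = bm.ClipMask(
            retained, np.where(retained, 0, REASON_GEOGRAPHIC).astype(np.int8)
        )
        v = bm.validate_mask_against_detections(mask, hist)
        assert (hist.species_ids[i], hist.site_ids[j]) in v

    def test_clean_mask_empty_list(self, small_sim):
        mask = bm.ClipMask.full(small_sim.history.n_species, small_sim.history.n_sites)
        assert bm.validate_mask_against_detections(mask, small_sim.history) == []

    def test_widening_range_clears_violation(self, small_sim):
        """End to end: a too-tight distance clip flags omissions; rebuilding the
        mask from a widened polygon clears them."""
        hist, ranges, sites = small_sim.history, small_sim.ranges, small_sim.sites
        d = bm.signed_distance_matrix(ranges, sites)
        det = hist.detected_anywhere_by_cell()
        # choose a threshold that cuts off at least one detection
        dmax = bm.max_detection_distance(hist, d)
        thr = dmax - 1e-6
        mask = bm.clip_by_distance(d, max(thr, 1.0))
        violations = bm.validate_mask_against_detections(mask, hist)
        assert violations
        # widen: buffer every offending species' polygon outward
        bad_species = {v[0] for v in violations}
        widened = [
            bm.RangeInfo(
                r.species_id,
                r.geometry.buffer(2 * (dmax - thr + 1.0)),
                r.elev_lower_m,
                r.elev_upper_m,
            )
            if r.species_id in bad_species
            else r
            for r in ranges
        ]
        d2 = bm.signed_distance_matrix(widened, sites)
        mask2 = bm.clip_by_distance(d2, max(thr, 1.0))
        assert bm.validate_mask_against_detections(mask2, hist) == []

    def test_model_refuses_violating_mask(self, small_sim):
        hist = small_sim.history
        det = hist.detected_anywhere_by_cell()
        i, j = np.argwhere(det)[0]
        retained = np.ones(det.shape, bool)
        retained[i, j] = False
        mask = bm.ClipMask(
            retained, np.where(retained, 0, REASON_GEOGRAPHIC).astype(np.int8)
        )
        spec = bm.ModelSpec.msom()
        bundle = bm.build_covariate_bundle(small_sim.ranges, small_sim.sites, spec)
        with pytest.raises(ValueError, match="omission"):
            bm.OccupancyModel(hist, bundle, spec, mask=mask)
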