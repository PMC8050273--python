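"""Streamline filtering, ensemble concatenation, ROI intersection, endpoints."""

import numpy as np
import pytest

from prfconn.connectivity import (Connectome, EndpointRecord, arc_lengths,
                                  assign_endpoint_eccentricity,
                                  concatenate_ensemble, endpoint_band_proportions,
                                  filter_streamlines, fwmt_percentage,
                                  intersect_roi, life_validate, make_disk_roi)
from prfconn.synthetic import synth_endpoints, synth_evc_surface, synth_streamlines


def straight_streamline(start, direction, length, step=1.0):
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    n = int(round(length / step))
    return np.asarray(start, float) + np.outer(np.arange(n + 1) * step, direction)


class TestFiltering:
    def test_inclusive_length_bounds(self):
        c = Connectome(streamlines=[
            straight_streamline([0, 0, 0], [1, 0, 0], L) for L in (3, 4, 100, 200, 201)])
        kept = filter_streamlines(c, 4, 200)
        assert len(kept) == 3
        assert sorted(arc_lengths(kept)) == [4, 100, 200]

    def test_idempotent(self):
        c = synth_streamlines(50, length_distribution=(20, 30), seed=1)
        once = filter_streamlines(c)
        twice = filter_streamlines(once)
        assert len(once) == len(twice)

    def test_empty_and_identity(self):
        assert len(filter_streamlines(Connectome(streamlines=[]))) == 0
        c = Connectome(streamlines=[straight_streamline([0, 0, 0], [0, 1, 0], 50)])
        assert len(filter_streamlines(c)) == 1

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            filter_streamlines(Connectome(streamlines=[]), 10, 5)


class TestEnsemble:
    def test_count_additivity(self):
        cands = [synth_streamlines(n, seed=i) for i, n in enumerate([5, 0, 12, 3])]
        ens = concatenate_ensemble(cands)
        assert len(ens) == 20
        assert [m["n_streamlines"] for m in ens.metadata["candidates"]] == [5, 0, 12, 3]

    def test_empty_list(self):
        assert len(concatenate_ensemble([])) == 0

    def test_duplicates_retained(self):
        s = straight_streamline([0, 0, 0], [1, 0, 0], 10)
        c = Connectome(streamlines=[s])
        assert len(concatenate_ensemble([c, c, c])) == 3

    def test_life_stub(self):
        c = synth_streamlines(10, seed=2)
        assert len(life_validate(c)) == 10
        culled = life_validate(c, retain=lambda idx: idx % 2 == 0)
        assert len(culled) == 5


class TestIntersectROI:
    def make_surface_rois(self):
        surf = synth_evc_surface(n_vertices=600, seed=0)
        roi = make_disk_roi(np.array([55.0, 4.0]), 4.0, surf, label="face-roi")
        evc = make_disk_roi(np.array([5.0, 4.0]), 4.0, surf, label="evc")
        return surf, roi, evc

    def test_endpoint_on_vertex_included_far_excluded(self):
        surf, roi, evc = self.make_surface_rois()
        v = np.append(roi.vertices()[0], 0.0)
        hit = np.stack([v, v + [0, 0, 50]])
        miss = np.stack([[300.0, 300, 0], [310.0, 300, 0]])
        c = Connectome(streamlines=[hit, miss])
        assert len(intersect_roi(c, roi)) == 1

    def test_pairwise_requires_both_ends(self):
        surf, roi, evc = self.make_surface_rois()
        a = np.append(roi.vertices()[0], 0.0)
        b = np.append(evc.vertices()[0], 0.0)
        both = np.stack([a, b])
        one = np.stack([a, a + [0, 0, 50]])
        c = Connectome(streamlines=[both, one, both[::-1]])
        assert len(intersect_roi(c, roi, evc)) == 2

    def test_matches_bruteforce_distance_oracle(self, rng):
        surf, roi, evc = self.make_surface_rois()
        streamlines = [rng.uniform(-5, 65, size=(4, 3)) for _ in range(10)]
        c = Connectome(streamlines=streamlines)
        got = intersect_roi(c, roi, capture_dist=3.0)
        verts3 = np.column_stack([roi.vertices(), np.zeros(len(roi.vertices()))])
        expected = []
        for s in streamlines:
            near = [np.min(np.linalg.norm(verts3 - e, axis=1)) <= 3.0
                    for e in (s[0], s[-1])]
            if any(near):
                expected.append(s)
        assert len(got) == len(expected)


class TestFwmtPercentage:
    @pytest.mark.parametrize("total,conn,expected",
                             [(12, 3, 25.0), (10, 10, 100.0), (7, 0, 0.0)])
    def test_values(self, total, conn, expected):
        assert fwmt_percentage(total, conn) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            fwmt_percentage(0, 0)
        with pytest.raises(ValueError):
            fwmt_percentage(3, 5)


class TestEndpointEccentricity:
    def test_coincident_vertex(self):
        surf = synth_evc_surface(n_vertices=200, seed=0)
        pos = surf.vertices[17][None, :]
        recs, dropped = assign_endpoint_eccentricity(pos, surf)
        assert dropped == 0
        assert recs[0].eccentricity == surf.eccentricity[17]

    def test_far_endpoint_dropped(self):
        surf = synth_evc_surface(n_vertices=200, seed=0)
        recs, dropped = assign_endpoint_eccentricity(np.array([[500.0, 500.0]]),
                                                     surf, max_dist=2.0)
        assert recs == [] and dropped == 1

    def test_matches_exhaustive_nearest_neighbor(self, rng):
        surf = synth_evc_surface(n_vertices=300, seed=1)
        cloud = rng.uniform(0, 60, size=(25, 2))
        recs, _ = assign_endpoint_eccentricity(cloud, surf, max_dist=100.0)
        for pos, rec in zip(cloud, recs):
            d = np.linalg.norm(surf.vertices - pos, axis=1)
            assert rec.eccentricity == surf.eccentricity[np.argmin(d)]


class TestEndpointBandProportions:
    def test_single_band_equal_weights(self):
        recs = [EndpointRecord(position=np.zeros(2), eccentricity=3.0)] * 4
        bp = endpoint_band_proportions(recs)
        assert np.array_equal(bp.fractions, [1, 0, 0, 0])

    def test_weighted_fractions(self):
        recs = [EndpointRecord(position=np.zeros(2), eccentricity=3.0, tdi_weight=3.0),
                EndpointRecord(position=np.zeros(2), eccentricity=15.0, tdi_weight=1.0)]
        bp = endpoint_band_proportions(recs)
        assert np.allclose(bp.fractions, [0.75, 0, 0.25, 0])
        unweighted = endpoint_band_proportions(recs, weighted=False)
        assert np.allclose(unweighted.fractions, [0.5, 0, 0.5, 0])

    def test_invariant_to_uniform_weight_scaling(self):
        recs = [EndpointRecord(position=np.zeros(2), eccentricity=e, tdi_weight=w)
                for e, w in [(2, 1.0), (7, 2.0), (12, 0.5), (30, 4.0)]]
        scaled = [EndpointRecord(position=r.position, eccentricity=r.eccentricity,
                                 tdi_weight=10 * r.tdi_weight) for r in recs]
        assert np.allclose(endpoint_band_proportions(recs).fractions,
                           endpoint_band_proportions(scaled).fractions)

    def test_foveal_generator_beats_uniform_in_band_one(self):
        surf = synth_evc_surface(seed=0)
        foveal = synth_endpoints((0.6, 0.2, 0.1, 0.1), 2000, surf, seed=3)
        uniform = synth_endpoints((0.25, 0.25, 0.25, 0.25), 2000, surf, seed=4)
        assert (endpoint_band_proportions(foveal).fractions[0]
                > endpoint_band_proportions(uniform).fractions[0])


class TestDiskROI:
    def test_area_on_unit_sheet(self):
        surf = synth_evc_surface(n_vertices=4026, seed=0)
        roi = make_disk_roi(np.array([30.0, 30.0]), 5.0, surf)
        assert len(roi.vertex_indices) == pytest.approx(np.pi * 25, rel=0.1)

    def test_whole_surface(self):
        surf = synth_evc_surface(n_vertices=200, seed=0)
        roi = make_disk_roi(np.array([30.0, 2.0]), 1000.0, surf)
        assert len(roi.vertex_indices) == surf.n_vertices

    def test_radius_below_spacing_rejected(self):
        surf = synth_evc_surface(n_vertices=200, seed=0)
        with pytest.raises(ValueError):
            make_disk_roi(np.array([30.5, 1.5]), 0.3, surf)
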