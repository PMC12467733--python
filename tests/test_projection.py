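"""Forward projection models: analytic contracts, rendering, stitching."""

import dataclasses

import numpy as np
import pytest

from radphantom import phantom
from radphantom.projection import (
    AcquisitionGeometry,
    NoiseModel,
    ProjectionError,
    project_one_shot,
    project_slot,
    render,
    rotational_segment_map,
    simulate_rotational,
    world_positions,
)


def _geometry(modality="one_shot", sid=1500.0, sod=1230.0, spacing=1.0,
              size=(2001, 1001), **kw):
    return AcquisitionGeometry(modality=modality, sid=sid, sod=sod,
                               pixel_spacing=spacing, detector_size=size, **kw)


class TestOneShot:
    def test_point_on_central_ray_at_detector_plane_is_identity(self):
        geo = _geometry()
        (row, col), mag = project_one_shot((0.0, geo.sid, 0.0), geo)
        assert mag == 1.0
        assert (row, col) == geo.principal_point

    def test_similar_triangles_magnification(self):
        """Hand-evaluated: sid = 1500, depth 1230, offset 100 mm gives
        magnification 1500/1230 ~ 1.2195 and image offset ~121.95 mm."""
        geo = _geometry()
        (row, col), mag = project_one_shot((100.0, 1230.0, 0.0), geo)
        assert mag == pytest.approx(1500.0 / 1230.0, abs=1e-12)
        offset_mm = (col - geo.principal_point[1]) * geo.pixel_spacing
        assert offset_mm == pytest.approx(121.9512, abs=1e-3)

    def test_same_depth_pairs_scale_exactly_mixed_depth_pairs_do_not(self):
        geo = _geometry()
        (r1, c1), mag = project_one_shot((0.0, 1230.0, 50.0), geo)
        (r2, c2), _ = project_one_shot((0.0, 1230.0, -50.0), geo)
        assert (r1 - r2) * geo.pixel_spacing == pytest.approx(100.0 * mag,
                                                              abs=1e-9)
        # mixed depth: separation is not a uniform scaling of 100 mm
        (r3, _), _ = project_one_shot((0.0, 1300.0, -50.0), geo)
        assert (r1 - r3) * geo.pixel_spacing != pytest.approx(100.0 * mag,
                                                              abs=1e-3)

    def test_point_behind_source_rejected(self):
        with pytest.raises(ProjectionError, match="behind the source"):
            project_one_shot((0.0, -5.0, 0.0), _geometry())

    def test_off_detector_projection_named(self):
        with pytest.raises(ProjectionError, match="detector"):
            project_one_shot((2000.0, 1230.0, 0.0), _geometry())


class TestSlot:
    def test_longitudinal_distances_exactly_preserved(self):
        """Scan-direction coordinates pass at unit magnification on the
        raw analytic path, regardless of depth."""
        geo = _geometry("slot")
        for depth in (800.0, 1230.0, 1499.0):
            (r1, _), _ = project_slot((0.0, depth, 250.0), geo)
            (r2, _), _ = project_slot((0.0, depth, -250.0), geo)
            assert (r1 - r2) * geo.pixel_spacing == pytest.approx(500.0,
                                                                  abs=1e-9)

    def test_transverse_magnified_by_sid_over_depth(self):
        geo = _geometry("slot")
        (_, c), mag_t = project_slot((100.0, geo.sod, 0.0), geo)
        assert mag_t == pytest.approx(geo.sid / geo.sod)
        assert (c - geo.principal_point[1]) * geo.pixel_spacing == pytest.approx(
            100.0 * geo.sid / geo.sod, abs=1e-9)

    def test_parallel_beam_limit_slot_equals_one_shot(self):
        """As sid, sod grow with sid/sod -> 1 both projections converge to
        the identity mapping of in-plane coordinates."""
        geo = _geometry("slot", sid=1e9, sod=1e9 - 1, spacing=1.0)
        p = (120.0, 1e9 - 1, -340.0)
        (rs, cs), _ = project_slot(p, geo)
        (ro, co), mag = project_one_shot(p, dataclasses.replace(
            geo, modality="one_shot"))
        assert mag == pytest.approx(1.0, rel=1e-6)
        assert rs == pytest.approx(ro, abs=1e-3)
        assert cs == pytest.approx(co, abs=1e-3)


class TestRender:
    def test_provenance_diameter_follows_magnification(self, layout,
                                                       slot_geometry):
        """An 8 mm bead at magnification sid/depth renders with diameter
        8 x mag / spacing pixels."""
        rad = render(layout, slot_geometry)
        pos = world_positions(layout, slot_geometry)
        for lab, prov in rad.provenance.items():
            mag = slot_geometry.sid / pos[lab][1]
            want = 8.0 * mag / slot_geometry.pixel_spacing
            assert prov["diameter_px"] == pytest.approx(want, rel=1e-12)

    def test_zero_noise_disk_crosses_mid_intensity_at_true_radius(
            self, layout, one_shot_geometry):
        rad = render(layout, one_shot_geometry, background=0.1, contrast=0.8)
        prov = rad.provenance["C"]
        row, col = prov["center_px"]
        r = prov["diameter_px"] / 2
        # intensity at radius-0.75 px is above mid, at radius+0.75 below
        mid = 0.1 + 0.4
        ir, ic = int(round(row)), int(round(col))
        assert rad.image[ir, int(round(col - r + 1.0))] > mid
        assert rad.image[ir, int(round(col - r - 1.0))] < mid
        # bead interior well above background by the configured contrast
        assert rad.image[ir, ic] == pytest.approx(0.9, abs=1e-5)

    def test_seeded_render_is_bit_identical(self, layout, one_shot_geometry):
        noise = NoiseModel(gaussian_sigma=0.05, blur_sigma=0.7, seed=42)
        a = render(layout, one_shot_geometry, noise=noise)
        b = render(layout, one_shot_geometry, noise=noise)
        assert np.array_equal(a.image, b.image)

    def test_noise_requires_seed(self):
        with pytest.raises(ProjectionError, match="seed"):
            NoiseModel(gaussian_sigma=0.1)


class TestRotational:
    def test_single_segment_reduction(self, layout):
        """With the whole layout inside one segment and zero jitter, the
        stitched bead geometry equals that segment's cone-beam rendering:
        relative positions match project_one_shot up to a pure translation."""
        geo = _geometry("rotational", size=(8001, 1001), segments=3,
                        overlap_fraction=0.1)
        rad = simulate_rotational(layout, geo)
        pos = world_positions(layout, geo)
        segs = {p["segment"] for p in rad.provenance.values()}
        assert len(segs) == 1  # layout fits in one segment
        one = dataclasses.replace(geo, modality="one_shot")
        deltas = {}
        for lab, prov in rad.provenance.items():
            (r_os, c_os), _ = project_one_shot(pos[lab], one)
            assert prov["center_px"][1] == pytest.approx(c_os, abs=1e-9)
            deltas[lab] = prov["center_px"][0] - r_os
        # per depth plane the offset is a rigid translation; across the two
        # planes the tilt rectification leaves only a sub-pixel residual
        for plane in (1, 2):
            labs = [l for l in deltas if phantom.PLANE_OF_LABEL[l] == plane]
            assert np.ptp([deltas[l] for l in labs]) < 1e-9
        assert np.ptp(list(deltas.values())) < 0.1

    def test_near_source_plane_underestimates_vs_cone_beam(
            self, layout, rotational_geometry):
        """Beads nearer the source than the object plane: stitched
        longitudinal inter-bead distances fall below the single-exposure
        cone-beam projection (the analytic oracle), i.e. stitching biases
        distances toward underestimation."""
        geo = rotational_geometry  # phantom posed source-ward of sod
        assert geo.object_offset > 0
        rad = simulate_rotational(layout, geo)
        pos = world_positions(layout, geo)
        one = dataclasses.replace(geo, modality="one_shot")
        # C (its own segment) vs the hip beads (central segment): the most
        # longitudinal, cross-segment pairs
        for pair in (("C", "LH"), ("C", "RH")):
            d_st = abs(rad.provenance[pair[0]]["center_px"][0]
                       - rad.provenance[pair[1]]["center_px"][0])
            r0, _ = project_one_shot(pos[pair[0]], one)[0], None
            r1 = project_one_shot(pos[pair[1]], one)[0]
            d_cone = abs(r0[0] - r1[0])
            assert d_st < d_cone

    def test_same_seed_is_identical(self, layout, rotational_geometry):
        a = simulate_rotational(layout, rotational_geometry,
                                registration_error_sigma=0.8, seed=11)
        b = simulate_rotational(layout, rotational_geometry,
                                registration_error_sigma=0.8, seed=11)
        assert np.array_equal(a.image, b.image)
        assert a.meta["segment_shifts"] == b.meta["segment_shifts"]

    def test_jitter_without_seed_rejected(self, layout, rotational_geometry):
        with pytest.raises(ProjectionError, match="seed"):
            simulate_rotational(layout, rotational_geometry,
                                registration_error_sigma=1.0)

    def test_geometry_validation(self):
        with pytest.raises(ProjectionError, match="sid > sod"):
            _geometry(sid=1230.0, sod=1500.0)
        with pytest.raises(ProjectionError, match="segments"):
            _geometry("rotational", segments=1)

    def test_segment_map_reduces_to_cone_at_anchor_plane(self):
        """A point on the segment's central ray at the object plane maps to
        the mechanically calibrated panorama position."""
        geo = _geometry("rotational", segments=3, overlap_fraction=0.2,
                        size=(4001, 1001))
        m_k = 200.0
        (row, _), mag = rotational_segment_map((0.0, geo.sod, m_k), geo, m_k)
        want = geo.principal_point[0] + m_k * geo.sid / geo.sod / geo.pixel_spacing
        assert row == pytest.approx(want, abs=1e-9)
        assert mag == pytest.approx(geo.sid / geo.sod)
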