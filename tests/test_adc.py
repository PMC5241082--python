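"""ADC computation, clipping, and the two correction routes."""

import numpy as np
import pytest

import gnlcorr as g


def make_series(shape=(4, 4, 3), adc=1.5, s0=1000.0, bvals=(0.0, 1000.0), schema=None):
    """Uniform monoexponential phantom series, one acquisition per (b, u)."""
    schema = schema or g.DirectionSchema.lab()
    geom = g.ImageGeometry.from_origin_spacing(
        (-20.0, -20.0, -10.0), (10.0, 10.0, 10.0), shape
    )
    data, bl, vl = [], [], []
    for b in bvals:
        dirs = [np.zeros(3)] if b == 0 else schema.directions
        for u in dirs:
            data.append(np.full(shape, s0 * np.exp(-b * adc * 1e-3)))
            bl.append(b)
            vl.append(u)
    return g.DWISeries(
        np.stack(data, axis=-1), np.array(bl), np.array(vl), geom, schema=schema
    )


def test_trace_of_identical_direction_images_is_that_image():
    s = make_series(adc=1.2)
    t = g.trace_image(s, 1000.0)
    np.testing.assert_allclose(t, s.data[..., 1], rtol=1e-12)


def test_trace_is_geometric_mean():
    s = make_series()
    data = s.data.copy()
    data[0, 0, 0, 1:4] = [100.0, 200.0, 400.0]
    s2 = g.DWISeries(data, s.bvals, s.bvecs, s.geometry, schema=s.schema)
    assert g.trace_image(s2, 1000.0)[0, 0, 0] == pytest.approx(200.0, rel=1e-12)


def test_trace_missing_direction_is_named():
    s = make_series()
    keep = [0, 1, 2]  # drop the SI direction at b=1000
    s2 = g.DWISeries(
        s.data[..., keep], s.bvals[keep], s.bvecs[keep], s.geometry, schema=s.schema
    )
    with pytest.raises(ValueError, match="missing direction.*index 2"):
        g.trace_image(s2, 1000.0)


def test_adc_closed_form():
    s = make_series(adc=1.5)
    adc = g.compute_adc(s)
    assert adc.values[2, 2, 1] == pytest.approx(1.5, abs=1e-12)
    assert adc.mask.all()


def test_adc_below_plausibility_window_zeroed_and_masked():
    s = make_series(adc=0.4)
    adc = g.compute_adc(s)
    assert np.all(adc.values == 0.0)
    assert not adc.mask.any()


def test_adc_invariant_to_global_intensity_scaling():
    s = make_series(adc=2.1)
    scaled = g.DWISeries(
        s.data * 37.5, s.bvals, s.bvecs, s.geometry, schema=s.schema
    )
    np.testing.assert_allclose(
        g.compute_adc(scaled).values, g.compute_adc(s).values, atol=1e-12
    )


def test_two_point_adc_equals_loglinear_regression():
    """With exact monoexponential decay the b=0/b_high two-point estimate
    coincides with the three-shell log-linear regression."""
    s = make_series(adc=1.8, bvals=(0.0, 500.0, 1000.0))
    adc = g.compute_adc(s)
    b = np.array([0.0, 500.0, 1000.0])
    logs = [np.log(g.trace_image(s, bb)[1, 1, 1]) for bb in b]
    slope = np.polyfit(b, logs, 1)[0]
    assert adc.values[1, 1, 1] == pytest.approx(-slope * 1e3, abs=1e-12)


def test_nonpositive_intensity_masks_voxel_without_raising():
    s = make_series()
    data = s.data.copy()
    data[0, 0, 0, 0] = 0.0
    s2 = g.DWISeries(data, s.bvals, s.bvecs, s.geometry, schema=s.schema)
    adc = g.compute_adc(s2)
    assert not adc.mask[0, 0, 0]
    assert adc.values[0, 0, 0] == 0.0
    assert adc.mask[1, 1, 1]


def test_clip_idempotent():
    rng = np.random.default_rng(2)
    vals = rng.uniform(-1.0, 5.0, (6, 6, 6))
    mask = np.ones(vals.shape, bool)
    v1, m1 = g.clip_adc(vals, mask)
    v2, m2 = g.clip_adc(v1, m1)
    np.testing.assert_array_equal(v1, v2)
    np.testing.assert_array_equal(m1, m2)


def unit_corrector(geom, value=1.0):
    return g.CorrectorMap(np.full(geom.shape, value), "average", geometry=geom)


def test_unit_corrector_leaves_adc_unchanged():
    s = make_series(adc=1.5)
    adc = g.compute_adc(s)
    out = g.correct_adc(adc, unit_corrector(adc.geometry))
    np.testing.assert_array_equal(out.values, adc.values)


def test_correct_adc_divides_by_corrector():
    s = make_series(adc=1.5)
    adc = g.compute_adc(s)
    out = g.correct_adc(adc, unit_corrector(adc.geometry, 0.75))
    assert out.values[1, 1, 1] == pytest.approx(2.0, abs=1e-12)


def test_correct_adc_geometry_mismatch_raises():
    s = make_series()
    adc = g.compute_adc(s)
    other = g.ImageGeometry.from_origin_spacing(
        (0.0, 0.0, 0.0), (5.0, 5.0, 5.0), adc.geometry.shape
    )
    with pytest.raises(ValueError, match="geometry"):
        g.correct_adc(adc, unit_corrector(other))


def test_intensity_route_unit_correctors_no_op():
    s = make_series(adc=1.5)
    cors = [(u, unit_corrector(s.geometry)) for u in s.schema.directions]
    out = g.correct_intensities(s, cors)
    np.testing.assert_allclose(out.data, s.data, atol=1e-12)


def test_intensity_route_uniform_corrector_matches_division():
    s = make_series(adc=1.5)
    cors = [(u, unit_corrector(s.geometry, 0.8)) for u in s.schema.directions]
    adc_i = g.compute_adc(g.correct_intensities(s, cors))
    adc_d = g.correct_adc(g.compute_adc(s), unit_corrector(s.geometry, 0.8))
    np.testing.assert_allclose(adc_i.values, adc_d.values, atol=1e-9)


def test_intensity_route_equivalence_spatially_varying(generic_field, small_config):
    """Noise-free simulated phantom: both correction routes agree to 1e-9."""
    scan = g.simulate_series(small_config, generic_field)[2]
    direct = g.correct_adc(g.compute_adc(scan.series), scan.c_av)
    routed = g.compute_adc(g.correct_intensities(scan.series, scan.correctors))
    both = direct.mask & routed.mask
    assert both.sum() > 1000
    assert np.abs(direct.values[both] - routed.values[both]).max() < 1e-9


def test_zero_fill_preserves_original_samples_and_positions():
    s = make_series(shape=(8, 8, 3), adc=1.5)
    data = s.data.copy()
    rng = np.random.default_rng(4)
    data += rng.uniform(0, 50, data.shape)  # structure beyond a constant
    s2 = g.DWISeries(data, s.bvals, s.bvecs, s.geometry, schema=s.schema)
    z = g.zero_fill(s2, (16, 16))
    np.testing.assert_allclose(z.data[::2, ::2], s2.data, rtol=1e-10)
    np.testing.assert_allclose(
        z.geometry.voxel_to_mm([2.0, 4.0, 1.0]),
        s2.geometry.voxel_to_mm([1.0, 2.0, 1.0]),
        atol=1e-12,
    )
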