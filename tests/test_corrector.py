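"""Corrector-map identities, schema invariance, and resampling."""

import numpy as np
import pytest

import gnlcorr as g
from gnlcorr.corrector import NONLAB_SCHEMA_U

from conftest import identity_field


def tensor_with_node(diag, node=(1, 1, 1)):
    """Identity field with one off-center node set to diag(...)."""
    f = identity_field()
    t = f.tensor.copy()
    t[node] = np.diag(diag)
    return g.NonlinearityTensorField(f.grid, t), node


def test_identity_tensor_gives_unit_corrector(identity_tensor):
    for u in np.eye(3):
        c = g.corrector_for_direction(identity_tensor, u)
        assert np.abs(c.values - 1.0).max() < 1e-14
    cav = g.schema_average_corrector(identity_tensor, g.DirectionSchema.lab())
    assert np.abs(cav.values - 1.0).max() < 1e-14


def test_direction_corrector_is_squared_column_norm():
    field, node = tensor_with_node([0.8, 1.0, 1.1])
    c = g.corrector_for_direction(field, np.array([1.0, 0.0, 0.0]))
    assert c.values[node] == pytest.approx(0.64, abs=1e-14)


def test_diagonal_average_is_mean_of_squares():
    field, node = tensor_with_node([0.9, 1.05, 1.2])
    cav = g.schema_average_corrector(field, g.DirectionSchema.lab())
    expected = (0.9**2 + 1.05**2 + 1.2**2) / 3.0
    assert cav.values[node] == pytest.approx(expected, abs=1e-14)


def test_frobenius_dyadic_identity_random():
    """|| (Lu)(Lu)^T ||_F == |Lu|^2, brute-force oracle on random tensors."""
    rng = np.random.default_rng(123)
    for _ in range(500):
        L = np.eye(3) + rng.normal(0, 0.3, (3, 3))
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        lu = L @ u
        dyadic = np.outer(lu, lu)
        assert np.linalg.norm(dyadic, "fro") == pytest.approx(
            lu @ lu, rel=1e-12, abs=1e-12
        )


def test_schema_average_is_orthonormal_invariant(generic_field):
    """C_av identical for LAB and the oblique non-LAB triad everywhere."""
    lab = g.schema_average_corrector(generic_field, g.DirectionSchema.lab())
    nonlab = g.schema_average_corrector(generic_field, g.DirectionSchema.nonlab())
    assert np.abs(lab.values - nonlab.values).max() < 1e-10
    # and for a random orthonormal triad
    rng = np.random.default_rng(9)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    rnd = g.schema_average_corrector(
        generic_field, g.DirectionSchema("custom", q)
    )
    assert np.abs(lab.values - rnd.values).max() < 1e-10


def test_nonlab_schema_is_orthonormal():
    assert np.abs(NONLAB_SCHEMA_U.T @ NONLAB_SCHEMA_U - np.eye(3)).max() < 1e-12


def test_sign_structure_horizontal_bore(generic_field):
    """Negative b-value bias along SI, positive along RL/AP off-axis."""
    cav = g.schema_average_corrector(generic_field, g.DirectionSchema.lab())
    i0 = generic_field.grid.isocenter_index()
    assert cav.values[i0] == pytest.approx(1.0, abs=1e-9)
    for step in (5, 10, 15, 20):  # 50..200 mm on the 10-mm grid
        assert cav.values[i0[0], i0[1], i0[2] + step] < 1.0
        assert cav.values[i0[0], i0[1], i0[2] - step] < 1.0
        assert cav.values[i0[0] + step, i0[1], i0[2]] > 1.0
        assert cav.values[i0[0], i0[1] + step, i0[2]] > 1.0


def test_monotone_bias_growth_along_axes(generic_field):
    cav = g.schema_average_corrector(generic_field, g.DirectionSchema.lab())
    i0 = generic_field.grid.isocenter_index()
    si = cav.values[i0[0], i0[1], i0[2] : i0[2] + 21]  # 0..200 mm
    ap = cav.values[i0[0] : i0[0] + 21, i0[1], i0[2]]
    assert np.all(np.diff(np.abs(si - 1.0)) >= 0)
    assert np.all(np.diff(np.abs(ap - 1.0)) >= 0)


def test_non_unit_direction_rejected(identity_tensor):
    with pytest.raises(ValueError, match="unit"):
        g.corrector_for_direction(identity_tensor, np.array([1.0, 1.0, 0.0]))


def test_non_orthonormal_schema_warns_and_tags_custom(identity_tensor):
    U = np.eye(3)
    U[:, 1] = [np.sqrt(0.5), np.sqrt(0.5), 0.0]  # unit but not orthogonal
    with pytest.warns(UserWarning, match="not orthonormal"):
        c = g.schema_average_corrector(
            identity_tensor, g.DirectionSchema("tilted", U)
        )
    assert c.schema == "custom"


def test_resample_on_coincident_grid_is_identity(coarse_field):
    cav = g.schema_average_corrector(coarse_field, g.DirectionSchema.lab())
    grid = coarse_field.grid
    geom = g.ImageGeometry.from_origin_spacing(grid.origin, grid.spacing, grid.shape)
    res = g.resample_to_image(cav, geom)
    np.testing.assert_allclose(res.values, cav.values, atol=1e-12)


def test_resample_constant_field_stays_constant():
    grid = g.GridSpec.centered(300.0, 50.0)
    c = g.CorrectorMap(np.full(grid.shape, 1.3), "average", grid=grid)
    geom = g.ImageGeometry.from_origin_spacing(
        (-40.0, -40.0, -40.0), (7.0, 7.0, 7.0), (12, 12, 12)
    )
    res = g.resample_to_image(c, geom)
    assert np.abs(res.values - 1.3).max() < 1e-12


def test_trilinear_error_bound_for_quadratic_field():
    """Half-spacing resampling error stays below the O(h^2) trilinear bound."""
    alpha = 1e-5
    h = 20.0
    grid = g.GridSpec.centered(400.0, h)
    pts = grid.meshgrid()
    vals = 1.0 + alpha * np.sum(pts**2, axis=-1)
    c = g.CorrectorMap(vals, "average", grid=grid)
    geom = g.ImageGeometry.from_origin_spacing(
        (-100.0, -100.0, -100.0), (h / 2, h / 2, h / 2), (21, 21, 21)
    )
    res = g.resample_to_image(c, geom)
    exact = 1.0 + alpha * np.sum(geom.voxel_centers_mm() ** 2, axis=-1)
    # per-axis quadratic interpolation error <= alpha h^2 / 4, three axes
    bound = 3 * alpha * h**2 / 4
    assert np.abs(res.values - exact).max() <= bound + 1e-12


def test_resample_outside_fov_reports_extent(coarse_field):
    cav = g.schema_average_corrector(coarse_field, g.DirectionSchema.lab())
    geom = g.ImageGeometry.from_origin_spacing(
        (250.0, 0.0, 0.0), (20.0, 20.0, 20.0), (10, 4, 4)
    )
    with pytest.raises(ValueError, match="extent"):
        g.resample_to_image(cav, geom)
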