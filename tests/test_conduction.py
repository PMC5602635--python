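"""Forward conduction model: shear rate, field building, impedance solve."""

import numpy as np
import pytest

from conftest import dense_nodal_impedance
from thrombovol.conduction import (
    ChannelGeometry,
    ConductivityField,
    ConductivityModel,
    ForwardModel,
    VoxelGrid,
    cell_constant,
    estimate_blood_conductivity,
    forward_impedance,
    shear_rate,
    thrombus_conductivity,
)
from thrombovol.volumetry import ImagePlane


class TestShearRate:
    def test_reference_conditions_give_1500(self):
        """75 µl/min through a 500 x 100 µm section: arteriolar 1500 1/s."""
        assert shear_rate(ChannelGeometry()) == pytest.approx(1500.0)

    def test_linear_in_flow_rate(self):
        g1 = ChannelGeometry(flow_rate_ul_min=75.0)
        g2 = ChannelGeometry(flow_rate_ul_min=150.0)
        assert shear_rate(g2) == pytest.approx(2 * shear_rate(g1))

    def test_half_flow(self):
        assert shear_rate(
            ChannelGeometry(flow_rate_ul_min=37.5)
        ) == pytest.approx(750.0)


class TestBuildField:
    def test_zero_scale_factor_uniform_blood(self, small_device):
        img = ImagePlane(np.random.default_rng(0).integers(0, 255, (32, 32)).astype(np.uint8))
        fld = small_device.field(img, 0.0)
        assert np.allclose(fld.sigma, small_device.model.sigma_blood)

    def test_saturated_image_fills_channel(self, small_device):
        """Full-255 image with k·255 above the roof: thrombus fills every
        voxel column the image covers, clamped at the channel height."""
        img = ImagePlane(np.full((256, 256), 255, dtype=np.uint8))
        h = small_device.geom.height
        fld = small_device.field(img, 2 * h / 255.0)
        g = fld.grid
        extent = 256 * img.pixel_pitch
        ox = g.x0_window + (g.window - extent) / 2.0
        oy = g.y0_window + (g.window - extent) / 2.0
        xe = np.concatenate([[0.0], np.cumsum(g.dx)])
        ye = np.concatenate([[0.0], np.cumsum(g.dy)])
        checked = 0
        for i in range(len(g.dx)):
            if not (xe[i] >= ox and xe[i + 1] <= ox + extent):
                continue
            for j in range(len(g.dy)):
                if ye[j] >= oy and ye[j + 1] <= oy + extent:
                    assert np.allclose(
                        fld.sigma[i, j, :], small_device.model.sigma_thrombus
                    )
                    checked += 1
        assert checked > 0

    def test_rejects_negative_scale(self, small_device):
        img = ImagePlane(np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            small_device.field(img, -0.1)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_fill_fractions_match_per_voxel_oracle(self, small_device, seed):
        """Conductivities equal a brute-force per-voxel recomputation of the
        block-averaged height and fractional fill."""
        rng = np.random.default_rng(seed)
        img = ImagePlane(rng.integers(0, 255, (48, 48)).astype(np.uint8))
        k = 0.1
        fm = small_device
        fld = fm.field(img, k)
        g = fld.grid
        heights = np.minimum(img.intensities * k, fm.geom.height)
        f = img.pixel_pitch
        ox = g.x0_window + (g.window - 48 * f) / 2.0
        oy = g.y0_window + (g.window - 48 * f) / 2.0
        xe = np.concatenate([[0.0], np.cumsum(g.dx)])
        ye = np.concatenate([[0.0], np.cumsum(g.dy)])
        ze = np.concatenate([[0.0], np.cumsum(g.dz)])
        sb = fm.model.sigma_blood
        st = fm.model.sigma_thrombus
        for i in range(len(g.dx)):
            for j in range(len(g.dy)):
                # exact area-weighted mean height over the voxel footprint,
                # accumulated pixel by pixel (zero outside the image)
                acc = 0.0
                for r in range(48):
                    ovx = min(xe[i + 1], ox + (r + 1) * f) - max(xe[i], ox + r * f)
                    if ovx <= 0:
                        continue
                    for c in range(48):
                        ovy = min(ye[j + 1], oy + (c + 1) * f) - max(
                            ye[j], oy + c * f
                        )
                        if ovy > 0:
                            acc += heights[r, c] * ovx * ovy
                hv = acc / (g.dx[i] * g.dy[j])
                for kk in range(len(g.dz)):
                    fill = np.clip((hv - ze[kk]) / g.dz[kk], 0.0, 1.0)
                    expect = 1.0 / (fill / st + (1 - fill) / sb)
                    assert fld.sigma[i, j, kk] == pytest.approx(expect, rel=1e-10)


class TestForwardImpedance:
    def test_two_cell_series_resistor_closed_form(self):
        """Parallel-plate toy: |Z| equals the series sum dz / (sigma A)."""
        grid = VoxelGrid(
            dx=np.array([1.0]), dy=np.array([1.0]), dz=np.array([1.0, 2.0]),
            x0_window=0.0, y0_window=0.0, window=1.0,
        )
        fld = ConductivityField(grid=grid, sigma=np.array([[[0.5, 2.0]]]))
        m = np.ones((1, 1), dtype=bool)
        z = forward_impedance(fld, None, masks=(m, m), inner_on_top=True)
        assert z == pytest.approx((1.0 / 0.5 + 2.0 / 2.0) / 1e-6, rel=1e-12)

    def test_conductivity_scaling_scales_impedance_inversely(self, small_device):
        fld = small_device.uniform_field(0.59)
        z1 = small_device.impedance_of_field(fld)
        fld3 = ConductivityField(grid=fld.grid, sigma=fld.sigma * 3.0)
        z3 = small_device.impedance_of_field(fld3)
        assert z3 == pytest.approx(z1 / 3.0, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_nodal_oracle(self, small_device, seed):
        """Sparse finite-volume solve vs independent dense nodal analysis."""
        rng = np.random.default_rng(seed)
        grid = small_device.grid
        sigma = rng.uniform(0.05, 2.0, grid.shape)
        fld = ConductivityField(grid=grid, sigma=sigma)
        masks = (small_device.mask_outer, small_device.mask_inner)
        z = forward_impedance(fld, None, masks=masks)
        z_ref = dense_nodal_impedance(fld, masks)
        assert z == pytest.approx(z_ref, rel=1e-8)

    def test_charge_conservation(self, small_device):
        """Current into one electrode equals current out of the other."""
        rng = np.random.default_rng(3)
        sigma = rng.uniform(0.1, 1.0, small_device.grid.shape)
        fld = ConductivityField(grid=small_device.grid, sigma=sigma)
        z, (i_out, i_in) = forward_impedance(
            fld, None, masks=(small_device.mask_outer, small_device.mask_inner),
            return_currents=True,
        )
        assert abs(i_out + i_in) <= 1e-10 * abs(i_out)

    def test_strictly_increasing_in_scale_factor(self, small_device):
        rng = np.random.default_rng(4)
        img = ImagePlane(rng.integers(1, 255, (64, 64)).astype(np.uint8))
        zs = [small_device.impedance(img, k) for k in (0.0, 0.02, 0.05, 0.1)]
        assert np.all(np.diff(zs) > 0)

    def test_baseline_equals_uniform_blood(self, small_device):
        img = ImagePlane(np.zeros((16, 16), dtype=np.uint8))
        assert small_device.impedance(img, 0.2) == pytest.approx(
            small_device.baseline_impedance(), rel=1e-9
        )


class TestCellConstant:
    def test_independent_of_conductivity(self, small_device):
        k1 = cell_constant(small_device)
        z = small_device.impedance_of_field(small_device.uniform_field(0.59))
        assert z * 0.59 == pytest.approx(k1, rel=1e-9)

    def test_positive(self, small_device):
        assert cell_constant(small_device) > 0

    def test_extrapolated_constant_stable_under_halving(self, small_device):
        """The edge-singularity-corrected cell constant moves < 2% when every
        voxel is halved."""
        fm = small_device
        k_coarse = cell_constant(fm, extrapolate=True)
        fm_half = ForwardModel(
            geom=fm.geom, layout=fm.layout, model=fm.model,
            grid=fm.grid.refined(2),
        )
        k_fine = cell_constant(fm_half, extrapolate=True)
        assert abs(k_fine - k_coarse) / abs(k_fine) <= 0.02


class TestConductivityEstimates:
    def test_round_trip_blood_conductivity(self, small_device):
        """Forward-solved baseline at 0.59 S/m inverts back to 0.59 S/m."""
        k = cell_constant(small_device)
        z_baseline = small_device.impedance_of_field(
            small_device.uniform_field(0.59)
        )
        assert estimate_blood_conductivity(z_baseline, k) == pytest.approx(
            0.59, rel=1e-9
        )

    def test_reciprocal_in_baseline(self):
        assert estimate_blood_conductivity(500.0, 1000.0) == pytest.approx(
            2 * estimate_blood_conductivity(1000.0, 1000.0)
        )

    def test_unit_round_trip(self, small_device):
        k = cell_constant(small_device)
        z1 = small_device.impedance_of_field(small_device.uniform_field(1.0))
        assert estimate_blood_conductivity(z1, k) == pytest.approx(1.0, rel=1e-9)

    def test_rejects_non_positive_baseline(self):
        with pytest.raises(ValueError):
            estimate_blood_conductivity(0.0, 1000.0)

    @pytest.mark.parametrize(
        "sigma_blood, expect", [(0.59, 0.07375), (0.8, 0.1), (8.0, 1.0)]
    )
    def test_thrombus_conductivity_one_eighth(self, sigma_blood, expect):
        assert thrombus_conductivity(sigma_blood) == pytest.approx(expect)

    def test_thrombus_conductivity_rejects_non_positive(self):
        with pytest.raises(ValueError):
            thrombus_conductivity(0.0)


def test_electrode_footprints_disjoint_and_present(device):
    assert device.mask_outer.any() and device.mask_inner.any()
    assert not (device.mask_outer & device.mask_inner).any()


def test_conductivity_model_requires_contrast():
    with pytest.raises(ValueError):
        ConductivityModel(sigma_blood=0.5, sigma_thrombus=0.6)
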