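"""Optical CFR simulator: PSF structure, background scaling, CFR trends."""

from dataclasses import replace

import numpy as np
import pytest

import minfluxpaint as mp
from minfluxpaint.cfr import (TCP, _debye_integrals, background_intensity,
                              detection_psf, effective_psf, simulate_cfr)

#: coarser, smaller model for the tests that rebuild PSFs themselves
FAST = mp.OpticalConfig(grid_spacing=25.0, grid_halfspan=1000.0, n_theta=128)


class TestExcitationDonut:
    def test_central_null(self, optics):
        _, h_exc, _ = optics
        assert h_exc.at_origin() <= 1e-3 * h_exc.data.max()

    def test_null_along_the_whole_axis(self, optics):
        _, h_exc, _ = optics
        ci = h_exc.center_index
        axis_line = h_exc.data[ci[0], ci[1], :]
        assert axis_line.max() <= 1e-3 * h_exc.data.max()

    def test_rotational_symmetry_in_focal_plane(self, optics):
        _, h_exc, _ = optics
        iz = h_exc.center_index[2]
        plane = h_exc.data[:, :, iz]
        assert np.allclose(plane, plane.T, rtol=0.01, atol=1e-6)
        assert np.allclose(plane, plane[::-1, :], rtol=0.01, atol=1e-6)

    def test_ring_radius_matches_scalar_vortex_oracle(self, optics):
        cfg, h_exc, _ = optics
        prof = h_exc.radial
        iz = np.argmin(np.abs(prof.z))
        r_vec = prof.r[np.argmax(prof.intensity[:, iz])]
        # independent scalar vortex model: |integral J1 * sin * sqrt(cos)|^2
        (comp,) = _debye_integrals(prof.r, np.array([0.0]), cfg.lambda_exc,
                                   cfg, [(1, lambda ct: np.ones_like(ct))])
        r_scal = prof.r[np.argmax(np.abs(comp[:, 0]) ** 2)]
        assert r_vec == pytest.approx(r_scal, rel=0.2)

    def test_coarse_grid_warns(self):
        with pytest.warns(UserWarning, match="grid spacing"):
            mp.OpticalConfig(grid_spacing=80.0)


class TestDetectionPSF:
    def test_peak_on_axis(self, optics):
        _, _, h_det = optics
        assert h_det.at_origin() >= h_det.data.max() * (1 - 1e-4)

    def test_smaller_pinhole_tightens_sectioning(self):
        ratios = []
        for au in (0.5, 1.0, 2.0):
            h = detection_psf(replace(FAST, pinhole_au=au))
            ci = h.center_index
            off = h.data[ci[0] + 8, ci[1], ci[2]]  # 200 nm off axis
            ratios.append(off / h.at_origin())
        assert ratios[0] < ratios[1] < ratios[2]

    def test_invalid_pinhole_rejected(self):
        with pytest.raises(ValueError, match="pinhole"):
            mp.OpticalConfig(pinhole_au=0.0)


class TestEffectivePSF:
    def test_zero_shift_is_pointwise_product(self, optics):
        _, h_exc, h_det = optics
        h_eff = effective_psf(h_exc, h_det, (0.0, 0.0))
        np.testing.assert_allclose(h_eff.data, h_exc.data * h_det.data,
                                   rtol=1e-6, atol=1e-12)

    def test_product_bound(self, optics):
        _, h_exc, h_det = optics
        h_eff = effective_psf(h_exc, h_det, (20.0, 0.0))
        assert np.all(h_eff.data <= h_det.data * h_exc.data.max() + 1e-12)

    def test_shifted_donut_null_lands_on_exposure_position(self, optics):
        _, h_exc, h_det = optics
        d = 40.0  # two grid steps
        h_eff = effective_psf(h_exc, h_det, (d, 0.0))
        ci = h_eff.center_index
        step = int(round(d / h_eff.spacing))
        at_shift = h_eff.data[ci[0] + step, ci[1], ci[2]]
        assert at_shift <= 1e-6 * h_eff.data.max()

    def test_shift_outside_grid_rejected(self, optics):
        _, h_exc, h_det = optics
        with pytest.raises(ValueError, match="outside"):
            effective_psf(h_exc, h_det, (1e6, 0.0))


class TestBackground:
    def test_zero_concentration_zero_background(self, optics):
        _, h_exc, h_det = optics
        h_eff = effective_psf(h_exc, h_det, (20.0, 0.0))
        assert background_intensity(h_eff, 0.0) == 0.0

    def test_exactly_linear_in_concentration(self, optics):
        _, h_exc, h_det = optics
        h_eff = effective_psf(h_exc, h_det, (20.0, 0.0))
        b1 = background_intensity(h_eff, 1.0)
        assert background_intensity(h_eff, 2.0) == pytest.approx(2 * b1,
                                                                 rel=1e-12)
        assert background_intensity(h_eff, 0.5) == pytest.approx(b1 / 2,
                                                                 rel=1e-12)

    def test_outer_exposures_symmetric(self, optics):
        cfg, h_exc, h_det = optics
        sc = simulate_cfr(cfg, TCP(L=40.0), 2.0, _psfs=(h_exc, h_det))
        outer = sc.b_exposures[1:]
        assert outer.std() / outer.mean() < 0.01


class TestCFR:
    def test_perfect_zero_no_background_gives_zero(self, optics):
        cfg, h_exc, h_det = optics
        sc = simulate_cfr(cfg, TCP(L=40.0), 0.0, _psfs=(h_exc, h_det))
        assert sc.i_center == 0.0
        assert sc.cfr == 0.0

    def test_monotone_in_concentration(self, optics):
        cfg, h_exc, h_det = optics
        cfrs = [simulate_cfr(cfg, TCP(L=40.0), c,
                             _psfs=(h_exc, h_det)).cfr
                for c in (0.25, 0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(cfrs) > 0)

    def test_monotone_in_pinhole_diameter(self):
        h_exc = mp.excitation_donut(FAST)
        cfrs = []
        for au in (0.5, 1.0, 1.5):
            cfg = replace(FAST, pinhole_au=au)
            cfrs.append(simulate_cfr(cfg, TCP(L=40.0), 2.0,
                                     _psfs=(h_exc,
                                            detection_psf(cfg))).cfr)
        assert cfrs[0] < cfrs[1] < cfrs[2]

    def test_imperfect_zero_raises_cfr(self, optics):
        cfg, h_exc, h_det = optics
        ideal = simulate_cfr(cfg, TCP(L=40.0), 1.0, _psfs=(h_exc, h_det))
        leaky = simulate_cfr(cfg, TCP(L=40.0), 1.0, epsilon_zero=0.01,
                             _psfs=(h_exc, h_det))
        assert leaky.cfr > ideal.cfr
        assert leaky.i_center > 0

    def test_sweep_table_shape_and_trends(self):
        table = mp.sweep_cfr(FAST, concentrations=[0.5, 2.0],
                             pinholes=[0.8], Ls=[40.0, 76.0])
        assert len(table) == 4
        assert set(table.columns) >= {"c_imager", "pinhole_au", "L", "cfr"}
        for L, grp in table.groupby("L"):
            g = grp.sort_values("c_imager")
            assert g["cfr"].is_monotonic_increasing
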