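"""Generator correctness: structures, kinetics, noise and determinism."""

import numpy as np
import pandas as pd
import pytest

import minfluxpaint as mp


class TestStructures:
    def test_grid_exact_lattice(self):
        s = mp.make_structure("grid", nx=3, ny=3, spacing=50.0)
        assert s.n_sites == 9
        expected = {(i * 50.0, j * 50.0) for i in range(3) for j in range(3)}
        assert {tuple(p) for p in s.sites} == expected

    def test_ring_corners_equally_spaced(self):
        s = mp.make_structure("ring_array", n_corners=8, diameter=100.0,
                              array_shape=(1, 1))
        assert s.n_sites == 8
        radii = np.hypot(*s.sites.T)
        np.testing.assert_allclose(radii, 50.0)
        ang = np.sort(np.arctan2(s.sites[:, 1], s.sites[:, 0]))
        np.testing.assert_allclose(np.diff(ang), 2 * np.pi / 8, atol=1e-9)

    def test_same_seed_same_sites(self):
        a = mp.make_structure("random", n_sites=40, seed=5)
        b = mp.make_structure("random", n_sites=40, seed=5)
        np.testing.assert_array_equal(a.sites, b.sites)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            mp.make_structure("helix")


class TestKinetics:
    def test_zero_concentration_zero_events(self):
        struct = mp.make_structure("grid")
        acq = mp.AcquisitionConfig(c_imager=0.0, duration=100.0)
        ds, truth = mp.simulate_acquisition(struct, acq, seed=0)
        assert len(ds) == 0
        assert len(truth.events) == 0

    def test_mean_gap_matches_merged_poisson(self):
        # merged start process over N independent sites: rate k_on * c * N
        struct = mp.make_structure("grid", nx=5, ny=5)
        acq = mp.AcquisitionConfig(c_imager=4.0, k_on=0.01, duration=2000.0,
                                   mean_event_duration=0.05)
        ds, truth = mp.simulate_acquisition(struct, acq, seed=21)
        ev = truth.events.sort_values("t_start")
        gaps = ev["t_start"].to_numpy()[1:] - ev["t_end"].to_numpy()[:-1]
        gaps = np.clip(gaps, 0.0, None)
        expected = mp.expected_t_btw(acq, struct)  # mean waiting time
        se = gaps.std(ddof=1) / np.sqrt(len(gaps))
        assert len(gaps) > 300
        assert abs(gaps.mean() - expected) < 3 * se

    def test_localization_noise_recovers_sigma_true(self):
        struct = mp.make_structure("grid", nx=2, ny=2)
        acq = mp.AcquisitionConfig(sigma_true=3.0, duration=400.0,
                                   c_imager=4.0, mean_event_duration=0.5)
        ds, truth = mp.simulate_acquisition(struct, acq, seed=3)
        big = truth.events[truth.events["n"] >= 30]
        assert len(big) >= 20
        sds = []
        for _, ev in big.iterrows():
            rows = ds.records[(ds.records["tid"] == ev.tid)
                              & ds.records["vld"]]
            sds.append(rows["x"].std(ddof=1))
        assert abs(np.mean(sds) - acq.sigma_true) < 0.15 * acq.sigma_true


class TestExpectedTbtw:
    def test_closed_form_value(self):
        struct = mp.make_structure("random", n_sites=50, seed=0)
        acq = mp.AcquisitionConfig(k_on=0.01, c_imager=2.0)
        assert mp.expected_t_btw(acq, struct) == pytest.approx(1.0)

    def test_doubling_concentration_halves_it(self):
        struct = mp.make_structure("grid")
        a = mp.expected_t_btw(mp.AcquisitionConfig(c_imager=1.0), struct)
        b = mp.expected_t_btw(mp.AcquisitionConfig(c_imager=2.0), struct)
        assert b == pytest.approx(a / 2)

    def test_zero_rate_is_infinite(self):
        struct = mp.make_structure("grid")
        assert np.isinf(mp.expected_t_btw(
            mp.AcquisitionConfig(c_imager=0.0), struct))

    def test_median_is_log2_of_mean(self):
        struct = mp.make_structure("grid")
        acq = mp.AcquisitionConfig()
        assert mp.expected_t_btw(acq, struct, "median") == pytest.approx(
            np.log(2) * mp.expected_t_btw(acq, struct, "mean"))


class TestInvariants:
    def test_same_seed_identical_dataset(self, tmp_path):
        struct = mp.make_structure("grid")
        drift = mp.DriftModel("spline_random_walk",
                              {"knot_spacing": 60, "step_sigma": 3}, seed=1)
        a, _ = mp.simulate_acquisition(struct, drift=drift, seed=9)
        b, _ = mp.simulate_acquisition(struct, drift=drift, seed=9)
        mp.write_records(a, tmp_path / "a.csv")
        mp.write_records(b, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == \
            (tmp_path / "b.csv").read_bytes()

    def test_events_per_site_never_overlap(self, grid_acquisition):
        _, _, _, truth = grid_acquisition
        for _, grp in truth.events.groupby("site"):
            g = grp.sort_values("t_start")
            assert (g["t_start"].to_numpy()[1:]
                    >= g["t_end"].to_numpy()[:-1]).all()

    def test_tids_increase_with_start_time(self, grid_acquisition):
        _, _, _, truth = grid_acquisition
        ev = truth.events.sort_values("t_start")
        assert ev["tid"].is_monotonic_increasing

    def test_records_time_sorted_and_drift_starts_at_zero(self):
        struct = mp.make_structure("grid")
        drift = mp.DriftModel("spline_random_walk",
                              {"knot_spacing": 60, "step_sigma": 5}, seed=4)
        ds, truth = mp.simulate_acquisition(struct, drift=drift, seed=1)
        assert ds.records["tim"].is_monotonic_increasing
        np.testing.assert_allclose(truth.drift_at(np.array([0.0])), 0.0,
                                   atol=1e-9)
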