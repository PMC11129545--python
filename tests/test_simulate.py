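"""Forward simulator: response model, yields, transport and statistics."""

import numpy as np
import pytest

from pyxfet import physics as ph
from pyxfet.geometry import analytic_sensitivity
from pyxfet.phantom import PhantomSpec, Tube, ray_segments
from pyxfet.simulate import (
    DetectorResponseModel,
    apply_response,
    escape_probabilities,
    simulate_charge_sharing,
    simulate_position,
    xrf_yield_per_path,
)


class TestResponseModel:
    def test_fwhm_anchors(self, response):
        assert response.fwhm(35.0) == pytest.approx(0.5)
        assert response.fwhm(60.0) == pytest.approx(0.88)
        assert response.fwhm(122.0) == pytest.approx(1.02)

    def test_fwhm_monotone_between_anchors_and_flat_outside(self, response):
        grid = np.linspace(30.0, 130.0, 200)
        w = response.fwhm(grid)
        assert np.all(np.diff(w) >= -1e-12)
        assert response.fwhm(10.0) == pytest.approx(0.5)
        assert response.fwhm(150.0) == pytest.approx(1.02)

    def test_decreasing_anchors_rejected(self):
        with pytest.raises(ValueError):
            DetectorResponseModel(fwhm_anchors=((35.0, 0.9), (60.0, 0.5)))

    def test_blur_width_matches_fwhm(self, response):
        rng = np.random.default_rng(0)
        out = apply_response(np.full(200_000, 35.0), response, rng)
        assert np.std(out) == pytest.approx(0.5 / 2.3548, rel=0.02)

    def test_nonpositive_energy_rejected(self, response):
        with pytest.raises(ValueError):
            apply_response(0.0, response, np.random.default_rng(0))


class TestChargeSharing:
    def test_zero_probability_is_identity(self):
        ev = {"frame": 3, "module": 1, "row": 10, "col": 12, "energy": 43.0}
        out = simulate_charge_sharing(ev, 0.0, np.random.default_rng(0))
        assert out == [ev]

    def test_certain_sharing_splits_conservatively(self):
        """p=1 always yields two same-frame neighbors conserving energy."""
        rng = np.random.default_rng(1)
        for _ in range(300):
            ev = {"frame": 7, "module": 0,
                  "row": int(rng.integers(0, 80)), "col": int(rng.integers(0, 80)),
                  "energy": 43.0}
            out = simulate_charge_sharing(ev, 1.0, rng)
            assert len(out) == 2
            assert out[0]["frame"] == out[1]["frame"] == 7
            assert out[0]["energy"] + out[1]["energy"] == pytest.approx(43.0)
            d = max(abs(out[0]["row"] - out[1]["row"]), abs(out[0]["col"] - out[1]["col"]))
            assert d == 1
            for e in out:
                assert 0 <= e["row"] < 80 and 0 <= e["col"] < 80

    def test_corner_pixel_neighbors_valid(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            out = simulate_charge_sharing(
                {"frame": 0, "module": 0, "row": 0, "col": 0, "energy": 10.0}, 1.0, rng
            )
            for e in out:
                assert 0 <= e["row"] < 80 and 0 <= e["col"] < 80

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate_charge_sharing({"row": 0, "col": 0, "energy": 1.0}, 1.5,
                                    np.random.default_rng(0))


class TestEscape:
    def test_la_line_escapes_more_than_gd_line(self):
        p_la, _ = escape_probabilities(np.array([ph.line_energy("La")]))
        p_gd, _ = escape_probabilities(np.array([ph.line_energy("Gd")]))
        assert p_la.sum() > p_gd.sum() > 0

    def test_no_escape_below_cd_k_edge(self):
        p, _ = escape_probabilities(np.array([20.0]))
        assert p.sum() == 0.0


class TestYields:
    def test_absent_element_gives_zero_profile(self, study1, spectrum):
        y, lam = xrf_yield_per_path(study1, 0.0, spectrum, "Au")
        assert np.all(lam == 0.0)

    def test_yield_support_inside_metal_tube(self, study1, spectrum):
        y, lam = xrf_yield_per_path(study1, 5.5, spectrum, "Gd")
        inside = np.abs(y) <= 1.5  # 3 mm inner bore at (5.5, 0)
        assert lam[inside].sum() > 0
        assert np.all(lam[~inside] == 0.0)

    def test_dilute_linearity(self, spectrum):
        """Doubling a trace concentration doubles the yield to 1e-6."""
        def phantom_with(c):
            return PhantomSpec(tubes=[Tube((0.0, 5.5), ph.solution({"Gd": c}))])

        _, lam1 = xrf_yield_per_path(phantom_with(1e-4), 0.0, spectrum, "Gd")
        _, lam2 = xrf_yield_per_path(phantom_with(2e-4), 0.0, spectrum, "Gd")
        nz = lam1 > 0
        assert np.allclose(lam2[nz] / lam1[nz], 2.0, rtol=1e-6)

    def test_beam_missing_phantom_gives_empty(self, study1, spectrum):
        y, lam = xrf_yield_per_path(study1, 12.0, spectrum, "Gd")
        assert len(y) == 0


class TestSimulatePosition:
    def test_no_metal_no_xrf_events(self, geometry, spectrum):
        plain = PhantomSpec(tubes=[Tube((0.0, 5.5), ph.WATER)])
        lm = simulate_position(plain, 0.0, geometry, spectrum,
                               dwell=30, flux=2e6, seed=1, compton_scale=0.01)
        assert not np.any(lm.truth >= 2)
        assert np.any(lm.truth == 1)  # Compton background present

    def test_background_off_means_silent_continuum(self, study1, geometry, spectrum):
        lm = simulate_position(study1, 9.0, geometry, spectrum,  # beam misses tubes
                               dwell=60, flux=2e6, seed=1, include_compton=False)
        assert not np.any(lm.truth == 1)

    def test_determinism(self, study1, geometry, spectrum):
        a = simulate_position(study1, 5.5, geometry, spectrum, dwell=20, flux=1e6,
                              seed=13, compton_scale=0.01)
        b = simulate_position(study1, 5.5, geometry, spectrum, dwell=20, flux=1e6,
                              seed=13, compton_scale=0.01)
        for col in ("frame", "module", "row", "col", "energy", "truth"):
            assert np.array_equal(getattr(a, col), getattr(b, col))

    def test_events_within_detector_bounds(self, study1, geometry, spectrum):
        lm = simulate_position(study1, 0.0, geometry, spectrum, dwell=30, flux=2e6,
                               seed=3, compton_scale=0.01)
        assert np.all((lm.row >= 0) & (lm.row < 80))
        assert np.all((lm.col >= 0) & (lm.col < 80))
        assert np.all(lm.energy > 0)
        assert np.all(np.diff(lm.frame) >= 0)

    def test_invalid_flux_or_dwell(self, study1, geometry, spectrum):
        with pytest.raises(ValueError):
            simulate_position(study1, 0.0, geometry, spectrum, dwell=0, flux=1e6)
        with pytest.raises(ValueError):
            simulate_position(study1, 0.0, geometry, spectrum, dwell=10, flux=0)

    def test_detected_counts_match_expectation_oracle(self, geometry, spectrum):
        """Detected XRF counts agree with a closed-form expectation (3 sigma).

        The oracle integrates, independently of the transport code, the
        per-depth emission rates against the analytic per-pinhole solid
        angles, the central-ray exit attenuation and the detector
        photoelectric efficiency.
        """
        phantom = PhantomSpec(tubes=[Tube((0.0, 0.0), ph.solution({"Gd": 3.0}))])
        resp = DetectorResponseModel(charge_sharing_prob=0.0, threshold=1.0,
                                     escape_peaks=False)
        flux, dwell = 4e6, 120.0
        lm = simulate_position(phantom, 0.0, geometry, spectrum, dwell=dwell,
                               flux=flux, seed=21, response=resp,
                               include_compton=False)
        detected = int((lm.truth == 64).sum())

        expected = 0.0
        for line in ("Ka", "Kb"):
            yc, lam = xrf_yield_per_path(phantom, 0.0, spectrum, "Gd", line=line)
            e0 = ph.line_energy("Gd", line)
            eff = float(resp.efficiency(e0))
            for y, l in zip(yc, lam):
                if l == 0:
                    continue
                point = np.array([0.0, y, 0.0])
                w = 0.0
                for pin in geometry.pinholes:
                    to = pin.center - point
                    d = np.linalg.norm(to)
                    cos = to @ pin.axis / d
                    if cos <= 0:
                        continue
                    att = 0.0
                    for mat, a, b in ray_segments(phantom, point, to / d):
                        att += ph.linear_attenuation(mat, e0) * (b - a) / 10.0
                    w += (np.pi * (pin.diameter / 2) ** 2 * cos
                          / (4 * np.pi * d**2) * np.exp(-att))
                expected += flux * dwell * l * w * eff
        assert abs(detected - expected) < 3 * np.sqrt(expected) + 0.02 * expected

    def test_count_linearity_in_concentration(self, geometry, spectrum):
        """Detected K-alpha counts scale linearly with dilute concentration."""
        from scipy import stats

        counts = []
        concs = [1.0, 2.0, 3.0]
        for c in concs:
            phantom = PhantomSpec(tubes=[Tube((0.0, 0.0), ph.solution({"Gd": c}))])
            lm = simulate_position(phantom, 0.0, geometry, spectrum, dwell=600,
                                   flux=3e6, seed=31, include_compton=False)
            assert sum(v for k, v in lm.meta["emitted"].items() if "Gd" in k) > 1e5
            counts.append(int((lm.truth == 64).sum()))
        fit = stats.linregress(concs, counts)
        assert fit.rvalue**2 > 0.99

    def test_emitted_bookkeeping_scales_with_flux(self, study1, geometry, spectrum):
        lo = simulate_position(study1, 5.5, geometry, spectrum, dwell=30, flux=1e6,
                               seed=7, include_compton=False)
        hi = simulate_position(study1, 5.5, geometry, spectrum, dwell=30, flux=4e6,
                               seed=7, include_compton=False)
        r = hi.meta["emitted"]["Gd_Ka"] / lo.meta["emitted"]["Gd_Ka"]
        assert r == pytest.approx(4.0, rel=0.05)
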