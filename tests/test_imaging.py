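"""View splitting, merging, background subtraction, image assembly."""

import numpy as np
import pytest

from pyxfet import physics as ph
from pyxfet.geometry import isotropic_directions, make_scan_plan, trace_to_detector
from pyxfet.imaging import (
    assemble_image,
    collapse_columns,
    merge_views,
    net_xrf,
    split_views,
)
from pyxfet.listmode import ListMode


def _point_source_events(geometry, point, n=400_000, energy=42.77, seed=0,
                         panels=None):
    rng = np.random.default_rng(seed)
    dirs = isotropic_directions(n, rng)
    hit, mod, row, col = trace_to_detector(point, dirs, geometry)
    acc = hit >= 0
    if panels is not None:
        acc &= np.isin(np.array([geometry.pinholes[h].panel if h >= 0 else -1
                                 for h in hit]), panels)
    k = int(acc.sum())
    return ListMode(np.arange(k), mod[acc], np.floor(row[acc]).astype(int),
                    np.floor(col[acc]).astype(int), np.full(k, energy),
                    np.full(k, 64), meta={"x_pos": point[0]})


class TestSplitViews:
    def test_corner_pixel_belongs_to_its_region(self, geometry):
        pin = geometry.pinholes[10]
        r0, r1, c0, c1 = pin.region
        lm = ListMode([0, 1], [pin.module] * 2, [r0, r1 - 1], [c0, c1 - 1],
                      [40.0, 40.0], [0, 0])
        stack = split_views(lm, geometry)
        assert stack.n_dropped == 0
        assert np.all(stack.view_id == pin.id)

    def test_empty_input_gives_96_empty_views(self, geometry):
        stack = split_views(ListMode.empty(), geometry)
        assert stack.n_views == 96
        assert stack.counts_per_view().sum() == 0

    def test_uniform_flood_splits_evenly(self, geometry):
        """A flat flood sends ~1/96 of in-region events to every view."""
        rng = np.random.default_rng(1)
        n = 96_000
        lm = ListMode(np.arange(n), rng.integers(0, 24, n),
                      rng.integers(0, 80, n), rng.integers(0, 80, n),
                      np.full(n, 40.0), np.zeros(n))
        stack = split_views(lm, geometry)
        counts = stack.counts_per_view()
        assert stack.n_dropped == 0  # regions tile the full detector area
        expect = counts.sum() / 96
        z = (counts - expect) / np.sqrt(expect * (1 - 1 / 96))
        assert np.abs(z).mean() < 1.5
        assert np.abs(z).max() < 4.5

    def test_views_disjoint_and_complete(self, geometry, scan_I):
        lm = scan_I[18]
        stack = split_views(lm, geometry)
        assert len(stack.events) + stack.n_dropped == len(lm)


class TestMergeViews:
    def test_point_source_peaks_at_true_depth(self, geometry):
        for y0, want in ((2.3, 12), (-4.6, 5)):
            lm = _point_source_events(geometry, np.array([5.5, y0, 0.0]), n=300_000)
            prof = merge_views(split_views(lm, geometry), geometry)
            rows = collapse_columns(prof).sum(axis=1)
            assert abs(int(np.argmax(rows)) - want) <= 1

    def test_opposite_panels_merge_to_single_peak(self, geometry):
        """Views from opposite panels land on the same row after flips."""
        peaks = []
        for panel in (0, 3):
            lm = _point_source_events(geometry, np.array([2.0, 3.3, 0.0]),
                                      n=600_000, panels=[panel], seed=panel)
            prof = merge_views(split_views(lm, geometry), geometry)
            rows = collapse_columns(prof).sum(axis=1)
            peaks.append(int(np.argmax(rows)))
        assert abs(peaks[0] - peaks[1]) <= 1  # one peak, not two mirrored ones

    def test_count_conservation(self, geometry, scan_I):
        lm = scan_I[10]
        stack = split_views(lm, geometry)
        prof = merge_views(stack, geometry)
        assert prof.total() == len(stack.events)

    def test_permutation_invariance(self, geometry, scan_I):
        lm = scan_I[18]
        stack = split_views(lm, geometry)
        prof1 = merge_views(stack, geometry)
        perm = np.random.default_rng(2).permutation(len(lm))
        stack2 = split_views(lm.select(perm), geometry)
        prof2 = merge_views(stack2, geometry)
        assert np.array_equal(prof1.counts, prof2.counts)


class TestCollapse:
    def test_single_column_identity(self, geometry, scan_I):
        prof = merge_views(split_views(scan_I[18], geometry), geometry)
        single = prof.counts[:, 5:6, :]
        prof.counts = single
        assert np.array_equal(collapse_columns(prof), single[:, 0, :])

    def test_conservation_and_additivity(self, geometry, scan_I):
        prof = merge_views(split_views(scan_I[18], geometry), geometry)
        rows = collapse_columns(prof)
        assert rows.sum() == prof.counts.sum()
        two = prof.counts[:, 3, :] + prof.counts[:, 4, :]
        assert np.array_equal(prof.counts[:, 3:5, :].sum(axis=1), two)


class TestNetXRF:
    edges = np.arange(30.0, 56.0, 0.25)

    def _centers(self):
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def test_null_consistency_on_linear_background(self):
        """Pure linear background: |net| < 3 sigma in >= 95 of 100 trials."""
        rng = np.random.default_rng(3)
        centers = self._centers()
        passes = 0
        for _ in range(100):
            lam = 50.0 + 3.0 * (centers - 40.0)
            counts = rng.poisson(np.clip(lam, 0, None))
            net, sigma = net_xrf(counts, self.edges, 43.0)
            passes += abs(net) < 3 * sigma
        assert passes >= 95

    def test_recovers_injected_gaussian_area(self):
        """Known-area peak on a linear background is recovered within 3 sigma."""
        rng = np.random.default_rng(4)
        centers = self._centers()
        area = 2000.0
        peak = area * 0.25 / np.sqrt(2 * np.pi * 0.3**2) * np.exp(
            -0.5 * ((centers - 43.0) / 0.3) ** 2
        )
        # numeric-integration oracle of the constructed truth inside the window
        in_win = np.abs(centers - 43.0) <= 1.5
        truth = peak[in_win].sum()
        lam = 40.0 + 2.0 * (centers - 40.0) + peak
        counts = rng.poisson(lam)
        net, sigma = net_xrf(counts, self.edges, 43.0)
        assert abs(net - truth) < 3 * sigma

    def test_gd_window_bins(self):
        """The 3 keV window sits symmetrically on the Gd K-alpha line."""
        e0 = ph.line_energy("Gd")
        centers = self._centers()
        counts = np.zeros(len(centers))
        counts[np.abs(centers - e0) <= 1.5] = 10.0
        net, _ = net_xrf(counts, self.edges, e0, window=3.0)
        assert net == pytest.approx(counts.sum(), rel=1e-9)

    def test_empty_sidebands_raise(self):
        edges = np.arange(41.5, 44.6, 0.25)  # window only, no flanks
        with pytest.raises(ValueError):
            net_xrf(np.ones(len(edges) - 1), edges, 43.0)


class TestAssembleImage:
    def test_study_shape_20_by_37(self, images_I):
        assert images_I["Gd"].shape == (20, 37)
        assert images_I["Gd"].sigma.shape == (20, 37)

    def test_all_zero_profiles_give_zero_image(self, geometry):
        plan = make_scan_plan(5, 0.5, 10.0)
        profiles = []
        for x in plan.positions:
            lm = ListMode.empty({"x_pos": float(x)})
            profiles.append(merge_views(split_views(lm, geometry), geometry, x_pos=float(x)))
        img = assemble_image(profiles, plan, "Gd")
        assert np.all(img.counts == 0.0)

    def test_missing_position_reported(self, geometry):
        plan = make_scan_plan(5, 0.5, 10.0)
        lm = ListMode.empty({"x_pos": float(plan.positions[0])})
        profiles = [merge_views(split_views(lm, geometry), geometry,
                                x_pos=float(plan.positions[0]))]
        with pytest.raises(ValueError, match="missing"):
            assemble_image(profiles, plan, "Gd")

    def test_strongest_tube_localized(self, images_I, study1):
        """The 3 mg/mL tube peaks within 1 voxel of its true position."""
        img = images_I["Gd"]
        tube = study1.tubes[0]
        r, c = img.voxel_of(tube.center[0], tube.center[1])
        pr, pc = np.unravel_index(np.argmax(img.counts), img.shape)
        assert max(abs(pr - r), abs(pc - c)) <= 1

    def test_tiff_and_csv_outputs(self, images_I, tmp_path):
        import tifffile

        img = images_I["Gd"]
        img.to_tiff(tmp_path / "gd.tiff")
        img.to_csv(tmp_path / "gd.csv", tmp_path / "gd_sigma.csv")
        assert tifffile.imread(tmp_path / "gd.tiff").shape == (20, 37)


class TestStudyII:
    def test_element_separability(self, images_II, study2):
        """Each element's image peaks at its own highest-concentration tube."""
        from pyxfet.metrics import tube_peak_offset, tube_rois

        hottest = {"Gd": 2, "La": 0}  # tube indices of the 6 mg/mL fills
        for el, img in images_II.items():
            rois = tube_rois(study2, img)
            peak_vals = []
            for roi in rois[:3]:
                rs, cs = roi.slices(img.shape)
                peak_vals.append(img.counts[rs, cs].mean())
            assert int(np.argmax(peak_vals)) == hottest[el]

    def test_per_row_peak_matches_tube_depth(self, geometry, scan_I):
        """Gd K-alpha rows peak where the beam crosses the metal tube."""
        from pyxfet import physics as ph

        lm = scan_I[18]  # x = 0: the 0.6 mg/mL tube sits at y = +5.5
        prof = merge_views(split_views(lm, geometry), geometry)
        rows = collapse_columns(prof)
        centers = prof.energy_centers
        win = np.abs(centers - ph.line_energy("Gd")) <= 1.5
        per_row = rows[:, win].sum(axis=1)
        peak = int(np.argmax(per_row))
        assert abs(peak - 15) <= 1  # y in [5, 6) is row 15
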