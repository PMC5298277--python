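"""Ridge segmentation in the Hilbert spectrum and component features."""

import numpy as np
import pytest

import casbdr as cb
from casbdr.candidate_detection import AnalysisArea
from casbdr.component_segmentation import AcousticComponent
from casbdr.hilbert import HilbertSpectrum

RATE = 3125.0
BIN = 5.0


def _spectrum(n_t=400, n_f=313):
    edges = np.arange(0.0, BIN * n_f + BIN / 2, BIN)[: n_f + 1]
    return HilbertSpectrum(np.zeros((n_t, n_f)), 1.0 / RATE, edges)


def _paint_ridge(spec, t0, t1, f_hz, energy=1.0, thickness=1):
    b = int(f_hz / BIN)
    for k in range(thickness):
        spec.energy[t0:t1, b + k] = energy
    return spec


def _area(t0, t1, f_hz, half=30.0, kind="cas_area"):
    return AnalysisArea(start_index=t0, end_index=t1, center_hz=f_hz,
                        half_width_hz=half, kind=kind)


class TestFindSeeds:
    def test_top_seed_on_ridge(self):
        spec = _paint_ridge(_spectrum(), 50, 300, 400.0, energy=2.0)
        rng = np.random.default_rng(0)
        spec.energy += 0.01 * rng.random(spec.energy.shape)
        seeds = cb.find_seeds(spec, [_area(40, 310, 400.0)])
        t, f, e, kind = seeds[0]
        assert abs(spec.bin_centers_hz[f] - 400.0) <= BIN
        assert kind == "cas_area"

    def test_all_zero_spectrum_no_seeds(self):
        assert cb.find_seeds(_spectrum(), [_area(0, 400, 400.0)]) == []

    def test_two_disjoint_ridges_two_seeds(self):
        spec = _spectrum()
        _paint_ridge(spec, 50, 150, 380.0, energy=2.0)
        _paint_ridge(spec, 200, 300, 420.0, energy=2.0)
        seeds = cb.find_seeds(spec, [_area(0, 400, 400.0, half=60.0)])
        times = {t for t, _, _, _ in seeds}
        assert any(50 <= t < 150 for t in times)
        assert any(200 <= t < 300 for t in times)


class TestGrowRegion:
    def test_clean_ridge_fully_covered(self):
        spec = _paint_ridge(_spectrum(), 50, 350, 400.0, energy=1.0)
        pts = cb.grow_region(spec, (200, int(400 / BIN)))
        t_span = pts[:, 0].max() - pts[:, 0].min() + 1
        assert t_span >= 0.9 * 300

    def test_isolated_pixel_single_point_region(self):
        spec = _spectrum()
        spec.energy[100, 80] = 5.0
        pts = cb.grow_region(spec, (100, 80))
        assert len(pts) == 1 and tuple(pts[0]) == (100, 80)

    def test_two_ridges_100hz_apart_stay_disjoint(self):
        spec = _spectrum()
        _paint_ridge(spec, 50, 350, 400.0)
        _paint_ridge(spec, 50, 350, 500.0)
        claimed = np.zeros(spec.energy.shape, dtype=bool)
        a = cb.grow_region(spec, (200, int(400 / BIN)), claimed)
        b = cb.grow_region(spec, (200, int(500 / BIN)), claimed)
        fa = set(map(tuple, a))
        fb = set(map(tuple, b))
        assert not fa & fb
        assert {p[1] for p in fa} == {int(400 / BIN)}
        assert {p[1] for p in fb} == {int(500 / BIN)}

    def test_first_claim_wins(self):
        spec = _paint_ridge(_spectrum(), 50, 350, 400.0)
        claimed = np.zeros(spec.energy.shape, dtype=bool)
        first = cb.grow_region(spec, (200, int(400 / BIN)), claimed)
        second = cb.grow_region(spec, (200, int(400 / BIN)), claimed)
        assert len(first) > 0 and len(second) == 0

    def test_thickness_bounded(self):
        spec = _paint_ridge(_spectrum(), 50, 350, 400.0, thickness=8)
        pts = cb.grow_region(spec, (200, int(400 / BIN)), max_thickness_bins=4)
        _, counts = np.unique(pts[:, 0], return_counts=True)
        assert counts.max() <= 4

    def test_seed_outside_spectrum_rejected(self):
        with pytest.raises(ValueError):
            cb.grow_region(_spectrum(), (10_000, 0))


class TestLinkRegions:
    def _component(self, spec, t0, t1, f_hz, kind="cas_area"):
        b = int(f_hz / BIN)
        pts = np.array([(t, b) for t in range(t0, t1)])
        return AcousticComponent(points=pts,
                                 energies=np.ones(len(pts)), area_kind=kind)

    def test_collinear_fragments_30ms_10hz_merge_in_cas_area(self):
        spec = _spectrum()
        gap = int(0.03 * RATE)
        a = self._component(spec, 50, 150, 400.0)
        b = self._component(spec, 150 + gap, 250, 410.0)
        spec.energy[:] = 1.0  # energies come from the components
        merged = cb.link_regions([a, b], spec)
        assert len(merged) == 1
        assert len(merged[0].points) == len(a.points) + len(b.points)

    def test_fragments_300ms_apart_not_merged(self):
        spec = _spectrum(n_t=2000)
        gap = int(0.3 * RATE)
        a = self._component(spec, 50, 150, 400.0)
        b = self._component(spec, 150 + gap, 250 + gap, 400.0)
        assert len(cb.link_regions([a, b], spec)) == 2

    def test_normal_area_tolerances_are_tighter(self):
        spec = _spectrum()
        gap = int(0.03 * RATE)  # 30 ms: allowed for cas, not for normal
        a = self._component(spec, 50, 150, 400.0, kind="normal_area")
        b = self._component(spec, 150 + gap, 250, 400.0, kind="normal_area")
        assert len(cb.link_regions([a, b], spec)) == 2

    def test_large_frequency_jump_blocks_merge(self):
        spec = _spectrum()
        a = self._component(spec, 50, 150, 400.0)
        b = self._component(spec, 160, 250, 480.0)
        assert len(cb.link_regions([a, b], spec)) == 2


class TestFilterComponents:
    @pytest.mark.parametrize("duration_s,kept", [
        (0.09, False),
        (0.100, False),  # strict: exactly 100 ms is rejected
        (0.25, True),
    ])
    def test_strict_100ms_rule(self, duration_s, kept):
        spec = _spectrum(n_t=2000)
        n = int(round(duration_s * RATE))
        pts = np.array([(t, 80) for t in range(100, 101 + n)])
        comp = AcousticComponent(points=pts, energies=np.ones(len(pts)))
        # duration spans t_max - t_min = n samples = duration_s exactly
        out = cb.filter_components([comp], spec)
        assert (len(out) == 1) == kept


def brute_force_features(points, energies, centers, total_power, square=True):
    """Independent summation oracle for intensity / F_Mean / sigma_F."""
    f = centers[[p[1] for p in points]]
    w = np.asarray(energies, dtype=float)
    ridge_power = sum(wi**2 if square else wi for wi in w)
    outside = total_power - ridge_power
    i_db = 10 * np.log10(ridge_power / outside)
    f_mean = sum(fi * wi for fi, wi in zip(f, w)) / sum(w)
    sigma = np.sqrt(sum((fi - f_mean) ** 2 * wi for fi, wi in zip(f, w)) / sum(w))
    by_col = {}
    for (t, _b), fi, wi in zip(points, f, w):
        by_col.setdefault(t, []).append((fi, wi))
    sds = []
    for col in by_col.values():
        cw = sum(wi for _, wi in col)
        mu = sum(fi * wi for fi, wi in col) / cw
        sds.append(np.sqrt(sum((fi - mu) ** 2 * wi for fi, wi in col) / cw))
    return i_db, f_mean, sigma, float(np.mean(sds))


class TestComputeFeatures:
    def test_hand_example_f_mean_and_sigma(self):
        # two points: (300 Hz, H=1) and (500 Hz, H=3)
        spec = _spectrum()
        spec.energy[10, 60] = 1.0   # bin center 302.5 -> use explicit centers
        spec.energy[10, 100] = 3.0
        pts = np.array([(10, 60), (10, 100)])
        comp = AcousticComponent(points=pts, energies=np.array([1.0, 3.0]))
        cb.compute_features(comp, spec)
        c1, c2 = spec.bin_centers_hz[60], spec.bin_centers_hz[100]
        expected_mean = (c1 * 1 + c2 * 3) / 4
        expected_sigma = np.sqrt(((c1 - expected_mean) ** 2 * 1
                                  + (c2 - expected_mean) ** 2 * 3) / 4)
        assert comp.F_mean_hz == pytest.approx(expected_mean, rel=1e-12)
        assert comp.sigma_F_hz == pytest.approx(expected_sigma, rel=1e-12)
        # the 1:3 weighting puts the mean 3/4 of the way up, sigma = sqrt(3)/4 gap
        gap = c2 - c1
        assert comp.F_mean_hz == pytest.approx(c1 + 0.75 * gap)
        assert comp.sigma_F_hz == pytest.approx(gap * np.sqrt(3) / 4)

    @pytest.mark.parametrize("ratio,expected_db", [(1.0, 0.0), (10.0, 10.0)])
    def test_intensity_closed_form(self, ratio, expected_db):
        spec = _spectrum()
        spec.energy[10, 50] = 2.0            # ridge point, H^2 = 4
        spec.energy[20, 70] = np.sqrt(4.0 / ratio)  # outside point
        comp = AcousticComponent(points=np.array([(10, 50)]),
                                 energies=np.array([2.0]))
        cb.compute_features(comp, spec)
        assert comp.I_db == pytest.approx(expected_db, abs=1e-9)

    def test_single_bin_ridge_zero_sigmas(self):
        spec = _spectrum()
        spec.energy[10:40, 50] = 1.0
        spec.energy[100, 200] = 1.0  # something outside
        pts = np.array([(t, 50) for t in range(10, 40)])
        comp = AcousticComponent(points=pts, energies=np.ones(30))
        cb.compute_features(comp, spec)
        assert comp.sigma_F_hz == 0.0
        assert comp.sigma_F_bar_hz == 0.0
        assert comp.D_s == pytest.approx(29 / RATE)

    def test_zero_outside_energy_flagged(self):
        spec = _spectrum()
        spec.energy[10, 50] = 1.0
        comp = AcousticComponent(points=np.array([(10, 50)]),
                                 energies=np.array([1.0]))
        cb.compute_features(comp, spec)
        assert comp.intensity_flagged

    @pytest.mark.parametrize("square", [True, False])
    def test_brute_force_oracle_random_point_sets(self, square):
        rng = np.random.default_rng(42)
        for _ in range(200):
            spec = _spectrum(n_t=50, n_f=40)
            spec.energy[:] = rng.random((50, 40)) * rng.integers(0, 2, (50, 40))
            occupied = np.argwhere(spec.energy > 0)
            k = rng.integers(1, min(20, len(occupied)))
            idx = rng.choice(len(occupied), size=k, replace=False)
            pts = occupied[idx]
            en = spec.energy[pts[:, 0], pts[:, 1]]
            comp = AcousticComponent(points=pts, energies=en)
            cb.compute_features(comp, spec, intensity_square_h=square)
            total = float(np.sum(spec.energy**2 if square else spec.energy))
            i_db, f_mean, sigma, sigma_bar = brute_force_features(
                [tuple(p) for p in pts], en, spec.bin_centers_hz, total, square)
            assert comp.I_db == pytest.approx(i_db, rel=1e-9)
            assert comp.F_mean_hz == pytest.approx(f_mean, rel=1e-9)
            assert comp.sigma_F_hz == pytest.approx(sigma, rel=1e-9, abs=1e-9)
            assert comp.sigma_F_bar_hz == pytest.approx(sigma_bar, rel=1e-9,
                                                        abs=1e-9)


class TestEndToEndTone:
    def test_injected_tone_recovered(self, tone_modes, tone_phase, rate):
        modes, _ = tone_modes
        _, _, spec_in = tone_phase
        segs = cb.detect_segments(modes, rate)
        cb.label_segments(segs)
        areas = cb.build_areas(segs)
        spectrum = cb.build_spectrum(modes, rate)
        regions = cb.segment_components(spectrum, areas)
        kept = cb.filter_components(cb.link_regions(regions, spectrum), spectrum)
        feats = [cb.compute_features(c, spectrum) for c in kept]
        match = [c for c in feats if abs(c.F_mean_hz - spec_in.pitch_hz) <= 10]
        assert match
        best = max(match, key=lambda c: c.D_s)
        assert abs(best.D_s - spec_in.duration_s) <= 0.2 * spec_in.duration_s
        assert best.area_kind == "cas_area"
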