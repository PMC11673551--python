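import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycotrace import peaks as pk
from glycotrace.errors import GlycotraceError
from glycotrace.types import Spectrum

from conftest import gaussians, make_spectrum


# ---------------------------------------------------------------------------
# Independent brute-force oracle: local maxima (leftmost plateau sample,
# strictly higher than the values flanking the plateau) and topological
# prominence by direct saddle search.
# ---------------------------------------------------------------------------

def brute_force_apexes(y, rel_threshold=0.01):
    y = np.asarray(y, dtype=float)
    top = max(y.max(), 0.0)
    if top <= 0:
        return []
    thr = rel_threshold * top
    out = []
    n = y.size
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        if j == n - 1:
            break
        if y[i - 1] < y[i] > y[j + 1]:
            h = y[i]
            prom = brute_force_prominence(y, i)
            if h >= thr and prom >= thr:
                out.append(i)
        i = j + 1
    return out


def brute_force_prominence(y, apex):
    h = y[apex]
    left_min = h
    m = h
    for k in range(apex - 1, -1, -1):
        m = min(m, y[k])
        if y[k] > h:
            break
    else:
        m = min(m, y[0]) if apex > 0 else h
    left_min = m
    m = h
    for k in range(apex + 1, len(y)):
        m = min(m, y[k])
        if y[k] > h:
            break
    right_min = m
    return h - max(left_min, right_min)


def _spec(y, step=0.05):
    x = 150.0 + step * np.arange(len(y))
    return Spectrum(x, y, stage="baseline-corrected")


class TestDetectApexes:
    def test_flat(self):
        assert pk.detect_apexes(_spec(np.zeros(100))) == []
        assert pk.detect_apexes(_spec(np.full(100, 5.0))) == []

    def test_one_percent_gate(self, spectrum_factory):
        below = spectrum_factory([(200.0, 100.0, 2.0), (300.0, 0.9, 2.0)])
        assert len(pk.detect_apexes(below)) == 1
        above = spectrum_factory([(200.0, 100.0, 2.0), (300.0, 1.1, 2.0)])
        assert len(pk.detect_apexes(above)) == 2

    def test_ten_separated_peaks(self, spectrum_factory):
        centers = np.linspace(160, 340, 10)
        spec = spectrum_factory([(c, 100.0 if i else 1000.0, 1.5)
                                 for i, c in enumerate(centers)])
        idx = pk.detect_apexes(spec)
        assert len(idx) == 10
        for i, c in zip(idx, centers):
            assert abs(spec.positions[i] - c) <= 0.5

    def test_requires_corrected_stage(self, spectrum_factory):
        spec = spectrum_factory([(200.0, 10.0, 2.0)], stage="normalized")
        with pytest.raises(GlycotraceError):
            pk.detect_apexes(spec)

    def test_plateau_leftmost(self):
        y = np.zeros(50)
        y[20:23] = 5.0
        assert pk.detect_apexes(_spec(y)) == [20]

    def test_against_brute_force_random(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(10, 200)
            y = np.round(rng.uniform(0, 10, n), 1)  # ties are likely
            assert pk.detect_apexes(_spec(y)) == brute_force_apexes(y)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(0, 20), min_size=10, max_size=60))
    def test_against_brute_force_hypothesis(self, vals):
        y = np.array(vals, dtype=float)
        assert pk.detect_apexes(_spec(y)) == brute_force_apexes(y)


class TestFitPeakShape:
    def test_noiseless_sigma_recovered(self, spectrum_factory):
        spec = spectrum_factory([(250.0, 800.0, 2.0)])
        apex = pk.detect_apexes(spec)[0]
        center, sigma, amp, fallback = pk.fit_peak_shape(spec, apex)
        assert not fallback
        assert abs(sigma - 2.0) < 0.02
        assert abs(center - 250.0) < 0.02
        assert abs(amp - 800.0) / 800.0 < 0.01

    def test_noisy_sigma_within_5pct(self):
        errs = []
        x = 150.0 + 0.05 * np.arange(4001)
        clean = gaussians(x, [(250.0, 100.0, 2.0)])
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = clean + rng.normal(0, 1.0, x.size)  # 1% of height
            spec = Spectrum(x, y, stage="baseline-corrected")
            apex = int(np.argmin(np.abs(x - 250.0)))
            _, sigma, _, _ = pk.fit_peak_shape(spec, apex)
            errs.append(abs(sigma - 2.0) / 2.0)
        assert np.median(errs) < 0.05
        assert np.max(errs) < 0.05

    def test_flat_top_fallback(self):
        y = np.minimum(gaussians(150.0 + 0.05 * np.arange(2001),
                                 [(175.0, 1000.0, 2.0)]), 500.0)
        spec = _spec(y)
        apex = pk.detect_apexes(spec)[0]
        _, _, _, fallback = pk.fit_peak_shape(spec, apex)
        assert fallback


class TestIntegratePeak:
    def test_quadratic_exact(self):
        x = 150.0 + 0.05 * np.arange(4001)
        y = 3.0 * x ** 2 - 2.0 * x + 1.0
        spec = Spectrum(x, y, stage="baseline-corrected")
        a, b = 160.0, 240.0
        area, method = pk.integrate_peak(spec, a, b)
        exact = (b ** 3 - a ** 3) - (b ** 2 - a ** 2) + (b - a)
        assert method == "simpson"
        assert abs(area - exact) / exact < 1e-12

    def test_gaussian_three_sigma(self, spectrum_factory):
        from scipy.special import erf
        h, s = 700.0, 2.0
        spec = spectrum_factory([(250.0, h, s)])
        area, _ = pk.integrate_peak(spec, 250 - 3 * s, 250 + 3 * s)
        analytic = h * s * np.sqrt(2 * np.pi) * erf(3 / np.sqrt(2))
        assert abs(area - analytic) / analytic < 0.005

    def test_zero_signal(self):
        area, _ = pk.integrate_peak(_spec(np.zeros(100)), 151.0, 152.0)
        assert area == 0.0

    def test_even_sample_count_patched(self):
        x = 150.0 + 0.05 * np.arange(100)
        spec = Spectrum(x, np.ones(100), stage="baseline-corrected")
        area, method = pk.integrate_peak(spec, x[0], x[-1])
        assert method == "simpson+trapezoid"
        assert abs(area - (x[-1] - x[0])) < 1e-9

    def test_few_samples_trapezoid(self):
        spec = _spec(np.ones(100))
        area, method = pk.integrate_peak(spec, 150.0, 150.05)
        assert method == "trapezoid"
        assert abs(area - 0.05) < 1e-12

    def test_bad_bounds(self):
        with pytest.raises(GlycotraceError):
            pk.integrate_peak(_spec(np.ones(100)), 152.0, 151.0)


class TestBuildPeakTable:
    def test_thirty_peak_scene(self, spectrum_factory):
        rng = np.random.default_rng(5)
        centers = 156.0 + np.cumsum(np.concatenate([[0], rng.uniform(5, 6.3, 29)]))
        heights = rng.uniform(30, 1000, 30)
        spec = spectrum_factory([(c, h, 0.7) for c, h in zip(centers, heights)])
        table = pk.build_peak_table(spec)
        assert len(table) == 30
        assert abs(sum(p.area_ta for p in table.peaks) - 1.0) < 1e-9
        assert max(p.height_mh for p in table.peaks) == 1.0

    def test_overlap_flags(self, spectrum_factory):
        # 7 nt apart with sigma=2: apexes resolve, +/-3 sigma windows intersect
        spec = spectrum_factory([(200.0, 100.0, 2.0), (207.0, 100.0, 2.0)])
        table = pk.build_peak_table(spec)
        assert len(table) == 2
        assert all(p.overlap_flag for p in table.peaks)

    def test_single_peak_normalization(self, spectrum_factory):
        spec = spectrum_factory([(250.0, 123.0, 2.0)])
        table = pk.build_peak_table(spec)
        assert len(table) == 1
        assert table.peaks[0].height_mh == 1.0
        assert table.peaks[0].area_ta == 1.0

    def test_scale_equivariance(self, spectrum_factory):
        spec = spectrum_factory([(200.0, 50.0, 1.5), (280.0, 400.0, 2.0)])
        t1 = pk.build_peak_table(spec)
        scaled = spec.with_intensities(7.0 * spec.intensities,
                                       stage="baseline-corrected")
        t2 = pk.build_peak_table(scaled)
        for p1, p2 in zip(t1.peaks, t2.peaks):
            assert p1.apex_nt == p2.apex_nt
            assert abs(p1.sigma_nt - p2.sigma_nt) < 1e-6
            assert abs(p1.height_mh - p2.height_mh) < 1e-12
            assert abs(p1.area_ta - p2.area_ta) < 1e-9
            assert abs(p2.height - 7.0 * p1.height) < 1e-9
            assert abs(p2.area - 7.0 * p1.area) / p2.area < 1e-6

    def test_boundary_clipping_flag(self, spectrum_factory):
        spec = spectrum_factory([(151.0, 500.0, 2.0)])
        table = pk.build_peak_table(spec)
        assert table.peaks[0].left_nt == 150.0
        assert "clipped_left" in table.peaks[0].flags

    def test_isolated_recovery_invariant(self, spectrum_factory):
        # separation >= 8 sigma, noise <= 1%: perfect recall/precision,
        # areas within 3% of planted truth
        rng = np.random.default_rng(11)
        planted = [(c, float(h), 1.0) for c, h in
                   zip(np.arange(160.0, 340.0, 10.0),
                       rng.uniform(100, 1000, 18))]
        from glycotrace.preprocess import gaussian_smooth
        spec = spectrum_factory(planted, stage="normalized")
        noisy = spec.with_intensities(
            spec.intensities + rng.normal(0, 0.005 * spec.intensities.max(),
                                          len(spec)),
            stage="normalized")
        smoothed = gaussian_smooth(noisy)
        table = pk.build_peak_table(
            smoothed.with_intensities(smoothed.intensities,
                                      stage="baseline-corrected"))
        assert len(table) == len(planted)
        for p, (c, h, s) in zip(table.peaks, planted):
            assert abs(p.apex_nt - c) <= 0.5
            truth = 0.99730 * h * s * np.sqrt(2 * np.pi)
            assert abs(p.area - truth) / truth < 0.03

    def test_tsv_json_roundtrip(self, tmp_path, spectrum_factory):
        spec = spectrum_factory([(200.0, 50.0, 1.5), (280.0, 400.0, 2.0)])
        table = pk.build_peak_table(spec)
        table.to_tsv(tmp_path / "t.tsv")
        table.to_json(tmp_path / "t.json")
        back = pk.PeakTable.from_json(tmp_path / "t.json")
        assert len(back) == len(table)
        assert back.peaks[0].apex_nt == table.peaks[0].apex_nt
        header = (tmp_path / "t.tsv").read_text().splitlines()[0].split("\t")
        assert header[:10] == pk.TSV_COLUMNS
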