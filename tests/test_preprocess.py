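"""Spectrum preprocessing chain: smoothing, SNIP baseline, TIC, peak
detection, binning, presence filtering, replicate averaging."""

import numpy as np
import pandas as pd
import pytest

from maldiag.containers import FeatureMatrix, RawSpectrum
from maldiag import preprocess as pp


def make_spectrum(intensity, lo=66.0, hi=350.0, **kw):
    n = len(intensity)
    return RawSpectrum(mz=np.linspace(lo, hi, n), intensity=np.asarray(intensity, float), **kw)


def gaussians(grid, centers, widths, amps):
    y = np.zeros_like(grid)
    for c, w, a in zip(centers, widths, amps):
        y += a * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return y


class TestSmooth:
    def test_constant_spectrum_unchanged(self):
        s = make_spectrum(np.full(512, 7.0))
        out = pp.smooth(s, halfwindow=10)
        assert np.allclose(out.intensity, 7.0)

    def test_cubic_trend_reproduced(self):
        grid = np.linspace(66, 350, 512)
        y = 1.0 + 0.5 * grid - 0.01 * grid**2 + 1e-4 * grid**3
        s = RawSpectrum(mz=grid, intensity=y - y.min() + 1)
        out = pp.smooth(s, halfwindow=10)
        core = slice(15, -15)
        assert np.allclose(out.intensity[core], s.intensity[core], atol=1e-8)

    def test_noise_variance_reduced(self, rng):
        s = make_spectrum(100 + rng.normal(0, 1.0, 4096))
        out = pp.smooth(s, halfwindow=10)
        assert np.var(out.intensity) < np.var(s.intensity)

    def test_halfwindow_validation(self):
        s = make_spectrum(np.ones(32))
        with pytest.raises(ValueError):
            pp.smooth(s, halfwindow=0)
        with pytest.raises(ValueError):
            pp.smooth(s, halfwindow=16)


class TestSnipBaseline:
    def test_flat_spectrum_baseline_equals_value(self):
        s = make_spectrum(np.full(256, 3.5))
        base = pp.snip_baseline(s, iterations=20)
        assert np.allclose(base, 3.5)

    def test_offset_recovered_away_from_peak(self):
        grid = np.linspace(66, 350, 4096)
        c, w = 200.0, 0.5
        y = 10.0 + gaussians(grid, [c], [w], [100.0])
        s = RawSpectrum(mz=grid, intensity=y)
        base = pp.snip_baseline(s, iterations=60)
        far = np.abs(grid - c) > 3 * w
        assert np.all(np.abs(base[far] - 10.0) <= 0.5)

    def test_monotone_in_iterations_and_below_signal(self):
        grid = np.linspace(66, 350, 1024)
        y = 5.0 + gaussians(grid, [120, 250], [0.8, 1.2], [50, 80])
        s = RawSpectrum(mz=grid, intensity=y)
        b1 = pp.snip_baseline(s, iterations=1)
        b100 = pp.snip_baseline(s, iterations=100)
        assert np.all(b100 <= b1 + 1e-12)
        assert np.all(b1 <= y + 1e-12)

    def test_subtract_clips_at_zero(self, rng):
        s = make_spectrum(np.abs(rng.normal(5, 2, 512)))
        out = pp.subtract_baseline(s, iterations=30)
        assert (out.intensity >= 0).all()


class TestNormalizeTic:
    def test_simple_scaling(self):
        s = make_spectrum([1.0, 2.0, 3.0])
        out = pp.normalize_tic(s, target_sum=1.0)
        assert np.allclose(out.intensity, [1 / 6, 2 / 6, 3 / 6])

    def test_idempotent(self):
        s = make_spectrum([0.25, 0.25, 0.5])
        out = pp.normalize_tic(s, target_sum=1.0)
        assert np.allclose(out.intensity, s.intensity)

    def test_sum_contract_and_rank_preserved(self, rng):
        s = make_spectrum(rng.uniform(0, 50, 256))
        out = pp.normalize_tic(s, target_sum=1e5)
        assert abs(out.intensity.sum() - 1e5) / 1e5 < 1e-10
        assert np.array_equal(np.argsort(out.intensity), np.argsort(s.intensity))

    def test_empty_spectrum_error(self):
        s = make_spectrum(np.zeros(16))
        with pytest.raises(ValueError, match="empty spectrum"):
            pp.normalize_tic(s, 1.0)


class TestDetectPeaks:
    def test_planted_peaks_recovered_exactly(self, rng):
        grid = np.linspace(66, 350, 16384)
        y = 6.0 + gaussians(grid, [100, 200, 300], [0.05, 0.05, 0.05],
                            [50, 50, 50]) + rng.normal(0, 1.0, grid.size)
        s = RawSpectrum(mz=grid, intensity=np.clip(y, 0, None))
        peaks = pp.detect_peaks(pp.subtract_baseline(pp.smooth(s, 3)), snr_min=5)
        assert len(peaks) == 3
        step = grid[1] - grid[0]
        for c in (100, 200, 300):
            assert np.min(np.abs(peaks.mz - c)) <= step

    def test_subthreshold_peak_not_detected(self, rng):
        grid = np.linspace(66, 350, 8192)
        y = 6.0 + gaussians(grid, [200.0], [0.05], [2.0]) + rng.normal(0, 1.0, grid.size)
        s = RawSpectrum(mz=grid, intensity=np.clip(y, 0, None))
        peaks = pp.detect_peaks(pp.subtract_baseline(pp.smooth(s, 3)), snr_min=5)
        assert not np.any(np.abs(peaks.mz - 200.0) < 0.2)

    def test_false_positive_rate_below_one_per_spectrum(self):
        total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            s = make_spectrum(np.clip(6.0 + rng.normal(0, 1.0, 8192), 0, None))
            total += len(pp.detect_peaks(pp.subtract_baseline(pp.smooth(s, 3)),
                                         snr_min=5))
        assert total / 100 < 1.0

    def test_snr_validation(self):
        s = make_spectrum(np.ones(64))
        with pytest.raises(ValueError):
            pp.detect_peaks(s, snr_min=0)

    def test_peaks_sorted_by_mz(self, rng):
        grid = np.linspace(66, 350, 8192)
        y = gaussians(grid, [120, 180, 260], [0.05] * 3, [60] * 3)
        s = RawSpectrum(mz=grid, intensity=y + np.abs(rng.normal(0, 1, grid.size)))
        peaks = pp.detect_peaks(pp.smooth(s, 3))
        assert np.all(np.diff(peaks.mz) > 0)


def _peaklist(mz, intensity, sample_id="S", replicate_idx=1):
    mz = np.asarray(mz, float)
    return pp.PeakList(mz=mz, intensity=np.asarray(intensity, float),
                       snr=np.full(mz.size, 10.0), sample_id=sample_id,
                       replicate_idx=replicate_idx)


class TestAlignAndBin:
    def test_within_tolerance_merged(self):
        a = _peaklist([150.000], [10], "A")
        b = _peaklist([150.030], [30], "B")
        fm = pp.align_and_bin([a, b], tolerance_ppm=500)
        assert fm.n_features == 1
        # feature m/z is the intensity-weighted member mean
        assert fm.feature_mz[0] == pytest.approx(
            (150.0 * 10 + 150.030 * 30) / 40)

    def test_beyond_tolerance_split(self):
        a = _peaklist([150.0], [10], "A")
        b = _peaklist([151.0], [10], "B")
        fm = pp.align_and_bin([a, b], tolerance_ppm=500)
        assert fm.n_features == 2

    def test_bin_centers_separated_and_vs_single_linkage(self, rng):
        # oracle: single-linkage chaining gives the coarsest clustering, so
        # greedy bins can never be fewer; centers must stay separated
        for trial in range(20):
            r = np.random.default_rng(trial)
            mz = np.sort(r.uniform(100, 102, r.integers(5, 20)))
            lists = [
                _peaklist(mz[::2], r.uniform(1, 10, mz[::2].size), "A"),
                _peaklist(mz[1::2], r.uniform(1, 10, mz[1::2].size), "B"),
            ]
            tol_ppm = 500.0
            fm = pp.align_and_bin(lists, tolerance_ppm=tol_ppm)
            centers = fm.feature_mz
            assert np.all(np.diff(centers) > 0)
            gaps = np.diff(centers)
            tol = 0.5 * (centers[:-1] + centers[1:]) * tol_ppm * 1e-6
            assert np.all(gaps > tol)
            # single-linkage cluster count on the pooled peaks
            pooled = np.sort(mz)
            links = np.diff(pooled) <= pooled[:-1] * tol_ppm * 1e-6
            n_single = 1 + int((~links).sum())
            assert fm.n_features >= n_single

    def test_tolerance_validation(self):
        a = _peaklist([150.0], [1], "A")
        with pytest.raises(ValueError):
            pp.align_and_bin([a, a], tolerance_ppm=0)
        with pytest.raises(ValueError):
            pp.align_and_bin([a], tolerance_ppm=500)


class TestPresenceFilter:
    def _fm(self, present_count, n=100):
        values = pd.DataFrame({
            "mz_100.0000": [1.0] * present_count + [np.nan] * (n - present_count),
            "mz_200.0000": [1.0] * n,
        })
        return FeatureMatrix(values=values)

    def test_strictly_over_80_percent_kept(self):
        fm = pp.presence_filter(self._fm(81), min_fraction=0.80)
        assert "mz_100.0000" in fm.values.columns

    def test_exactly_80_percent_dropped(self):
        fm = pp.presence_filter(self._fm(80), min_fraction=0.80)
        assert "mz_100.0000" not in fm.values.columns
        assert "mz_200.0000" in fm.values.columns

    def test_all_present_identity(self):
        fm = self._fm(100)
        out = pp.presence_filter(fm)
        assert list(out.values.columns) == list(fm.values.columns)

    def test_empty_matrix_error(self):
        fm = FeatureMatrix(values=pd.DataFrame())
        with pytest.raises(ValueError):
            pp.presence_filter(fm)


class TestAverageReplicates:
    def _fm(self, rows):
        idx = pd.MultiIndex.from_tuples([r[:2] for r in rows],
                                        names=["sample_id", "replicate_idx"])
        return FeatureMatrix(values=pd.DataFrame(
            {"mz_100.0000": [r[2] for r in rows]}, index=idx))

    def test_triplicate_mean(self):
        fm = self._fm([("S1", 1, 10.0), ("S1", 2, 20.0), ("S1", 3, 30.0)])
        out = pp.average_replicates(fm)
        assert out.values.loc["S1", "mz_100.0000"] == 20.0

    def test_single_replicate_identity(self):
        fm = self._fm([("S1", 1, 42.0)])
        out = pp.average_replicates(fm)
        assert out.values.loc["S1", "mz_100.0000"] == 42.0

    def test_mean_over_present_only(self):
        fm = self._fm([("S1", 1, 10.0), ("S1", 2, np.nan), ("S1", 3, 30.0)])
        out = pp.average_replicates(fm)
        assert out.values.loc["S1", "mz_100.0000"] == 20.0


class TestPipelineEndToEnd:
    def test_deterministic_and_survival_band(self, small_cohort, small_panel):
        from maldiag import synthgen as sg

        effects = sg.default_effects(small_panel, seed=3, n_up=2, n_down=2,
                                     n_weak=1, n_blocks=0)
        meta = small_cohort.iloc[:14]
        spectra = sg.generate_spectra(meta, small_panel, effects, seed=6,
                                      replicates=2)
        pre = pp.SpectrumPreprocessor()
        a = pre.transform(spectra)
        b = pre.transform(spectra)
        pd.testing.assert_frame_equal(a.values, b.values)
        # surviving features within +-15% of the strong-panel size
        assert 0.85 * 40 <= a.n_features <= 1.15 * (40 + 10)

    def test_two_column_text_round_trip(self, tmp_path, rng):
        s = make_spectrum(rng.uniform(0, 10, 64), sample_id="S1")
        path = tmp_path / "s1.txt.gz"
        s.write_txt(path)
        back = RawSpectrum.read_txt(path, sample_id="S1")
        assert np.allclose(back.mz, s.mz, atol=1e-6)
        assert np.allclose(back.intensity, s.intensity, rtol=1e-4)

    @pytest.mark.parametrize("compress", [False, True])
    def test_mzml_reader(self, tmp_path, rng, compress):
        import base64
        import zlib

        mz = np.linspace(100, 110, 50)
        inten = np.abs(np.sin(mz)) * 100

        def enc(a):
            raw = np.asarray(a, dtype=np.float64).tobytes()
            if compress:
                raw = zlib.compress(raw)
            return base64.b64encode(raw).decode()

        comp_cv = ("MS:1000574" if compress else "MS:1000576")
        arrays = ""
        for acc, data in (("MS:1000514", mz), ("MS:1000515", inten)):
            arrays += f"""
          <binaryDataArray>
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="{comp_cv}" name="compression"/>
            <cvParam cvRef="MS" accession="{acc}" name="array"/>
            <binary>{enc(data)}</binary>
          </binaryDataArray>"""
        xml = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r"><spectrumList count="1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{mz.size}">
        <binaryDataArrayList count="2">{arrays}
        </binaryDataArrayList>
      </spectrum>
  </spectrumList></run>
</mzML>"""
        path = tmp_path / "one.mzML"
        path.write_text(xml)
        s = RawSpectrum.read_mzml(path, sample_id="S1")
        assert np.allclose(s.mz, mz)
        assert np.allclose(s.intensity, inten)
        assert s.sample_id == "S1"
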