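"""Spectral templates (ictal/interictal) and the GDF weight function."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seizurespec import (
    GdfTemplate,
    MagnitudeSeries,
    SeizureAnnotation,
    SpectralTemplate,
    WindowSpec,
    average_templates,
    build_gdf,
    interictal_mean_spectrum,
    read_annotation,
    read_gdf,
    seizure_mean_spectrum,
    write_annotation,
    write_gdf,
)
from seizurespec.simulate import SimConfig, simulate_recording
from seizurespec.recording import vector_magnitude, window_start_indices
from seizurespec.templates import _normalize


SPEC = WindowSpec()


def _series(values, fs=100.0):
    return MagnitudeSeries(values=np.asarray(values, dtype=float), sample_rate=fs)


class TestSeizureMeanSpectrum:
    def test_single_window_is_self_normalized_spectrum(self, rng):
        x = rng.uniform(0.5, 1.5, size=100)
        t = seizure_mean_spectrum(_series(x), (0.0, 1.0), SPEC)
        assert t.n_windows == 1
        assert t.values.sum() == pytest.approx(1.0, abs=1e-12)
        from seizurespec import window_spectrum

        raw = window_spectrum(x, SPEC).magnitudes
        np.testing.assert_allclose(t.values, raw / raw.sum(), rtol=1e-12)

    def test_identical_windows_match_single_window(self, rng):
        # averaging is idempotent on equal inputs: two identical
        # non-overlapping windows give the single-window template
        x = rng.uniform(0.5, 1.5, size=100)
        spec0 = WindowSpec(overlap_fraction=0.0)
        single = seizure_mean_spectrum(_series(x), (0.0, 1.0), spec0)
        double = seizure_mean_spectrum(_series(np.tile(x, 2)), (0.0, 2.0), spec0)
        assert double.n_windows == 2
        np.testing.assert_allclose(double.values, single.values, rtol=1e-9)

    def test_mean_and_grand_sum_normalization_arithmetic(self):
        # hand oracle on a 3-bin toy: mean of (2,1,1) and (0,2,2) is
        # (1, 1.5, 1.5); divided by its sum 4 -> (0.25, 0.375, 0.375)
        spectra = np.array([[2.0, 1.0, 1.0], [0.0, 2.0, 2.0]])
        np.testing.assert_allclose(
            _normalize(spectra.mean(axis=0)), [0.25, 0.375, 0.375], rtol=1e-12
        )

    def test_interval_shorter_than_window_errors(self):
        with pytest.raises(ValueError, match="segment too short"):
            seizure_mean_spectrum(_series(np.ones(1000)), (0.0, 0.5), SPEC)

    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 100))
    def test_amplitude_scale_invariance(self, scale, seed):
        x = np.random.default_rng(seed).uniform(0.1, 2.0, size=300)
        a = seizure_mean_spectrum(_series(x), (0.0, 3.0), SPEC)
        b = seizure_mean_spectrum(_series(scale * x), (0.0, 3.0), SPEC)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9, atol=1e-12)


class TestAverageTemplates:
    def test_single_template_unchanged(self):
        t = SpectralTemplate(values=np.array([0.2, 0.3, 0.5]))
        np.testing.assert_array_equal(average_templates([t]).values, t.values)

    def test_two_one_hot_templates(self):
        a = SpectralTemplate(values=np.array([1.0, 0.0, 0.0]))
        b = SpectralTemplate(values=np.array([0.0, 1.0, 0.0]))
        np.testing.assert_allclose(
            average_templates([a, b]).values, [0.5, 0.5, 0.0]
        )

    def test_mixed_sources_rejected(self):
        a = SpectralTemplate(values=np.array([1.0, 0.0]), source="gtcs")
        b = SpectralTemplate(values=np.array([0.0, 1.0]), source="interictal")
        with pytest.raises(ValueError, match="mixed"):
            average_templates([a, b])

    def test_mismatched_grids_rejected(self):
        a = SpectralTemplate(values=np.array([1.0, 0.0]))
        b = SpectralTemplate(values=np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="grid"):
            average_templates([a, b])

    @given(
        data=st.lists(
            st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
            min_size=1,
            max_size=6,
        ).filter(lambda rows: all(sum(r) > 1e-6 for r in rows))
    )
    def test_average_of_unit_sum_templates_sums_to_one(self, data):
        templates = [
            SpectralTemplate(values=np.asarray(row) / sum(row)) for row in data
        ]
        assert average_templates(templates).values.sum() == pytest.approx(1.0, abs=1e-9)


class TestInterictalMeanSpectrum:
    def test_unannotated_recording_contributes_all_windows(self, rng):
        series = _series(rng.uniform(0.5, 1.5, size=1000))
        t = interictal_mean_spectrum([(series, SeizureAnnotation())], SPEC)
        assert t.n_windows == window_start_indices(1000, SPEC).size
        assert t.source == "interictal"
        assert t.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_fully_ictal_recording_errors(self, rng):
        series = _series(rng.uniform(0.5, 1.5, size=500))
        ann = SeizureAnnotation(intervals=[(0.0, 5.0)])
        with pytest.raises(ValueError, match="no interictal windows"):
            interictal_mean_spectrum([(series, ann)], SPEC)

    def test_boundary_straddling_windows_excluded(self, rng):
        # 10 s series, seizure (3.2 s, 6.1 s): windows starting in
        # [2.3, 6.1) s intersect it and must be dropped.
        series = _series(rng.uniform(0.5, 1.5, size=1000))
        ann = SeizureAnnotation(intervals=[(3.2, 6.1)])
        t = interictal_mean_spectrum([(series, ann)], SPEC)
        starts = window_start_indices(1000, SPEC) / 100.0
        expected = np.sum((starts + 1.0 <= 3.2) | (starts >= 6.1))
        assert t.n_windows == expected

    def test_synthetic_interictal_mass_below_4_hz(self):
        rec, ann = simulate_recording(
            SimConfig(duration_h=1 / 6, n_seizures=0, distractor_rate_per_h=0.0, seed=5)
        )
        t = interictal_mean_spectrum([(vector_magnitude(rec), ann)], SPEC)
        assert t.values[:4].sum() > 0.5


class TestBuildGdf:
    def test_identical_templates_give_all_ones(self):
        t = SpectralTemplate(values=np.array([0.5, 0.5, 0.0]))
        gdf = build_gdf(t, SpectralTemplate(values=t.values.copy(), source="interictal"))
        np.testing.assert_array_equal(gdf.weights, np.ones(3))

    def test_ratio_of_bins(self):
        a = SpectralTemplate(values=np.array([0.2, 0.8]))
        b = SpectralTemplate(values=np.array([0.1, 0.9]), source="interictal")
        gdf = build_gdf(a, b)
        assert gdf.weights[0] == pytest.approx(2.0)

    def test_zero_interictal_bin_floored(self):
        a = SpectralTemplate(values=np.array([0.2, 0.8]))
        b = SpectralTemplate(values=np.array([0.0, 1.0]), source="interictal")
        gdf = build_gdf(a, b, eps_floor=1e-12)
        assert gdf.weights[0] == pytest.approx(0.2 / 1e-12)
        assert np.all(np.isfinite(gdf.weights))

    def test_template_against_itself_is_identity_even_with_zero_bins(self, rng):
        v = rng.uniform(size=51)
        v[20:30] = 0.0
        v /= v.sum()
        t1 = SpectralTemplate(values=v)
        t2 = SpectralTemplate(values=v.copy(), source="interictal")
        np.testing.assert_array_equal(build_gdf(t1, t2).weights, np.ones(51))


class TestJsonRoundTrips:
    def test_gdf_round_trip_lossless(self, tmp_path, rng):
        gdf = GdfTemplate(weights=rng.uniform(0.1, 100.0, size=51))
        path = tmp_path / "gdf.json"
        write_gdf(gdf, path)
        back = read_gdf(path)
        np.testing.assert_array_equal(back.weights, gdf.weights)
        assert back.eps_floor == gdf.eps_floor

    def test_wrong_bin_count_rejected(self, tmp_path):
        import json

        path = tmp_path / "gdf.json"
        path.write_text(
            json.dumps({"f_max_hz": 50, "values": [1.0] * 50}), encoding="utf-8"
        )
        with pytest.raises(ValueError, match="bins"):
            read_gdf(path)

    def test_negative_weight_rejected(self, tmp_path):
        path = tmp_path / "gdf.json"
        path.write_text(
            '{"f_max_hz": 1, "values": [1.0, -2.0]}', encoding="utf-8"
        )
        with pytest.raises(ValueError, match="positive"):
            read_gdf(path)

    def test_annotation_round_trip(self, tmp_path):
        ann = SeizureAnnotation(intervals=[(10.0, 99.5), (200.0, 300.0)], recording_id="r1")
        path = tmp_path / "ann.json"
        write_annotation(ann, path)
        back = read_annotation(path)
        assert back.intervals == ann.intervals
        assert back.recording_id == "r1"

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            SeizureAnnotation(intervals=[(0.0, 10.0), (5.0, 15.0)])
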