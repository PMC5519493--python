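import numpy as np
import pandas as pd
import pytest

from interdigitate import (
    PreprocParams,
    discard_initial,
    lowpass_filter,
    preprocess_session,
    regress_nuisance,
    smooth_surface,
)
from interdigitate.preprocess import build_design, nominal_edge_mm, smoothing_schedule
from tests.conftest import make_ts


class TestDiscard:
    def test_identity_at_zero(self):
        ts = make_ts(np.random.default_rng(0).normal(size=(5, 100)))
        assert discard_initial(ts, 0) is ts

    def test_seven_minute_run(self):
        """A 7 m 2 s run at TR 1 s minus the 12 equilibration frames."""
        ts = make_ts(np.zeros((3, 422)))
        out = discard_initial(ts, 12)
        assert out.n_frames == 410
        assert len(out.nuisance) == 410

    def test_nuisance_truncated_identically(self):
        nuis = pd.DataFrame({"g": np.arange(50, dtype=float)})
        ts = make_ts(np.random.default_rng(1).normal(size=(2, 50)), nuisance=nuis)
        out = discard_initial(ts, 10)
        assert list(out.nuisance["g"]) == list(range(10, 50))

    def test_empty_output_guard(self):
        ts = make_ts(np.zeros((2, 30)))
        with pytest.raises(ValueError):
            discard_initial(ts, 30)


class TestLowpass:
    def test_constant_series_unchanged(self):
        ts = make_ts(np.full((3, 200), 7.5))
        out = lowpass_filter(ts, 0.08)
        assert np.allclose(out.data, 7.5, atol=1e-8)

    def test_mean_preserved(self):
        ts = make_ts(np.random.default_rng(2).normal(5.0, 1.0, size=(10, 256)))
        out = lowpass_filter(ts, 0.08)
        assert np.allclose(out.data.mean(axis=1), ts.data.mean(axis=1), rtol=1e-8)

    def test_stop_band_attenuation(self):
        """0.20 Hz sinusoid suppressed below 2% (checked at its FFT bin)."""
        t = np.arange(1000)
        ts = make_ts(np.sin(2 * np.pi * 0.20 * t)[None, :])
        out = lowpass_filter(ts, 0.08)
        amp = lambda x: np.abs(np.fft.rfft(x[0]))[200]
        assert amp(out.data) / amp(ts.data) < 0.02

    def test_pass_band_preserved(self):
        """0.05 Hz sinusoid passes within 2% amplitude."""
        t = np.arange(1000)
        ts = make_ts(np.sin(2 * np.pi * 0.05 * t)[None, :])
        out = lowpass_filter(ts, 0.08)
        amp = lambda x: np.abs(np.fft.rfft(x[0]))[50]
        assert amp(out.data) / amp(ts.data) == pytest.approx(1.0, abs=0.02)

    def test_cutoff_above_nyquist_rejected(self):
        ts = make_ts(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            lowpass_filter(ts, 0.5)


class TestRegress:
    def test_exact_projection_of_regressor(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=100)
        ts = make_ts(np.vstack([2.0 * g + 1.0, -0.5 * g]),
                     nuisance=pd.DataFrame({"g": g}))
        out = regress_nuisance(ts, add_derivatives=False)
        assert np.max(np.abs(out.data)) < 1e-8

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(4)
        nuis = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        ts = make_ts(rng.normal(size=(20, 200)), nuisance=nuis)
        out = regress_nuisance(ts, add_derivatives=True)
        design, _ = build_design(nuis, True)
        for col in design.T[1:]:
            c = np.corrcoef(np.vstack([out.data, col[None, :]]))[-1, :-1]
            assert np.max(np.abs(c)) < 1e-8

    def test_derivative_augmentation_count(self):
        """The published 9-regressor nuisance set doubles to 18 + intercept."""
        nuis = pd.DataFrame(np.random.default_rng(5).normal(size=(100, 9)))
        design, names = build_design(nuis, add_derivatives=True)
        assert design.shape[1] == 19
        assert names[0] == "intercept" and sum(n.startswith("d_") for n in names) == 9

    def test_empty_table_demeans(self):
        ts = make_ts(np.random.default_rng(6).normal(3.0, 1.0, size=(4, 80)))
        out = regress_nuisance(ts, add_derivatives=False)
        assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(out.data, ts.data - ts.data.mean(axis=1, keepdims=True))

    def test_collinear_design_names_columns(self):
        g = np.random.default_rng(7).normal(size=60)
        nuis = pd.DataFrame({"one": g, "two": 2 * g})
        ts = make_ts(np.random.default_rng(8).normal(size=(2, 60)), nuisance=nuis)
        with pytest.raises(ValueError, match="collinear.*(one|two)"):
            regress_nuisance(ts, add_derivatives=False)


class TestSmooth:
    def test_constant_field_unchanged(self, mesh2):
        x = np.full(mesh2.n_vertices, 3.3)
        assert np.allclose(smooth_surface(x, mesh2, 2.0), 3.3)

    def test_impulse_normalized_and_unimodal(self, mesh2):
        x = np.zeros(mesh2.n_vertices)
        x[10] = 1.0
        out = smooth_surface(x, mesh2, 4.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.argmax(out) == 10

    def test_sum_preserved_per_frame(self, mesh2):
        x = np.random.default_rng(9).normal(size=(mesh2.n_vertices, 5))
        out = smooth_surface(x, mesh2, 3.0)
        assert np.allclose(out.sum(axis=0), x.sum(axis=0), rtol=1e-6, atol=1e-6)

    def test_noise_variance_strictly_decreases(self, mesh2):
        x = np.random.default_rng(10).normal(size=mesh2.n_vertices)
        out = smooth_surface(x, mesh2, 2.0)
        assert out.var() < x.var()

    def test_zero_fwhm_identity_and_negative_rejected(self, mesh2):
        x = np.random.default_rng(11).normal(size=mesh2.n_vertices)
        assert np.array_equal(smooth_surface(x, mesh2, 0.0), x)
        with pytest.raises(ValueError):
            smooth_surface(x, mesh2, -1.0)

    def test_hemispheres_never_mixed(self, mesh2):
        x = np.zeros(mesh2.n_vertices)
        x[0] = 1.0  # left-hemisphere vertex
        out = smooth_surface(x, mesh2, 6.0)
        assert np.all(out[mesh2.n_per_hemisphere:] == 0)

    def test_schedule_matches_requested_width(self):
        n, tau = smoothing_schedule(2.0, nominal_edge_mm(6))
        sigma_sq = (2.0 / np.sqrt(8 * np.log(2)) / nominal_edge_mm(6)) ** 2
        assert n * 2 * tau == pytest.approx(sigma_sq)
        assert tau <= 1 / 12


class TestPipeline:
    def test_nuisance_only_signal_removed(self, mesh2):
        """Data built purely from nuisance columns vanishes after the
        filter + regression stages."""
        rng = np.random.default_rng(12)
        nuis = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
        weights = rng.normal(size=(mesh2.n_vertices, 3))
        ts = make_ts(weights @ nuis.to_numpy().T, nuisance=nuis)
        out = preprocess_session(ts, mesh2, PreprocParams(
            n_discard=0, smooth_fwhm_mm=0.0, add_derivatives=False))
        in_rms = np.sqrt(np.mean(ts.data**2))
        assert np.sqrt(np.mean(out.data**2)) < 1e-6 * in_rms

    def test_stage_order_default(self):
        p = PreprocParams()
        assert p.order == ("discard", "filter", "regress", "smooth")

    def test_vertexwise_independence_without_smoothing(self, mesh2):
        rng = np.random.default_rng(13)
        nuis = pd.DataFrame({"g": rng.normal(size=100)})
        base = rng.normal(size=(mesh2.n_vertices, 100))
        pert = base.copy()
        pert[5] += rng.normal(size=100)
        par = PreprocParams(n_discard=4, smooth_fwhm_mm=0.0)
        a = preprocess_session(make_ts(base, nuisance=nuis), mesh2, par)
        b = preprocess_session(make_ts(pert, nuisance=nuis), mesh2, par)
        changed = np.flatnonzero(np.any(a.data != b.data, axis=1))
        assert list(changed) == [5]

    def test_smoothing_spreads_only_to_neighbors(self, mesh2):
        rng = np.random.default_rng(14)
        base = rng.normal(size=(mesh2.n_vertices, 64))
        pert = base.copy()
        pert[5] += 1.0
        par = PreprocParams(n_discard=0, order=("smooth",))
        a = preprocess_session(make_ts(base), mesh2, par)
        b = preprocess_session(make_ts(pert), mesh2, par)
        changed = set(np.flatnonzero(np.any(~np.isclose(a.data, b.data), axis=1)))
        assert changed <= {5} | set(mesh2.neighbors(5))
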