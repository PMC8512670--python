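"""EXAFS construction, transforms and anomaly removal."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrashell.core import SpectrumK
from hydrashell.errors import DomainError, GridError, ParseError, StateError
from hydrashell.exafs import (
    ETA_E0,
    PathModel,
    ScatteringPath,
    apply_e0_shift,
    average_spectra,
    chi_path_sum,
    chi_paths,
    fourier_transform_chi,
    k_weight,
    mee_remove,
    parametric_path_model,
    read_feff_path,
    write_feff_path,
)
from hydrashell.synth import gen_exafs_signal


class TestChiPathSum:
    def test_hand_evaluation(self):
        """Single scatterer, flat model: χ(k=2) = sin(10)/(2·6.25)."""
        m = parametric_path_model(flat=True)
        s = chi_path_sum([2.5], m, r_cut=None)
        i = int(np.argmin(np.abs(m.k - 2.0)))
        assert s.chi[i] == pytest.approx(math.sin(10.0) / 12.5, rel=1e-9)

    def test_zero_amplitude_gives_zero(self):
        m = parametric_path_model(flat=True)
        m.amplitude[:] = 0.0
        s = chi_path_sum([2.5, 2.7], m, r_cut=None)
        np.testing.assert_array_equal(s.chi, 0.0)

    def test_linearity_in_scatterer_count(self):
        m = parametric_path_model()
        one = chi_path_sum([2.5], m, r_cut=None)
        five = chi_path_sum([2.5] * 5, m, r_cut=None)
        np.testing.assert_allclose(five.chi, 5 * one.chi, rtol=1e-12)

    def test_additive_over_disjoint_sets(self):
        m = parametric_path_model()
        a = chi_path_sum([2.5, 2.6], m, r_cut=None)
        b = chi_path_sum([2.9], m, r_cut=None)
        both = chi_path_sum([2.5, 2.6, 2.9], m, r_cut=None)
        np.testing.assert_allclose(both.chi, a.chi + b.chi, rtol=1e-12)

    def test_s02_scaling(self):
        k = np.arange(0.5, 10, 0.05)
        m1 = PathModel(k, np.ones_like(k), np.zeros_like(k),
                       np.full_like(k, 1e12), s02=1.0)
        m2 = PathModel(k, np.ones_like(k), np.zeros_like(k),
                       np.full_like(k, 1e12), s02=0.5)
        a = chi_path_sum([2.5], m1, r_cut=None)
        b = chi_path_sum([2.5], m2, r_cut=None)
        np.testing.assert_allclose(b.chi, 0.5 * a.chi, rtol=1e-12)

    def test_empty_shell_raises(self):
        m = parametric_path_model()
        with pytest.raises(DomainError, match="scatterer"):
            chi_path_sum([5.0], m, r_cut=3.5)


class TestFeffIO:
    def test_round_trip(self, tmp_path):
        m = parametric_path_model()
        scat = ScatteringPath(8.0, 2.63)
        f = tmp_path / "feff0001.dat"
        write_feff_path(m, scat, f)
        m2, scat2 = read_feff_path(f)
        np.testing.assert_allclose(m2.k, m.k, atol=1e-4)
        np.testing.assert_allclose(m2.amplitude, m.amplitude, rtol=1e-5)
        np.testing.assert_allclose(m2.phase, m.phase, rtol=1e-5)
        np.testing.assert_allclose(m2.lam, m.lam, rtol=1e-5)
        assert scat2.n == scat.n
        assert scat2.r == pytest.approx(scat.r)
        assert np.all(np.diff(m2.k) > 0)
        assert np.all(m2.lam > 0)

    def test_truncated_file_raises(self, tmp_path):
        m = parametric_path_model()
        f = tmp_path / "feff0002.dat"
        write_feff_path(m, ScatteringPath(6, 2.8), f)
        lines = f.read_text().splitlines()
        bad = tmp_path / "trunc.dat"
        bad.write_text("\n".join(lines[:4]) + "\n 1.0 2.0\n")
        with pytest.raises(ParseError):
            read_feff_path(bad)

    def test_unknown_header_raises(self, tmp_path):
        f = tmp_path / "junk.dat"
        f.write_text("this is not\na path file\n")
        with pytest.raises(ParseError, match="separator"):
            read_feff_path(f)


class TestAveraging:
    def test_identity(self):
        m = parametric_path_model()
        s = chi_path_sum([2.5], m, r_cut=None)
        avg = average_spectra([s, s.copy(), s.copy()])
        np.testing.assert_allclose(avg.chi, s.chi, atol=1e-15)
        assert avg.n_snapshots == 3

    def test_grid_mismatch_rejected(self):
        k = np.arange(0.5, 10, 0.05)
        a = SpectrumK(k, np.zeros_like(k), 0)
        b = SpectrumK(k + 0.01, np.zeros_like(k), 0)
        with pytest.raises(GridError):
            average_spectra([a, b])

    def test_gaussian_disorder_matches_cumulant_form(self):
        """Configurational averaging over Gaussian R reproduces the
        second-cumulant damping exp(-2σ²k²) with its first-order phase
        shift -4σ²k(1/R + 1/λ) and the second-order prefactor correction
        from ⟨e^(-2R/λ)/R²⟩, within 2% of peak for σ²k² < 0.5."""
        rng = np.random.default_rng(0)
        m = parametric_path_model()
        r0, var = 2.93, 0.034
        spectra = [chi_path_sum(rng.normal(r0, math.sqrt(var), 10), m,
                                r_cut=None) for _ in range(6000)]
        avg = average_spectra(spectra)
        k = m.k
        phase_corr = -4.0 * var * k * (1.0 / r0 + 1.0 / m.lam)
        prefac_corr = 1.0 + 0.5 * var * ((2.0 / m.lam + 2.0 / r0) ** 2
                                         + 2.0 / r0 ** 2)
        analytic = (m.s02 * 10.0 / (k * r0 ** 2) * m.amplitude
                    * np.exp(-2.0 * r0 / m.lam) * prefac_corr
                    * np.exp(-2.0 * var * k ** 2)
                    * np.sin(2.0 * k * r0 + m.phase + phase_corr))
        sel = (var * k ** 2 < 0.5) & (k > 1.0)
        scale = np.abs(analytic[sel]).max()
        assert np.max(np.abs(avg.chi[sel] - analytic[sel])) / scale < 0.02

    def test_snapshot_convergence(self, sr_traj):
        """More snapshots converge toward the dense average: the 250-snapshot
        mean is closer to the 500-snapshot mean than the 50-snapshot mean."""
        traj, _ = sr_traj
        m = parametric_path_model()
        every = [chi_path_sum(traj.frame(i), m, r_cut=3.3)
                 for i in range(0, traj.n_frames, 20)]   # 500 snapshots
        s500 = average_spectra(every)
        s250 = average_spectra(every[::2])
        s50 = average_spectra(every[::10])
        d250 = np.abs(s250.chi - s500.chi).mean()
        d50 = np.abs(s50.chi - s500.chi).mean()
        assert d250 < d50


class TestKWeight:
    def test_zero_exponent_identity(self):
        k = np.arange(0.5, 10, 0.05)
        s = SpectrumK(k, np.sin(k), 0)
        np.testing.assert_array_equal(k_weight(s, 0).chi, s.chi)

    def test_arithmetic(self):
        s = SpectrumK(np.array([3.0]), np.array([0.01]), 0)
        assert k_weight(s, 2).chi[0] == pytest.approx(0.09)

    def test_double_weighting_rejected(self):
        k = np.arange(0.5, 10, 0.05)
        s = k_weight(SpectrumK(k, np.sin(k), 0), 2)
        with pytest.raises(StateError, match="already"):
            k_weight(s, 2)


class TestE0Shift:
    def test_zero_shift_identity(self):
        k = np.arange(0.5, 10, 0.05)
        s = SpectrumK(k, np.sin(2 * k * 2.5), 0)
        out = apply_e0_shift(s, 0.0)
        np.testing.assert_array_equal(out.chi, s.chi)

    def test_closed_form_mapping(self):
        """For χ(k) = k, the shifted spectrum equals √(k² + η ΔE₀):
        e.g. k = 10, ΔE₀ = 3.81 eV maps from k′ = 9.9499."""
        k = np.arange(1.0, 12.0, 0.05)
        s = SpectrumK(k, k.copy(), 0)
        de0 = 3.81
        out = apply_e0_shift(s, de0)
        np.testing.assert_allclose(out.chi,
                                   np.sqrt(out.k ** 2 + ETA_E0 * de0),
                                   rtol=1e-5)
        assert math.sqrt(10.0 ** 2 - ETA_E0 * de0) == pytest.approx(9.9499,
                                                                    abs=2e-4)

    def test_round_trip(self):
        k = np.arange(0.5, 12.0, 0.05)
        s = SpectrumK(k, np.sin(2 * k * 2.5) * np.exp(-0.05 * k), 0)
        back = apply_e0_shift(apply_e0_shift(s, 3.81), -3.81)
        ref = np.interp(back.k, s.k, s.chi)
        assert np.max(np.abs(back.chi - ref)) < 1e-3

    def test_overshift_rejected(self):
        k = np.arange(0.5, 2.0, 0.05)
        s = SpectrumK(k, np.sin(k), 0)
        with pytest.raises(DomainError):
            apply_e0_shift(s, 100.0)


class TestFourier:
    def test_zero_signal_zero_magnitude(self):
        k = np.arange(0.05, 12, 0.05)
        ft = fourier_transform_chi(SpectrumK(k, np.zeros_like(k), 0),
                                   (2.0, 10.0))
        np.testing.assert_allclose(ft.magnitude, 0.0, atol=1e-15)

    def test_single_frequency_peak(self):
        k = np.arange(0.05, 12, 0.05)
        s = SpectrumK(k, np.sin(2 * k * 2.5), 0)
        ft = fourier_transform_chi(s, (2.0, 10.0), "hann")
        assert ft.peak_r == pytest.approx(2.5, abs=0.05)

    def test_peak_invariant_to_padding(self):
        k = np.arange(0.05, 12, 0.05)
        s = SpectrumK(k, np.sin(2 * k * 2.8), 0)
        p4 = fourier_transform_chi(s, (2.0, 10.0), pad_factor=4).peak_r
        p16 = fourier_transform_chi(s, (2.0, 10.0), pad_factor=16).peak_r
        assert abs(p4 - p16) < 0.02

    def test_kaiser_window_supported(self):
        k = np.arange(0.05, 12, 0.05)
        s = SpectrumK(k, np.sin(2 * k * 2.5), 0)
        ft = fourier_transform_chi(s, (2.0, 10.0), "kaiser")
        assert ft.peak_r == pytest.approx(2.5, abs=0.05)

    def test_out_of_range_rejected(self):
        k = np.arange(2.0, 8.0, 0.05)
        s = SpectrumK(k, np.sin(k), 0)
        with pytest.raises(DomainError):
            fourier_transform_chi(s, (1.0, 10.0))

    @settings(derandomize=True, max_examples=10)
    @given(st.floats(2.2, 3.4))
    def test_peak_tracks_distance(self, r0):
        k = np.arange(0.05, 12, 0.05)
        s = SpectrumK(k, np.sin(2 * k * r0), 0)
        ft = fourier_transform_chi(s, (2.0, 10.0))
        assert ft.peak_r == pytest.approx(r0, abs=0.06)


@pytest.fixture(scope="module")
def model_and_paths():
    return parametric_path_model(), [ScatteringPath(9, 2.8, 0.02)]


class TestMEERemoval:
    def test_no_anomaly_is_noop(self, model_and_paths):
        m, paths = model_and_paths
        sig = gen_exafs_signal(paths, m, noise_sd=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clean, desc = mee_remove(sig.spectrum, region=(5.0, 7.0))
        assert not desc["found"]
        sd = np.std(sig.spectrum.chi)
        assert np.max(np.abs(clean.chi - sig.spectrum.chi)) < 0.01 * sd

    def test_injection_recovery(self, model_and_paths):
        """Ba-like anomaly at 5.5 Å⁻¹: centre recovered within 0.2 Å⁻¹ and
        the cleaned spectrum within 20% RMS of the anomaly amplitude."""
        m, paths = model_and_paths
        amp = 0.01
        sig = gen_exafs_signal(paths, m, noise_sd=0.0,
                               mee={"center": 5.5, "width": 0.15,
                                    "amplitude": amp})
        clean, desc = mee_remove(sig.spectrum, region=(5.0, 7.0))
        assert desc["found"]
        assert desc["center"] == pytest.approx(5.5, abs=0.2)
        rms = math.sqrt(np.mean((clean.chi - sig.clean.chi) ** 2))
        assert rms < 0.2 * amp

    def test_untouched_outside_support(self, model_and_paths):
        m, paths = model_and_paths
        sig = gen_exafs_signal(paths, m, noise_sd=0.0,
                               mee={"center": 5.5, "width": 0.15,
                                    "amplitude": 0.01})
        clean, desc = mee_remove(sig.spectrum, region=(5.0, 7.0))
        outside = (sig.spectrum.k < 3.0) | (sig.spectrum.k > 9.0)
        sd = np.std(sig.spectrum.chi)
        assert np.max(np.abs(clean.chi - sig.spectrum.chi)[outside]) \
            <= 1e-3 * sd

    def test_region_outside_span_rejected(self, model_and_paths):
        m, paths = model_and_paths
        sig = gen_exafs_signal(paths, m)
        with pytest.raises(DomainError, match="region"):
            mee_remove(sig.spectrum, region=(20.0, 25.0))


def test_chi_paths_sigma_sq_damps_amplitude():
    m = parametric_path_model()
    a = chi_paths([ScatteringPath(8, 2.6, 0.0)], m)
    b = chi_paths([ScatteringPath(8, 2.6, 0.02)], m)
    ratio = np.abs(b.chi[-50:]).max() / np.abs(a.chi[-50:]).max()
    assert ratio < 0.5  # strong high-k damping
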