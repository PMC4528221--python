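"""Detrending and the spherical-spline surface Laplacian.

The Laplacian's ground truth is a finite-difference Laplace-Beltrami
oracle evaluated on closed-form spherical functions at 1-degree steps.
"""

import numpy as np
import pytest

from erdswitch.io_epochs import EpochSet
from erdswitch.session_model import Condition, DEFAULT_EEG_CHANNELS, MOTOR_CHANNELS
from erdswitch.spatial_filter import (
    Montage,
    SplineParams,
    laplacian_transform,
    linear_detrend,
    load_montage,
    spherical_spline_laplacian,
    standard_montage,
)


def _epochs_from(data, fs=100.0, labels=None):
    n_tr, n_ch, n_s = data.shape
    labels_ = labels or tuple(DEFAULT_EEG_CHANNELS[:n_ch])
    return EpochSet(
        data=data,
        times=np.arange(n_s) / fs,
        labels=[Condition("none", 2)] * n_tr,
        sample_rate_hz=fs,
        channel_labels=labels_,
    )


def fd_laplace_beltrami(f, theta, phi, h=np.pi / 180):
    """Finite-difference surface Laplacian of callable f(theta, phi) on the
    unit sphere: f_tt + cot(t) f_t + f_pp / sin(t)^2, 1-degree stencil."""
    f0 = f(theta, phi)
    ftt = (f(theta + h, phi) - 2 * f0 + f(theta - h, phi)) / h**2
    ft = (f(theta + h, phi) - f(theta - h, phi)) / (2 * h)
    fpp = (f(theta, phi + h) - 2 * f0 + f(theta, phi - h)) / h**2
    return ftt + ft / np.tan(theta) + fpp / np.sin(theta) ** 2


class TestDetrend:
    def test_line_and_constant_annihilated(self):
        t = np.arange(200) / 100.0
        ramp = 3.0 * t + 5.0
        const = np.full_like(t, 7.0)
        data = np.stack([[ramp, const]])
        out = linear_detrend(_epochs_from(data, labels=("C3", "C4"))).data
        assert np.abs(out).max() < 1e-10

    def test_sinusoid_survives_superposed_ramp(self):
        fs = 100.0
        t = np.arange(2000) / fs
        sine = np.sin(2 * np.pi * 10 * t)
        data = (sine + 5.0 * t)[None, None, :]
        out = linear_detrend(_epochs_from(data, fs, labels=("C3",))).data[0, 0]
        # oracle: subtract the closed-form least-squares line from the input
        A = np.vstack([t, np.ones_like(t)]).T
        coef, *_ = np.linalg.lstsq(A, sine + 5.0 * t, rcond=None)
        expected = sine + 5.0 * t - A @ coef
        assert np.allclose(out, expected, atol=1e-10)
        interior = slice(25, -25)
        assert np.abs(out[interior] - sine[interior]).max() < 0.01

    def test_idempotent(self, rng):
        data = rng.standard_normal((3, 2, 150))
        once = linear_detrend(_epochs_from(data, labels=("C3", "C4")))
        twice = linear_detrend(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)


class TestMontage:
    def test_vertex_and_mirror_symmetry(self):
        m = standard_montage(DEFAULT_EEG_CHANNELS)
        assert np.allclose(m.position("Cz"), [0, 0, 1])
        c3, c4 = m.position("C3"), m.position("C4")
        assert c3[2] == pytest.approx(c4[2])
        assert c3[0] == pytest.approx(-c4[0])
        assert np.allclose(np.linalg.norm(m.positions, axis=1), 1.0, atol=1e-12)

    def test_motor_subset_available(self):
        m = standard_montage(MOTOR_CHANNELS)
        assert m.labels == MOTOR_CHANNELS

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="XX9"):
            standard_montage(["C3", "XX9"])

    def test_plain_text_override_file(self, tmp_path):
        path = tmp_path / "coords.txt"
        path.write_text("A 0 0 2\nB 1 0 0\n")
        m = load_montage(path)
        assert np.allclose(m.position("A"), [0, 0, 1])  # normalized


class TestLaplacian:
    def test_constant_potential_maps_to_zero(self):
        m = standard_montage(DEFAULT_EEG_CHANNELS)
        T = laplacian_transform(m)
        out = T @ np.full(30, 42.0)
        assert np.abs(out).max() < 1e-6 * 42.0

    def test_degree_one_harmonic_matches_fd_oracle(self):
        m = standard_montage(DEFAULT_EEG_CHANNELS)
        T = laplacian_transform(m)
        pos = m.positions
        theta = np.arccos(np.clip(pos[:, 2], -1, 1))
        phi = np.arctan2(pos[:, 1], pos[:, 0])
        f = lambda th, ph: np.sin(th) * np.cos(ph)  # the x-coordinate harmonic
        out = T @ f(theta, phi)
        ok = theta > 1e-6  # FD stencil is singular at the vertex
        oracle = fd_laplace_beltrami(f, theta[ok], phi[ok])
        scale = np.abs(oracle).max()
        assert np.abs(out[ok] - oracle).max() < 0.05 * scale

    def test_focal_bump_peaks_at_c3_with_opposite_neighbors(self):
        m = standard_montage(DEFAULT_EEG_CHANNELS)
        T = laplacian_transform(m)
        v = np.zeros(30)
        c3 = list(m.labels).index("C3")
        v[c3] = 1.0
        out = T @ v
        assert np.argmax(np.abs(out)) == c3
        # the spline interpolant of an isolated bump produces a center-
        # surround field: the response flips sign at the ring of electrodes
        # one step beyond the immediate neighbors
        for label in ("Cz", "T7"):
            j = list(m.labels).index(label)
            assert np.sign(out[j]) == -np.sign(out[c3])

    def test_linearity_and_reference_invariance(self, rng):
        data = rng.standard_normal((2, 30, 40))
        epochs = _epochs_from(data)
        lap = lambda d: spherical_spline_laplacian(_epochs_from(d)).data
        a, b = data, rng.standard_normal(data.shape)
        assert np.allclose(lap(2.0 * a + 0.5 * b), 2.0 * lap(a) + 0.5 * lap(b),
                           atol=1e-9)
        shifted = data + 123.4  # common offset on all channels
        assert np.allclose(lap(shifted), lap(data), atol=1e-8 * np.abs(lap(data)).max()
                           + 1e-9)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SplineParams(m=1)
        with pytest.raises(ValueError):
            SplineParams(n_terms=3)
        with pytest.raises(ValueError):
            SplineParams(ridge=-1e-3)

    def test_montage_must_cover_channels(self, rng):
        epochs = _epochs_from(rng.standard_normal((1, 3, 10)),
                              labels=("C3", "C4", "Cz"))
        small = standard_montage(["C3", "C4"])
        with pytest.raises(ValueError, match="Cz"):
            spherical_spline_laplacian(epochs, montage=small)
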