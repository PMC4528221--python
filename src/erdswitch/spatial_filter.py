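"""Per-epoch detrending and the spherical-spline surface Laplacian.

The surface Laplacian acts as a spatial high-pass re-reference: it
estimates the second spatial derivative of the scalp potential, which
sharpens focal sensorimotor sources and removes any common reference
signal.  It is computed here with spherical-spline interpolation on an
idealized spherical head: scalp potentials sampled at the electrodes are
interpolated with the kernel

    g(cos t) = (1/4pi) * sum_{n=1..N} (2n+1) / (n (n+1))^m * P_n(cos t)

under a zero-sum constraint on the spline coefficients, and the Laplacian
of the interpolant is evaluated through the companion kernel carrying the
order-(m-1) weights (each Legendre term of degree n picks up the
Laplace-Beltrami eigenvalue -n(n+1)).  The operator reduces to a single
channels x channels matrix applied to every time sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy import signal as sps

if TYPE_CHECKING:  # pragma: no cover
    from .io_epochs import EpochSet

__all__ = [
    "Montage",
    "SplineParams",
    "standard_montage",
    "load_montage",
    "linear_detrend",
    "laplacian_transform",
    "spherical_spline_laplacian",
]


# --------------------------------------------------------------------------
# Idealized 10/20 electrode geometry on the unit sphere
# --------------------------------------------------------------------------
# Convention: x = right, y = anterior, z = up; Cz at the vertex (0, 0, 1).
# Midline electrodes sit on the nasion-inion meridian at 10% steps; the
# outer ring (Fpz, Fp1, AF7, F7, ... Oz) lies at 72 deg inclination in 18 deg
# azimuth steps; "9/10"-suffixed electrodes sit 18 deg lower (equator);
# intermediate electrodes are placed by great-circle interpolation between
# their midline and ring anchors, which makes left/right homologs exact
# mirrors in the sagittal plane.

_MIDLINE_FRACTIONS = {
    "Fpz": 0.1, "AFz": 0.2, "Fz": 0.3, "FCz": 0.4, "Cz": 0.5,
    "CPz": 0.6, "Pz": 0.7, "POz": 0.8, "Oz": 0.9,
}

# Left outer-ring labels in order from Fpz (azimuth 0) to Oz (180 deg).
_RING_LEFT = ["Fpz", "Fp1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1", "Oz"]

# (midline anchor, ring anchor, {label: arc fraction from midline})
_CHAINS = [
    ("AFz", "AF7", {"AF3": 0.5}),
    ("Fz", "F7", {"F1": 0.25, "F3": 0.5, "F5": 0.75}),
    ("FCz", "FT7", {"FC1": 0.25, "FC3": 0.5, "FC5": 0.75}),
    ("Cz", "T7", {"C1": 0.25, "C3": 0.5, "C5": 0.75}),
    ("CPz", "TP7", {"CP1": 0.25, "CP3": 0.5, "CP5": 0.75}),
    ("Pz", "P7", {"P1": 0.25, "P3": 0.5, "P5": 0.75}),
    ("POz", "PO7", {"PO3": 0.5}),
]


def _sph(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector at given inclination from vertex; azimuth from anterior
    midline rotating toward the left ear."""
    th = math.radians(inclination_deg)
    az = math.radians(azimuth_deg)
    return np.array(
        [-math.sin(th) * math.sin(az), math.sin(th) * math.cos(az), math.cos(th)]
    )


def _slerp(p0: np.ndarray, p1: np.ndarray, t: float) -> np.ndarray:
    omega = math.acos(float(np.clip(p0 @ p1, -1.0, 1.0)))
    if omega < 1e-12:
        return p0.copy()
    return (math.sin((1 - t) * omega) * p0 + math.sin(t * omega) * p1) / math.sin(omega)


def _mirror_label(label: str) -> str | None:
    """Right-hemisphere homolog of a left-hemisphere label, else None."""
    i = 0
    while i < len(label) and not label[i].isdigit():
        i += 1
    if i == len(label):
        return None
    num = int(label[i:])
    if num % 2 == 0:
        return None
    return label[:i] + str(num + 1)


def _build_ideal_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    for label, frac in _MIDLINE_FRACTIONS.items():
        pos[label] = _sph(abs(90.0 - frac * 180.0), 0.0 if frac <= 0.5 else 180.0)
    for i, label in enumerate(_RING_LEFT):
        pos[label] = _sph(72.0, 18.0 * i)
        if label.endswith("7"):  # equatorial "9" electrode below it
            pos[label[:-1] + "9"] = _sph(90.0, 18.0 * i)
    for mid, ring, members in _CHAINS:
        for label, t in members.items():
            p = _slerp(pos[mid], pos[ring], t)
            pos[label] = p / np.linalg.norm(p)
    for label in list(pos):
        right = _mirror_label(label)
        if right is not None:
            p = pos[label].copy()
            p[0] = -p[0]
            pos[right] = p
    return pos


_IDEAL_POSITIONS = _build_ideal_positions()


@dataclass(frozen=True)
class Montage:
    """Electrode labels with unit-sphere 3D positions (rows of ``positions``)."""

    labels: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be n_labels x 3")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)

    def position(self, label: str) -> np.ndarray:
        try:
            return self.positions[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"label {label!r} not in montage") from None

    def subset(self, labels: "tuple[str, ...] | list[str]") -> "Montage":
        idx = [self.labels.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx])


def standard_montage(labels: "tuple[str, ...] | list[str]") -> Montage:
    """Idealized spherical 10/20 montage for the given labels.

    Raises
    ------
    ValueError
        If a label is not part of the extended 10/20 nomenclature table.
    """
    rows = []
    for label in labels:
        if label not in _IDEAL_POSITIONS:
            raise ValueError(f"unknown 10/20 label {label!r}")
        rows.append(_IDEAL_POSITIONS[label])
    return Montage(tuple(labels), np.array(rows))


def load_montage(path: str | Path) -> Montage:
    """Read a plain-text electrode file: ``label x y z`` per line.

    Positions are normalized onto the unit sphere.
    """
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed montage line: {line!r}")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    pos = np.asarray(rows)
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("electrode at the origin cannot be normalized")
    return Montage(tuple(labels), pos / norms)


@dataclass(frozen=True)
class SplineParams:
    """Spherical-spline constants.

    ``m`` is the spline stiffness order, ``n_terms`` the length of the
    truncated Legendre series, ``ridge`` a small diagonal regularizer added
    to the interpolation matrix for numerical stability.
    """

    m: int = 4
    n_terms: int = 50
    ridge: float = 1e-5

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("spline order m must be >= 2")
        if self.n_terms < 7:
            raise ValueError("n_terms must be >= 7")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


def _kernel_matrices(cosang: np.ndarray, params: SplineParams) -> tuple[np.ndarray, np.ndarray]:
    n = np.arange(1, params.n_terms + 1, dtype=float)
    g_coef = np.zeros(params.n_terms + 1)
    h_coef = np.zeros(params.n_terms + 1)
    g_coef[1:] = (2 * n + 1) / (n * (n + 1)) ** params.m / (4 * np.pi)
    # Laplace-Beltrami eigenvalue of degree n is -n(n+1).
    h_coef[1:] = -(2 * n + 1) / (n * (n + 1)) ** (params.m - 1) / (4 * np.pi)
    return npleg.legval(cosang, g_coef), npleg.legval(cosang, h_coef)


def laplacian_transform(montage: Montage, params: SplineParams | None = None) -> np.ndarray:
    """Channels x channels matrix mapping scalp potentials to their surface
    Laplacian (up to the global 1/head-radius^2 scale, which is immaterial
    for classification)."""
    params = params or SplineParams()
    pos = montage.positions
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    G, H = _kernel_matrices(cosang, params)
    n_ch = len(montage.labels)
    A = np.zeros((n_ch + 1, n_ch + 1))
    A[:n_ch, :n_ch] = G + params.ridge * np.eye(n_ch)
    A[:n_ch, n_ch] = 1.0
    A[n_ch, :n_ch] = 1.0
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular spline interpolation matrix; set SplineParams.ridge > 0"
        ) from err
    # coefficients c = A_inv[:n, :n] @ v  (the constant term is absorbed by
    # the bordered row, making the operator reference-invariant).
    return H @ A_inv[:n_ch, :n_ch]


def linear_detrend(epochs: "EpochSet") -> "EpochSet":
    """Remove a least-squares straight line per channel and trial.

    Suppresses slow DC drifts that would otherwise leak into the low
    band-power bins.  Idempotent to float tolerance.
    """
    if epochs.data.shape[-1] < 2:
        raise ValueError("need at least 2 samples per trial to detrend")
    detrended = sps.detrend(epochs.data, axis=-1, type="linear")
    return replace(epochs, data=detrended)


def spherical_spline_laplacian(
    epochs: "EpochSet",
    montage: Montage | None = None,
    params: SplineParams | None = None,
) -> "EpochSet":
    """Apply the spherical-spline surface Laplacian to every time sample.

    Channel count and order are unchanged.  ``montage`` defaults to the
    idealized 10/20 montage of the epoch channel labels; it must cover all
    of them.
    """
    if montage is None:
        montage = standard_montage(epochs.channel_labels)
    missing = [l for l in epochs.channel_labels if l not in montage.labels]
    if missing:
        raise ValueError(f"montage does not cover channels: {missing}")
    montage = montage.subset(list(epochs.channel_labels))
    T = laplacian_transform(montage, params)
    return replace(epochs, data=np.matmul(T, epochs.data))
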