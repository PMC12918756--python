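"""Synthetic OPM-MEG benchmark data with known gains and interference.

The static benchmark draws an interference field from a spherical-harmonic
basis of order ``L_true`` with unit-norm columns, scales each amplitude
coefficient's standard deviation to ``interference_scale`` times the neural
residual's, multiplies each channel by a static gain drawn from
N(1, sigma_C^2), and adds a neural residual e = G X produced by a
spherical-conductor lead field G and white Gaussian source activity X:

    B = diag(c_true) S_true H_true + e_true.

The dynamic benchmark replaces the static gains with per-channel sinusoids
(default 0.01 Hz, amplitude ~ N(1, 0.1^2), random phase), applied samplewise
via a Hadamard product:

    B = C_vary o (S_true H_true) + e_true.

The lead field uses the standard spherical-conductor magnetometer forward
solution (Sarvas) with tangential dipoles on an inner shell — a synthetic
stand-in for a cortical source model, so benchmark numbers are statistical
reproductions rather than bitwise ones.  Scales are arbitrary units: with
``residual_std`` read as fT, the default interference magnitude corresponds
to 10 pT against a 100 fT residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import InvalidGeometryError, SensorArray, build_sensor_array
from .harmonics import HarmonicBasis, n_basis, regular_harmonic_basis
from .projection import GainVector, Recording

__all__ = [
    "SimConfig",
    "SimTruth",
    "sphere_lead_field",
    "sample_static_gains",
    "sample_dynamic_gains",
    "simulate",
]

_MU0_4PI = 1e-7  # magnetic constant / 4 pi


@dataclass(frozen=True)
class SimConfig:
    """Benchmark generation settings.

    ``M_sensors`` sensor sites (tri-axial: 3 channels each) on a helmet of
    ``helmet_radius`` metres; interference of order ``L_true``; gain sd
    ``sigma_C`` (the "gain error" in percent is 100 sigma_C); ``T`` samples
    at ``fs`` Hz.  ``interference_scale`` is the ratio of each amplitude
    coefficient's sd to the residual sd.  Dynamic mode uses sinusoidal
    channel gains of frequency ``gain_freq`` Hz with amplitude
    ~ N(1, gain_amp_sd^2) and random phase per channel.
    """

    L_true: int
    sigma_C: float = 0.0
    M_sensors: int = 15
    axes_per_sensor: int = 3
    helmet_radius: float = 0.1
    T: int = 10_000
    fs: float = 1000.0
    interference_scale: float = 100.0
    residual_std: float = 100.0
    dynamic: bool = False
    gain_freq: float = 0.01
    gain_amp_sd: float = 0.1
    n_sources: int = 1000
    source_radius_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.L_true <= 8:
            raise ValueError("L_true must be in 1..8")
        if not 0.0 <= self.sigma_C <= 0.5:
            raise ValueError("sigma_C must be in [0, 0.5]")
        for name in ("helmet_radius", "fs", "interference_scale", "residual_std"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.T < 2:
            raise ValueError("T must be >= 2")


@dataclass(frozen=True)
class SimTruth:
    """Generated data plus every ground-truth factor needed for scoring."""

    recording: Recording
    array: SensorArray
    S_true: HarmonicBasis
    H_true: np.ndarray          # (N_true, T)
    e_true: np.ndarray          # (M, T)
    C_true: GainVector          # static gains (dynamic: time-average amplitudes)
    C_vary: np.ndarray | None   # (M, T) in dynamic mode, else None
    G: np.ndarray               # (M, V) lead field
    X: np.ndarray               # (V, T) source time series
    config: SimConfig

    @property
    def B(self) -> np.ndarray:
        return self.recording.B


def sphere_lead_field(
    array: SensorArray,
    n_sources: int,
    source_radius_fraction: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Spherical-conductor magnetometer lead field for tangential dipoles.

    Dipoles are placed quasi-uniformly (Fibonacci lattice) on a spherical
    shell at ``source_radius_fraction`` of the smallest sensor radius, with
    seeded random tangential orientations; radial dipoles are magnetically
    silent in a spherical conductor.  Returns the (M, V) field map computed
    with the Sarvas formula, projected on each channel's orientation.
    """
    if not 0.0 < source_radius_fraction < 0.95:
        raise InvalidGeometryError("source_radius_fraction must be in (0, 0.95)")
    pos = array.centered_positions()
    sensor_radius = np.linalg.norm(pos, axis=1).min()
    r_src = source_radius_fraction * sensor_radius
    rng = np.random.default_rng(seed)

    i = np.arange(n_sources)
    z = 1.0 - 2.0 * (i + 0.5) / n_sources
    rho = np.sqrt(1.0 - z**2)
    phi = i * np.pi * (3.0 - np.sqrt(5.0)) + rng.uniform(0, 2 * np.pi)
    src = r_src * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    # seeded random tangential moment at each source
    raw = rng.normal(size=(n_sources, 3))
    n_hat = src / np.maximum(np.linalg.norm(src, axis=1, keepdims=True), 1e-300)
    q = raw - (np.einsum("ij,ij->i", raw, n_hat))[:, None] * n_hat
    q /= np.linalg.norm(q, axis=1, keepdims=True)

    G = np.empty((array.n_channels, n_sources))
    for v in range(n_sources):
        G[:, v] = _sarvas_field(src[v], q[v], pos, array.orientations)
    if not np.isfinite(G).all():
        raise InvalidGeometryError("non-finite lead field (source too close to a sensor?)")
    return G


def _sarvas_field(
    r0: np.ndarray, q: np.ndarray, r: np.ndarray, ori: np.ndarray
) -> np.ndarray:
    """Magnetic field of a current dipole in a spherical conductor.

    ``r0``/``q``: dipole position and moment; ``r``: (M, 3) sensor positions
    (relative to the sphere centre); ``ori``: (M, 3) channel orientations.
    A dipole at the centre (or a radial dipole) produces zero field.
    """
    a = r - r0[None, :]
    A = np.linalg.norm(a, axis=1)
    R = np.linalg.norm(r, axis=1)
    ar = np.einsum("ij,ij->i", a, r)
    F = A * (R * A + R**2 - np.einsum("j,ij->i", r0, r))
    gradF = (
        (A**2 / R + ar / A + 2.0 * A + 2.0 * R)[:, None] * r
        - (A + 2.0 * R + ar / A)[:, None] * r0[None, :]
    )
    qxr0 = np.cross(q, r0)
    B = _MU0_4PI / (F**2)[:, None] * (
        F[:, None] * qxr0[None, :] - (qxr0 @ r.T)[:, None] * gradF
    )
    return np.einsum("ij,ij->i", B, ori)


def sample_static_gains(M: int, sigma_C: float, seed: int = 0) -> GainVector:
    """Static channel gains c_m ~ N(1, sigma_C^2)."""
    rng = np.random.default_rng(seed)
    c = np.ones(M) if sigma_C == 0 else rng.normal(1.0, sigma_C, size=M)
    return GainVector(c, "true")


def sample_dynamic_gains(
    M: int, T: int, fs: float, freq: float = 0.01, amp_sd: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Sinusoidal gain time series A_m sin(2 pi f t + phi_m), one row per channel."""
    rng = np.random.default_rng(seed)
    amp = rng.normal(1.0, amp_sd, size=M)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=M)
    t = np.arange(T) / fs
    return amp[:, None] * np.sin(2.0 * np.pi * freq * t[None, :] + phase[:, None])


def simulate(config: SimConfig) -> SimTruth:
    """Generate one benchmark dataset with ground truth.

    Static mode: B = diag(c) S H + e.  Dynamic mode: B = C o (S H) + e.
    The residual e = G X is rescaled by a single global factor so that its
    pooled standard deviation equals ``residual_std`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    # independent substreams so changing one ingredient leaves the others untouched
    s_arr, s_lead, s_H, s_X, s_gain = rng.integers(0, 2**31 - 1, size=5)

    array = build_sensor_array(
        config.M_sensors, config.axes_per_sensor, config.helmet_radius, seed=int(s_arr)
    )
    M = array.n_channels
    S_true = regular_harmonic_basis(array, config.L_true, normalize=True)
    N = n_basis(config.L_true)

    sigma_H = config.interference_scale * config.residual_std
    H_true = np.random.default_rng(int(s_H)).normal(0.0, sigma_H, size=(N, config.T))

    G = sphere_lead_field(
        array, config.n_sources, config.source_radius_fraction, seed=int(s_lead)
    )
    X = np.random.default_rng(int(s_X)).normal(size=(config.n_sources, config.T))
    e = G @ X
    scale = config.residual_std / e.std()
    X = scale * X
    e = scale * e

    field = S_true.S @ H_true
    if config.dynamic:
        C_vary = sample_dynamic_gains(
            M, config.T, config.fs, config.gain_freq, config.gain_amp_sd, seed=int(s_gain)
        )
        B = C_vary * field + e
        amp = np.abs(C_vary).max(axis=1)
        C_true = GainVector(amp, "true")
    else:
        C_vary = None
        C_true = sample_static_gains(M, config.sigma_C, seed=int(s_gain))
        B = C_true.c[:, None] * field + e

    rec = Recording(B, config.fs, array.channel_ids)
    return SimTruth(
        recording=rec,
        array=array,
        S_true=S_true,
        H_true=H_true,
        e_true=e,
        C_true=C_true,
        C_vary=C_vary,
        G=G,
        X=X,
        config=config,
    )
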