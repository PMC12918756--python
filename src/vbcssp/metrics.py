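"""Scoring of interference suppression: shielding factors, correlations,
lead-field attenuation, and the simulation benchmark driver.

The shielding factor SF = 10 log10(var(B) / var(e_hat)) measures how much
signal power projection removed; because a badly conditioned projector can
inflate SF by shrinking the output arbitrarily, it is complemented by the
mean per-channel Pearson correlation between the true and estimated
residuals CORR(e), and for gain-estimating methods by the correlation of
true and estimated gains CORR(C).  Lead-field attenuation quantifies how
much of a source's sensor footprint a projector destroys, per vertex, in dB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.signal

from .harmonics import regular_harmonic_basis
from .projection import GainVector, Projector, Recording, cssp_fit, ssp_apply, ssp_fit
from .simulate import SimConfig, SimTruth, simulate
from .vb import VBOptions, vbcssp_fit

__all__ = [
    "shielding_factor",
    "spectral_shielding_factor",
    "corr_residuals",
    "corr_gains",
    "lead_field_attenuation",
    "run_benchmark",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Raised when a score is mathematically undefined for the given input."""


def shielding_factor(B: np.ndarray, e_hat: np.ndarray) -> float:
    """Broadband shielding factor 10 log10(var(B)/var(e_hat)) in dB.

    Variances are pooled over all channels and samples.  A zero residual
    variance yields +inf (with a warning) rather than an error, so the
    under-determined SSP breakdown stays visible in score tables.
    """
    B = np.asarray(B, float)
    e_hat = np.asarray(e_hat, float)
    if B.shape != e_hat.shape:
        raise ValueError(f"shape mismatch: {B.shape} vs {e_hat.shape}")
    v_in = B.var()
    v_out = e_hat.var()
    if v_out == 0.0:
        warnings.warn("zero residual variance; SF is +inf", RuntimeWarning, stacklevel=2)
        return np.inf
    return float(10.0 * np.log10(v_in / v_out))


def spectral_shielding_factor(
    B_pre: np.ndarray,
    B_post: np.ndarray,
    fs: float,
    f_band: tuple[float, float],
    nperseg_seconds: float = 2.0,
) -> float:
    """Band-averaged spectral shielding factor in dB.

    PSDs are estimated per channel by Welch's averaged periodogram (Hann
    windows of ``nperseg_seconds``, 50% overlap), averaged across channels,
    and the ratio pre/post is averaged over the requested band.
    """
    lo, hi = f_band
    if not 0.0 <= lo < hi <= fs / 2.0:
        raise ValueError(f"band {f_band} outside [0, fs/2] = [0, {fs / 2}]")
    nperseg = min(int(round(nperseg_seconds * fs)), np.asarray(B_pre).shape[-1])
    f, p_pre = scipy.signal.welch(B_pre, fs=fs, nperseg=nperseg, axis=-1)
    _, p_post = scipy.signal.welch(B_post, fs=fs, nperseg=nperseg, axis=-1)
    pre = p_pre.mean(axis=0)
    post = p_post.mean(axis=0)
    sel = (f >= lo) & (f <= hi)
    if not sel.any():
        raise ValueError("no PSD bins inside the requested band")
    with np.errstate(divide="ignore"):
        sf = 10.0 * np.log10(pre[sel] / post[sel])
    return float(sf.mean())


def corr_residuals(e_true: np.ndarray, e_hat: np.ndarray) -> float:
    """Mean over channels of the per-channel Pearson correlation."""
    e_true = np.asarray(e_true, float)
    e_hat = np.asarray(e_hat, float)
    if e_true.shape != e_hat.shape:
        raise ValueError(f"shape mismatch: {e_true.shape} vs {e_hat.shape}")
    a = e_true - e_true.mean(axis=1, keepdims=True)
    b = e_hat - e_hat.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(a, axis=1)
    sb = np.linalg.norm(b, axis=1)
    ok = (sa > 0) & (sb > 0)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} constant channel(s) excluded from CORR(e)",
            RuntimeWarning,
            stacklevel=2,
        )
    if not ok.any():
        raise UndefinedMetricError("all channels constant; CORR(e) undefined")
    r = np.einsum("mt,mt->m", a[ok], b[ok]) / (sa[ok] * sb[ok])
    return float(r.mean())


def corr_gains(
    c_true: GainVector | np.ndarray,
    c_hat: GainVector | np.ndarray,
    align_sign: bool = False,
) -> float:
    """Pearson correlation of true vs estimated channel gains.

    Channels with non-finite estimates (e.g. rejected by VBCSSP) are
    excluded pairwise.  Undefined (zero-variance truth) raises rather than
    silently returning NaN.

    ``align_sign=True`` scores the estimate modulo the joint sign flip of
    gains and amplitudes (returning |r|): the factor-analysis gauge symmetry
    (C, H) -> (-C, -H) leaves the sign of a gain vector unidentifiable, which
    matters when true gains are signed (windowed fits of oscillating gains).
    """
    ct = np.asarray(c_true.c if isinstance(c_true, GainVector) else c_true, float)
    ch = np.asarray(c_hat.c if isinstance(c_hat, GainVector) else c_hat, float)
    if ct.shape != ch.shape:
        raise ValueError("gain vectors must have equal length")
    ok = np.isfinite(ct) & np.isfinite(ch)
    ct, ch = ct[ok], ch[ok]
    if ct.size < 2:
        raise UndefinedMetricError("fewer than 2 usable channels")
    if ct.std() == 0:
        raise UndefinedMetricError("true gains have zero variance; CORR(C) undefined")
    if ch.std() == 0:
        raise UndefinedMetricError("estimated gains have zero variance; CORR(C) undefined")
    r = float(np.corrcoef(ct, ch)[0, 1])
    return abs(r) if align_sign else r


def lead_field_attenuation(P: Projector | np.ndarray, G: np.ndarray) -> np.ndarray:
    """Per-vertex dB attenuation 10 log10(var(P G_i)/var(G_i)) of a lead field.

    Negative values mean the projector removed part of that source's sensor
    footprint (neural-signal loss).  Zero-variance columns yield NaN with a
    warning; a fully annihilated column yields -inf.
    """
    Pm = P.P if isinstance(P, Projector) else np.asarray(P, float)
    G = np.asarray(G, float)
    PG = Pm @ G
    v_in = G.var(axis=0)
    v_out = PG.var(axis=0)
    att = np.full(G.shape[1], np.nan)
    ok = v_in > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} zero-variance lead-field column(s) skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        att[ok] = 10.0 * np.log10(v_out[ok] / v_in[ok])
    return att


@dataclass(frozen=True)
class BenchmarkCell:
    """One benchmark condition: a simulation config, an analysis order, a method."""

    method: str  # "ssp" | "cssp" | "vbcssp"
    L_ssp: int
    config: SimConfig


def _score_cell(cell: BenchmarkCell, truth: SimTruth, vb_opts: VBOptions | None):
    rec = truth.recording
    basis = regular_harmonic_basis(truth.array, cell.L_ssp, normalize=True)
    gains = None
    free_e = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if cell.method == "ssp":
            e_hat = ssp_apply(ssp_fit(basis), rec).B
        elif cell.method == "cssp":
            proj, gains = cssp_fit(rec, basis)
            e_hat = ssp_apply(proj, rec).B
        elif cell.method == "vbcssp":
            res = vbcssp_fit(rec, basis, opts=vb_opts)
            e_hat = res.cleaned.B
            gains = res.gains
            free_e = res.free_energy
        else:
            raise ValueError(f"unknown method {cell.method!r}")
    row = {
        "method": cell.method,
        "L_true": cell.config.L_true,
        "L_ssp": cell.L_ssp,
        "sigma_C": cell.config.sigma_C,
        "seed": cell.config.seed,
        "SF_dB": shielding_factor(rec.B, e_hat),
        "CORR_e": corr_residuals(truth.e_true, e_hat),
        "free_energy": free_e,
    }
    if gains is not None and not cell.config.dynamic and cell.config.sigma_C > 0:
        try:
            row["CORR_C"] = corr_gains(truth.C_true, gains)
        except UndefinedMetricError:
            row["CORR_C"] = np.nan
    else:
        row["CORR_C"] = np.nan
    return row


def run_benchmark(
    configs: list[SimConfig],
    L_ssp_values: list[int],
    methods: list[str],
    replicates: int = 10,
    base_seed: int = 0,
    vb_opts: VBOptions | None = None,
) -> pd.DataFrame:
    """Run simulate → fit → score over a condition grid and tidy the scores.

    Every (config, L_ssp, method, replicate) cell gets its own deterministic
    seed derived from ``base_seed``; per-cell failures are recorded as rows
    with an ``error`` column instead of aborting the grid.
    """
    rows = []
    for ci, cfg in enumerate(configs):
        for rep in range(replicates):
            seed = base_seed + 1000 * ci + rep
            truth = simulate(replace(cfg, seed=seed))
            for L in L_ssp_values:
                for method in methods:
                    cell = BenchmarkCell(method, L, truth.config)
                    try:
                        rows.append({**_score_cell(cell, truth, vb_opts), "error": ""})
                    except Exception as exc:  # noqa: BLE001 - per-cell isolation
                        rows.append(
                            {
                                "method": method,
                                "L_true": cfg.L_true,
                                "L_ssp": L,
                                "sigma_C": cfg.sigma_C,
                                "seed": seed,
                                "SF_dB": np.nan,
                                "CORR_e": np.nan,
                                "free_energy": np.nan,
                                "CORR_C": np.nan,
                                "error": str(exc),
                            }
                        )
    return pd.DataFrame(rows)
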