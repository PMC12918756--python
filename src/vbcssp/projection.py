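"""Classical SSP and regression-calibrated CSSP.

Signal space projection models a recording as B = S H + e and removes the
interference component by projecting onto the orthogonal complement of
span(S):  e_hat = (I - S S+) B.  CSSP additionally estimates a per-channel
gain c_m by regressing each measured channel onto its SSP-predicted
interference time course, then projects with the gain-scaled basis diag(c) S.

When N > M (e.g. order 6 on a 45-channel array) the normal equations are
singular; the pseudo-inverse is then computed by SVD with a warning so the
known breakdown of SSP/CSSP in the under-determined regime stays observable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .harmonics import HarmonicBasis

__all__ = [
    "Recording",
    "Projector",
    "GainVector",
    "ssp_fit",
    "ssp_apply",
    "cssp_gains",
    "cssp_fit",
]

_SVD_RCOND = 1e-10  # relative singular-value cutoff for rank-deficient bases


@dataclass(frozen=True)
class Recording:
    """Multichannel time series: an (M, T) data matrix with sampling rate."""

    B: np.ndarray
    fs: float
    channel_ids: tuple[str, ...] = ()
    active_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if B.shape[1] < 1:
            raise ValueError("recording needs at least one sample")
        if not np.isfinite(B).all():
            raise ValueError("recording contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        ids = tuple(self.channel_ids) or tuple(f"ch{i:03d}" for i in range(B.shape[0]))
        if len(ids) != B.shape[0]:
            raise ValueError("channel_ids length does not match data")
        mask = self.active_mask
        mask = np.ones(B.shape[0], bool) if mask is None else np.asarray(mask, bool)
        if mask.shape != (B.shape[0],):
            raise ValueError("active_mask length does not match data")
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "channel_ids", ids)
        object.__setattr__(self, "active_mask", mask)

    @property
    def n_channels(self) -> int:
        return self.B.shape[0]

    @property
    def n_samples(self) -> int:
        return self.B.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Projector:
    """An M x M spatial projector with its method tag and basis order."""

    P: np.ndarray
    method: str  # "SSP" | "CSSP" | "VBCSSP"
    basis_order: int

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("projector must be square")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class GainVector:
    """Per-channel gain estimates (the diagonal of C)."""

    c: np.ndarray
    source: str  # "true" | "cssp" | "vbcssp"

    def __post_init__(self) -> None:
        object.__setattr__(self, "c", np.asarray(self.c, dtype=float).ravel())

    def __len__(self) -> int:
        return self.c.size


def _pinv_basis(S: np.ndarray, order: int) -> np.ndarray:
    """S+ = (S'S)^-1 S' when well conditioned, else SVD pseudo-inverse."""
    M, N = S.shape
    gram = S.T @ S
    cond_limit = 1.0 / _SVD_RCOND
    if N <= M and np.linalg.cond(gram) < cond_limit:
        return scipy.linalg.solve(gram, S.T, assume_a="pos")
    warnings.warn(
        f"interference basis is rank-deficient (M={M}, N={N}); using SVD "
        "pseudo-inverse — projection is unreliable in this regime",
        RuntimeWarning,
        stacklevel=3,
    )
    return np.linalg.pinv(S, rcond=_SVD_RCOND)


def ssp_fit(S: HarmonicBasis | np.ndarray, order: int | None = None) -> Projector:
    """Fit the SSP projector P = I - S S+ annihilating span(S)."""
    if isinstance(S, HarmonicBasis):
        order = S.order if order is None else order
        S = S.S
    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if not np.isfinite(S).all():
        raise ValueError("basis contains non-finite values")
    P = np.eye(S.shape[0]) - S @ _pinv_basis(S, order or 0)
    return Projector(P, "SSP", order if order is not None else 0)


def ssp_apply(P: Projector, rec: Recording) -> Recording:
    """Apply a projector to the active channels of a recording."""
    mask = rec.active_mask
    B = rec.B[mask]
    if P.P.shape[0] != B.shape[0]:
        raise ValueError(
            f"projector dimension {P.P.shape[0]} does not match "
            f"{B.shape[0]} active channels"
        )
    ids = tuple(c for c, keep in zip(rec.channel_ids, mask) if keep)
    return Recording(P.P @ B, rec.fs, ids)


def cssp_gains(rec: Recording, S: HarmonicBasis) -> GainVector:
    """Per-channel regression gains against the SSP interference prediction.

    The SSP amplitude estimate H_SSP = S+ B predicts the interference seen by
    channel m as b_hat_m = s_m H_SSP; the gain is the least-squares slope
    <b_m, b_hat_m> / <b_hat_m, b_hat_m>.  Channels whose predicted signal is
    identically zero get gain NaN and a warning.
    """
    if rec.n_samples < 2:
        raise ValueError("gain regression needs at least 2 samples")
    B = rec.B[rec.active_mask]
    Smat = S.S if isinstance(S, HarmonicBasis) else np.asarray(S, float)
    if Smat.shape[0] != B.shape[0]:
        raise ValueError("basis rows do not match active channel count")
    H_ssp = _pinv_basis(Smat, getattr(S, "order", 0)) @ B
    B_hat = Smat @ H_ssp
    num = np.einsum("mt,mt->m", B, B_hat)
    den = np.einsum("mt,mt->m", B_hat, B_hat)
    c = np.full(B.shape[0], np.nan)
    ok = den > 0
    c[ok] = num[ok] / den[ok]
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} channel(s) with zero predicted interference; "
            "gain set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    return GainVector(c, "cssp")


def cssp_fit(rec: Recording, S: HarmonicBasis) -> tuple[Projector, GainVector]:
    """Gain-calibrated SSP: estimate gains, then project with diag(c) S."""
    gains = cssp_gains(rec, S)
    c = np.where(np.isfinite(gains.c), gains.c, 0.0)
    Smat = S.S if isinstance(S, HarmonicBasis) else np.asarray(S, float)
    CS = c[:, None] * Smat
    proj = ssp_fit(CS, order=getattr(S, "order", 0))
    return Projector(proj.P, "CSSP", proj.basis_order), gains
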