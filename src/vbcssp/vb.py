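"""Variational-Bayes calibrated signal space projection (VBCSSP).

The observation model extends SSP with an unknown diagonal gain matrix C:

    b(t) = C S h(t) + e(t),      e(t) ~ N(0, Lambda^-1),  Lambda = lambda I,

with priors h(t) ~ N(0, I) and c_d ~ N(0, rho K).  The posterior over the
interference amplitudes H and the channel gains c_d is approximated by a
factorised Gaussian Q(H) Q(c_d) optimised by coordinate ascent on the
variational free energy; the noise precision scale lambda and the gain prior
scale rho are updated by empirical Bayes.  The closed-form updates are

    h_bar(t) = Gamma^-1 S' Cbar Lambda b(t),      Gamma = S' C2bar Lambda S + I,
    c_bar    = Phi^-1 diag(S R_hb Lambda),        Phi = diag{diag(S R_hh S' Lambda)} + D,

with D = (rho K)^-1, R_hh = T Gamma^-1 + sum_t h h', R_hb = sum_t h b', and
C2bar the posterior second moment diag(c_bar^2 + diag(Phi^-1)).

Because the model is L2-regularised by the amplitude prior, the resulting
projector  P = I - Cbar S Gamma^-1 (Cbar S)' Lambda  remains well defined
even when the basis is under-determined (N > M), where plain SSP breaks
down.  Channels whose posterior gain turns negative (physically implausible
under the harmonic field model, e.g. a flipped sensor axis) are rejected and
the fit restarts on the reduced array.  The converged free energy is used
both for convergence monitoring and for selecting the harmonic order.

Data are standardised per channel (mean 0, sd 1) before the fit and results
are mapped back to input units afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .geometry import SensorArray
from .harmonics import HarmonicBasis, regular_harmonic_basis
from .projection import GainVector, Projector, Recording, _pinv_basis

__all__ = [
    "VBState",
    "VBResult",
    "VBOptions",
    "TooManyRejectionsError",
    "NumericalFailureError",
    "h_step",
    "c_step",
    "update_hyperparameters",
    "free_energy",
    "vbcssp_fit",
    "windowed_vbcssp",
    "select_order",
]

_FLOOR = 1e-12  # lower bound for lambda^-1 and rho in exact-fit corner cases


class TooManyRejectionsError(RuntimeError):
    """Raised when negative-gain rejection would discard too many channels."""


class NumericalFailureError(RuntimeError):
    """Raised when an update produces an inconsistent (non-positive) moment."""


@dataclass
class VBState:
    """Posterior moments and hyperparameters of the VB fit.

    Gains and amplitudes live on the *standardised* data scale.  ``c_mean``
    is the posterior mean of the gain vector, ``phi`` its precision matrix,
    ``c2_mean`` the diagonal of the posterior second moment C2bar.  ``gamma``
    is the (shared-over-time) posterior precision of the amplitudes, and
    ``H_mean`` their posterior mean time series.
    """

    c_mean: np.ndarray          # (M,)
    phi: np.ndarray             # (M, M) gain posterior precision
    phi_inv: np.ndarray         # (M, M)
    c2_mean: np.ndarray         # (M,) diagonal of C2bar
    H_mean: np.ndarray          # (N, T)
    gamma: np.ndarray           # (N, N) amplitude posterior precision
    gamma_inv: np.ndarray       # (N, N)
    lambda_: float              # noise precision scale (Lambda = lambda I)
    rho: float                  # gain prior scale (prior cov = rho K)
    K: np.ndarray               # (M, M) SPD gain prior structure
    K_inv: np.ndarray
    logdet_K: float
    Rhh: np.ndarray = field(default=None)  # type: ignore[assignment]
    Rhb: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def C_bar(self) -> np.ndarray:
        return np.diag(self.c_mean)

    @property
    def C2_bar(self) -> np.ndarray:
        return np.diag(self.c2_mean)

    @classmethod
    def initialize(cls, M: int, N: int, T: int, K: np.ndarray | None = None) -> "VBState":
        """No-error initial belief: unit gains, unit scales, zero amplitudes."""
        if K is None:
            K = np.eye(M)
            K_inv = np.eye(M)
            logdet_K = 0.0
        else:
            K = np.asarray(K, dtype=float)
            if K.shape != (M, M):
                raise ValueError(f"K must be ({M}, {M})")
            cho = scipy.linalg.cho_factor(K)
            K_inv = scipy.linalg.cho_solve(cho, np.eye(M))
            logdet_K = 2.0 * np.sum(np.log(np.diag(cho[0])))
        return cls(
            c_mean=np.ones(M),
            phi=np.eye(M),
            phi_inv=np.eye(M),
            c2_mean=np.full(M, 2.0),  # 1^2 + diag(Phi^-1)
            H_mean=np.zeros((N, T)),
            gamma=np.eye(N),
            gamma_inv=np.eye(N),
            lambda_=1.0,
            rho=1.0,
            K=K,
            K_inv=K_inv,
            logdet_K=logdet_K,
        )


def _as_matrix(S: HarmonicBasis | np.ndarray) -> np.ndarray:
    return S.S if isinstance(S, HarmonicBasis) else np.asarray(S, dtype=float)


def h_step(state: VBState, B: np.ndarray, S: HarmonicBasis | np.ndarray) -> VBState:
    """Update the amplitude posterior Q(H) and the sufficient statistics."""
    Smat = _as_matrix(S)
    T = B.shape[1]
    lam = state.lambda_
    state.gamma = lam * (Smat * state.c2_mean[:, None]).T @ Smat + np.eye(Smat.shape[1])
    cho = scipy.linalg.cho_factor(state.gamma)
    state.gamma_inv = scipy.linalg.cho_solve(cho, np.eye(Smat.shape[1]))
    state.H_mean = lam * scipy.linalg.cho_solve(
        cho, (Smat * state.c_mean[:, None]).T @ B
    )
    state.Rhh = T * state.gamma_inv + state.H_mean @ state.H_mean.T
    state.Rhb = state.H_mean @ B.T
    return state


def c_step(state: VBState, B: np.ndarray, S: HarmonicBasis | np.ndarray) -> VBState:
    """Update the gain posterior Q(c_d) and refresh its second moment."""
    Smat = _as_matrix(S)
    lam = state.lambda_
    diag_SRS = np.einsum("mn,nk,mk->m", Smat, state.Rhh, Smat, optimize=True)
    D = state.K_inv / state.rho
    state.phi = np.diag(lam * diag_SRS) + D
    cho = scipy.linalg.cho_factor(state.phi)
    state.phi_inv = scipy.linalg.cho_solve(cho, np.eye(Smat.shape[0]))
    rhs = lam * np.einsum("mn,nm->m", Smat, state.Rhb)
    state.c_mean = scipy.linalg.cho_solve(cho, rhs)
    state.c2_mean = state.c_mean**2 + np.diag(state.phi_inv)
    return state


def _expected_residual(state: VBState, B: np.ndarray, S: np.ndarray) -> float:
    """E_Q ||B - C S H||^2 summed over channels and samples."""
    CS = state.c_mean[:, None] * S
    term1 = float(np.sum(B * B))
    term2 = -2.0 * float(np.sum((CS @ state.H_mean) * B))
    A = (S * state.c2_mean[:, None]).T @ S
    term3 = float(np.sum(A * state.Rhh))
    return term1 + term2 + term3


def update_hyperparameters(
    state: VBState, B: np.ndarray, S: HarmonicBasis | np.ndarray
) -> VBState:
    """Empirical-Bayes point updates of the noise and gain prior scales."""
    Smat = _as_matrix(S)
    M, T = B.shape
    R = _expected_residual(state, B, Smat)
    lam_inv = R / (T * M)
    if lam_inv < -1e-8 * max(1.0, float(np.sum(B * B)) / (T * M)):
        raise NumericalFailureError(
            f"negative expected residual power ({lam_inv:.3e}): inconsistent moments"
        )
    state.lambda_ = 1.0 / max(lam_inv, _FLOOR)
    trace = float(np.sum(state.K_inv * (state.phi_inv + np.outer(state.c_mean, state.c_mean))))
    state.rho = max(trace / (2.0 * M), _FLOOR)
    return state


def free_energy(state: VBState, B: np.ndarray, S: HarmonicBasis | np.ndarray) -> float:
    """Variational free energy (evidence lower bound) of the current state.

    F = E_Q[log N(B | C S H, Lambda^-1)] - KL(Q(H) || N(0, I))
        - KL(Q(c_d) || N(0, rho K)) - (M/2) log rho,

    the last term being the scale hyperprior on rho under which the
    empirical-Bayes rho update is the exact coordinate-ascent maximiser.
    """
    Smat = _as_matrix(S)
    M, T = B.shape
    N = Smat.shape[1]
    lam = state.lambda_
    R = _expected_residual(state, B, Smat)
    loglik = 0.5 * T * M * (np.log(lam) - np.log(2.0 * np.pi)) - 0.5 * lam * R

    sign, logdet_gamma = np.linalg.slogdet(state.gamma)
    kl_h = 0.5 * (float(np.trace(state.Rhh)) - T * N + T * logdet_gamma)

    quad = float(np.sum(state.K_inv * (state.phi_inv + np.outer(state.c_mean, state.c_mean))))
    sign_p, logdet_phi = np.linalg.slogdet(state.phi)
    kl_c = 0.5 * (
        quad / state.rho - M + M * np.log(state.rho) + state.logdet_K + logdet_phi
    )
    F = loglik - kl_h - kl_c - 0.5 * M * np.log(state.rho)
    if not np.isfinite(F):
        raise NumericalFailureError("non-finite free energy")
    return float(F)


@dataclass
class VBOptions:
    """Tunable settings of the VB fit.

    ``tol`` is the relative free-energy change declaring convergence
    (default 5e-5, i.e. 0.005%); ``max_iter`` caps iterations per rejection
    round; ``max_reject_frac`` aborts if more than this fraction of channels
    would be rejected cumulatively; ``standardize`` toggles the internal
    per-channel mean/sd normalisation.
    """

    tol: float = 5e-5
    max_iter: int = 500
    standardize: bool = True
    reject_negative_gains: bool = True
    max_reject_frac: float = 0.25


@dataclass
class VBResult:
    """Outcome of a VBCSSP fit."""

    state: VBState
    free_energy_trace: list[float]
    restart_iterations: list[int]      # trace indices where a rejection round restarted
    n_iterations: int
    rejected_channels: tuple[str, ...]
    alpha: float
    projector: Projector
    converged: bool
    gains: GainVector                  # input-unit gains, NaN at rejected channels
    cleaned: Recording                 # full-channel cleaned data; rejected rows zeroed
    active_mask: np.ndarray

    @property
    def free_energy(self) -> float:
        return self.free_energy_trace[-1]


def _run_rounds(
    B_full: np.ndarray,
    Smat_full: np.ndarray,
    mask0: np.ndarray,
    K_full: np.ndarray | None,
    opts: VBOptions,
    init_signs: np.ndarray | None,
) -> tuple[VBState, np.ndarray, list[float], list[int], bool, int]:
    """Run the VB iteration with negative-gain rejection rounds.

    ``init_signs`` (full-length, +-1) seeds the initial gain means; the
    default is all ones.  Returns the converged state, the final active
    mask, the free-energy trace, the trace indices where a rejection round
    restarted, the convergence flag and the iteration count.
    """
    mask = mask0.copy()
    M0 = int(mask0.sum())
    N = Smat_full.shape[1]
    T = B_full.shape[1]
    min_active = max(int(np.ceil(N / 4)), 4)

    trace: list[float] = []
    restarts: list[int] = []
    converged = False
    n_iter_total = 0
    while True:  # rejection rounds
        act = np.flatnonzero(mask)
        B = B_full[act]
        Smat = Smat_full[act]
        K_sub = None if K_full is None else K_full[np.ix_(act, act)]
        state = VBState.initialize(len(act), N, T, K_sub)
        if init_signs is not None:
            state.c_mean = init_signs[act].astype(float)
            state.c2_mean = state.c_mean**2 + np.diag(state.phi_inv)
        rejected_now: np.ndarray | None = None
        prev_F = None
        for _ in range(opts.max_iter):
            h_step(state, B, Smat)
            c_step(state, B, Smat)
            update_hyperparameters(state, B, Smat)
            F = free_energy(state, B, Smat)
            trace.append(F)
            n_iter_total += 1
            if opts.reject_negative_gains and np.any(state.c_mean < 0):
                rejected_now = act[state.c_mean < 0]
                break
            if prev_F is not None and abs(F - prev_F) < opts.tol * abs(prev_F):
                converged = True
                break
            prev_F = F
        if rejected_now is None:
            break
        mask[rejected_now] = False
        restarts.append(len(trace))
        n_active = int(mask.sum())
        n_rejected = M0 - n_active
        if n_rejected > opts.max_reject_frac * M0 or n_active < min_active:
            raise TooManyRejectionsError(
                f"{n_rejected}/{M0} channels rejected (negative gains); "
                "the interference model likely does not fit this data"
            )
        warnings.warn(
            f"rejected {len(rejected_now)} channel(s) with negative gain; restarting",
            RuntimeWarning,
            stacklevel=2,
        )
    return state, mask, trace, restarts, converged, n_iter_total


def _reduced_order_signs(
    B_full: np.ndarray,
    S: HarmonicBasis,
    mask: np.ndarray,
    K_full: np.ndarray | None,
    opts: VBOptions,
) -> np.ndarray | None:
    """Gain signs from a quick fit with a well-determined sub-basis.

    Used as a multi-start candidate when the full basis is under-determined:
    with N >= M every per-channel sign flip of (c_m, contributions of H) is
    an exact model symmetry broken only by the amplitude prior, so a
    lower-order fit (where signs are strongly identified) provides a good
    starting basin.
    """
    from .harmonics import n_basis  # local import to avoid cycle at module load

    M_active = int(mask.sum())
    L_red = 0
    for L in range(1, S.order):
        if n_basis(L) <= max(0.8 * M_active, 3):
            L_red = L
    if L_red == 0:
        return None
    keep = [j for j, (l, _) in enumerate(S.column_labels) if l <= L_red]
    sub = S.S[:, keep]
    probe_opts = VBOptions(
        tol=opts.tol, max_iter=opts.max_iter, standardize=False,
        reject_negative_gains=False,
    )
    state, _, _, _, _, _ = _run_rounds(B_full, sub, mask, K_full, probe_opts, None)
    signs = np.ones(B_full.shape[0])
    signs[mask] = np.where(state.c_mean >= 0, 1.0, -1.0)
    return signs


def vbcssp_fit(
    rec: Recording,
    S: HarmonicBasis,
    K: np.ndarray | None = None,
    opts: VBOptions | None = None,
    init_gains: np.ndarray | None = None,
) -> VBResult:
    """Joint VB estimation of interference amplitudes and channel gains.

    Iterates the amplitude step, gain step and hyperparameter updates until
    the relative free-energy change falls below ``opts.tol`` or ``max_iter``
    is reached.  Whenever a posterior gain turns negative the offending
    channels are rejected and the fit restarts from initialisation on the
    reduced channel set.  On convergence the scale split between H and c_d is
    fixed by matching ||H||_F to the SSP solution (alpha correction), which
    leaves the interference field estimate C S H unchanged.

    When the basis is under-determined (N >= active channels) the gain signs
    are only weakly identified and coordinate ascent can converge to
    sign-flipped local optima; the fit is then run from several sign
    initialisations (all-positive, a reduced-order probe fit, and
    ``init_gains`` if given) and the solution with the highest free energy
    is kept.  ``init_gains`` (length M, only its signs are used) can carry
    sign information from e.g. the previous window of a segmented fit.
    """
    opts = opts or VBOptions()
    Smat_full = _as_matrix(S)
    mask0 = rec.active_mask.copy()
    M0 = int(mask0.sum())
    if M0 < 2:
        raise ValueError("need at least 2 active channels")
    if Smat_full.shape[0] != rec.n_channels:
        raise ValueError("basis rows must match recording channels")
    N = Smat_full.shape[1]

    ids = np.asarray(rec.channel_ids, dtype=object)
    mean = rec.B.mean(axis=1)
    sd = rec.B.std(axis=1)
    sd = np.where(sd > 0, sd, 1.0)
    if opts.standardize:
        B_full = (rec.B - mean[:, None]) / sd[:, None]
    else:
        B_full = rec.B.copy()

    K_full = None if K is None else np.asarray(K, dtype=float)

    starts: list[np.ndarray | None] = [None]
    if init_gains is not None:
        g0 = np.asarray(init_gains, dtype=float).ravel()
        if g0.shape != (rec.n_channels,):
            raise ValueError("init_gains must have one entry per channel")
        signs = np.where(np.isfinite(g0) & (g0 < 0), -1.0, 1.0)
        if np.any(signs < 0):
            starts.append(signs)
    if N >= M0 and isinstance(S, HarmonicBasis) and S.order > 1:
        red = _reduced_order_signs(B_full, S, mask0, K_full, opts)
        if red is not None and np.any(red < 0):
            starts.append(red)

    best = None
    for s0 in starts:
        try:
            out = _run_rounds(B_full, Smat_full, mask0, K_full, opts, s0)
        except (TooManyRejectionsError, NumericalFailureError):
            if len(starts) == 1:
                raise
            continue
        if best is None or out[2][-1] > best[2][-1]:
            best = out
    if best is None:
        raise TooManyRejectionsError("all starts failed (too many rejected channels)")
    state, mask, trace, restarts, converged, n_iter_total = best
    if not converged:
        warnings.warn("VBCSSP did not converge within max_iter", RuntimeWarning, stacklevel=2)

    act = np.flatnonzero(mask)
    B = B_full[act]
    Smat = Smat_full[act]

    # Projector (pre-correction state; P @ B equals the residual estimate)
    CS = state.c_mean[:, None] * Smat
    P = np.eye(len(act)) - state.lambda_ * (CS @ state.gamma_inv @ CS.T)
    projector = Projector(P, "VBCSSP", getattr(S, "order", 0))

    resid_std = B - CS @ state.H_mean

    # Scale correction: match ||H||_F to the SSP amplitude estimate
    H_ssp = _pinv_basis(Smat, getattr(S, "order", 0)) @ B
    norm_vb = float(np.linalg.norm(state.H_mean))
    norm_ssp = float(np.linalg.norm(H_ssp))
    # degenerate fits (no interference found) leave the scale split alone
    alpha = norm_ssp / norm_vb if norm_vb > 1e-12 * max(norm_ssp, 1.0) else 1.0
    state.H_mean = alpha * state.H_mean
    state.c_mean = state.c_mean / alpha
    state.c2_mean = state.c_mean**2 + np.diag(state.phi_inv) / alpha**2

    # Map back to input units
    cleaned_full = np.zeros_like(B_full)
    cleaned_full[act] = sd[act, None] * resid_std if opts.standardize else resid_std
    cleaned = Recording(cleaned_full, rec.fs, tuple(ids), active_mask=mask)

    gains_full = np.full(rec.n_channels, np.nan)
    g = sd[act] * state.c_mean if opts.standardize else state.c_mean.copy()
    # relative gains: unit RMS, mean made nonnegative (the overall scale and
    # joint sign of C and H are not identifiable from the data)
    g_rms = float(np.sqrt(np.mean(g**2)))
    if g_rms > 0:
        g = g / g_rms
    if g.mean() < 0:
        g = -g
    gains_full[act] = g
    rejected = tuple(ids[i] for i in range(rec.n_channels) if rec.active_mask[i] and not mask[i])

    return VBResult(
        state=state,
        free_energy_trace=trace,
        restart_iterations=restarts,
        n_iterations=n_iter_total,
        rejected_channels=rejected,
        alpha=alpha,
        projector=projector,
        converged=converged,
        gains=GainVector(gains_full, "vbcssp"),
        cleaned=cleaned,
        active_mask=mask,
    )


def windowed_vbcssp(
    rec: Recording,
    S: HarmonicBasis,
    window_seconds: float,
    K: np.ndarray | None = None,
    opts: VBOptions | None = None,
) -> tuple[Recording, list[GainVector], list[VBResult]]:
    """Fit VBCSSP on non-overlapping temporal windows and concatenate.

    Short windows let the static-gain model track slowly varying gains: each
    segment is fit independently and its cleaned data concatenated in order.
    A trailing partial segment is processed if it has at least 2N samples,
    otherwise appended unprocessed with a warning.

    Unless options are supplied, negative-gain rejection is disabled here:
    a slowly oscillating gain legitimately passes through zero, so a negative
    quasi-static gain inside a window is signal to be tracked, not a flipped
    sensor to be discarded (the heuristic remains appropriate for static
    full-record fits).
    """
    if opts is None:
        opts = VBOptions(reject_negative_gains=False)
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    N = S.n_components
    win = int(round(window_seconds * rec.fs))
    if win > rec.n_samples:
        warnings.warn(
            "window longer than recording; fitting a single window",
            RuntimeWarning,
            stacklevel=2,
        )
        win = rec.n_samples
    if win < 2 * N:
        warnings.warn(
            f"window of {win} samples is short relative to the basis size "
            f"(2N = {2 * N}); estimates may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    starts = list(range(0, rec.n_samples - win + 1, win))
    segments: list[np.ndarray] = []
    gains: list[GainVector] = []
    results: list[VBResult] = []
    mask_all = np.ones(rec.n_channels, bool)

    def _fit_segment(seg_data: np.ndarray) -> VBResult:
        seg = Recording(seg_data, rec.fs, rec.channel_ids, rec.active_mask)
        prev_gains = gains[-1].c if gains else None
        res = vbcssp_fit(seg, S, K=K, opts=opts, init_gains=prev_gains)
        # The (C, H) -> (-C, -H) gauge symmetry leaves each window's sign
        # arbitrary; gains vary slowly, so align each window with the last.
        if gains:
            prev = gains[-1].c
            both = np.isfinite(prev) & np.isfinite(res.gains.c)
            if both.any() and float(prev[both] @ res.gains.c[both]) < 0:
                res.state.c_mean *= -1.0
                res.state.H_mean *= -1.0
                object.__setattr__(res.gains, "c", -res.gains.c)
        return res

    for s0 in starts:
        res = _fit_segment(rec.B[:, s0 : s0 + win])
        segments.append(res.cleaned.B)
        gains.append(res.gains)
        results.append(res)
        mask_all &= res.active_mask
    tail0 = starts[-1] + win
    if tail0 < rec.n_samples:
        n_tail = rec.n_samples - tail0
        if n_tail >= 2 * N:
            res = _fit_segment(rec.B[:, tail0:])
            segments.append(res.cleaned.B)
            gains.append(res.gains)
            results.append(res)
            mask_all &= res.active_mask
        else:
            warnings.warn(
                f"trailing {n_tail} samples too short to fit; passed through",
                RuntimeWarning,
                stacklevel=2,
            )
            segments.append(rec.B[:, tail0:])
    cleaned = Recording(
        np.concatenate(segments, axis=1), rec.fs, rec.channel_ids, active_mask=mask_all
    )
    return cleaned, gains, results


def select_order(
    rec: Recording,
    array: SensorArray,
    candidate_orders: list[int],
    K: np.ndarray | None = None,
    opts: VBOptions | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose the harmonic order maximising the converged free energy.

    Runs a full VBCSSP fit per candidate order and returns the order with the
    highest converged free energy (ties broken toward the smallest order),
    together with the free energy per candidate.
    """
    if not candidate_orders:
        raise ValueError("need at least one candidate order")
    energies: dict[int, float] = {}
    for L in sorted(set(int(x) for x in candidate_orders)):
        try:
            basis = regular_harmonic_basis(array, L)
            res = vbcssp_fit(rec, basis, K=K, opts=opts)
            energies[L] = res.free_energy
        except Exception as exc:  # noqa: BLE001 - candidate exclusion is the contract
            warnings.warn(f"order {L} failed ({exc}); excluded", RuntimeWarning, stacklevel=2)
    if not energies:
        raise RuntimeError("all candidate orders failed")
    best = max(energies, key=lambda L: (energies[L], -L))
    return best, energies
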