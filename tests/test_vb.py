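"""VB machinery: scalar oracles for the closed-form updates, coordinate-ascent
monotonicity, the SSP reduction limit, the norm correction, channel rejection
and windowed application."""

import numpy as np
import pytest

from vbcssp.harmonics import HarmonicBasis, regular_harmonic_basis
from vbcssp.projection import Recording, ssp_fit
from vbcssp.simulate import SimConfig, simulate
from vbcssp.vb import (
    TooManyRejectionsError,
    VBOptions,
    VBState,
    c_step,
    free_energy,
    h_step,
    select_order,
    update_hyperparameters,
    vbcssp_fit,
    windowed_vbcssp,
)

SQ2 = np.sqrt(2.0)


@pytest.fixture()
def toy():
    """2 channels, 1 basis column, 2 samples — every update is scalar arithmetic."""
    S = np.array([[1.0], [1.0]]) / SQ2
    B = np.array([[1.0, 2.0], [1.0, 2.0]])
    state = VBState.initialize(2, 1, 2)
    state.c2_mean = np.ones(2)  # toy condition: C2bar = I exactly
    return state, B, S


class TestUpdateOracles:
    def test_h_step_scalar_oracle(self, toy):
        state, B, S = toy
        h_step(state, B, S)
        # gamma = lam * s'C2 s + 1 = (1/2 + 1/2) + 1
        assert np.allclose(state.gamma, [[2.0]])
        # h(t) = gamma^-1 s'C b(t) = (b1 + b2) / (2 sqrt(2))
        assert np.allclose(state.H_mean, [[1.0 / SQ2, SQ2]])
        # Rhh = T/gamma + sum h^2 = 1 + 1/2 + 2
        assert np.allclose(state.Rhh, [[3.5]])
        # Rhb_m = sum_t h(t) b_m(t) = 1/sqrt2 + 2*sqrt2
        assert np.allclose(state.Rhb, [[5.0 / SQ2, 5.0 / SQ2]])

    def test_c_step_scalar_oracle(self, toy):
        state, B, S = toy
        h_step(state, B, S)
        c_step(state, B, S)
        # Phi = diag(s_m^2 Rhh) + D = 3.5/2 + 1
        assert np.allclose(np.diag(state.phi), [2.75, 2.75])
        # c_m = (s_m Rhb_m) / Phi_mm = 2.5 / 2.75
        assert np.allclose(state.c_mean, [10.0 / 11.0, 10.0 / 11.0])
        assert np.allclose(state.c2_mean, state.c_mean**2 + 1.0 / 2.75)

    def test_hyperparameter_scalar_oracle(self, toy):
        state, B, S = toy
        h_step(state, B, S)
        c_step(state, B, S)
        update_hyperparameters(state, B, S)
        c = 10.0 / 11.0
        c2 = c * c + 1.0 / 2.75
        # expanded residual: sum b'b - 2 sum b'CSh + tr(S'C2S Rhh), TM = 4
        lam_inv = (10.0 - 2.0 * 5.0 * c + 3.5 * c2) / 4.0
        assert np.isclose(1.0 / state.lambda_, lam_inv)
        rho = (2.0 / 2.75 + 2.0 * c * c) / 4.0  # tr(Phi^-1 + cc') / (2M)
        assert np.isclose(state.rho, rho)

    def test_h_step_high_precision_limit(self, rng, array45):
        """With unit gains and lambda -> inf the amplitude mean tends to S+ B."""
        basis = regular_harmonic_basis(array45, 2)
        B = rng.normal(size=(45, 50))
        state = VBState.initialize(45, 8, 50)
        state.c2_mean = np.ones(45)
        state.lambda_ = 1e12
        h_step(state, B, basis.S)
        expected = np.linalg.pinv(basis.S) @ B
        assert np.allclose(state.H_mean, expected, rtol=1e-4, atol=1e-8)

    def test_h_step_zero_data(self, array45):
        basis = regular_harmonic_basis(array45, 1)
        state = VBState.initialize(45, 3, 20)
        h_step(state, np.zeros((45, 20)), basis.S)
        assert np.allclose(state.H_mean, 0.0)
        assert np.allclose(state.Rhh, 20 * state.gamma_inv)

    def test_strong_zero_prior_shrinks_gains(self, rng, array45):
        """rho -> 0 means an infinitely strong N(0, rho K) prior: gains -> 0."""
        basis = regular_harmonic_basis(array45, 1)
        B = rng.normal(size=(45, 100))
        state = VBState.initialize(45, 3, 100)
        state.rho = 1e-12
        h_step(state, B, basis.S)
        c_step(state, B, basis.S)
        assert np.abs(state.c_mean).max() < 1e-6

    def test_rho_plugin_value(self):
        """K = I, Phi^-1 = I, c = 0 gives rho = M / (2M) = 1/2."""
        M = 7
        state = VBState.initialize(M, 2, 10)
        state.c_mean = np.zeros(M)
        state.phi_inv = np.eye(M)
        state.Rhh = np.zeros((2, 2))
        state.H_mean = np.zeros((2, 10))
        update_hyperparameters(state, np.zeros((M, 10)), np.zeros((M, 2)))
        assert np.isclose(state.rho, 0.5)

    def test_lambda_floor_in_exact_fit(self, rng, array45):
        """A residual-free configuration floors lambda^-1 instead of dividing by 0."""
        basis = regular_harmonic_basis(array45, 1)
        H = rng.normal(size=(3, 40))
        state = VBState.initialize(45, 3, 40)
        state.c2_mean = np.ones(45)
        state.H_mean = H
        state.Rhh = H @ H.T  # no posterior-covariance term
        B = basis.S @ H  # exactly C S H with C = I
        update_hyperparameters(state, B, basis.S)
        assert state.lambda_ <= 1.0 / 1e-12 + 1
        assert state.lambda_ > 1e10


class TestFit:
    def test_free_energy_monotone_random_data(self, array_small):
        """Coordinate ascent never decreases the free energy, even on
        unstructured data (rejection disabled: white noise has no
        interference subspace, so gain signs are arbitrary)."""
        basis = regular_harmonic_basis(array_small, 2)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            rec = Recording(rng.normal(size=(15, 300)), 500.0)
            res = vbcssp_fit(
                rec, basis, opts=VBOptions(max_iter=60, reject_negative_gains=False)
            )
            f = np.asarray(res.free_energy_trace)
            assert (np.diff(f) >= -1e-6 * np.abs(f[:-1])).all()

    def test_gain_recovery_static(self, static_sim, basis3):
        res = vbcssp_fit(static_sim.recording, basis3)
        c_hat = res.gains.c
        c_true = static_sim.C_true.c
        r = np.corrcoef(c_true, c_hat)[0, 1]
        assert r > 0.9
        assert res.converged

    def test_norm_correction_scale_duality(self, static_sim, basis3):
        """After the correction ||H|| matches the SSP amplitudes and the
        interference field estimate C S H is unchanged (checked via the
        cleaned output equalling B - C S H in standardised space)."""
        res = vbcssp_fit(static_sim.recording, basis3)
        rec = static_sim.recording
        sd = rec.B.std(axis=1)
        B_std = (rec.B - rec.B.mean(axis=1, keepdims=True)) / sd[:, None]
        H_ssp = np.linalg.pinv(basis3.S) @ B_std
        assert np.isclose(
            np.linalg.norm(res.state.H_mean), np.linalg.norm(H_ssp), rtol=1e-8
        )
        # corrected C and H reproduce the same interference estimate
        resid = B_std - (res.state.c_mean[:, None] * basis3.S) @ res.state.H_mean
        assert np.allclose(sd[:, None] * resid, res.cleaned.B, rtol=1e-10, atol=1e-8)

    def test_reduces_to_ssp_with_frozen_unit_gains(self, rng, array45):
        """Unit gains, C2 = I and a huge lambda make the VB projector the SSP one."""
        basis = regular_harmonic_basis(array45, 2)
        B = rng.normal(size=(45, 100))
        state = VBState.initialize(45, 8, 100)
        state.c2_mean = np.ones(45)
        state.lambda_ = 1e10
        h_step(state, B, basis.S)
        CS = state.c_mean[:, None] * basis.S
        P_vb = np.eye(45) - state.lambda_ * (CS @ state.gamma_inv @ CS.T)
        P_ssp = ssp_fit(basis).P
        assert np.linalg.norm(P_vb - P_ssp) < 1e-3

    def test_underdetermined_order_six_is_solvable(self):
        """N = 48 > M = 45 still yields a finite fit thanks to the L2 prior."""
        truth = simulate(SimConfig(L_true=6, sigma_C=0.05, T=3000, seed=4))
        basis = regular_harmonic_basis(truth.array, 6)
        with pytest.warns(RuntimeWarning):  # the internal SSP comparison warns
            res = vbcssp_fit(truth.recording, basis)
        assert np.isfinite(res.free_energy)
        assert np.isfinite(res.projector.P).all()

    def test_flipped_channel_rejected(self):
        truth = simulate(SimConfig(L_true=2, sigma_C=0.05, T=4000, seed=3))
        B = truth.B.copy()
        B[7] *= -1.0
        rec = Recording(B, truth.recording.fs, truth.recording.channel_ids)
        basis = regular_harmonic_basis(truth.array, 2)
        with pytest.warns(RuntimeWarning, match="rejected"):
            res = vbcssp_fit(rec, basis)
        assert truth.recording.channel_ids[7] in res.rejected_channels
        assert not res.active_mask[7]

    def test_mass_rejection_aborts(self):
        truth = simulate(SimConfig(L_true=1, sigma_C=0.05, T=2000, seed=5))
        B = truth.B.copy()
        B[: 20] *= -1.0  # 20 of 45 channels inverted
        rec = Recording(B, truth.recording.fs, truth.recording.channel_ids)
        basis = regular_harmonic_basis(truth.array, 1)
        with pytest.raises(TooManyRejectionsError):
            vbcssp_fit(rec, basis)

    def test_free_energy_scale_shift_preserves_ranking(self, static_sim):
        """Rescaling the data (units change) must not change which order wins."""
        rec = static_sim.recording
        rec2 = Recording(2.0 * rec.B, rec.fs, rec.channel_ids)
        best1, F1 = select_order(rec, static_sim.array, [2, 3, 4])
        best2, F2 = select_order(rec2, static_sim.array, [2, 3, 4])
        assert best1 == best2 == 3
        assert max(F1, key=F1.get) == max(F2, key=F2.get)


class TestWindowed:
    def test_full_window_equals_single_fit(self, static_sim, basis3):
        opts = VBOptions()
        cleaned, gains, results = windowed_vbcssp(
            static_sim.recording, basis3, window_seconds=static_sim.recording.duration,
            opts=opts,
        )
        single = vbcssp_fit(static_sim.recording, basis3, opts=opts)
        assert len(results) == 1
        assert np.allclose(cleaned.B, single.cleaned.B)

    def test_window_longer_than_recording_falls_back(self, static_sim, basis3):
        with pytest.warns(RuntimeWarning, match="longer than recording"):
            _, _, results = windowed_vbcssp(
                static_sim.recording, basis3, window_seconds=1e6
            )
        assert len(results) == 1

    def test_short_trailing_segment_passed_through(self, array_small):
        basis = regular_harmonic_basis(array_small, 1)
        rng = np.random.default_rng(2)
        T = 1005  # 2 windows of 500 + 5-sample tail < 2N
        rec = Recording(rng.normal(size=(15, T)), 100.0)
        with pytest.warns(RuntimeWarning, match="passed through"):
            cleaned, gains, results = windowed_vbcssp(rec, basis, window_seconds=5.0)
        assert cleaned.n_samples == T
        assert len(results) == 2
        assert np.array_equal(cleaned.B[:, -5:], rec.B[:, -5:])


class TestOrderSelection:
    def test_single_candidate_returned(self, static_sim):
        best, F = select_order(static_sim.recording, static_sim.array, [2])
        assert best == 2
        assert set(F) == {2}

    def test_recovers_true_order(self, static_sim):
        best, F = select_order(static_sim.recording, static_sim.array, [2, 3, 4])
        assert best == 3
        assert F[3] > F[2] and F[3] > F[4]

    def test_empty_candidates_rejected(self, static_sim):
        with pytest.raises(ValueError):
            select_order(static_sim.recording, static_sim.array, [])
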