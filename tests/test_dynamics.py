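"""Wavepacket propagation: closed forms, dense oracle, conservation laws."""

import numpy as np
import pytest

from lvckit._constants import HBAR_EV_FS
from lvckit.dynamics import (
    build_hamiltonian,
    diabatic_populations,
    initial_wavepacket,
    pes_expectations,
    propagate,
    reduce_modes,
)
from lvckit.model import DiabaticStateMeta, LVCModel, NormalModeBasis
from lvckit.synthetic import make_truth_model


def electronic_only_model(e11=5.0, e22=5.0, c=0.05):
    """Two electronic states, one spectator mode without any coupling."""
    modes = NormalModeBasis(frequencies=np.array([0.2]))
    states = (DiabaticStateMeta(label="a"), DiabaticStateMeta(label="b"))
    return LVCModel(
        modes=modes, states=states,
        constant_matrix=np.array([[e11, c], [c, e22]]),
        couplings=np.zeros((2, 2, 1)),
    )


def dense_oracle_populations(model, psi0, times):
    """Eigendecomposition propagation: independent of the package's
    propagators, exact on the truncated basis."""
    h = build_hamiltonian(model, psi0.n_max).toarray()
    evals, evecs = np.linalg.eigh(h)
    c0 = evecs.conj().T @ psi0.flat()
    n = model.n_states
    pops = np.empty((len(times), n))
    for k, t in enumerate(times):
        psi_t = evecs @ (np.exp(-1j * evals * t / HBAR_EV_FS) * c0)
        pops[k] = np.sum(np.abs(psi_t.reshape(n, -1)) ** 2, axis=1)
    return pops


class TestInitialWavepacket:
    def test_population_starts_on_requested_state(self, two_state_two_mode):
        psi = initial_wavepacket(two_state_two_mode, 1, (6, 6))
        block = psi.coefficients
        assert abs(block[1, 0, 0]) == 1.0
        assert np.sum(np.abs(block[0]) ** 2) == 0.0
        assert psi.norm() == pytest.approx(1.0, abs=1e-15)

    def test_vacuum_position_moments(self, two_state_two_mode):
        """<q> = 0 and <q^2> = 1/2 per mode for the oscillator vacuum."""
        from lvckit.dynamics import _embed, _q2_operator, _q_operator

        psi = initial_wavepacket(two_state_two_mode, 0, (8, 8))
        vib = psi.coefficients[0].reshape(-1)
        for a in range(2):
            q_op = _embed(_q_operator(8), (8, 8), a)
            q2_op = _embed(_q2_operator(8), (8, 8), a)
            assert np.vdot(vib, q_op @ vib).real == pytest.approx(0.0, abs=1e-15)
            assert np.vdot(vib, q2_op @ vib).real == pytest.approx(0.5, abs=1e-15)

    def test_zero_point_pes_expectation(self, two_state_two_mode):
        """<V_ii> at t=0 is E_ii(0) + sum_a w_a / 4."""
        m = two_state_two_mode
        res = propagate(m, initial_wavepacket(m, 1, (6, 6)), t_final=1.0, dt=0.5)
        expected = m.constant_matrix[1, 1] + 0.25 * np.sum(m.modes.frequencies)
        assert res.pes_expectations[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_state_label_lookup_and_errors(self, two_state_two_mode):
        psi = initial_wavepacket(two_state_two_mode, "b", (4, 4))
        assert abs(psi.coefficients[1, 0, 0]) == 1.0
        with pytest.raises(IndexError):
            initial_wavepacket(two_state_two_mode, 5, (4, 4))


class TestPropagateClosedForms:
    def test_uncoupled_model_has_constant_populations(self):
        modes = NormalModeBasis(frequencies=np.array([0.2]))
        states = (DiabaticStateMeta(label="a"), DiabaticStateMeta(label="b"))
        lam = np.zeros((2, 2, 1))
        lam[0, 0, 0] = 0.1
        lam[1, 1, 0] = -0.05
        m = LVCModel(modes=modes, states=states,
                     constant_matrix=np.diag([5.0, 5.3]), couplings=lam)
        res = propagate(m, initial_wavepacket(m, 0, (12,)), t_final=50.0, dt=1.0)
        np.testing.assert_allclose(res.populations[:, 0], 1.0, atol=1e-12)

    def test_rabi_oscillation_closed_form(self):
        c = 0.05
        m = electronic_only_model(c=c)
        res = propagate(m, initial_wavepacket(m, 0, (1,)), t_final=100.0, dt=0.5)
        expected = np.sin(c * res.times / HBAR_EV_FS) ** 2
        np.testing.assert_allclose(res.populations[:, 1], expected, atol=1e-10)

    @pytest.mark.parametrize("method", ["lanczos", "chebyshev", "expm"])
    def test_methods_agree_with_dense_oracle(self, two_state_two_mode, method):
        psi0 = initial_wavepacket(two_state_two_mode, 1, (8, 8))
        res = propagate(two_state_two_mode, psi0, t_final=40.0, dt=0.5, method=method)
        oracle = dense_oracle_populations(two_state_two_mode, psi0, res.times)
        assert np.abs(res.populations - oracle).max() < 1e-9

    def test_basis_convergence(self, two_state_two_mode):
        """Doubling every n_max changes populations by < 1e-6."""
        m = two_state_two_mode
        r1 = propagate(m, initial_wavepacket(m, 1, (12, 12)), t_final=60.0, dt=1.0)
        r2 = propagate(m, initial_wavepacket(m, 1, (24, 24)), t_final=60.0, dt=1.0)
        assert np.abs(r1.populations - r2.populations).max() < 1e-6


class TestConservationLaws:
    @pytest.fixture(scope="class")
    def result(self):
        m = make_truth_model(4, 2, seed=3)
        m, _ = reduce_modes(m, 2)
        return m, propagate(m, initial_wavepacket(m, 0, (8, 8)), t_final=250.0, dt=2.5)

    def test_norm_conserved(self, result):
        _, res = result
        np.testing.assert_allclose(res.norms, 1.0, atol=1e-9)

    def test_populations_sum_to_one(self, result):
        _, res = result
        np.testing.assert_allclose(res.populations.sum(axis=1), 1.0, atol=1e-8)

    def test_energy_conserved(self, result):
        _, res = result
        assert np.abs(res.energy - res.energy[0]).max() < 1e-8

    def test_time_reversal_returns_initial_state(self, result):
        m, res = result
        back = propagate(m, res.final_state, t_final=-250.0, dt=2.5)
        psi0 = initial_wavepacket(m, 0, (8, 8))
        overlap = abs(np.vdot(psi0.flat(), back.final_state.flat()))
        assert overlap == pytest.approx(1.0, abs=1e-7)

    def test_autocorrelation_conjugate_symmetry(self, result):
        """C(-t) = C(t)* for a real initial state and real Hamiltonian."""
        m, res = result
        psi0 = initial_wavepacket(m, 0, (8, 8))
        rev = propagate(m, psi0, t_final=-50.0, dt=2.5)
        fwd = propagate(m, psi0, t_final=50.0, dt=2.5)
        np.testing.assert_allclose(
            rev.autocorrelation, np.conj(fwd.autocorrelation), atol=1e-9
        )


class TestObservables:
    def test_pes_masked_on_empty_states(self, two_state_two_mode):
        m = electronic_only_model(c=0.0)  # no transfer at all
        res = propagate(m, initial_wavepacket(m, 0, (4,)), t_final=5.0, dt=1.0)
        assert np.all(res.pes_expectations.mask[:, 1])
        assert not np.any(res.pes_expectations.mask[:, 0])

    def test_undisplaced_uncoupled_pes_constant_in_time(self):
        """With no interstate coupling and no intrastate gradient the
        initial vacuum is stationary, so every unmasked PES expectation
        stays at its zero-point value."""
        modes = NormalModeBasis(frequencies=np.array([0.25, 0.1]))
        states = (DiabaticStateMeta(label="a"), DiabaticStateMeta(label="b"))
        m = LVCModel(modes=modes, states=states,
                     constant_matrix=np.diag([5.0, 5.4]),
                     couplings=np.zeros((2, 2, 2)))
        res = propagate(m, initial_wavepacket(m, 0, (6, 6)), t_final=40.0, dt=2.0)
        expected = 5.0 + 0.25 * np.sum(modes.frequencies)
        np.testing.assert_allclose(res.pes_expectations[:, 0], expected, atol=1e-10)

    def test_population_tables_carry_state_labels(self, two_state_two_mode):
        res = propagate(
            two_state_two_mode, initial_wavepacket(two_state_two_mode, 0, (4, 4)),
            t_final=2.0, dt=1.0,
        )
        pops = diabatic_populations(res, two_state_two_mode)
        pes = pes_expectations(res, two_state_two_mode)
        assert list(pops.columns) == ["time_fs", "a", "b"]
        assert list(pes.columns) == ["time_fs", "a", "b"]
        np.testing.assert_allclose(pops[["a", "b"]].sum(axis=1), 1.0, atol=1e-10)

    def test_total_pes_convention_available(self, two_state_two_mode):
        m = two_state_two_mode
        res = propagate(m, initial_wavepacket(m, 0, (6, 6)), t_final=2.0, dt=1.0,
                        pes_convention="total")
        assert res.metadata["pes_convention"] == "total"
        # total = conditional * population at t=0 where P=1
        expected = m.constant_matrix[0, 0] + 0.25 * np.sum(m.modes.frequencies)
        assert res.pes_expectations[0, 0] == pytest.approx(expected, abs=1e-12)


class TestGuards:
    def test_basis_cap_enforced(self, two_state_two_mode):
        psi0 = initial_wavepacket(two_state_two_mode, 0, (40, 40))
        with pytest.raises(ValueError, match="exceeds cap"):
            propagate(two_state_two_mode, psi0, t_final=1.0, dt=1.0, max_basis_size=100)

    def test_reduce_modes_keeps_strongest_coupled(self):
        m = make_truth_model(4, 6, seed=1)
        red, kept = reduce_modes(m, 3)
        score = np.sum(m.couplings**2, axis=(0, 1))
        assert set(kept) == set(np.argsort(score)[::-1][:3])
        np.testing.assert_array_equal(red.modes.frequencies, m.modes.frequencies[kept])
        np.testing.assert_array_equal(red.couplings, m.couplings[:, :, kept])
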