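"""Displacement protocol, finite-difference couplings, model assembly."""

import numpy as np
import pytest

from lvckit.diabatize import diabatize_record
from lvckit.model import NormalModeBasis, adiabatic_energies, potential_matrix
from lvckit.parametrize import (
    DisplacementProtocol,
    build_lvc_model,
    displacement_grid,
    finite_difference_couplings,
    lvc_validity_diagnostic,
)
from lvckit.synthetic import TruthSpec, generate_record, generate_records, make_truth_model


def pipeline(truth, delta=0.1, strategy="FrD", **spec_kwargs):
    spec = TruthSpec(truth=truth, **spec_kwargs)
    protocol = displacement_grid(truth.modes, delta)
    records = generate_records(spec, protocol)
    return build_lvc_model(
        records, truth.n_states, strategy, protocol=protocol, modes=truth.modes
    )


class TestDisplacementGrid:
    def test_two_mode_tags(self):
        modes = NormalModeBasis(frequencies=np.array([0.1, 0.2]))
        p = displacement_grid(modes, 0.1)
        assert p.tags == ("FC", "m1+", "m1-", "m2+", "m2-")
        geoms = dict(p.geometries())
        np.testing.assert_array_equal(geoms["FC"], [0.0, 0.0])
        np.testing.assert_array_equal(geoms["m2-"], [0.0, -0.1])

    def test_per_mode_magnitudes(self):
        modes = NormalModeBasis(frequencies=np.array([0.1, 0.2]))
        p = displacement_grid(modes, np.array([0.1, 0.2]))
        geoms = dict(p.geometries())
        assert geoms["m1+"][0] == 0.1
        assert geoms["m2+"][1] == 0.2

    def test_nonpositive_delta_rejected(self):
        modes = NormalModeBasis(frequencies=np.array([0.1]))
        with pytest.raises(ValueError, match="positive"):
            displacement_grid(modes, 0.0)


class TestFiniteDifferences:
    def test_exact_on_lvc_truth(self, truth_small):
        """Central differences are exact on a quadratic-diagonal /
        linear-off-diagonal potential."""
        model, _ = pipeline(truth_small)
        np.testing.assert_allclose(model.couplings, truth_small.couplings, atol=1e-8)
        np.testing.assert_allclose(
            model.constant_matrix, truth_small.constant_matrix, atol=1e-10
        )

    def test_symmetry_forbidden_couplings_stay_zero(self, truth_paper_size):
        m = truth_paper_size
        model, _ = pipeline(m)
        anti = np.array([s.symmetry == "Adoubleprime" for s in m.states])
        mode_anti = np.array([lab == 'a"' for lab in m.modes.symmetry])
        forbidden = (anti[:, None] ^ anti[None, :])[:, :, None] ^ mode_anti[None, None, :]
        assert np.abs(model.couplings[forbidden]).max() < 1e-10

    def test_cubic_contamination_converges_quadratically(self):
        """A c*q^3 diagonal term biases the gradient by c*d^2: halving the
        step must reduce the bias by ~4 (Richardson ratio)."""
        truth = make_truth_model(n_states=2, n_modes=1, seed=2)
        c = 0.05

        def diabatic_h(q, delta_tag):
            v = potential_matrix(truth, q).astype(float)
            v[0, 0] += c * q[0] ** 3
            return v

        errs = {}
        for d in (0.2, 0.1):
            hp = np.array([diabatic_h(np.array([d]), "+")])
            hm = np.array([diabatic_h(np.array([-d]), "-")])
            proto = displacement_grid(truth.modes, d)
            lam = finite_difference_couplings(hp, hm, proto)
            errs[d] = abs(lam[0, 0, 0] - truth.couplings[0, 0, 0])
        ratio = errs[0.2] / errs[0.1]
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_missing_geometry_raises(self, truth_small):
        proto = displacement_grid(truth_small.modes, 0.1)
        with pytest.raises(ValueError, match="per sign"):
            finite_difference_couplings(
                np.zeros((truth_small.n_modes - 1, 4, 4)),
                np.zeros((truth_small.n_modes, 4, 4)),
                proto,
            )

    def test_recovered_couplings_symmetric(self, truth_small):
        model, _ = pipeline(truth_small)
        np.testing.assert_array_equal(
            model.couplings, model.couplings.transpose(1, 0, 2)
        )


class TestValidityDiagnostic:
    def test_exact_truth_reports_harmonic_curvature(self, truth_small):
        proto = displacement_grid(truth_small.modes, 0.1)
        spec = TruthSpec(truth=truth_small)
        h_fc = potential_matrix(truth_small, np.zeros(truth_small.n_modes))
        hp, hm = [], []
        for a in range(truth_small.n_modes):
            for sign, acc in ((+1, hp), (-1, hm)):
                q = np.zeros(truth_small.n_modes)
                q[a] = sign * 0.1
                rec = generate_record(spec, q, proto.tag(a, sign))
                acc.append(diabatize_record(rec).H_diabatic)
        report = lvc_validity_diagnostic(
            np.array(hp), np.array(hm), h_fc, truth_small.modes, proto
        )
        np.testing.assert_allclose(report["diag_curvature_dev_ev"], 0.0, atol=1e-8)
        np.testing.assert_allclose(report["offdiag_curvature_ev"], 0.0, atol=1e-8)
        assert not report["flagged"].any()

    def test_cubic_contamination_flagged(self):
        truth = make_truth_model(n_states=2, n_modes=1, seed=2)
        d = 0.3
        h_fc = potential_matrix(truth, np.zeros(1))
        hp = potential_matrix(truth, np.array([d]))
        hm = potential_matrix(truth, np.array([-d]))
        hp[0, 0] += 1.5 * d**2  # quadratic excess on the diagonal
        proto = displacement_grid(truth.modes, d)
        report = lvc_validity_diagnostic(
            hp[None], hm[None], h_fc, truth.modes, proto, threshold=0.01
        )
        assert report["flagged"].iloc[0]


class TestBuildLVCModel:
    def test_st_strategy_zeroes_constant_couplings(self, truth_small):
        model, _ = pipeline(truth_small, strategy="St",
                            embedding_shift=np.zeros(truth_small.n_states))
        off = model.constant_matrix - np.diag(np.diag(model.constant_matrix))
        np.testing.assert_array_equal(off, 0.0)

    def test_st_diagonal_is_adiabatic_energies(self, truth_small):
        model, _ = pipeline(truth_small, strategy="St",
                            embedding_shift=np.zeros(truth_small.n_states))
        expected = adiabatic_energies(truth_small, np.zeros(truth_small.n_modes))
        np.testing.assert_allclose(np.diag(model.constant_matrix), expected, atol=1e-12)

    def test_full_recovery_on_paper_size_truth(self, truth_paper_size):
        model, results = pipeline(truth_paper_size)
        np.testing.assert_allclose(
            model.constant_matrix, truth_paper_size.constant_matrix, atol=1e-10
        )
        np.testing.assert_allclose(model.couplings, truth_paper_size.couplings, atol=1e-8)
        # the full adiabatic set spans every reference state exactly
        np.testing.assert_allclose(results["FC"].completeness, 1.0, atol=1e-12)

    def test_mixed_references_drop_weights_and_bound_error(self, truth_paper_size):
        model, results = pipeline(truth_paper_size, reference_mixing_angle=0.05, seed=3)
        assert np.all(results["FC"].weights < 1.0)
        err = np.abs(model.constant_matrix - truth_paper_size.constant_matrix).max()
        assert 0 < err < 0.1  # perturbation-bounded, not exact

    def test_recovery_error_monotone_in_mixing_angle(self, truth_paper_size):
        errs = []
        for theta in (0.0, 0.01, 0.02, 0.04):
            model, _ = pipeline(truth_paper_size, reference_mixing_angle=theta, seed=3)
            errs.append(np.abs(model.constant_matrix - truth_paper_size.constant_matrix).max())
        assert all(b >= a - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_truncated_adiabatic_set_lowers_completeness(self, truth_paper_size):
        """Dropping high adiabatic states leaves the (fewer) reference
        states incompletely spanned, and the recovery error stays bounded
        by the truncation weight."""
        n = truth_paper_size.n_states
        n_model = n - 4
        spec = TruthSpec(truth=truth_paper_size, n_adiabatic_out=n - 2,
                         n_reference_out=n_model)
        proto = displacement_grid(truth_paper_size.modes, 0.1)
        records = generate_records(spec, proto)
        model, results = build_lvc_model(
            records, n_model, "FrD", protocol=proto, modes=truth_paper_size.modes
        )
        comp = results["FC"].completeness
        assert np.all(comp <= 1.0 + 1e-12)
        assert np.any(comp < 1.0 - 1e-9)
        err = np.abs(
            model.constant_matrix - truth_paper_size.constant_matrix[:n_model, :n_model]
        ).max()
        assert err < 0.2

    def test_missing_record_raises_with_tag(self, truth_small):
        spec = TruthSpec(truth=truth_small)
        proto = displacement_grid(truth_small.modes, 0.1)
        records = generate_records(spec, proto)[:-1]
        with pytest.raises(ValueError, match="m3-"):
            build_lvc_model(records, truth_small.n_states, "FrD",
                            protocol=proto, modes=truth_small.modes)

    def test_inconsistent_state_counts_rejected(self, truth_small):
        spec = TruthSpec(truth=truth_small)
        proto = displacement_grid(truth_small.modes, 0.1)
        records = generate_records(spec, proto)
        records[1].overlap = records[1].overlap[:-1]
        with pytest.raises(ValueError, match="reference"):
            build_lvc_model(records, truth_small.n_states, "FrD",
                            protocol=proto, modes=truth_small.modes)
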