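"""Linear vibronic coupling (LVC) model Hamiltonians.

An LVC model describes ``N`` coupled diabatic electronic states on top of
the harmonic ground-state surface of a molecule with ``F`` normal modes.
In dimensionless normal-mode coordinates ``q`` the diabatic potential
matrix is

    V_ii(q) = E_ii(0) + 1/2 * sum_a w_a q_a**2 + lambda_ii . q
    V_ij(q) = E_ij(0) + lambda_ij . q            (i != j)

where ``E(0)`` is the constant diabatic matrix at the reference
(Franck-Condon) geometry, ``w_a`` are the ground-state vibrational quanta
and the ``lambda`` vectors collect intrastate gradients (diagonal) and
linear interstate couplings (off-diagonal).  Constant off-diagonal terms
``E_ij(0)`` appear whenever the diabatic states do not coincide with the
adiabatic states at the reference geometry.

All energies are in eV; coordinates are dimensionless; see
:mod:`lvckit._constants` for the unit system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "NormalModeBasis",
    "DiabaticStateMeta",
    "LVCModel",
    "potential_matrix",
    "adiabatic_energies",
    "diabatic_minimum",
    "reorganization_energy",
]

Character = Literal["LE_pipi", "LE_npi", "CT"]
Irrep = Literal["Aprime", "Adoubleprime"]

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class NormalModeBasis:
    """Ground-state normal modes in the dimensionless-coordinate convention.

    Parameters
    ----------
    frequencies
        Vibrational quanta ``hbar*w_a`` in eV, one per mode, all > 0.
    mode_labels
        Optional human-readable labels (default ``m1 .. mF``).
    symmetry
        Optional per-mode irrep labels (``"a'"`` totally symmetric,
        ``'a"'`` antisymmetric) for Cs-symmetric systems.
    """

    frequencies: np.ndarray
    mode_labels: tuple[str, ...] | None = None
    symmetry: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        if freq.ndim != 1 or freq.size == 0:
            raise ValueError("frequencies must be a non-empty 1-D array")
        if np.any(freq <= 0):
            raise ValueError("all mode frequencies must be strictly positive")
        object.__setattr__(self, "frequencies", freq)
        for name in ("mode_labels", "symmetry"):
            val = getattr(self, name)
            if val is not None:
                val = tuple(val)
                if len(val) != freq.size:
                    raise ValueError(f"{name} must have one entry per mode")
                object.__setattr__(self, name, val)

    @property
    def n_modes(self) -> int:
        return self.frequencies.size

    def labels(self) -> tuple[str, ...]:
        if self.mode_labels is not None:
            return self.mode_labels
        return tuple(f"m{a + 1}" for a in range(self.n_modes))


@dataclass(frozen=True)
class DiabaticStateMeta:
    """Metadata for one diabatic electronic state."""

    label: str
    fragment: str = ""
    character: Character | None = None
    symmetry: Irrep | None = None
    oscillator_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.oscillator_strength < 0:
            raise ValueError("oscillator_strength must be >= 0")


@dataclass
class LVCModel:
    """A complete LVC Hamiltonian.

    Attributes
    ----------
    modes
        The shared :class:`NormalModeBasis`.
    states
        Ordered diabatic-state metadata; length fixes ``N``.
    constant_matrix
        Symmetric ``(N, N)`` diabatic matrix at the reference geometry (eV).
    couplings
        ``(N, N, F)`` array; ``couplings[i, i]`` is the intrastate energy
        gradient, ``couplings[i, j]`` (i != j) the linear interstate
        coupling vector.  Symmetric in ``i <-> j``.
    provenance
        Free-form dict recording how the model was built (diabatization
        weights, completeness, strategy ...); not used numerically.
    """

    modes: NormalModeBasis
    states: tuple[DiabaticStateMeta, ...]
    constant_matrix: np.ndarray
    couplings: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        n = len(self.states)
        f = self.modes.n_modes
        labels = [s.label for s in self.states]
        if len(set(labels)) != n:
            raise ValueError("diabatic state labels must be unique")
        e0 = np.asarray(self.constant_matrix, dtype=float)
        lam = np.asarray(self.couplings, dtype=float)
        if e0.shape != (n, n):
            raise ValueError(f"constant_matrix must be ({n}, {n}), got {e0.shape}")
        if lam.shape != (n, n, f):
            raise ValueError(f"couplings must be ({n}, {n}, {f}), got {lam.shape}")
        if not np.allclose(e0, e0.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValueError("constant_matrix must be symmetric to 1e-12")
        if not np.allclose(lam, lam.transpose(1, 0, 2), atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValueError("couplings must be symmetric in i <-> j")
        self.constant_matrix = 0.5 * (e0 + e0.T)
        self.couplings = 0.5 * (lam + lam.transpose(1, 0, 2))
        self._check_symmetry_selection_rules()

    def _check_symmetry_selection_rules(self) -> None:
        """Cs selection rule: lambda_ij,a may be nonzero only when the
        product of the two state irreps and the mode irrep is totally
        symmetric.  Only enforced when all labels are present."""
        state_sym = [s.symmetry for s in self.states]
        if self.modes.symmetry is None or any(s is None for s in state_sym):
            return
        anti_state = np.array([s == "Adoubleprime" for s in state_sym])
        anti_mode = np.array([lab.strip() in ('a"', "a''", "A''", 'A"') for lab in self.modes.symmetry])
        # parity of the triple product: state_i XOR state_j must equal mode parity
        pair_anti = anti_state[:, None] ^ anti_state[None, :]
        forbidden = pair_anti[:, :, None] ^ anti_mode[None, None, :]
        bad = np.abs(self.couplings) > _SYMMETRY_TOL
        if np.any(bad & forbidden):
            i, j, a = np.argwhere(bad & forbidden)[0]
            raise ValueError(
                "symmetry-forbidden coupling: "
                f"lambda[{self.states[i].label}, {self.states[j].label}, mode {a}] != 0"
            )
        e_forbidden = pair_anti & (np.abs(self.constant_matrix) > _SYMMETRY_TOL)
        np.fill_diagonal(e_forbidden, False)
        if np.any(e_forbidden):
            i, j = np.argwhere(e_forbidden)[0]
            raise ValueError(
                "symmetry-forbidden constant coupling between "
                f"{self.states[i].label} and {self.states[j].label}"
            )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_modes(self) -> int:
        return self.modes.n_modes

    def state_index(self, label: str) -> int:
        for i, s in enumerate(self.states):
            if s.label == label:
                return i
        raise KeyError(f"no diabatic state labelled {label!r}")

    def oscillator_strengths(self) -> np.ndarray:
        return np.array([s.oscillator_strength for s in self.states])


def _check_q(model: LVCModel, q: Sequence[float]) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (model.n_modes,):
        raise ValueError(
            f"coordinate vector has shape {q.shape}, expected ({model.n_modes},)"
        )
    return q


def potential_matrix(model: LVCModel, q: Sequence[float]) -> np.ndarray:
    """Diabatic potential matrix ``V(q)`` in eV.

    The diagonal carries the shared harmonic term plus the state gradient;
    off-diagonal elements are constant plus linear -- there is no harmonic
    contribution off the diagonal.
    """
    q = _check_q(model, q)
    v = model.constant_matrix + model.couplings @ q
    harmonic = 0.5 * float(model.modes.frequencies @ (q * q))
    return v + harmonic * np.eye(model.n_states)


def _fix_eigenvector_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each column positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def adiabatic_energies(
    model: LVCModel, q: Sequence[float], return_vectors: bool = False
):
    """Adiabatic energies (ascending, eV) at ``q``; optionally eigenvectors.

    Eigenvectors are returned as columns, normalized, with the sign fixed
    so that the largest-magnitude component of each is positive -- a
    deterministic convention needed for reproducible weight tables.
    """
    v = potential_matrix(model, q)
    if return_vectors:
        vals, vecs = np.linalg.eigh(v)
        return vals, _fix_eigenvector_signs(vecs)
    return np.linalg.eigvalsh(v)


def diabatic_minimum(model: LVCModel, i: int) -> tuple[np.ndarray, float]:
    """Minimum of the diabatic surface ``V_ii``: closed harmonic form.

    Returns ``(q_min, E_min)`` with ``q_min,a = -lambda_ii,a / w_a`` and
    ``E_min = E_ii(0) - 1/2 sum_a lambda_ii,a**2 / w_a``.
    """
    if not 0 <= i < model.n_states:
        raise IndexError(f"state index {i} out of range for N={model.n_states}")
    lam = model.couplings[i, i]
    w = model.modes.frequencies
    q_min = -lam / w
    e_min = model.constant_matrix[i, i] - 0.5 * float(np.sum(lam * lam / w))
    return q_min, e_min


def reorganization_energy(model: LVCModel, i: int) -> float:
    """Energy drop from the vertical point to state ``i``'s own minimum.

    In the LVC model this is ``1/2 sum_a lambda_ii,a**2 / w_a``.
    """
    if not 0 <= i < model.n_states:
        raise IndexError(f"state index {i} out of range for N={model.n_states}")
    lam = model.couplings[i, i]
    return 0.5 * float(np.sum(lam * lam / model.modes.frequencies))
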