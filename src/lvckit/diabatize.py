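"""Overlap-based diabatization by Löwdin (symmetric) orthogonalization.

Given the overlap matrix ``S`` between ``N`` reference states and ``M >= N``
adiabatic states of the full system, ``S_im = <R_i | a_m>``, the diabatic
states are the orthonormal combinations of adiabatic states closest (in the
least-squares sense) to the reference states:

    D = (S S^T)^(-1/2) S

The rows of ``D`` expand each diabatic state in the adiabatic basis, and the
diabatic Hamiltonian follows by a similarity transform of the diagonal
adiabatic-energy matrix, ``H^D = D diag(E^A) D^T``.

Reference states may be of three kinds, all consumed identically here:
adiabatic states of the full system at the reference geometry (the standard
LVC choice, for which ``S`` is the identity and the constant couplings vanish),
excited states of the isolated fragments (fragment diabatization, FrD), or
fragment states computed in the electrostatic field of the partner fragments
(FrD with MM-embedded references).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectronicStructureRecord",
    "DiabatizationResult",
    "lowdin_transform",
    "diabatic_hamiltonian",
    "reference_weights",
    "phase_align",
    "diabatize_record",
    "RankDeficiencyError",
]

#: eigenvalue floor for S S^T below which the transform is refused
_EIG_FLOOR = 1e-10
_ROW_NORM_TOL = 1e-6


class RankDeficiencyError(np.linalg.LinAlgError):
    """Raised when a reference state is (numerically) outside the span of
    the adiabatic set, making ``(S S^T)^(-1/2)`` ill-defined."""


@dataclass
class ElectronicStructureRecord:
    """Electronic-structure output at one geometry.

    Attributes
    ----------
    geometry_tag
        Deterministic tag of the geometry ("FC", "m3+", "m3-", ...).
    q
        Dimensionless normal-coordinate displacement from the reference.
    adiabatic_energies
        ``M`` adiabatic excitation energies in eV, ascending.
    overlap
        ``(N, M)`` matrix of reference/adiabatic overlaps ``<R_i|a_m>``.
    oscillator_strengths
        Optional per-adiabatic-state oscillator strengths.
    provenance
        Free-form origin tag (backend name, reference strategy ...).
    """

    geometry_tag: str
    q: np.ndarray
    adiabatic_energies: np.ndarray
    overlap: np.ndarray
    oscillator_strengths: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.adiabatic_energies = np.asarray(self.adiabatic_energies, dtype=float)
        self.overlap = np.asarray(self.overlap, dtype=float)
        if self.overlap.ndim != 2:
            raise ValueError("overlap must be a 2-D (N, M) matrix")
        n, m = self.overlap.shape
        if m < n:
            raise ValueError(
                f"need at least as many adiabatic as reference states (N={n}, M={m})"
            )
        if self.adiabatic_energies.shape != (m,):
            raise ValueError("adiabatic_energies length must match overlap columns")
        row_norms = np.sum(self.overlap**2, axis=1)
        if np.any(row_norms > 1.0 + _ROW_NORM_TOL):
            i = int(np.argmax(row_norms))
            raise ValueError(
                f"overlap row {i} has squared norm {row_norms[i]:.6f} > 1; "
                "reference states cannot exceed completeness 1"
            )
        if self.oscillator_strengths is not None:
            self.oscillator_strengths = np.asarray(self.oscillator_strengths, float)
            if self.oscillator_strengths.shape != (m,):
                raise ValueError("oscillator_strengths length must match M")

    @property
    def n_reference(self) -> int:
        return self.overlap.shape[0]

    @property
    def n_adiabatic(self) -> int:
        return self.overlap.shape[1]

    def completeness(self) -> np.ndarray:
        """Squared row norms of S: how much of each reference state the
        adiabatic set spans (1 = fully spanned)."""
        return np.sum(self.overlap**2, axis=1)


@dataclass
class DiabatizationResult:
    """Outcome of diabatizing one record."""

    D: np.ndarray
    H_diabatic: np.ndarray
    weights: np.ndarray
    completeness: np.ndarray
    geometry_tag: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.D, dtype=float)
        gram = d @ d.T
        if not np.allclose(gram, np.eye(d.shape[0]), atol=1e-10, rtol=0.0):
            raise ValueError("rows of D must be orthonormal to 1e-10")
        h = np.asarray(self.H_diabatic, dtype=float)
        if not np.allclose(h, h.T, atol=1e-10, rtol=0.0):
            raise ValueError("H_diabatic must be symmetric")


def lowdin_transform(S: np.ndarray) -> np.ndarray:
    """Symmetric orthonormalization of the rows of ``S``.

    Computes ``D = (S S^T)^(-1/2) S`` via an eigen-decomposition of
    ``S S^T``; this is the row-orthonormal matrix closest to ``S`` in
    Frobenius norm.

    Raises
    ------
    RankDeficiencyError
        If an eigenvalue of ``S S^T`` falls below 1e-10, i.e. some linear
        combination of reference states is not represented in the adiabatic
        set.  The error names the reference state with the largest weight
        in the deficient combination.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[1] < S.shape[0]:
        raise ValueError("S must be (N, M) with M >= N")
    gram = S @ S.T
    evals, evecs = np.linalg.eigh(gram)
    if evals[0] < _EIG_FLOOR:
        culprit = int(np.argmax(np.abs(evecs[:, 0])))
        raise RankDeficiencyError(
            f"overlap matrix is rank deficient (smallest eigenvalue of S S^T = "
            f"{evals[0]:.3e} < {_EIG_FLOOR:g}); reference state {culprit} is not "
            "spanned by the adiabatic set"
        )
    inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
    return inv_sqrt @ S


def diabatic_hamiltonian(D: np.ndarray, E_adiabatic: np.ndarray) -> np.ndarray:
    """Diabatic Hamiltonian ``H^D = D diag(E^A) D^T`` (eV)."""
    D = np.asarray(D, dtype=float)
    E = np.asarray(E_adiabatic, dtype=float)
    if E.shape != (D.shape[1],):
        raise ValueError(
            f"E_adiabatic length {E.shape} inconsistent with D columns {D.shape[1]}"
        )
    h = (D * E) @ D.T
    return 0.5 * (h + h.T)


def reference_weights(S: np.ndarray) -> np.ndarray:
    """Weight of the best-matching reference state for each adiabatic state.

    ``W_m = max_i S_im**2``; values near 1 mean the adiabatic state is well
    described by a single reference (diabatic) state.
    """
    S = np.asarray(S, dtype=float)
    return np.max(S**2, axis=0)


def phase_align(
    D: np.ndarray,
    D_ref: np.ndarray,
    warn_threshold: float = 0.5,
    return_signs: bool = False,
):
    """Fix the arbitrary sign of each diabatic vector against a reference.

    Each row of ``D`` is multiplied by +/-1 so that its inner product with
    the corresponding row of ``D_ref`` is non-negative.  Adiabatic phases
    are arbitrary per geometry, so this is required before finite
    differences across displaced geometries.  A warning is emitted when the
    aligned inner product stays below ``warn_threshold`` (possible state
    reordering between geometries).
    """
    D = np.asarray(D, dtype=float)
    D_ref = np.asarray(D_ref, dtype=float)
    if D.shape != D_ref.shape:
        raise ValueError(f"shape mismatch: {D.shape} vs {D_ref.shape}")
    dots = np.sum(D * D_ref, axis=1)
    signs = np.where(dots < 0, -1.0, 1.0)
    aligned = D * signs[:, None]
    small = np.abs(dots) < warn_threshold
    if np.any(small):
        rows = np.flatnonzero(small).tolist()
        warnings.warn(
            f"phase alignment: rows {rows} have |<d|d_ref>| < {warn_threshold}; "
            "diabatic states may have reordered between geometries",
            stacklevel=2,
        )
    if return_signs:
        return aligned, signs
    return aligned


def diabatize_record(record: ElectronicStructureRecord) -> DiabatizationResult:
    """Full diabatization of one record: Löwdin transform, diabatic
    Hamiltonian, reference weights and completeness diagnostics."""
    D = lowdin_transform(record.overlap)
    return DiabatizationResult(
        D=D,
        H_diabatic=diabatic_hamiltonian(D, record.adiabatic_energies),
        weights=reference_weights(record.overlap),
        completeness=record.completeness(),
        geometry_tag=record.geometry_tag,
    )
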