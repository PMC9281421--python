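"""Build an LVC model from electronic-structure records.

The pipeline mirrors how LVC Hamiltonians are parametrized in practice:

1. diabatize the reference-geometry record to get the constant diabatic
   matrix ``E(0)`` and the reference transformation ``D(0)``;
2. displace each normal coordinate by ``+/- delta_a``, diabatize each
   displaced record (phase-aligned against ``D(0)``);
3. extract gradients and linear couplings by central finite differences,

       lambda_ij,a = [H^D_ij(+d_a) - H^D_ij(-d_a)] / (2 d_a).

On an exactly linear-vibronic potential the central difference is exact:
the shared harmonic term ``1/2 w_a d_a**2`` on the diagonal cancels between
the two displaced points, so recovered couplings carry no O(delta) bias.

A validity diagnostic based on the second difference along each mode
(which must equal ``w_a`` on the diagonal and vanish off-diagonal for a
true LVC potential) is provided as quality control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diabatize import (
    DiabatizationResult,
    ElectronicStructureRecord,
    diabatic_hamiltonian,
    lowdin_transform,
    phase_align,
    reference_weights,
)
from .model import DiabaticStateMeta, LVCModel, NormalModeBasis

__all__ = [
    "DisplacementProtocol",
    "displacement_grid",
    "finite_difference_couplings",
    "lvc_validity_diagnostic",
    "build_lvc_model",
]

REFERENCE_TAG = "FC"

#: minimum squared row norm of S before a completeness warning is issued
COMPLETENESS_WARN = 0.5

_DEGENERACY_GAP = 1e-6


@dataclass(frozen=True)
class DisplacementProtocol:
    """The 2F+1 geometries needed for central differences along each mode."""

    deltas: np.ndarray  # (F,) positive displacement magnitudes
    tags: tuple[str, ...]  # ordered tags: FC, m1+, m1-, m2+, ...

    def __post_init__(self) -> None:
        d = np.asarray(self.deltas, dtype=float)
        if np.any(d <= 0):
            raise ValueError("all displacement magnitudes must be positive")
        object.__setattr__(self, "deltas", d)
        if len(self.tags) != 2 * d.size + 1:
            raise ValueError("protocol must contain exactly 2F+1 geometries")

    @property
    def n_modes(self) -> int:
        return self.deltas.size

    @staticmethod
    def tag(mode: int, sign: int) -> str:
        return f"m{mode + 1}{'+' if sign > 0 else '-'}"

    def geometries(self) -> list[tuple[str, np.ndarray]]:
        """Ordered (tag, q) pairs: reference first, then +/- per mode."""
        f = self.n_modes
        out: list[tuple[str, np.ndarray]] = [(REFERENCE_TAG, np.zeros(f))]
        for a in range(f):
            for sign in (+1, -1):
                q = np.zeros(f)
                q[a] = sign * self.deltas[a]
                out.append((self.tag(a, sign), q))
        return out


def displacement_grid(
    modes: NormalModeBasis, delta: float | np.ndarray = 0.1
) -> DisplacementProtocol:
    """Displacement protocol with scalar or per-mode step sizes.

    The default step of 0.1 dimensionless units is small enough that cubic
    contamination of realistic surfaces stays below typical electronic-
    structure noise, yet large enough that energy differences are well
    resolved.
    """
    f = modes.n_modes
    deltas = np.broadcast_to(np.asarray(delta, dtype=float), (f,)).copy()
    if np.any(deltas <= 0):
        raise ValueError("displacement delta must be positive")
    tags = [REFERENCE_TAG]
    for a in range(f):
        tags.append(DisplacementProtocol.tag(a, +1))
        tags.append(DisplacementProtocol.tag(a, -1))
    return DisplacementProtocol(deltas=deltas, tags=tuple(tags))


def finite_difference_couplings(
    H_plus: np.ndarray,
    H_minus: np.ndarray,
    protocol: DisplacementProtocol,
) -> np.ndarray:
    """Central-difference couplings from per-mode diabatic Hamiltonians.

    ``H_plus``/``H_minus`` are ``(F, N, N)`` stacks of phase-aligned
    diabatic matrices at ``+delta_a`` / ``-delta_a``.  Returns the
    ``(N, N, F)`` coupling array (gradients on the diagonal).
    """
    H_plus = np.asarray(H_plus, dtype=float)
    H_minus = np.asarray(H_minus, dtype=float)
    f = protocol.n_modes
    if H_plus.shape[0] != f or H_minus.shape[0] != f:
        missing = "+" if H_plus.shape[0] != f else "-"
        raise ValueError(
            f"expected {f} displaced Hamiltonians per sign, got "
            f"{H_plus.shape[0]}/{H_minus.shape[0]} (sign {missing})"
        )
    lam = (H_plus - H_minus) / (2.0 * protocol.deltas[:, None, None])
    lam = np.moveaxis(lam, 0, -1)  # (N, N, F)
    return 0.5 * (lam + lam.transpose(1, 0, 2))


def lvc_validity_diagnostic(
    H_plus: np.ndarray,
    H_minus: np.ndarray,
    H_fc: np.ndarray,
    modes: NormalModeBasis,
    protocol: DisplacementProtocol,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-mode curvature check of the linear-vibronic assumption.

    The second difference ``[H(+d) + H(-d) - 2 H(0)] / d**2`` must equal
    ``w_a`` on every diagonal element and zero off the diagonal if the true
    potential is LVC.  Deviations beyond ``threshold`` (eV) are flagged;
    they indicate quadratic state-dependent or anharmonic terms.
    """
    H_plus = np.asarray(H_plus, dtype=float)
    H_minus = np.asarray(H_minus, dtype=float)
    second = (H_plus + H_minus - 2.0 * H_fc[None]) / protocol.deltas[:, None, None] ** 2
    n = H_fc.shape[0]
    diag = second[:, np.arange(n), np.arange(n)]
    off = second.copy()
    off[:, np.arange(n), np.arange(n)] = 0.0
    diag_dev = np.max(np.abs(diag - modes.frequencies[:, None]), axis=1)
    off_dev = np.max(np.abs(off).reshape(second.shape[0], -1), axis=1)
    return pd.DataFrame(
        {
            "mode": modes.labels(),
            "frequency_ev": modes.frequencies,
            "diag_curvature_dev_ev": diag_dev,
            "offdiag_curvature_ev": off_dev,
            "flagged": (diag_dev > threshold) | (off_dev > threshold),
        }
    )


def _records_by_tag(
    records: list[ElectronicStructureRecord],
) -> dict[str, ElectronicStructureRecord]:
    by_tag: dict[str, ElectronicStructureRecord] = {}
    for rec in records:
        if rec.geometry_tag in by_tag:
            raise ValueError(f"duplicate record for geometry {rec.geometry_tag!r}")
        by_tag[rec.geometry_tag] = rec
    return by_tag


def _diabatize_for_strategy(
    record: ElectronicStructureRecord, n_states: int, strategy: str
) -> tuple[np.ndarray, np.ndarray]:
    """Return (D, H_diabatic) for one record under the given strategy.

    For the standard-LVC strategy the reference states ARE the lowest
    ``n_states`` adiabatic states at the reference geometry, so the
    reference-geometry transform is the identity block and the constant
    couplings vanish exactly; displaced geometries still go through the
    Löwdin transform of the recorded overlaps.
    """
    if strategy == "St" and record.geometry_tag == REFERENCE_TAG:
        m = record.n_adiabatic
        D = np.eye(n_states, m)
        H = np.diag(record.adiabatic_energies[:n_states])
        return D, H
    gaps = np.diff(record.adiabatic_energies)
    if np.any(np.abs(gaps) < _DEGENERACY_GAP):
        warnings.warn(
            f"near-degenerate adiabatic states at {record.geometry_tag!r} "
            f"(gap < {_DEGENERACY_GAP:g} eV); diabatization remains well-defined "
            "but overlaps may mix the degenerate pair",
            stacklevel=3,
        )
    D = lowdin_transform(record.overlap)
    return D, diabatic_hamiltonian(D, record.adiabatic_energies)


def build_lvc_model(
    records: list[ElectronicStructureRecord],
    n_states: int,
    strategy: str = "FrD",
    protocol: DisplacementProtocol | None = None,
    modes: NormalModeBasis | None = None,
    states: tuple[DiabaticStateMeta, ...] | None = None,
) -> tuple[LVCModel, dict[str, DiabatizationResult]]:
    """Assemble a full LVC model from a complete record set.

    Parameters
    ----------
    records
        One record per protocol geometry (reference plus +/- per mode).
    n_states
        Number of diabatic states N (= number of reference states).
    strategy
        "St" (references = reference-geometry adiabatic states), "FrD"
        (isolated-fragment references) or "FrD_MMref" (MM-embedded
        fragment references).  The two fragment strategies differ only in
        how the backend computed the references; this builder treats them
        identically and stores the tag in the model provenance.
    protocol
        Displacement protocol; required (defines deltas and tags).
    modes
        Normal-mode basis of the parametrized model; required.
    states
        Optional diabatic-state metadata; auto-generated labels otherwise.

    Returns
    -------
    (model, results)
        The assembled :class:`LVCModel` and the per-geometry
        :class:`DiabatizationResult` diagnostics.
    """
    if strategy not in ("St", "FrD", "FrD_MMref"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if protocol is None or modes is None:
        raise ValueError("both protocol and modes are required")
    by_tag = _records_by_tag(records)
    f = protocol.n_modes
    if modes.n_modes != f:
        raise ValueError("protocol and mode basis disagree on the number of modes")

    m_counts = {rec.n_adiabatic for rec in records}
    if len(m_counts) != 1:
        raise ValueError(f"inconsistent adiabatic state counts across records: {m_counts}")
    for rec in records:
        if rec.n_reference != n_states:
            raise ValueError(
                f"record {rec.geometry_tag!r} has {rec.n_reference} reference "
                f"states, expected {n_states}"
            )

    if REFERENCE_TAG not in by_tag:
        raise ValueError("missing reference-geometry record (tag 'FC')")
    fc_rec = by_tag[REFERENCE_TAG]
    D0, H0 = _diabatize_for_strategy(fc_rec, n_states, strategy)
    # diabatic states of the FC geometry expressed in the (geometry-
    # independent) reference basis; the alignment target for all geometries
    proj0 = D0 @ fc_rec.overlap.T

    results: dict[str, DiabatizationResult] = {
        REFERENCE_TAG: DiabatizationResult(
            D=D0,
            H_diabatic=H0,
            weights=reference_weights(fc_rec.overlap),
            completeness=fc_rec.completeness(),
            geometry_tag=REFERENCE_TAG,
        )
    }

    H_plus = np.empty((f, n_states, n_states))
    H_minus = np.empty((f, n_states, n_states))
    for a in range(f):
        for sign, target in ((+1, H_plus), (-1, H_minus)):
            tag = protocol.tag(a, sign)
            if tag not in by_tag:
                raise ValueError(
                    f"missing record for mode {a + 1}, sign {'+' if sign > 0 else '-'} "
                    f"(tag {tag!r})"
                )
            rec = by_tag[tag]
            D, _ = _diabatize_for_strategy(rec, n_states, strategy)
            # Adiabatic bases differ between geometries, so rows of D are
            # not directly comparable across records.  Express each
            # geometry's diabatic states in the shared reference basis
            # (D S^T) and align THOSE against the FC point -- never against
            # the previous geometry, which would accumulate drift.
            proj = D @ rec.overlap.T
            _, signs = phase_align(proj, proj0, return_signs=True)
            D = D * signs[:, None]
            target[a] = diabatic_hamiltonian(D, rec.adiabatic_energies)
            results[tag] = DiabatizationResult(
                D=D,
                H_diabatic=target[a],
                weights=reference_weights(rec.overlap),
                completeness=rec.completeness(),
                geometry_tag=tag,
            )

    couplings = finite_difference_couplings(H_plus, H_minus, protocol)

    low = results[REFERENCE_TAG].completeness < COMPLETENESS_WARN
    if np.any(low):
        warnings.warn(
            "low reference-state completeness at the reference geometry for "
            f"states {np.flatnonzero(low).tolist()}; consider enlarging the "
            "adiabatic set",
            stacklevel=2,
        )

    if states is None:
        states = tuple(DiabaticStateMeta(label=f"d{i + 1}") for i in range(n_states))
    model = LVCModel(
        modes=modes,
        states=states,
        constant_matrix=0.5 * (H0 + H0.T),
        couplings=couplings,
        provenance={
            "strategy": strategy,
            "delta": protocol.deltas.tolist(),
            "fc_weights": results[REFERENCE_TAG].weights.tolist(),
            "fc_completeness": results[REFERENCE_TAG].completeness.tolist(),
            "n_adiabatic": int(next(iter(m_counts))),
        },
    )
    return model, results
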