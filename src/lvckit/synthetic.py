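"""Synthetic electronic-structure backend.

Plays the role of the quantum-chemistry layer: given a hidden ground-truth
LVC model, it produces :class:`~lvckit.diabatize.ElectronicStructureRecord`
objects (adiabatic energies plus reference/adiabatic overlap matrices) at
any requested geometry.  Because the ground truth is known exactly, the
whole diabatization + finite-difference pipeline can be validated as a
round trip: with perfect reference states and a complete adiabatic set the
pipeline must reproduce the truth model to numerical precision.

Controllable imperfections emulate the realities of fragment-based
reference states:

* ``n_adiabatic_out`` truncates the adiabatic set (reference states are
  then no longer fully spanned, completeness < 1);
* ``reference_mixing_angle`` rotates the reference states away from the
  truth diabatic states by a seeded orthogonal transformation within each
  symmetry block (fragment states are not eigenstates of the full system);
* ``embedding_shift`` re-derives the references from the truth constant
  matrix with per-state energy shifts, emulating the difference between
  isolated-fragment references and references embedded in the partner
  fragment's point charges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diabatize import ElectronicStructureRecord
from .model import (
    DiabaticStateMeta,
    LVCModel,
    NormalModeBasis,
    adiabatic_energies,
    potential_matrix,
)

__all__ = ["TruthSpec", "generate_record", "generate_records", "make_truth_model"]


@dataclass
class TruthSpec:
    """A ground-truth model plus imperfection knobs for record generation."""

    truth: LVCModel
    n_adiabatic_out: int | str = "all"
    n_reference_out: int | str = "all"
    reference_mixing_angle: float = 0.0
    embedding_shift: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.truth.n_states
        if self.n_adiabatic_out == "all":
            self.n_adiabatic_out = n
        if not 1 <= int(self.n_adiabatic_out) <= n:
            raise ValueError(f"n_adiabatic_out must be in [1, {n}]")
        self.n_adiabatic_out = int(self.n_adiabatic_out)
        if self.n_reference_out == "all":
            self.n_reference_out = n
        self.n_reference_out = int(self.n_reference_out)
        if not 1 <= self.n_reference_out <= self.n_adiabatic_out:
            raise ValueError(
                "n_reference_out must be in [1, n_adiabatic_out]: records need "
                "at least as many adiabatic as reference states"
            )
        if not 0.0 <= self.reference_mixing_angle < np.pi / 4:
            raise ValueError("reference_mixing_angle must be in [0, pi/4)")
        if self.embedding_shift is not None:
            shift = np.asarray(self.embedding_shift, dtype=float)
            if shift.shape != (n,):
                raise ValueError("embedding_shift needs one entry per truth state")
            self.embedding_shift = shift

    def reference_matrix(self) -> np.ndarray:
        """Rows = reference states expressed in the truth diabatic basis.

        Perfect references are the truth diabatic states themselves
        (identity).  An embedding shift re-diagonalizes the shifted
        constant matrix, and the mixing angle applies a seeded orthogonal
        rotation within each symmetry block on top.
        """
        n = self.truth.n_states
        if self.embedding_shift is None:
            R = np.eye(n)
        else:
            h_ref = self.truth.constant_matrix + np.diag(self.embedding_shift)
            _, vecs = np.linalg.eigh(h_ref)
            idx = np.argmax(np.abs(vecs), axis=0)
            signs = np.sign(vecs[idx, np.arange(n)])
            signs[signs == 0] = 1.0
            # row i of R = reference state tracking truth state i
            order = np.argsort(idx)
            R = (vecs * signs).T[order]
        if self.reference_mixing_angle > 0.0:
            R = _block_rotation(self.truth, self.reference_mixing_angle, self.seed) @ R
        return R


def _block_rotation(truth: LVCModel, angle: float, seed: int) -> np.ndarray:
    """Seeded orthogonal rotation acting within same-symmetry state blocks.

    Built as ``expm(angle * G)`` with a fixed random antisymmetric
    generator ``G`` (unit scale) so that the perturbation grows linearly
    and monotonically with ``angle``.
    """
    from scipy.linalg import expm

    n = truth.n_states
    rng = np.random.default_rng(seed)
    gen = rng.standard_normal((n, n))
    gen = gen - gen.T
    syms = [s.symmetry for s in truth.states]
    if not any(s is None for s in syms):
        same = np.array([[a == b for b in syms] for a in syms])
        gen = np.where(same, gen, 0.0)
    norm = np.linalg.norm(gen)
    if norm > 0:
        gen = gen / norm * np.sqrt(2.0)  # one "radian" of total rotation per unit angle
    return expm(angle * gen)


def generate_record(spec: TruthSpec, q: np.ndarray, geometry_tag: str = "") -> ElectronicStructureRecord:
    """Emulated electronic-structure output at geometry ``q``.

    Diagonalizes the truth potential, keeps the lowest ``M`` adiabatic
    states, and returns overlaps ``S_im = <R_i|a_m>`` between the (possibly
    imperfect) reference states and the adiabatic eigenvectors.
    """
    truth = spec.truth
    q = np.asarray(q, dtype=float)
    energies, vecs = adiabatic_energies(truth, q, return_vectors=True)
    m = spec.n_adiabatic_out
    R = spec.reference_matrix()[: spec.n_reference_out]
    overlap = R @ vecs[:, :m]
    return ElectronicStructureRecord(
        geometry_tag=geometry_tag,
        q=q,
        adiabatic_energies=energies[:m],
        overlap=overlap,
        provenance={
            "backend": "synthetic",
            "mixing_angle": spec.reference_mixing_angle,
            "embedded": spec.embedding_shift is not None,
        },
    )


def generate_records(spec: TruthSpec, protocol) -> list[ElectronicStructureRecord]:
    """Records for every geometry of a displacement protocol."""
    return [generate_record(spec, q, tag) for tag, q in protocol.geometries()]


def make_truth_model(
    n_states: int = 12,
    n_modes: int = 10,
    character_template: list[str] | None = None,
    seed: int = 0,
) -> LVCModel:
    """Seeded, reproducible ground-truth model with realistic structure.

    The generated models mimic the electronic structure of a hydrogen-
    bonded purine/pyrimidine pair at vertical excitation: a handful of
    bright pi-pi* states and dark n-pi* states localized on either
    fragment plus one interfragment charge-transfer state, with vertical
    energies in the 5-7 eV window.  Conventions baked in:

    * frequencies drawn in 0.01-0.4 eV (covers H-bond stretches through
      ring/C=O stretches);
    * diagonal gradients scaled so that local states have reorganization
      energies of 0.1-0.7 eV while the CT state, whose minimum is reached
      after a large interfragment charge rearrangement, gets 1.2 eV --
      always the largest;
    * pi-pi* and CT states are A', n-pi* states are A''; roughly 2/3 of
      the modes are in-plane (a'); couplings are generated only in
      symmetry-allowed slots (A'-A'' pairs couple through a'' modes only);
    * constant interstate couplings of ~tens of meV within each symmetry
      block, zero across blocks.
    """
    if n_states < 2 or n_modes < 1:
        raise ValueError("need at least 2 states and 1 mode")
    rng = np.random.default_rng(seed)

    if character_template is None:
        character_template = _default_characters(n_states)
    if len(character_template) != n_states:
        raise ValueError("character_template length must equal n_states")

    n_inplane = max(1, int(round(n_modes * 2 / 3)))
    mode_sym = tuple("a'" if a < n_inplane else 'a"' for a in range(n_modes))
    freqs = rng.uniform(0.01, 0.4, size=n_modes)
    modes = NormalModeBasis(frequencies=freqs, symmetry=mode_sym)

    frag_cycle = ("A", "T")
    states = []
    counts: dict[str, int] = {}
    for i, char in enumerate(character_template):
        counts[char] = counts.get(char, 0) + 1
        frag = "A-T" if char == "CT" else frag_cycle[i % 2]
        sym = "Adoubleprime" if char == "LE_npi" else "Aprime"
        f_osc = float(rng.uniform(0.05, 0.3)) if char == "LE_pipi" else 0.0
        states.append(
            DiabaticStateMeta(
                label=f"{frag}({char}{counts[char]})",
                fragment=frag,
                character=char,  # type: ignore[arg-type]
                symmetry=sym,  # type: ignore[arg-type]
                oscillator_strength=f_osc,
            )
        )
    states = tuple(states)

    anti = np.array([s.symmetry == "Adoubleprime" for s in states])
    mode_anti = np.array([lab == 'a"' for lab in mode_sym])

    # vertical energies: LE in 5.0-6.8 eV, CT pushed toward the top
    diag = np.sort(rng.uniform(5.0, 6.8, size=n_states))
    e0 = np.diag(diag).copy()
    ct_idx = [i for i, s in enumerate(states) if s.character == "CT"]
    for i in ct_idx:
        e0[i, i] = float(rng.uniform(6.0, 6.5))
    for i in range(n_states):
        for j in range(i + 1, n_states):
            if anti[i] == anti[j]:
                c = rng.normal(0.0, 0.03)
                e0[i, j] = e0[j, i] = c

    lam = np.zeros((n_states, n_states, n_modes))
    inplane = ~mode_anti
    for i in range(n_states):
        g = np.zeros(n_modes)
        g[inplane] = rng.normal(0.0, 0.05, size=int(inplane.sum()))
        target = 1.2 if states[i].character == "CT" else float(rng.uniform(0.1, 0.7))
        reorg = 0.5 * np.sum(g * g / freqs)
        if reorg > 0:
            g *= np.sqrt(target / reorg)
        lam[i, i] = g
    for i in range(n_states):
        for j in range(i + 1, n_states):
            allowed = mode_anti if anti[i] != anti[j] else ~mode_anti
            v = np.zeros(n_modes)
            v[allowed] = rng.normal(0.0, 0.02, size=int(allowed.sum()))
            lam[i, j] = lam[j, i] = v

    return LVCModel(
        modes=modes,
        states=states,
        constant_matrix=e0,
        couplings=lam,
        provenance={"generator": "make_truth_model", "seed": int(seed)},
    )


def _default_characters(n_states: int) -> list[str]:
    """Paper-like mix: bright pi-pi*, dark n-pi*, and one CT state."""
    base = ["LE_pipi", "LE_npi", "LE_pipi", "LE_pipi", "LE_npi", "CT"]
    chars = list(base[: min(n_states, len(base))])
    fill = ["LE_npi", "LE_npi", "LE_npi", "LE_pipi", "LE_pipi", "LE_pipi"]
    while len(chars) < n_states:
        chars.append(fill[(len(chars) - len(base)) % len(fill)])
    if "CT" not in chars:
        chars[-1] = "CT"
    return chars
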