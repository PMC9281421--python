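"""File formats: model/record JSON schemas, trajectory files, MCTDH export.

The canonical on-disk form of an LVC model is a versioned JSON document --
human-diffable and lossless at full double precision (floats are written
with ``repr`` round-trip fidelity).  Electronic-structure records use a
sibling JSON schema.  Bulk propagation output goes to HDF5 with CSV
mirrors.  Models can additionally be exported in the MCTDH operator-file
dialect for cross-checks against MCTDH-family quantum dynamics codes; a
minimal re-parser for that dialect is bundled for round-trip validation.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np

from .diabatize import ElectronicStructureRecord
from .model import DiabaticStateMeta, LVCModel, NormalModeBasis

__all__ = [
    "read_model",
    "write_model",
    "read_record",
    "write_record",
    "write_mctdh_operator",
    "read_mctdh_operator",
    "read_xyz_modes",
    "CartesianDisplacer",
    "SchemaError",
]

MODEL_SCHEMA = "lvckit-model"
MODEL_SCHEMA_VERSION = 2
RECORD_SCHEMA = "lvckit-record"
RECORD_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A document violates its schema; the message carries the JSON path."""


# ---------------------------------------------------------------------------
# model JSON


_MODEL_KEYS = {
    "schema",
    "schema_version",
    "modes",
    "states",
    "constant_matrix_ev",
    "couplings_ev",
    "provenance",
}
_MODE_KEYS = {"frequencies_ev", "labels", "symmetry"}
_STATE_KEYS = {"label", "fragment", "character", "symmetry", "oscillator_strength"}


def _reject_unknown(doc: dict, allowed: set, path: str) -> None:
    for key in doc:
        if key not in allowed:
            raise SchemaError(f"unknown field at {path}/{key}")


def write_model(model: LVCModel, path: str | Path) -> None:
    """Serialize a model to the canonical JSON schema (version 2)."""
    doc = {
        "schema": MODEL_SCHEMA,
        "schema_version": MODEL_SCHEMA_VERSION,
        "modes": {
            "frequencies_ev": model.modes.frequencies.tolist(),
            "labels": list(model.modes.labels()),
            "symmetry": None if model.modes.symmetry is None else list(model.modes.symmetry),
        },
        "states": [
            {
                "label": s.label,
                "fragment": s.fragment,
                "character": s.character,
                "symmetry": s.symmetry,
                "oscillator_strength": s.oscillator_strength,
            }
            for s in model.states
        ],
        "constant_matrix_ev": model.constant_matrix.tolist(),
        "couplings_ev": model.couplings.tolist(),
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _migrate_v1(doc: dict, path: str) -> dict:
    """Schema version 1 stored frequencies and couplings under legacy keys
    ('frequencies', 'lambda') and states as bare label strings."""
    warnings.warn(
        f"{path}: migrating legacy model schema version 1 -> {MODEL_SCHEMA_VERSION}",
        stacklevel=3,
    )
    out = {
        "schema": MODEL_SCHEMA,
        "schema_version": MODEL_SCHEMA_VERSION,
        "modes": {
            "frequencies_ev": doc["frequencies"],
            "labels": None,
            "symmetry": None,
        },
        "states": [
            {"label": lab, "fragment": "", "character": None, "symmetry": None,
             "oscillator_strength": 0.0}
            for lab in doc["states"]
        ],
        "constant_matrix_ev": doc["constant"],
        "couplings_ev": doc["lambda"],
        "provenance": doc.get("provenance", {}),
    }
    return out


def read_model(path: str | Path) -> LVCModel:
    """Load a model, migrating supported legacy schema versions."""
    path = Path(path)
    doc = json.loads(path.read_text())
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: document root must be an object")
    version = doc.get("schema_version")
    if version == 1:
        doc = _migrate_v1(doc, str(path))
    elif version != MODEL_SCHEMA_VERSION:
        raise SchemaError(f"{path}/schema_version: unsupported version {version!r}")
    if doc.get("schema") != MODEL_SCHEMA:
        raise SchemaError(f"{path}/schema: expected {MODEL_SCHEMA!r}")
    _reject_unknown(doc, _MODEL_KEYS, str(path))
    modes_doc = doc["modes"]
    _reject_unknown(modes_doc, _MODE_KEYS, f"{path}/modes")
    modes = NormalModeBasis(
        frequencies=np.array(modes_doc["frequencies_ev"], dtype=float),
        mode_labels=None if modes_doc.get("labels") is None else tuple(modes_doc["labels"]),
        symmetry=None if modes_doc.get("symmetry") is None else tuple(modes_doc["symmetry"]),
    )
    states = []
    for k, s in enumerate(doc["states"]):
        _reject_unknown(s, _STATE_KEYS, f"{path}/states[{k}]")
        states.append(
            DiabaticStateMeta(
                label=s["label"],
                fragment=s.get("fragment", ""),
                character=s.get("character"),
                symmetry=s.get("symmetry"),
                oscillator_strength=float(s.get("oscillator_strength", 0.0)),
            )
        )
    return LVCModel(
        modes=modes,
        states=tuple(states),
        constant_matrix=np.array(doc["constant_matrix_ev"], dtype=float),
        couplings=np.array(doc["couplings_ev"], dtype=float),
        provenance=doc.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# record JSON

_RECORD_KEYS = {
    "schema",
    "schema_version",
    "geometry_tag",
    "q",
    "adiabatic_energies_ev",
    "overlap",
    "oscillator_strengths",
    "provenance",
}


def write_record(record: ElectronicStructureRecord, path: str | Path) -> None:
    doc = {
        "schema": RECORD_SCHEMA,
        "schema_version": RECORD_SCHEMA_VERSION,
        "geometry_tag": record.geometry_tag,
        "q": record.q.tolist(),
        "adiabatic_energies_ev": record.adiabatic_energies.tolist(),
        "overlap": record.overlap.tolist(),
        "oscillator_strengths": None
        if record.oscillator_strengths is None
        else record.oscillator_strengths.tolist(),
        "provenance": record.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_record(path: str | Path) -> ElectronicStructureRecord:
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("schema") != RECORD_SCHEMA:
        raise SchemaError(f"{path}/schema: expected {RECORD_SCHEMA!r}")
    if doc.get("schema_version") != RECORD_SCHEMA_VERSION:
        raise SchemaError(f"{path}/schema_version: unsupported version")
    _reject_unknown(doc, _RECORD_KEYS, str(path))
    osc = doc.get("oscillator_strengths")
    return ElectronicStructureRecord(
        geometry_tag=doc["geometry_tag"],
        q=np.array(doc["q"], dtype=float),
        adiabatic_energies=np.array(doc["adiabatic_energies_ev"], dtype=float),
        overlap=np.array(doc["overlap"], dtype=float),
        oscillator_strengths=None if osc is None else np.array(osc, dtype=float),
        provenance=doc.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# MCTDH operator export

_FLOAT_FMT = "{!r}"


def _sanitize(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9]", "", label) or "x"


def write_mctdh_operator(model: LVCModel, path: str | Path, title: str = "LVC model") -> None:
    """Export the model as an MCTDH operator file.

    Emits a parameter section (frequencies, constant energies/couplings and
    linear coupling constants, all annotated with their unit) and a
    Hamiltonian section with kinetic, harmonic, and vibronic terms; the
    electronic degree of freedom is the first mode (``el``).  States or
    modes without labels get auto-generated names with a warning.
    """
    n, f = model.n_states, model.n_modes
    mode_names = [f"v{a + 1:02d}" for a in range(f)]
    if model.modes.mode_labels is None:
        warnings.warn("modes have no labels; auto-generated names v01.. used", stacklevel=2)
    state_names = [_sanitize(s.label) for s in model.states]
    if len(set(state_names)) != n:
        warnings.warn("state labels collide after sanitizing; using S1..SN", stacklevel=2)
        state_names = [f"S{i + 1}" for i in range(n)]

    lines: list[str] = []
    lines.append("OP_DEFINE-SECTION")
    lines.append("title")
    lines.append(title)
    lines.append("end-title")
    lines.append("end-op_define-section")
    lines.append("")
    lines.append("PARAMETER-SECTION")
    for a in range(f):
        lines.append(f"w_{mode_names[a]} = {float(model.modes.frequencies[a])!r} , ev")
    for i in range(n):
        for j in range(i, n):
            val = float(model.constant_matrix[i, j])
            if i == j or val != 0.0:
                lines.append(f"E_{i + 1}_{j + 1} = {val!r} , ev")
    for i in range(n):
        for j in range(i, n):
            for a in range(f):
                val = float(model.couplings[i, j, a])
                if val != 0.0:
                    lines.append(f"lam_{i + 1}_{j + 1}_{mode_names[a]} = {val!r} , ev")
    lines.append("end-parameter-section")
    lines.append("")
    lines.append("HAMILTONIAN-SECTION")
    lines.append(" modes | el | " + " | ".join(mode_names))
    for a in range(f):
        lines.append(f"w_{mode_names[a]}      |{a + 2} KE")
        lines.append(f"0.5*w_{mode_names[a]}  |{a + 2} q^2")
    for i in range(n):
        for j in range(i, n):
            val = model.constant_matrix[i, j]
            if i == j or val != 0.0:
                lines.append(f"E_{i + 1}_{j + 1}  |1 S{i + 1}&{j + 1}")
    for i in range(n):
        for j in range(i, n):
            for a in range(f):
                if model.couplings[i, j, a] != 0.0:
                    lines.append(
                        f"lam_{i + 1}_{j + 1}_{mode_names[a]}  |1 S{i + 1}&{j + 1}  |{a + 2} q"
                    )
    lines.append("end-hamiltonian-section")
    lines.append("")
    lines.append("end-operator")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mctdh_operator(path: str | Path) -> dict:
    """Minimal re-parser for the exported MCTDH dialect.

    Returns ``{"frequencies": (F,), "constant_matrix": (N, N),
    "couplings": (N, N, F), "parameters": {name: value}}`` reconstructed
    from the parameter and Hamiltonian sections.  Intended for round-trip
    validation of :func:`write_mctdh_operator`, not as a general MCTDH
    operator parser.
    """
    text = Path(path).read_text()
    params: dict[str, float] = {}
    in_params = False
    mode_names: list[str] = []
    for raw in text.splitlines():
        line = raw.strip()
        if line.upper() == "PARAMETER-SECTION":
            in_params = True
            continue
        if line.lower() == "end-parameter-section":
            in_params = False
            continue
        if in_params and "=" in line:
            name, rhs = line.split("=", 1)
            value = rhs.split(",")[0].strip()
            params[name.strip()] = float(value)
        if line.startswith("modes") and "|" in line:
            cols = [c.strip() for c in line.split("|")[1:]]
            mode_names = cols[1:]  # first column is the electronic dof

    freq_names = [f"w_{m}" for m in mode_names]
    if not all(nm in params for nm in freq_names):
        raise SchemaError(f"{path}: missing frequency parameters for modes {mode_names}")
    f = len(mode_names)
    frequencies = np.array([params[nm] for nm in freq_names])

    n = 0
    for name in params:
        m = re.fullmatch(r"E_(\d+)_(\d+)", name)
        if m:
            n = max(n, int(m.group(1)), int(m.group(2)))
    constant = np.zeros((n, n))
    couplings = np.zeros((n, n, f))
    mode_index = {nm: a for a, nm in enumerate(mode_names)}
    for name, value in params.items():
        m = re.fullmatch(r"E_(\d+)_(\d+)", name)
        if m:
            i, j = int(m.group(1)) - 1, int(m.group(2)) - 1
            constant[i, j] = constant[j, i] = value
            continue
        m = re.fullmatch(r"lam_(\d+)_(\d+)_(\w+)", name)
        if m:
            i, j = int(m.group(1)) - 1, int(m.group(2)) - 1
            a = mode_index[m.group(3)]
            couplings[i, j, a] = couplings[j, i, a] = value
    return {
        "frequencies": frequencies,
        "constant_matrix": constant,
        "couplings": couplings,
        "parameters": params,
    }


# ---------------------------------------------------------------------------
# geometries and Cartesian normal modes

_MASSES_AMU = {
    "H": 1.00782503, "D": 2.01410178, "C": 12.0, "N": 14.0030740, "O": 15.9949146,
    "F": 18.9984032, "P": 30.97376200, "S": 31.97207117, "CL": 34.96885268,
    "BR": 78.9183376, "I": 126.904473, "NA": 22.98976928, "MG": 23.9850417,
}


class CartesianDisplacer:
    """Converts dimensionless normal-coordinate displacements to Cartesians.

    ``displace(q)`` returns ``x0 + sum_a q_a * l_a / sqrt(m) * sqrt(hbar^2
    / (w_a * C))`` in Angstrom, with ``l_a`` the mass-weighted (orthonormal)
    mode vectors and ``C`` the eV <-> amu*A^2/fs^2 conversion.
    """

    def __init__(
        self,
        symbols: list[str],
        coords: np.ndarray,
        modes: NormalModeBasis,
        displacements: np.ndarray,
    ):
        from ._constants import EV_PER_AMU_ANG2_FS2, HBAR_EV_FS

        self.symbols = list(symbols)
        self.coords = np.asarray(coords, dtype=float)
        self.modes = modes
        self.displacements = np.asarray(displacements, dtype=float)  # (F, natom, 3)
        try:
            masses = np.array([_MASSES_AMU[s.upper()] for s in symbols])
        except KeyError as exc:
            raise ValueError(f"no mass tabulated for element {exc.args[0]!r}") from exc
        self.masses = masses
        length = HBAR_EV_FS / np.sqrt(modes.frequencies * EV_PER_AMU_ANG2_FS2)
        # (F, natom, 3) Cartesian displacement per unit dimensionless q
        self._cart_per_q = (
            self.displacements / np.sqrt(masses)[None, :, None] * length[:, None, None]
        )

    def gram_matrix(self) -> np.ndarray:
        """Gram matrix of the supplied mass-weighted mode vectors; identity
        for a properly orthonormalized set."""
        flat = self.displacements.reshape(self.modes.n_modes, -1)
        return flat @ flat.T

    def orthonormality_deviation(self) -> float:
        return float(np.max(np.abs(self.gram_matrix() - np.eye(self.modes.n_modes))))

    def displace(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if q.shape != (self.modes.n_modes,):
            raise ValueError(f"q must have shape ({self.modes.n_modes},)")
        return self.coords + np.tensordot(q, self._cart_per_q, axes=1)


def read_xyz_modes(
    xyz_path: str | Path, modes_path: str | Path
) -> tuple[NormalModeBasis, CartesianDisplacer]:
    """Read a reference geometry (XYZ) and mass-weighted normal modes.

    The modes file is plain text: a header line ``nmodes F natoms K``, then
    per mode a line ``mode <label> <frequency_ev> [irrep]`` followed by K
    rows of mass-weighted Cartesian displacement components.
    """
    xyz_lines = Path(xyz_path).read_text().splitlines()
    natoms = int(xyz_lines[0].split()[0])
    symbols, coords = [], []
    for line in xyz_lines[2 : 2 + natoms]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    coords = np.array(coords)

    lines = [ln for ln in Path(modes_path).read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    if header[0] != "nmodes":
        raise SchemaError(f"{modes_path}: header must start with 'nmodes'")
    f, k = int(header[1]), int(header[3])
    if k != natoms:
        raise ValueError(f"modes file has {k} atoms but geometry has {natoms}")
    freqs, labels, irreps, disp = [], [], [], []
    pos = 1
    for _ in range(f):
        head = lines[pos].split()
        if head[0] != "mode":
            raise SchemaError(f"{modes_path}: expected 'mode' line at {pos}")
        labels.append(head[1])
        freqs.append(float(head[2]))
        irreps.append(head[3] if len(head) > 3 else None)
        block = [[float(x) for x in lines[pos + 1 + i].split()] for i in range(k)]
        disp.append(block)
        pos += 1 + k
    sym = None if any(s is None for s in irreps) else tuple(irreps)
    modes = NormalModeBasis(
        frequencies=np.array(freqs), mode_labels=tuple(labels), symmetry=sym
    )
    displacer = CartesianDisplacer(symbols, coords, modes, np.array(disp))
    dev = displacer.orthonormality_deviation()
    if dev > 1e-6:
        warnings.warn(
            f"mass-weighted modes deviate from orthonormality by {dev:.2e}", stacklevel=2
        )
    return modes, displacer


# ---------------------------------------------------------------------------
# trajectory files (HDF5 with CSV mirrors)


def write_trajectory(result, path: str | Path, state_labels=None, attrs: dict | None = None) -> None:
    """Write a :class:`~lvckit.dynamics.PropagationResult` to HDF5.

    Stores times, populations, PES expectations (NaN where masked),
    autocorrelation, energy and norms, plus JSON-encoded metadata in the
    file attributes.  A ``.csv`` sibling with the population trace is
    written alongside as a human-readable mirror.
    """
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times_fs", data=result.times)
        fh.create_dataset("populations", data=result.populations)
        fh.create_dataset("pes_expectations_ev", data=result.pes_expectations.filled(np.nan))
        fh.create_dataset("autocorrelation", data=result.autocorrelation)
        fh.create_dataset("energy_ev", data=result.energy)
        fh.create_dataset("norms", data=result.norms)
        meta = dict(result.metadata)
        if attrs:
            meta.update(attrs)
        fh.attrs["metadata"] = json.dumps(meta)
        if state_labels is not None:
            fh.attrs["state_labels"] = json.dumps(list(state_labels))
    _write_trace_csv(result, path.with_suffix(".csv"), state_labels)


def _write_trace_csv(result, path: Path, state_labels=None) -> None:
    import pandas as pd

    n = result.populations.shape[1]
    labels = list(state_labels) if state_labels is not None else [f"d{i+1}" for i in range(n)]
    df = pd.DataFrame(result.populations, columns=[f"P[{lab}]" for lab in labels])
    df.insert(0, "time_fs", result.times)
    for i, lab in enumerate(labels):
        df[f"V[{lab}]_ev"] = result.pes_expectations.filled(np.nan)[:, i]
    df["energy_ev"] = result.energy
    df["norm"] = result.norms
    df.to_csv(path, index=False)


def read_trajectory(path: str | Path) -> dict:
    """Load a trajectory written by :func:`write_trajectory`."""
    import h5py

    out: dict = {}
    with h5py.File(path, "r") as fh:
        for key in ("times_fs", "populations", "pes_expectations_ev",
                    "autocorrelation", "energy_ev", "norms"):
            out[key] = fh[key][...]
        out["metadata"] = json.loads(fh.attrs.get("metadata", "{}"))
        labels = fh.attrs.get("state_labels")
        out["state_labels"] = json.loads(labels) if labels is not None else None
    return out
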