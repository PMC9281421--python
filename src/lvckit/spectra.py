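"""Vibronic absorption spectra from wavepacket autocorrelation functions.

For photoexcitation to a bright diabatic state ``b``, the contribution to
the absorption lineshape is the half-Fourier transform of the wavepacket
autocorrelation ``C_b(t) = <psi_b(0)|psi_b(t)>``:

    I_b(E)  propto  f_b * Re INT_0^T C_b(t) g(t) exp(i (E + E_0) t / hbar) dt

where ``f_b`` is the oscillator strength of the initially excited state,
``E_0`` is the zero-point energy of the initial (ground-surface) vibrational
state so that the energy axis reads as excitation energy from the relaxed
ground state, and ``g(t)`` is the Gaussian damping whose energy-domain
conjugate is a Gaussian lineshape of the requested half-width at half
maximum (default 0.04 eV).  The total spectrum is the pointwise sum of the
per-initial-state contributions, normalized to unit maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._constants import HBAR_EV_FS

__all__ = ["SpectrumResult", "absorption_spectrum", "gaussian_sigma_from_hwhm"]

DEFAULT_HWHM_EV = 0.04

#: required damping at the end of the time grid; below this the truncated
#: half-Fourier transform would ring at the requested resolution
_MIN_DAMPING_DECADES = 5.0


def gaussian_sigma_from_hwhm(hwhm: float) -> float:
    """Standard deviation of a Gaussian with the given half-width at half max."""
    return hwhm / np.sqrt(2.0 * np.log(2.0))


@dataclass
class SpectrumResult:
    """Energy-resolved absorption spectrum with per-initial-state parts."""

    energies: np.ndarray  # (E,) grid in eV (after any rigid shift)
    contributions: dict[str, np.ndarray]  # per initial state, same normalization
    total: np.ndarray  # pointwise sum of contributions
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"energy_ev": self.energies})
        for name, curve in self.contributions.items():
            df[name] = curve
        df["total"] = self.total
        return df


def _lineshape(
    times: np.ndarray,
    autocorr: np.ndarray,
    energies: np.ndarray,
    sigma: float,
    e_zero: float,
) -> np.ndarray:
    damping = np.exp(-0.5 * (sigma * times / HBAR_EV_FS) ** 2)
    damped = autocorr * damping
    # trapezoid weights on the uniform grid; t = 0 enters with half weight
    dt = times[1] - times[0]
    w = np.full(times.size, dt)
    w[0] *= 0.5
    w[-1] *= 0.5
    phases = np.exp(1j * np.outer(energies + e_zero, times) / HBAR_EV_FS)
    return np.real(phases @ (damped * w))


def absorption_spectrum(
    autocorrelations: dict[str, tuple[np.ndarray, np.ndarray]],
    oscillator_strengths: dict[str, float],
    hwhm: float = DEFAULT_HWHM_EV,
    grid: np.ndarray | None = None,
    zero_point_energy: float = 0.0,
    vertical_energies: dict[str, float] | None = None,
    shift: float = 0.0,
    energy_prefactor: bool = False,
    normalize: bool = True,
) -> SpectrumResult:
    """Absorption spectrum from per-bright-state autocorrelation functions.

    Parameters
    ----------
    autocorrelations
        Mapping ``state label -> (times_fs, C(t))`` with a uniform time
        grid starting at t = 0 (e.g. from
        :attr:`~lvckit.dynamics.PropagationResult.autocorrelation`).
    oscillator_strengths
        ``f_b`` of each initially excited diabatic state; weights the
        state's contribution.
    hwhm
        Half-width at half maximum of the Gaussian broadening in eV.
    grid
        Energy grid in eV; if omitted, built from ``vertical_energies``
        (+/- 1.5 eV around their range) or from scratch.
    zero_point_energy
        Zero-point energy of the initial vibrational state (eV); shifts
        the energy axis so it reads as excitation energy.
    shift
        Rigid shift of the energy axis (eV), applied last; a comparison
        device for plots against experiment, never computed here.
    energy_prefactor
        If True, multiply intensities by the photon energy E (dipole vs
        oscillator-strength weighting convention); off by default.
    normalize
        Normalize the total curve to unit maximum (contributions scaled by
        the same factor so the sum rule is preserved).

    Raises
    ------
    ValueError
        If the time grid is too short for the requested broadening: the
        damping must suppress C(T) by several decades or the truncated
        transform rings.
    """
    if hwhm <= 0:
        raise ValueError("hwhm must be positive")
    if not autocorrelations:
        raise ValueError("need at least one autocorrelation trace")
    if all(float(oscillator_strengths.get(k, 0.0)) == 0.0 for k in autocorrelations):
        warnings.warn(
            "all oscillator strengths are zero; the spectrum will vanish "
            "(did the model lose its state metadata?)",
            stacklevel=2,
        )
    sigma = gaussian_sigma_from_hwhm(hwhm)

    t_needed = np.sqrt(2.0 * _MIN_DAMPING_DECADES * np.log(10.0)) * HBAR_EV_FS / sigma
    for name, (times, _) in autocorrelations.items():
        times = np.asarray(times, dtype=float)
        if times.size < 2 or not np.allclose(np.diff(times), times[1] - times[0]):
            raise ValueError(f"autocorrelation {name!r}: need a uniform time grid")
        if times[0] != 0.0:
            raise ValueError(f"autocorrelation {name!r}: time grid must start at 0")
        if times[-1] < t_needed:
            raise ValueError(
                f"time grid for {name!r} too short for hwhm={hwhm} eV: need "
                f"t_final >= {t_needed:.1f} fs, got {times[-1]:.1f} fs"
            )

    if grid is None:
        if vertical_energies:
            lo = min(vertical_energies.values()) - 1.5
            hi = max(vertical_energies.values()) + 1.5
        else:
            lo, hi = 0.0, 10.0
        grid = np.linspace(lo, hi, 2001)
    grid = np.asarray(grid, dtype=float)

    contributions: dict[str, np.ndarray] = {}
    for name, (times, corr) in autocorrelations.items():
        f_b = float(oscillator_strengths.get(name, 0.0))
        curve = f_b * _lineshape(
            np.asarray(times, float), np.asarray(corr, complex), grid, sigma, zero_point_energy
        )
        if energy_prefactor:
            curve = curve * grid
        contributions[name] = curve

    total = np.sum(list(contributions.values()), axis=0)
    scale = 1.0
    if normalize:
        peak = float(np.max(np.abs(total)))
        if peak > 0:
            scale = 1.0 / peak
    contributions = {k: v * scale for k, v in contributions.items()}
    total = total * scale

    return SpectrumResult(
        energies=grid + shift,
        contributions=contributions,
        total=total,
        metadata={
            "hwhm_ev": hwhm,
            "sigma_ev": sigma,
            "shift_ev": shift,
            "zero_point_energy_ev": zero_point_energy,
            "energy_prefactor": energy_prefactor,
            "normalized": normalize,
        },
    )
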