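"""Physical constants and unit conventions.

Energies are in eV throughout, nuclear coordinates are the dimensionless
normal-mode coordinates of the electronic ground state, and time is in
femtoseconds.  With these choices the only constant that ever enters is
hbar in eV*fs.
"""

#: Reduced Planck constant in eV*fs (CODATA).
HBAR_EV_FS: float = 0.6582119569

#: 1 amu * Angstrom**2 / fs**2 expressed in eV; used when converting
#: dimensionless normal-mode displacements to Cartesian geometries.
EV_PER_AMU_ANG2_FS2: float = 103.642697
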