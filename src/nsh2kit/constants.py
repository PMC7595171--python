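"""Physical constants and unit conventions.

Internal units throughout the package: lengths in nm, energies in kJ/mol,
temperatures in K, times in ps.  Angstrom appears only at I/O boundaries
(PDB files, order-parameter reports) with explicit conversion.
"""

#: Boltzmann constant, kJ/mol/K
KB = 0.0083145

#: Angstrom per nanometer
A_PER_NM = 10.0


def beta(temperature: float) -> float:
    """Inverse temperature 1/(kB*T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)


def nm_to_angstrom(x):
    return x * A_PER_NM


def angstrom_to_nm(x):
    return x / A_PER_NM
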