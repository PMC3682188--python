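"""Physical constants and the internal unit system.

Internal units: length nm, energy kcal/mol, mass amu, temperature K,
time ps.  With this choice accelerations require the kcal->kJ factor
(``KCAL_TO_KJ``) because amu*nm^2/ps^2 = kJ/mol.  EPR-side lengths are
reported in Angstrom (1 nm = 10 A).
"""

#: Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

#: kcal/mol -> kJ/mol (amu nm^2/ps^2)
KCAL_TO_KJ = 4.184

#: nm -> Angstrom
NM_TO_ANG = 10.0


def kt(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol."""
    return KB * temperature
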