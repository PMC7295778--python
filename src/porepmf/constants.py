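"""Physical constants and unit conversions.

Internal units throughout the package: length in Angstrom (A), energy in
kJ/mol, time in ps, temperature in K, electric field in V/nm (converted at
use sites), charge in elementary charges.
"""

#: Boltzmann constant, kJ mol^-1 K^-1 (CODATA-consistent value).
KB = 0.0083144621

#: Energy gained by one elementary charge crossing 1 V: kJ/mol per (e*V).
FARADAY_KJ_PER_MOL_V = 96.485

#: Conversion of a uniform field in V/nm acting on charge q (in e) to a
#: potential slope in kJ mol^-1 A^-1:  U_field(z) = -q * E * FIELD_SLOPE * z.
FIELD_SLOPE_KJ_PER_MOL_A = FARADAY_KJ_PER_MOL_V / 10.0  # 9.6485

#: Bondi van der Waals radius of oxygen, A.
R_VDW_OXYGEN = 1.52


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature


def force_constant_nm2_to_A2(k_kj_per_mol_nm2: float) -> float:
    """Convert a harmonic force constant from kJ/mol/nm^2 to kJ/mol/A^2."""
    return k_kj_per_mol_nm2 / 100.0
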