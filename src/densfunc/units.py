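"""Unit conventions and conversion constants.

All internal quantities use a single unit system: lengths in angstrom (Å),
energies in kcal·mol⁻¹, masses in unified atomic mass units (amu), time in
femtoseconds (fs). Conversions to other conventions (bohr in cube files,
atomic units of time for thermostat friction) happen only at interfaces,
using the constants defined here and nowhere else.
"""

#: 1 bohr in Å.
BOHR_TO_ANGSTROM = 0.529177

#: 1 atomic unit of time in fs.
AU_TIME_FS = 0.02418884

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹.
KB_KCAL_MOL_K = 0.0019872041

#: Acceleration in Å·fs⁻² produced by a force of 1 kcal·mol⁻¹·Å⁻¹ acting on
#: a mass of 1 amu.  Derived from 1 kcal = 4184 J exactly:
#: 4184 J·mol⁻¹·Å⁻¹ / (1e-3 kg·mol⁻¹) = 4.184e26 Å·s⁻² = 4.184e-4 Å·fs⁻².
FORCE_TO_ACCEL = 4.184e-4

#: Kinetic-energy conversion: KE[kcal·mol⁻¹] = ½ m v² [amu·Å²·fs⁻²] / FORCE_TO_ACCEL.
KINETIC_TO_KCAL = 1.0 / FORCE_TO_ACCEL


def friction_au_to_fs(friction_au: float) -> float:
    """Convert a Langevin friction from atomic units (a.u.⁻¹) to fs⁻¹.

    Example: 0.01 a.u. of friction is 0.413 fs⁻¹.
    """
    return friction_au / AU_TIME_FS
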