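"""Unit conventions shared by every module.

All energies are in eV, distances in Å, charges in units of the elementary
charge e, temperatures in K, times in fs.  The single Coulomb conversion
constant below turns q_i q_j / r (e²/Å) into eV; keeping one constant in one
place avoids silent unit mismatches between the summation modules.
"""

from __future__ import annotations

#: Coulomb constant e²/(4πϵ₀) in eV·Å·e⁻².
COULOMB_CONSTANT = 14.399645

#: Boltzmann constant in eV·K⁻¹.
K_B = 8.617333e-5

#: 1 amu·(Å/fs)² expressed in eV — converts kinetic energy m v²/2 with
#: masses in amu and velocities in Å/fs into eV.
AMU_A2_FS2_TO_EV = 103.642696

#: Reduced Planck constant in eV·fs.
HBAR = 0.6582119569

#: Atomic masses (amu) for the elements the toy systems use.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Cl": 35.453,
    "X": 12.011,  # generic heavy site in toy molecules
}


def thermal_voltage(temperature: float) -> float:
    """k_B·T/e in volts (numerically equal to k_B·T in eV)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return K_B * temperature
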