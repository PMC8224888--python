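"""Thermodynamic constants and unit conversions.

All internal energies are expressed in units of k_B*T (dimensionless);
this module supplies the conversions to SI and kcal/mol used for
reporting, and the conversion of wall spring constants quoted in pN/Å
into k_B*T/Å².
"""

from dataclasses import dataclass

BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO_PER_MOL = 6.02214076e23
JOULES_PER_KCAL = 4184.0

#: 1 pN/Å expressed in J/Å² (1e-12 N per 1e-10 m, per Å of displacement).
PN_PER_ANGSTROM_IN_J_PER_A2 = 1.0e-22


@dataclass(frozen=True)
class Thermo:
    """Temperature context for energy-unit conversions.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Default 310 K (physiological).
    """

    temperature: float = 310.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")

    @property
    def kT_joules(self) -> float:
        return BOLTZMANN_J_PER_K * self.temperature

    @property
    def kT_kcal_per_mol(self) -> float:
        return self.kT_joules * AVOGADRO_PER_MOL / JOULES_PER_KCAL

    def kT_to_kcal_per_mol(self, energy_kT: float) -> float:
        """Convert an energy in k_B*T units to kcal/mol."""
        return energy_kT * self.kT_kcal_per_mol

    def spring_pN_per_A_to_kT_per_A2(self, spring_pN_per_A: float) -> float:
        """Convert a spring constant from pN/Å to k_B*T/Å².

        At 310 K, 10 pN/Å ≈ 0.2336 k_B*T/Å².
        """
        return spring_pN_per_A * PN_PER_ANGSTROM_IN_J_PER_A2 / self.kT_joules
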