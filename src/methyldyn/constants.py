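"""Physical constants for ¹⁵N and methyl ¹H–¹H relaxation calculations.

The defaults are the values conventionally used in the methyl-relaxation
literature; every one of them can be overridden at construction, since
CSA and effective bond-length conventions vary between labs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: gas constant, J mol⁻¹ K⁻¹ (for entropy unit conversion)
GAS_CONSTANT = 8.31446261815324


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bag of constants entering the relaxation expressions.

    Attributes
    ----------
    gamma_H, gamma_N : float
        Gyromagnetic ratios, rad s⁻¹ T⁻¹ (¹⁵N is negative).
    hbar : float
        Reduced Planck constant, J s.
    mu0_over_4pi : float
        Magnetic constant over 4π, T² J⁻¹ m³.
    r_NH : float
        Effective amide N–H bond length, m.
    r_HH_methyl : float
        Intra-methyl ¹H–¹H distance, m.
    delta_sigma_N_ppm : float
        ¹⁵N chemical-shift anisotropy, ppm.
    theta_axis_HH_deg : float
        Angle between the methyl symmetry axis and the H–H vector, degrees.
        90° for an ideal tetrahedral methyl group.
    """

    gamma_H: float = 2.6752218744e8
    gamma_N: float = -2.7126e7
    hbar: float = 1.054571817e-34
    mu0_over_4pi: float = 1e-7
    r_NH: float = 1.02e-10
    r_HH_methyl: float = 1.813e-10
    delta_sigma_N_ppm: float = -170.0
    theta_axis_HH_deg: float = 90.0

    # -- derived quantities -------------------------------------------------

    def omega_H(self, field_MHz: float) -> float:
        """¹H Larmor frequency in rad s⁻¹ at the given spectrometer field."""
        return 2.0 * math.pi * field_MHz * 1e6

    def omega_N(self, field_MHz: float) -> float:
        """¹⁵N Larmor frequency in rad s⁻¹ (sign follows γ_N)."""
        return self.omega_H(field_MHz) * self.gamma_N / self.gamma_H

    def dipolar_NH_squared(self) -> float:
        """d² = [(μ₀/4π)·ħ·γ_H·γ_N / r³_NH]², rad² s⁻²."""
        d = self.mu0_over_4pi * self.hbar * self.gamma_H * self.gamma_N / self.r_NH**3
        return d * d

    def csa_N_squared(self, field_MHz: float) -> float:
        """c² = (Δσ·ω_N)²/3, rad² s⁻²."""
        c = self.delta_sigma_N_ppm * 1e-6 * self.omega_N(field_MHz)
        return c * c / 3.0

    def p2_axis_HH(self) -> float:
        """P₂(cos θ_axis,HH); −1/2 for the ideal 90° geometry."""
        x = math.cos(math.radians(self.theta_axis_HH_deg))
        return 0.5 * (3.0 * x * x - 1.0)


DEFAULT_CONSTANTS = PhysicalConstants()


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + 273.15
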