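"""Physical constants and unit conversions.

The package keeps a single canonical unit system throughout the numerics:
length in dm, volume in dm^3 (= litre), concentration in mol/dm^3 (= mol/L),
voltage in volt, time in second, specific conductance in S/dm^2, specific
capacitance in F/dm^2 and transmembrane flux density in C/(dm^2 s).

Laboratory-style inputs (uS/cm^2, F/cm^2, mM, um, pL) are converted at the
constructors; keeping one canon internally avoids silent factor-of-100
errors between cm- and dm-based quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "US_PER_CM2",
    "F_PER_CM2",
    "UM",
    "MM",
    "PL_PER_L",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants at body temperature (37 C).

    Attributes
    ----------
    F : float
        Faraday constant, C/mol.
    R : float
        Universal gas constant, J/(K mol).
    T : float
        Absolute temperature, K. Fixed at 310.15 K; the model applies no
        temperature scaling anywhere.
    """

    F: float = 96485.33
    R: float = 8.31446
    T: float = 310.15

    @property
    def RTF(self) -> float:
        """Thermal voltage RT/F in volt (~26.73 mV at 37 C)."""
        return self.R * self.T / self.F

    @property
    def RT_pressure(self) -> float:
        """RT expressed in N dm/mol (1 J = 10 N dm).

        Used to convert the membrane-tension pressure term into an
        equivalent osmolarity offset in mol/dm^3.
        """
        return self.R * self.T * 10.0


CONSTANTS = PhysicalConstants()

# Multiplicative conversions into canonical units.
US_PER_CM2 = 1e-4  # 1 uS/cm^2 = 1e-6 S / 1e-2 dm^2 = 1e-4 S/dm^2
F_PER_CM2 = 1e2    # 1 F/cm^2 = 100 F/dm^2
UM = 1e-5          # 1 um = 1e-5 dm
MM = 1e-3          # 1 mM = 1e-3 mol/L
PL_PER_L = 1e12    # 1 L (dm^3) = 1e12 pL
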