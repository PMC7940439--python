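"""Physical constants and unit conversions.

The internal unit system is (nm, ms, mM).  Diffusion coefficients are
stored in nm^2/ms, rate constants in ms^-1, bimolecular rate constants in
mM^-1 ms^-1, and concentrations in mM.  Avogadro's number is carried
explicitly wherever a per-ion volume is needed.
"""

#: Avogadro constant (mol^-1), CODATA 2018 exact value.
N_AVOGADRO = 6.02214076e23

#: nm^3 per litre.
NM3_PER_LITRE = 1.0e24

#: Ion number density of a 1 mM solution, in ions/nm^3:
#: 1 mM = 1e-3 mol/L = 1e-3 * N_A ions per 1e24 nm^3.
IONS_PER_NM3_PER_MM = N_AVOGADRO * 1.0e-27

#: Conversion of a bimolecular rate constant from mM^-1 ms^-1 to
#: nm^3 ms^-1 per ion:  1 mM^-1 ms^-1 = (1e27 / N_A) nm^3/ms.
KON_MM_TO_NM3 = 1.0e27 / N_AVOGADRO

#: Elementary charge (C).
ELEMENTARY_CHARGE = 1.602176634e-19

#: Ions of Ca2+ per millisecond carried by 1 pA of current
#: (1 pA = 1e-12 C/s; each ion carries charge 2e).
IONS_PER_MS_PER_PA = 1.0e-12 / (2.0 * ELEMENTARY_CHARGE) * 1.0e-3

#: micrometre^2/ms -> nm^2/ms
UM2_TO_NM2 = 1.0e6


def kon_to_nm3_per_ms(k_on_mm: float) -> float:
    """Convert a bimolecular rate constant from mM^-1 ms^-1 to nm^3/ms per ion."""
    return k_on_mm * KON_MM_TO_NM3
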