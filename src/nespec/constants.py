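"""Physical constants and unit-conversion factors.

The eV <-> nm conversion constant hc is pinned so that wavelength/energy
conversions are bit-stable across the package: lambda [nm] = HC_EV_NM / E [eV].
"""

import math

#: Planck constant times speed of light, in eV·nm (CODATA, rounded to 1e-6 nm·eV).
HC_EV_NM: float = 1239.841984

#: FWHM of a Gaussian divided by its standard deviation: 2*sqrt(2*ln 2).
FWHM_OVER_SIGMA: float = 2.0 * math.sqrt(2.0 * math.log(2.0))


def ev_to_nm(energy_ev: float) -> float:
    """Convert a photon energy in eV to its vacuum wavelength in nm."""
    return HC_EV_NM / energy_ev


def nm_to_ev(wavelength_nm: float) -> float:
    """Convert a vacuum wavelength in nm to photon energy in eV."""
    return HC_EV_NM / wavelength_nm
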