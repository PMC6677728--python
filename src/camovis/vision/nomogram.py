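"""Visual-pigment absorbance templates (Govardovskii et al. 2000, A1).

The template gives a pigment's relative absorbance as a function of
wavelength from its peak wavelength alone, as the sum of an alpha band
(main peak) and a smaller beta band at shorter wavelengths.
"""

from __future__ import annotations

import numpy as np

from ..spectra import GRID

# alpha-band shape constants for A1 pigments
_A = 69.7
_B = 28.0
_C = -14.9
_D = 0.674
_b = 0.922
_c = 1.104

# beta-band constants
_A_BETA = 0.26


def govardovskii_a1(lambda_max: float, wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the A1 pigment template (alpha + beta band), unnormalised.

    Parameters
    ----------
    lambda_max : peak wavelength of the alpha band, nm.
    wavelengths : evaluation grid in nm; defaults to the shared 300..700 grid.
    """
    wl = GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )
    lambda_m_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = _A_BETA * np.exp(-(((wl - lambda_m_beta) / b_beta) ** 2))
    return alpha + beta
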