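"""Illuminant spectra on the shared 1 nm grid, in relative quantal units."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ..spectra import GRID, GRID_SIZE


def _load_d65_energy() -> tuple[np.ndarray, np.ndarray]:
    ref = resources.files("camovis.vision").joinpath("data/cie_d65_10nm.csv")
    with ref.open("r") as fh:
        table = pd.read_csv(fh)
    return (
        table["wavelength_nm"].to_numpy(dtype=float),
        table["relative_spectral_power"].to_numpy(dtype=float),
    )


def d65_quantal() -> np.ndarray:
    """CIE D65 daylight converted to relative quantal irradiance.

    The tabulated relative spectral power (energy units, 10 nm steps) is
    interpolated to 1 nm and multiplied by wavelength (photon energy is
    proportional to 1/lambda), then scaled to unit maximum.
    """
    wl, power = _load_d65_energy()
    energy = np.interp(GRID, wl, power)
    quanta = energy * GRID
    return quanta / quanta.max()


def ideal_flat() -> np.ndarray:
    """Idealised illuminant: equal photon flux at every wavelength."""
    return np.ones(GRID_SIZE)


_BUILTIN = {"d65": d65_quantal, "ideal": ideal_flat}


def get_illuminant(name: str) -> np.ndarray:
    try:
        return _BUILTIN[name.lower()]()
    except KeyError:
        raise KeyError(
            f"unknown illuminant {name!r}; built-ins: {sorted(_BUILTIN)}"
        ) from None
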