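"""Receiver definition: cone sensitivities, abundances, noise, illuminant."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ..spectra import GRID, GRID_SIZE
from .illuminants import get_illuminant
from .nomogram import govardovskii_a1

#: Chromatic cone classes, in the receptor order used by the noise model
#: (1=UV, 2=SW, 3=MW, 4=LW).
CHROMATIC_CONES = ("UV", "SW", "MW", "LW")

#: Blue tit single-cone peak wavelengths (nm); the double (DD) cone shares
#: the LW pigment.  Generated from the A1 template; oil-droplet and ocular
#: media filtering are deliberately omitted (documented limitation).
BLUETIT_LAMBDA_MAX = {"UV": 371.0, "SW": 448.0, "MW": 503.0, "LW": 563.0, "DD": 563.0}

#: Blue tit relative cone abundances, anchored to LW = 1.
BLUETIT_ABUNDANCES = {"UV": 0.3704, "SW": 0.7111, "MW": 0.9926, "LW": 1.0}

DEFAULT_WEBER = 0.05


@dataclass
class ConeSensitivity:
    """Peak-normalised spectral sensitivity of one cone class."""

    cone_class: str
    lambda_max: float
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if self.sensitivity.shape != (GRID_SIZE,):
            raise ValueError("sensitivity must be on the shared 401-point grid")
        if np.any(self.sensitivity < 0):
            raise ValueError("sensitivity must be non-negative")
        if not np.isclose(self.sensitivity.max(), 1.0):
            raise ValueError("sensitivity must be peak-normalised to 1")


@dataclass
class Illuminant:
    name: str
    irradiance: np.ndarray  # relative quantal units on the shared grid

    def __post_init__(self) -> None:
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if self.irradiance.shape != (GRID_SIZE,):
            raise ValueError("irradiance must be on the shared 401-point grid")
        if np.any(self.irradiance < 0) or not np.any(self.irradiance > 0):
            raise ValueError("irradiance must be non-negative and not all zero")


def pigment_template(lambda_max: float, cone_class: str = "") -> ConeSensitivity:
    """A1-template cone sensitivity, peak-normalised to 1 on the grid."""
    if not (GRID[0] <= lambda_max <= GRID[-1]):
        raise ValueError(f"lambda_max {lambda_max} nm outside the 300-700 nm grid")
    curve = govardovskii_a1(lambda_max)
    return ConeSensitivity(cone_class, lambda_max, curve / curve.max())


@dataclass
class ViewerModel:
    """A receiver: sensitivities, abundances, Weber fractions, illuminant."""

    sensitivities: dict[str, ConeSensitivity]
    abundances: dict[str, float] = field(
        default_factory=lambda: dict(BLUETIT_ABUNDANCES)
    )
    weber: float = DEFAULT_WEBER
    weber_dd: float = DEFAULT_WEBER
    illuminant: Illuminant = None  # type: ignore[assignment]
    name: str = "viewer"

    def __post_init__(self) -> None:
        for cone in (*CHROMATIC_CONES, "DD"):
            if cone not in self.sensitivities:
                raise ValueError(f"missing sensitivity for cone class {cone}")
        for cone in CHROMATIC_CONES:
            if self.abundances.get(cone, 0.0) <= 0:
                raise ValueError(f"abundance for {cone} must be > 0")
        if not np.isclose(self.abundances["LW"], 1.0):
            raise ValueError("abundances must be anchored to the reference cone LW = 1")
        if self.weber <= 0 or self.weber_dd <= 0:
            raise ValueError("Weber fractions must be > 0")
        if self.illuminant is None:
            self.illuminant = Illuminant("d65", get_illuminant("d65"))


def receptor_noise(viewer: ViewerModel) -> dict[str, float]:
    """Per-cone noise e_i = w / sqrt(eta_i), Weber anchored to LW (eta = 1)."""
    return {
        cone: viewer.weber / np.sqrt(viewer.abundances[cone])
        for cone in CHROMATIC_CONES
    }


def bluetit(illuminant: str = "d65") -> ViewerModel:
    """Packaged default viewer: blue tit tetrachromat under D65."""
    sens = {
        cone: pigment_template(lmax, cone)
        for cone, lmax in BLUETIT_LAMBDA_MAX.items()
    }
    return ViewerModel(
        sensitivities=sens,
        abundances=dict(BLUETIT_ABUNDANCES),
        illuminant=Illuminant(illuminant, get_illuminant(illuminant)),
        name="bluetit",
    )


def load_viewer(source: str | Path) -> ViewerModel:
    """Build a viewer from a YAML config file.

    Keys: ``lambda_max`` (mapping cone class -> nm), ``abundances``,
    ``weber``, ``weber_dd``, ``illuminant`` (built-in name).  Missing keys
    fall back to the blue tit defaults.
    """
    with open(source) as fh:
        cfg = yaml.safe_load(fh) or {}
    lmax = {**BLUETIT_LAMBDA_MAX, **{k: float(v) for k, v in cfg.get("lambda_max", {}).items()}}
    abundances = {**BLUETIT_ABUNDANCES, **{k: float(v) for k, v in cfg.get("abundances", {}).items()}}
    illum_name = cfg.get("illuminant", "d65")
    sens = {cone: pigment_template(v, cone) for cone, v in lmax.items()}
    return ViewerModel(
        sensitivities=sens,
        abundances=abundances,
        weber=float(cfg.get("weber", DEFAULT_WEBER)),
        weber_dd=float(cfg.get("weber_dd", DEFAULT_WEBER)),
        illuminant=Illuminant(illum_name, get_illuminant(illum_name)),
        name=str(cfg.get("name", "custom")),
    )
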