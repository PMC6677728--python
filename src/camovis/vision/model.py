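"""Quantum catches, opponent statistics, tetrahedral colour space, and
receptor-noise-limited discriminability in JND units.

The chromatic distance between two stimuli is the Vorobyev-Osorio
receptor-noise-limited (RNL) metric for a tetrachromat: log catch
contrasts per cone, combined in a quadratic form weighted by per-cone
noise ``e_i = w / sqrt(eta_i)``.  Achromatic (luminance) distance uses
the double-cone catch alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..spectra import GRID_SIZE, ReflectanceSpectrum
from .viewer import CHROMATIC_CONES, ConeSensitivity, Illuminant, ViewerModel, receptor_noise

#: Quantum catches are floored here so that log contrasts stay finite for
#: pathological (all-zero) spectra.
CATCH_FLOOR = 1e-12

#: Circumradius of the colour-space tetrahedron.
TETRA_RADIUS = 0.75

#: Vertices of a regular tetrahedron centred on the origin, circumradius
#: 0.75, UV on the +z axis.  The remaining three vertices sit at
#: z = -0.25 on a circle of radius sqrt(0.75^2 - 0.25^2) = sqrt(0.5).
_RXY = np.sqrt(TETRA_RADIUS**2 - (TETRA_RADIUS / 3.0) ** 2)
TETRA_VERTICES = {
    "UV": np.array([0.0, 0.0, TETRA_RADIUS]),
    "SW": np.array([_RXY, 0.0, -TETRA_RADIUS / 3.0]),
    "MW": np.array([-_RXY / 2.0, _RXY * np.sqrt(3.0) / 2.0, -TETRA_RADIUS / 3.0]),
    "LW": np.array([-_RXY / 2.0, -_RXY * np.sqrt(3.0) / 2.0, -TETRA_RADIUS / 3.0]),
}

#: JND classification thresholds.
JND_LOWER = 1.0
JND_UPPER = 3.0


@dataclass
class ConeCatchVector:
    """Quantum catches of the four single cones and the double cone."""

    q_uv: float
    q_sw: float
    q_mw: float
    q_lw: float
    q_dd: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("q_uv", "q_sw", "q_mw", "q_lw", "q_dd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def chromatic(self) -> np.ndarray:
        """Catches in receptor order (UV, SW, MW, LW)."""
        return np.array([self.q_uv, self.q_sw, self.q_mw, self.q_lw])


@dataclass
class TetraPoint:
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class DiscriminationResult:
    id_a: str
    id_b: str
    delta_f: dict[str, float]
    jnd_chromatic: float
    jnd_achromatic: float
    class_chromatic: str
    class_achromatic: str


@dataclass
class PerceptualSummary:
    individual_id: str
    greenness: float
    luminance: float
    tetra: TetraPoint


def quantum_catch(
    spectrum: ReflectanceSpectrum, cone: ConeSensitivity, illuminant: Illuminant
) -> float:
    """q = integral of R * I * S over wavelength (trapezoid, 1 nm steps)."""
    if spectrum.reflectance.shape != (GRID_SIZE,):
        raise ValueError("spectrum not on the shared grid")
    integrand = spectrum.reflectance * illuminant.irradiance * cone.sensitivity
    q = float(np.trapezoid(integrand, dx=1.0))
    return max(q, CATCH_FLOOR)


def catch_vector(spectrum: ReflectanceSpectrum, viewer: ViewerModel) -> ConeCatchVector:
    """Quantum catch per cone class; no von Kries normalisation is applied."""
    q = {
        cone: quantum_catch(spectrum, viewer.sensitivities[cone], viewer.illuminant)
        for cone in (*CHROMATIC_CONES, "DD")
    }
    return ConeCatchVector(
        q_uv=q["UV"], q_sw=q["SW"], q_mw=q["MW"], q_lw=q["LW"], q_dd=q["DD"],
        label=spectrum.label,
    )


def greenness(catch: ConeCatchVector) -> float:
    """Opponent green statistic MW / (MW + LW), strictly inside (0, 1)."""
    return catch.q_mw / (catch.q_mw + catch.q_lw)


def luminance(catch: ConeCatchVector) -> float:
    """Double-cone catch, the achromatic (luminance) signal."""
    return catch.q_dd


def tetra_coords(catch: ConeCatchVector) -> TetraPoint:
    """Map relative chromatic catches into the colour-space tetrahedron.

    Relative catches r_i = q_i / sum(q) are barycentric coordinates; the
    point is the corresponding convex combination of the four vertices, so
    equal stimulation maps to the origin and a pure-cone stimulus to that
    cone's vertex at radius 0.75.
    """
    q = catch.chromatic()
    r = q / q.sum()
    point = sum(r_i * TETRA_VERTICES[cone] for r_i, cone in zip(r, CHROMATIC_CONES))
    return TetraPoint(*point)


def delta_f(a: ConeCatchVector, b: ConeCatchVector) -> np.ndarray:
    """Per-cone log catch contrast ln(q_a / q_b), receptor order UV,SW,MW,LW."""
    return np.log(a.chromatic() / b.chromatic())


def chromatic_jnd(a: ConeCatchVector, b: ConeCatchVector, viewer: ViewerModel) -> float:
    """RNL chromatic distance between two catch vectors, in JND units.

    For receptors 1..4 = UV, SW, MW, LW with noise e_i:

        N = (e1 e2)^2 (df4-df3)^2 + (e1 e3)^2 (df4-df2)^2
          + (e1 e4)^2 (df3-df2)^2 + (e2 e3)^2 (df4-df1)^2
          + (e2 e4)^2 (df3-df1)^2 + (e3 e4)^2 (df2-df1)^2
        D = (e1 e2 e3)^2 + (e1 e2 e4)^2 + (e1 e3 e4)^2 + (e2 e3 e4)^2
        JND = sqrt(N / D)
    """
    noise = receptor_noise(viewer)
    e1, e2, e3, e4 = (noise[c] for c in CHROMATIC_CONES)
    f1, f2, f3, f4 = delta_f(a, b)
    num = (
        (e1 * e2) ** 2 * (f4 - f3) ** 2
        + (e1 * e3) ** 2 * (f4 - f2) ** 2
        + (e1 * e4) ** 2 * (f3 - f2) ** 2
        + (e2 * e3) ** 2 * (f4 - f1) ** 2
        + (e2 * e4) ** 2 * (f3 - f1) ** 2
        + (e3 * e4) ** 2 * (f2 - f1) ** 2
    )
    den = (
        (e1 * e2 * e3) ** 2
        + (e1 * e2 * e4) ** 2
        + (e1 * e3 * e4) ** 2
        + (e2 * e3 * e4) ** 2
    )
    return float(np.sqrt(num / den))


def dichromat_jnd(
    qa: tuple[float, float], qb: tuple[float, float], e: tuple[float, float]
) -> float:
    """Two-receptor RNL distance: |df1 - df2| / sqrt(e1^2 + e2^2).

    Dedicated closed-form path for dichromat viewers; the tetrachromat
    quadratic form must not be abused with near-zero abundances for this.
    """
    df1 = np.log(qa[0] / qb[0])
    df2 = np.log(qa[1] / qb[1])
    return float(abs(df1 - df2) / np.sqrt(e[0] ** 2 + e[1] ** 2))


def achromatic_jnd(a: ConeCatchVector, b: ConeCatchVector, viewer: ViewerModel) -> float:
    """Luminance distance |ln(q_DD^a / q_DD^b)| / w_DD."""
    return float(abs(np.log(a.q_dd / b.q_dd)) / viewer.weber_dd)


def classify_jnd(jnd: float) -> str:
    """Interpret a JND value.

    < 1 is indiscriminable; 1-3 discriminable only under good viewing
    conditions ("conditional"); > 3 discriminable with increasing ease.
    """
    if jnd < 0:
        raise ValueError("JND must be non-negative")
    if jnd < JND_LOWER:
        return "indiscriminable"
    if jnd <= JND_UPPER:
        return "conditional"
    return "discriminable"


def discriminate(
    a: ConeCatchVector, b: ConeCatchVector, viewer: ViewerModel
) -> DiscriminationResult:
    """Full chromatic + achromatic discriminability between two stimuli."""
    df = delta_f(a, b)
    chrom = chromatic_jnd(a, b, viewer)
    achrom = achromatic_jnd(a, b, viewer)
    return DiscriminationResult(
        id_a=a.label,
        id_b=b.label,
        delta_f=dict(zip(CHROMATIC_CONES, df.tolist())),
        jnd_chromatic=chrom,
        jnd_achromatic=achrom,
        class_chromatic=classify_jnd(chrom),
        class_achromatic=classify_jnd(achrom),
    )


def perceptual_summary(
    spectrum: ReflectanceSpectrum, viewer: ViewerModel, individual_id: str | None = None
) -> PerceptualSummary:
    catch = catch_vector(spectrum, viewer)
    return PerceptualSummary(
        individual_id=individual_id or spectrum.label,
        greenness=greenness(catch),
        luminance=luminance(catch),
        tetra=tetra_coords(catch),
    )
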