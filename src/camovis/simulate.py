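"""Seeded generators for spectra, choice trials, and qPCR tables.

Every generator is a pure function of its parameters and a seed.  A single
global seed expands into independent per-stream generators via
``numpy.random.default_rng([seed, stream])`` with fixed stream ids
(0 = spectra, 1 = choice, 2 = qPCR).

Spectral noise is a low-order random cosine series rather than white
noise, so generated curves stay smooth and clipping artifacts are rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviour import ChoiceTrial
from .expression import DERMAL_TISSUES, GENES, HEAD_TISSUE, REFERENCE_GENE
from .spectra import GRID, ReflectanceSpectrum

STREAM_SPECTRA = 0
STREAM_CHOICE = 1
STREAM_QPCR = 2

#: Default per-group sample sizes of the diagonal-arena choice experiment,
#: keyed by (larval colour, blindfold).
DIAGONAL_GROUP_SIZES = {
    ("brown", "control"): 60,
    ("brown", "painted"): 56,
    ("green", "control"): 59,
    ("green", "painted"): 51,
}

#: Default per-group sample sizes of the horizontal-arena experiment.
HORIZONTAL_GROUP_SIZES = {
    ("brown", "control"): 34,
    ("brown", "painted"): 34,
    ("green", "control"): 37,
    ("green", "painted"): 32,
}

DOWEL_COLOURS = ("black", "white", "brown", "green")


def _stream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _smooth_noise(rng: np.random.Generator, sd: float, n_terms: int = 4) -> np.ndarray:
    """Low-order random cosine series with pointwise SD roughly ``sd``."""
    if sd == 0:
        return np.zeros(GRID.size)
    t = (GRID - GRID[0]) / (GRID[-1] - GRID[0])
    out = np.zeros(GRID.size)
    for k in range(1, n_terms + 1):
        amp = rng.normal(0.0, sd / np.sqrt(n_terms / 2.0) / k)
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.cos(np.pi * k * t + phase)
    return out


@dataclass
class SpectrumGenParams:
    """Shape parameters of the synthetic spectra."""

    base_black: float = 0.05
    base_white: float = 0.60
    base_green: float = 0.04
    base_brown: float = 0.03
    green_amp: float = 0.35
    green_centre: float = 520.0
    green_width: float = 45.0
    brown_slope: float = 0.0015  # long-wave rise per nm
    neutral_base: float = 0.12
    neutral_slope: float = 0.0003
    noise_sd: float = 0.02  # individual smooth-noise SD
    measurement_sd: float = 0.005  # per-replicate smooth-noise SD
    rho: float = 0.8  # response slope toward the dowel spectrum
    delta: float = 0.0  # blindfold shift of rho (painted larvae)
    n_replicates: int = 6

    def __post_init__(self) -> None:
        if not (0 <= self.rho <= 1 and 0 <= self.rho + self.delta <= 1):
            raise ValueError("rho and rho + delta must lie in [0, 1]")


def make_dowel_spectrum(colour: str, params: SpectrumGenParams | None = None) -> ReflectanceSpectrum:
    """Deterministic smooth reflectance curve for one dowel colour class."""
    p = params or SpectrumGenParams()
    if colour == "black":
        curve = np.full(GRID.size, p.base_black)
    elif colour == "white":
        curve = np.full(GRID.size, p.base_white)
    elif colour == "green":
        curve = p.base_green + p.green_amp * np.exp(
            -(((GRID - p.green_centre) / p.green_width) ** 2)
        )
    elif colour == "brown":
        curve = p.base_brown + p.brown_slope * (GRID - GRID[0])
    else:
        raise ValueError(f"unknown dowel colour {colour!r}; expected one of {DOWEL_COLOURS}")
    return ReflectanceSpectrum(np.clip(curve, 0, 1), label=f"dowel-{colour}")


def neutral_larva_spectrum(params: SpectrumGenParams | None = None) -> ReflectanceSpectrum:
    """Untreated (no dowel signal) larval reflectance curve."""
    p = params or SpectrumGenParams()
    curve = p.neutral_base + p.neutral_slope * (GRID - GRID[0])
    return ReflectanceSpectrum(np.clip(curve, 0, 1), label="neutral")


def simulate_colour_experiment(
    design: dict[tuple[str, str], int],
    params: SpectrumGenParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full treatment x blindfold spectral dataset.

    ``design`` maps (treatment colour, blindfold status) to the number of
    larvae.  Each larva's true spectrum interpolates between the neutral
    curve and its dowel's curve with weight ``rho_eff = rho + delta *
    [painted]`` plus smooth individual noise; six replicate measurements
    add smooth measurement noise.

    Returns (wide spectra table in the reader dialect, metadata table).
    Dowel spectra for every treatment colour in the design are appended as
    pseudo-individuals with ``life_stage = 'dowel'``.
    """
    p = params or SpectrumGenParams()
    rng = _stream(seed, STREAM_SPECTRA)
    neutral = neutral_larva_spectrum(p).reflectance
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    counter = 0
    for (treatment, blindfold), n in design.items():
        dowel = make_dowel_spectrum(treatment, p).reflectance
        rho_eff = np.clip(p.rho + (p.delta if blindfold == "painted" else 0.0), 0, 1)
        for _ in range(n):
            counter += 1
            ind = f"larva{counter:04d}"
            true = (1 - rho_eff) * neutral + rho_eff * dowel + _smooth_noise(rng, p.noise_sd)
            for rep in range(1, p.n_replicates + 1):
                measured = true + _smooth_noise(rng, p.measurement_sd)
                columns[f"{ind}_{rep}"] = np.clip(measured, 0, 1)
            meta_rows.append(
                {
                    "individual_id": ind,
                    "family": f"fam{1 + (counter % 4)}",
                    "treatment": treatment,
                    "blindfold": blindfold,
                    "life_stage": "larva",
                }
            )
    for treatment in dict.fromkeys(t for t, _ in design):
        ind = f"dowel-{treatment}"
        dowel = make_dowel_spectrum(treatment, p).reflectance
        for rep in range(1, p.n_replicates + 1):
            columns[f"{ind}_{rep}"] = dowel.copy()
        meta_rows.append(
            {
                "individual_id": ind,
                "family": "none",
                "treatment": treatment,
                "blindfold": "none",
                "life_stage": "dowel",
            }
        )
    spectra = pd.DataFrame({"wavelength_nm": GRID.astype(int), **columns})
    return spectra, pd.DataFrame(meta_rows)


@dataclass
class ChoiceGenParams:
    """Parameters of the background-choice trial generator."""

    diagonal_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DIAGONAL_GROUP_SIZES)
    )
    horizontal_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(HORIZONTAL_GROUP_SIZES)
    )
    p_match: dict[tuple[str, str], float] | float = 0.75
    position_effect: float = 0.0  # logit shift when the green end is far

    def match_probability(self, colour: str, blindfold: str) -> float:
        if isinstance(self.p_match, dict):
            p = self.p_match[(colour, blindfold)]
        else:
            p = self.p_match
        if not (0 < p <= 1):  # p = 1 allowed as the degenerate all-match limit
            raise ValueError("p_match must lie in (0, 1]")
        return p


def _other(colour: str) -> str:
    return "green" if colour == "brown" else "brown"


def simulate_choice_trials(params: ChoiceGenParams | None = None, seed: int = 0) -> list[ChoiceTrial]:
    """Bernoulli matching trials for both arena designs.

    Horizontal-arena larvae get two trials with opposite dowel positions;
    the position effect shifts the matching logit when the green end is at
    the far position.
    """
    p = params or ChoiceGenParams()
    rng = _stream(seed, STREAM_CHOICE)
    trials: list[ChoiceTrial] = []
    counter = 0
    for (colour, blindfold), n in p.diagonal_sizes.items():
        prob = p.match_probability(colour, blindfold)
        for _ in range(n):
            counter += 1
            match = rng.random() < prob
            trials.append(
                ChoiceTrial(
                    larva_id=f"ch{counter:04d}",
                    larval_colour=colour,
                    blindfold=blindfold,
                    arena="diagonal",
                    dowel_position="none",
                    chosen_colour=colour if match else _other(colour),
                )
            )
    for (colour, blindfold), n in p.horizontal_sizes.items():
        with np.errstate(divide="ignore"):  # p = 1 gives an infinite logit
            base_logit = np.log(p.match_probability(colour, blindfold)) - np.log1p(
                -p.match_probability(colour, blindfold)
            )
        for _ in range(n):
            counter += 1
            for position in ("brown_far", "green_far"):
                logit = base_logit + (p.position_effect if position == "green_far" else 0.0)
                prob = 1.0 / (1.0 + np.exp(-logit))
                match = rng.random() < prob
                trials.append(
                    ChoiceTrial(
                        larva_id=f"ch{counter:04d}",
                        larval_colour=colour,
                        blindfold=blindfold,
                        arena="horizontal",
                        dowel_position=position,
                        chosen_colour=colour if match else _other(colour),
                    )
                )
    return trials


@dataclass
class QpcrGenParams:
    """Parameters of the qPCR Cp-table generator."""

    ref_mean_cp: float = 20.0
    true_ratios: dict[tuple[str, str, str], float] = field(default_factory=dict)
    # keyed (gene, stage, tissue); missing keys default to ratio 1.0
    replicate_sd: float = 0.0  # cycles
    n_samples_per_stage: int = 4
    genes: tuple[str, ...] = GENES
    tissues: tuple[str, ...] = (HEAD_TISSUE, *DERMAL_TISSUES)

    def ratio(self, gene: str, stage: str, tissue: str) -> float:
        return self.true_ratios.get((gene, stage, tissue), 1.0)


def default_qpcr_params(seed_structure: bool = True) -> QpcrGenParams:
    """Structured generator defaults: higher head expression in adults and a
    larger dermal share in larvae, so the stage models have signal."""
    true_ratios: dict[tuple[str, str, str], float] = {}
    if seed_structure:
        for gene in GENES:
            head_larva, head_adult = 0.5, 5.0  # adult heads express far more
            dermal_p = {"larva": 0.6, "adult": 0.35}
            for stage, head in (("larva", head_larva), ("adult", head_adult)):
                true_ratios[(gene, stage, HEAD_TISSUE)] = head
                p = dermal_p[stage]
                per_tissue = head * (p / (1 - p)) / len(DERMAL_TISSUES)
                for tissue in DERMAL_TISSUES:
                    true_ratios[(gene, stage, tissue)] = per_tissue
    return QpcrGenParams(true_ratios=true_ratios, replicate_sd=0.2)


def ratios_for_dermal_proportion(p: float, head_ratio: float = 1.0) -> dict[str, float]:
    """Tissue ratios whose dermal proportion equals ``p`` exactly."""
    if not (0 < p < 1):
        raise ValueError("target proportion must lie in (0, 1)")
    per_tissue = head_ratio * (p / (1 - p)) / len(DERMAL_TISSUES)
    return {HEAD_TISSUE: head_ratio, **{t: per_tissue for t in DERMAL_TISSUES}}


def simulate_qpcr(params: QpcrGenParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Long Cp table (sample, stage, tissue, gene, rep, cp) in triplicate.

    Target Cp inverts the relative-expression formula: with efficiency 2,
    cp_target = cp_ref - log2(true ratio), plus Gaussian replicate noise.
    """
    p = params or QpcrGenParams()
    rng = _stream(seed, STREAM_QPCR)
    rows: list[dict] = []
    for stage in ("larva", "adult"):
        for s in range(1, p.n_samples_per_stage + 1):
            sample = f"{stage}{s}"
            for tissue in p.tissues:
                for gene in (REFERENCE_GENE, *p.genes):
                    if gene == REFERENCE_GENE:
                        base = p.ref_mean_cp
                    else:
                        base = p.ref_mean_cp - np.log2(p.ratio(gene, stage, tissue))
                    for rep in (1, 2, 3):
                        cp = base + (rng.normal(0, p.replicate_sd) if p.replicate_sd else 0.0)
                        rows.append(
                            {
                                "sample": sample,
                                "stage": stage,
                                "tissue": tissue,
                                "gene": gene,
                                "rep": rep,
                                "cp": float(np.clip(cp, 1e-6, 45.0)),
                            }
                        )
    return pd.DataFrame(rows)
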