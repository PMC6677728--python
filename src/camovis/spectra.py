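"""Reflectance-spectrum ingestion, validation, resampling and summaries.

All downstream visual modelling operates on spectra resampled to a fixed
1 nm grid over the visible range 300--700 nm (401 points).  Reflectance is
stored as a proportion in [0, 1]; percent-scale input is detected and
rescaled at read time.
"""

from __future__ import annotations

import io
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Common wavelength grid: 300..700 nm inclusive, 1 nm step (401 points).
GRID = np.arange(300, 701, dtype=float)
GRID_SIZE = GRID.size

#: Any reflectance value above this is taken to mean the column is on the
#: percent (0-100) scale rather than a proportion.
PERCENT_THRESHOLD = 1.5

#: Input wavelength span may fall short of [300, 700] by at most this many
#: nm at either end; the edge value is then extended flat.
EDGE_TOLERANCE_NM = 2.0

#: Nominal number of replicate measurements per individual.
NOMINAL_REPLICATES = 6

_COLUMN_RE = re.compile(r"^(?P<individual>.+)_(?P<rep>\d+)$")


@dataclass
class RawSpectrumTable:
    """Validated spectrometer output: wavelengths x measurement columns."""

    wavelengths: np.ndarray
    measurements: pd.DataFrame  # one column per measurement, proportion scale
    percent_rescaled: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("need at least 2 wavelength points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths not increasing")
        if len(self.measurements) != self.wavelengths.size:
            raise ValueError("measurement rows do not match wavelength count")

    @property
    def columns(self) -> list[str]:
        return list(self.measurements.columns)

    def individual_ids(self) -> list[str]:
        """Distinct individual ids, in first-appearance order."""
        seen: dict[str, None] = {}
        for col in self.columns:
            seen.setdefault(parse_column_label(col)[0])
        return list(seen)

    def columns_for(self, individual_id: str) -> list[str]:
        return [c for c in self.columns if parse_column_label(c)[0] == individual_id]


@dataclass
class ReflectanceSpectrum:
    """Reflectance proportion on the fixed 300..700 nm 1 nm grid."""

    reflectance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.shape != (GRID_SIZE,):
            raise ValueError(
                f"reflectance must have {GRID_SIZE} values, got {self.reflectance.shape}"
            )
        if np.any(self.reflectance < 0) or np.any(self.reflectance > 1):
            raise ValueError("reflectance outside [0, 1]; clip before constructing")

    @property
    def grid(self) -> np.ndarray:
        return GRID


@dataclass
class GroupSpectrumSummary:
    """Pointwise mean and standard error of a group of individual spectra."""

    group: str
    mean: np.ndarray
    se: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if np.any(self.se < 0):
            raise ValueError("SE must be non-negative")


def parse_column_label(label: str) -> tuple[str, int]:
    """Split a measurement column label into (individual_id, replicate index).

    Raises ``ValueError`` naming the column when the label does not follow
    the ``<individual_id>_<rep>`` convention.
    """
    m = _COLUMN_RE.match(str(label))
    if m is None:
        raise ValueError(
            f"column {label!r} has no parseable individual id "
            "(expected '<individual_id>_<rep>')"
        )
    return m.group("individual"), int(m.group("rep"))


def read_spectra(source: str | Path | io.IOBase) -> RawSpectrumTable:
    """Read a delimited (comma or tab, auto-detected) spectrum table.

    The first column holds wavelengths in nm; every other column is one
    measurement labelled ``<individual_id>_<rep>``.  Columns containing any
    value above :data:`PERCENT_THRESHOLD` are interpreted as percent
    reflectance and divided by 100 (logged).
    """
    df = pd.read_csv(source, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("spectrum table needs a wavelength column and >= 1 measurement")
    wavelengths = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wavelengths) > 0):
        raise ValueError("wavelengths not increasing")
    measurements = df.iloc[:, 1:].astype(float).copy()
    for col in measurements.columns:
        parse_column_label(col)  # hard error naming any malformed column
    rescaled = []
    for col in measurements.columns:
        if (measurements[col] > PERCENT_THRESHOLD).any():
            measurements[col] = measurements[col] / 100.0
            rescaled.append(col)
    if rescaled:
        logger.info(
            "interpreted %d column(s) as percent reflectance and divided by 100: %s",
            len(rescaled), ", ".join(map(str, rescaled)),
        )
    return RawSpectrumTable(wavelengths, measurements, percent_rescaled=rescaled)


def read_metadata(source: str | Path | io.IOBase) -> pd.DataFrame:
    """Read the sidecar metadata table (one row per individual)."""
    meta = pd.read_csv(source, sep=None, engine="python", dtype=str)
    required = {"individual_id", "treatment", "blindfold"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def resample_1nm(raw: RawSpectrumTable, column: str) -> ReflectanceSpectrum:
    """Linearly interpolate one measurement column onto the 300..700 grid.

    The source span may miss either endpoint by up to 2 nm (edge values are
    extended flat); a larger gap is an error.  Output is clipped to [0, 1].
    """
    if column not in raw.measurements.columns:
        raise KeyError(f"no measurement column {column!r}")
    lo, hi = raw.wavelengths[0], raw.wavelengths[-1]
    if lo > GRID[0] + EDGE_TOLERANCE_NM:
        raise ValueError(
            f"wavelength span starts at {lo:g} nm, missing the 300 nm edge "
            f"by {lo - GRID[0]:g} nm (> {EDGE_TOLERANCE_NM:g} nm tolerance)"
        )
    if hi < GRID[-1] - EDGE_TOLERANCE_NM:
        raise ValueError(
            f"wavelength span ends at {hi:g} nm, missing the 700 nm edge "
            f"by {GRID[-1] - hi:g} nm (> {EDGE_TOLERANCE_NM:g} nm tolerance)"
        )
    values = raw.measurements[column].to_numpy(dtype=float)
    interp = np.interp(GRID, raw.wavelengths, values)  # flat beyond the ends
    return ReflectanceSpectrum(np.clip(interp, 0.0, 1.0), label=str(column))


def average_individual(spectra: Sequence[ReflectanceSpectrum]) -> ReflectanceSpectrum:
    """Pointwise mean of an individual's replicate spectra.

    Nominally six replicates per individual; any other count is accepted
    with a warning.
    """
    if len(spectra) == 0:
        raise ValueError("cannot average an empty list of spectra")
    if len(spectra) != NOMINAL_REPLICATES:
        warnings.warn(
            f"averaging {len(spectra)} replicates (expected {NOMINAL_REPLICATES})",
            stacklevel=2,
        )
    stack = np.stack([s.reflectance for s in spectra])
    label = parse_column_label(spectra[0].label)[0] if "_" in spectra[0].label else spectra[0].label
    return ReflectanceSpectrum(stack.mean(axis=0), label=label)


def individual_means(raw: RawSpectrumTable) -> dict[str, ReflectanceSpectrum]:
    """Resample every column and average replicates per individual."""
    out: dict[str, ReflectanceSpectrum] = {}
    for ind in raw.individual_ids():
        reps = [resample_1nm(raw, c) for c in raw.columns_for(ind)]
        out[ind] = average_individual(reps)
    return out


def group_summary(
    individuals: Sequence[ReflectanceSpectrum], group: str
) -> GroupSpectrumSummary:
    """Pointwise mean and standard error (sd/sqrt(n); 0 when n = 1)."""
    n = len(individuals)
    if n < 1:
        raise ValueError("group must contain at least one spectrum")
    stack = np.stack([s.reflectance for s in individuals])
    mean = stack.mean(axis=0)
    if n == 1:
        se = np.zeros(GRID_SIZE)
    else:
        se = stack.std(axis=0, ddof=1) / np.sqrt(n)
    return GroupSpectrumSummary(group=group, mean=mean, se=se, n=n)


def spectra_to_long(spectra: dict[str, ReflectanceSpectrum]) -> pd.DataFrame:
    """Tidy long-format table: individual_id, wavelength_nm, reflectance."""
    frames = [
        pd.DataFrame(
            {"individual_id": ind, "wavelength_nm": GRID.astype(int), "reflectance": s.reflectance}
        )
        for ind, s in spectra.items()
    ]
    return pd.concat(frames, ignore_index=True)
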