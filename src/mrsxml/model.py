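"""Domain model for MRS preprocessing: signals, spectra, provenance, containers.

Conventions fixed here and relied on everywhere else:

* The ppm axis is strictly decreasing (high ppm on the left, the standard
  MRS display order).  Index ``k`` of an ``n``-point canonical axis maps to

      ppm(k) = reference_ppm + (n/2 - k) * sweep_width / (transmitter_frequency * n)

  so the centre index ``n//2`` sits exactly on the carrier (``reference_ppm``)
  and index 0 is the highest ppm.
* A baseband frequency ``f`` (Hz, signed offset from the carrier) converts to
  chemical shift as ``ppm = reference_ppm - f / transmitter_frequency`` with
  the transmitter frequency in MHz (Hz / MHz is ppm by construction).
* The forward DFT carries no scale factor; the inverse carries ``1/n``
  (numpy's default).  ``to_frequency_domain`` applies a half-spectrum
  rotation (fftshift) so that index 0 is the highest-ppm point.
* ppm ranges are closed intervals: a point belongs to ``[lower, upper]``
  iff ``lower <= ppm <= upper``, literally.  Wherever exact endpoint
  membership matters (the resampled grid of the change-points step) the
  axis is constructed so the endpoints are exact floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Optional, Union

import numpy as np

from .errors import ParameterError, ValidationError

__all__ = [
    "AcquisitionParams",
    "TimeSignal",
    "PpmAxis",
    "Spectrum",
    "PpmRange",
    "NoiseRegion",
    "SnrResult",
    "StepId",
    "StepRecord",
    "AdditionalInfo",
    "PreprocessingRecord",
    "VoxelRecord",
    "GridRecord",
    "Dataset",
    "build_ppm_axis",
    "to_frequency_domain",
    "to_time_domain",
    "hz_to_ppm",
    "ppm_to_hz",
    "DEFAULT_LABEL",
    "MAX_KEYWORD_LENGTH",
]

DEFAULT_LABEL = "***"
MAX_KEYWORD_LENGTH = 45



@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition context needed to construct the chemical-shift axis.

    Parameters
    ----------
    transmitter_frequency
        Carrier frequency in MHz (e.g. ~63.9 MHz for protons at 1.5 T).
    sweep_width
        Spectral width in Hz.
    num_points
        Number of complex points in the FID / spectrum.
    reference_ppm
        Chemical shift assigned to the carrier (the axis centre).
    nucleus
        Free-text nucleus label, e.g. ``"1H"``.
    """

    transmitter_frequency: float
    sweep_width: float
    num_points: int
    reference_ppm: float = 0.0
    nucleus: str = "1H"

    def __post_init__(self) -> None:
        if not self.transmitter_frequency > 0:
            raise ParameterError("transmitter_frequency must be > 0 MHz")
        if not self.sweep_width > 0:
            raise ParameterError("sweep_width must be > 0 Hz")
        if self.num_points < 2:
            raise ParameterError("num_points must be >= 2")

    @property
    def dwell_time(self) -> float:
        """Sampling interval in seconds (1 / sweep_width)."""
        return 1.0 / self.sweep_width

    @property
    def ppm_step(self) -> float:
        """Spacing of the canonical ppm axis (positive, ppm per point)."""
        return self.sweep_width / (self.transmitter_frequency * self.num_points)


def hz_to_ppm(freq_hz: Union[float, np.ndarray], params: AcquisitionParams):
    """Signed baseband frequency (Hz) -> chemical shift (ppm)."""
    return params.reference_ppm - np.asarray(freq_hz) / params.transmitter_frequency


def ppm_to_hz(ppm: Union[float, np.ndarray], params: AcquisitionParams):
    """Chemical shift (ppm) -> signed baseband frequency (Hz)."""
    return (params.reference_ppm - np.asarray(ppm)) * params.transmitter_frequency


@dataclass
class TimeSignal:
    """A complex free-induction decay plus its acquisition parameters."""

    samples: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1:
            raise ParameterError("FID samples must be one-dimensional")
        if len(self.samples) != self.params.num_points:
            raise ParameterError(
                f"FID length {len(self.samples)} != num_points {self.params.num_points}"
            )

    @property
    def dwell_time(self) -> float:
        return self.params.dwell_time

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at t = 0."""
        return np.arange(self.params.num_points) * self.dwell_time


@dataclass
class PpmAxis:
    """A strictly decreasing, uniformly spaced chemical-shift axis."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ParameterError("ppm axis needs at least two values")
        diffs = np.diff(self.values)
        if not np.all(diffs < 0):
            raise ParameterError("ppm axis must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def step(self) -> float:
        """Positive spacing between adjacent points (ppm)."""
        return float(self.values[0] - self.values[1])

    @classmethod
    def uniform(cls, first: float, step: float, n: int) -> "PpmAxis":
        """Build an axis from its first (highest) value and positive step."""
        if step <= 0:
            raise ParameterError("axis step must be positive")
        return cls(first - step * np.arange(n))

    def mask_range(self, rng: "PpmRange") -> np.ndarray:
        """Boolean mask of points inside the closed interval ``rng``."""
        return (self.values >= rng.lower) & (self.values <= rng.upper)

    def nearest_index(self, ppm: float) -> int:
        """Index of the axis point nearest ``ppm`` (ties -> lower index)."""
        frac = (self.values[0] - ppm) / self.step
        idx = int(np.ceil(frac - 0.5))
        return min(max(idx, 0), len(self.values) - 1)


@dataclass
class Spectrum:
    """A complex frequency-domain vector with its chemical-shift axis."""

    intensities: np.ndarray
    axis: PpmAxis
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=complex)
        if self.intensities.ndim != 1:
            raise ParameterError("spectral vector must be one-dimensional")
        if len(self.intensities) != len(self.axis):
            raise ParameterError(
                f"spectrum length {len(self.intensities)} != axis length {len(self.axis)}"
            )

    def __len__(self) -> int:
        return len(self.intensities)

    def copy(self) -> "Spectrum":
        return Spectrum(self.intensities.copy(), PpmAxis(self.axis.values.copy()), self.params)


@dataclass(frozen=True)
class PpmRange:
    """A closed chemical-shift interval ``[lower, upper]`` in ppm."""

    upper: float
    lower: float

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ParameterError(
                f"range upper bound {self.upper} must exceed lower bound {self.lower}"
            )

    def contains(self, ppm: float, eps: float = 0.0) -> bool:
        return self.lower - eps <= ppm <= self.upper + eps


@dataclass(frozen=True)
class NoiseRegion:
    """The ppm range whose points are treated as pure noise for SNR."""

    range: PpmRange

    def indices(self, axis: PpmAxis) -> np.ndarray:
        idx = np.flatnonzero(axis.mask_range(self.range))
        if len(idx) < 2:
            raise ParameterError(
                "noise region must contain at least 2 spectral points"
            )
        return idx


@dataclass(frozen=True)
class SnrResult:
    """SNR = max_peak / (2 * noise_std)."""

    snr: float
    max_peak: float
    noise_std: float


class StepId(IntEnum):
    """Preprocessing steps; the integer value is the execution order."""

    SetReference = 1
    Apodize = 2
    WaterFiltering = 3
    BaselineCorrection = 4
    ChangePoints = 5
    SetToZero = 6
    Normalization = 7
    AlignmentCorrection = 8
    OutputRange = 9


@dataclass
class StepRecord:
    """One applied preprocessing step: identity plus its exact inputs."""

    step_id: StepId
    parameters: dict = field(default_factory=dict)


@dataclass
class AdditionalInfo:
    """User-supplied export metadata (the compulsory provenance minimum).

    ``name`` and ``place`` must be non-empty so that every exported file
    records who preprocessed the data and where.  ``date`` is auto-assigned
    at export time when left ``None``.
    """

    name: str
    place: str
    date: Optional[str] = None
    label: str = DEFAULT_LABEL
    keywords: list = field(default_factory=list)
    include_snr: bool = False
    meta_data: str = ""

    def __post_init__(self) -> None:
        if not str(self.name).strip():
            raise ValidationError("Name and Place are compulsory: Name is empty")
        if not str(self.place).strip():
            raise ValidationError("Name and Place are compulsory: Place is empty")
        for kw in self.keywords:
            if len(kw) > MAX_KEYWORD_LENGTH:
                raise ValidationError(
                    f"keyword length {len(kw)} exceeds maximum of {MAX_KEYWORD_LENGTH} characters"
                )


@dataclass
class PreprocessingRecord:
    """Ordered provenance of every applied step plus the additional info."""

    additional_info: AdditionalInfo
    steps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.additional_info is None:
            raise ValidationError("AdditionalInformation is always required")
        self._check_order()

    def _check_order(self) -> None:
        ids = [s.step_id for s in self.steps]
        if any(b < a for a, b in zip(ids, ids[1:])):
            raise ValidationError(
                "step records must appear in nondecreasing execution order"
            )

    def append(self, record: StepRecord) -> None:
        if self.steps and record.step_id < self.steps[-1].step_id:
            raise ValidationError(
                f"step {record.step_id.name} recorded after a later step"
            )
        self.steps.append(record)


@dataclass
class VoxelRecord:
    """One labelled spectrum, optionally with SNR and a 1-based grid position."""

    spectrum: Spectrum
    label: str = DEFAULT_LABEL
    snr: Optional[SnrResult] = None
    position: Optional[tuple] = None  # (x_index, y_index, z_index), 1-based

    def __post_init__(self) -> None:
        if self.position is not None:
            x, y, z = self.position
            if min(x, y, z) < 1:
                raise ParameterError("grid positions are 1-based")
            if z != 1:
                raise ValidationError("Zaxis must always be 1 (single-slice grids)")


@dataclass
class GridRecord:
    """An m-rows by n-cols arrangement of voxels (multi-voxel acquisition).

    ``voxels[r][c]`` addresses row ``r``, column ``c`` (0-based in Python);
    the stored XML positions are 1-based with ``Xaxis`` = column and
    ``Yaxis`` = row, so the top-left voxel is (1, 1, 1).
    """

    voxels: list  # list of rows, each a list of VoxelRecord
    rows: int = 0
    cols: int = 0

    def __post_init__(self) -> None:
        if not self.voxels or not self.voxels[0]:
            raise ParameterError("grid must contain at least one voxel")
        self.rows = len(self.voxels)
        self.cols = len(self.voxels[0])
        if any(len(row) != self.cols for row in self.voxels):
            raise ParameterError("grid rows must all have the same length")
        ref = self.voxels[0][0].spectrum
        for r, row in enumerate(self.voxels):
            for c, vox in enumerate(row):
                expect = (c + 1, r + 1, 1)
                if vox.position is None:
                    vox.position = expect
                elif vox.position != expect:
                    raise ValidationError(
                        f"voxel at row {r + 1}, col {c + 1} carries position {vox.position},"
                        f" expected {expect}"
                    )
                if len(vox.spectrum) != len(ref) or not np.allclose(
                    vox.spectrum.axis.values, ref.axis.values
                ):
                    raise ValidationError(
                        "all grid voxels must share an identical ppm axis"
                    )

    def voxel(self, row: int, col: int) -> VoxelRecord:
        """1-based access following matrix notation (top-left = [1, 1])."""
        if not (1 <= row <= self.rows and 1 <= col <= self.cols):
            raise ParameterError(
                f"voxel position [{row}, {col}] outside {self.rows}x{self.cols} grid"
            )
        return self.voxels[row - 1][col - 1]

    def flat(self) -> np.ndarray:
        """Row-major 2-D array view of all spectra (one voxel per row)."""
        return np.array(
            [[v.spectrum.intensities for v in row] for row in self.voxels]
        ).reshape(self.rows * self.cols, -1)


@dataclass
class Dataset:
    """Root container: one preprocessing record and exactly one payload."""

    preprocessing: PreprocessingRecord
    payload: Union[VoxelRecord, GridRecord]

    def __post_init__(self) -> None:
        if not isinstance(self.payload, (VoxelRecord, GridRecord)):
            raise ValidationError(
                "dataset payload must be exactly one VoxelRecord or one GridRecord"
            )

    @property
    def is_grid(self) -> bool:
        return isinstance(self.payload, GridRecord)


def build_ppm_axis(params: AcquisitionParams) -> PpmAxis:
    """Canonical ppm axis for an acquisition: centre index on the carrier."""
    n = params.num_points
    step = params.ppm_step
    k = np.arange(n)
    return PpmAxis(params.reference_ppm + (n / 2 - k) * step)


def to_frequency_domain(sig: TimeSignal) -> Spectrum:
    """DFT with half-spectrum rotation: index 0 = highest ppm.

    A baseband frequency of +f Hz lands at chemical shift
    ``reference_ppm - f / transmitter_frequency``.
    """
    intens = np.fft.fftshift(np.fft.fft(sig.samples))
    return Spectrum(intens, build_ppm_axis(sig.params), sig.params)


def to_time_domain(spec: Spectrum) -> TimeSignal:
    """Exact inverse of :func:`to_frequency_domain`.

    Requires the spectrum to still live on the canonical full-bandwidth grid
    (no cropping/decimation applied yet); otherwise the inverse DFT is not
    defined for it.
    """
    if len(spec) != spec.params.num_points:
        raise ParameterError(
            "spectrum no longer matches its acquisition grid; cannot invert DFT"
        )
    samples = np.fft.ifft(np.fft.ifftshift(spec.intensities))
    return TimeSignal(samples, spec.params)
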