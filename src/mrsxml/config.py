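"""Processing templates: the full parameter set for the nine steps.

A :class:`ConfigTemplate` captures everything the pipeline needs — which
steps are enabled and with what parameters, plus the export metadata fields
(name, place, label, keywords, SNR option).  Free-text metadata and
per-voxel grid labels are deliberately outside the template: a template is
meant to be reused across many datasets, and those two are dataset-specific.

Templates round-trip losslessly through XML (see :mod:`mrsxml.xmlio`).
The stock templates are :func:`blank_template` (everything disabled) and
:func:`interpret_template`, which reproduces the canonical multi-centre
pattern-recognition format: 512 points spanning 7.1 to -2.7 ppm, first
point at 7.1 ppm, unit l2 norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ParameterError, ValidationError
from .model import PpmRange

__all__ = [
    "ConfigTemplate",
    "SetReferenceConfig",
    "ApodizeConfig",
    "WaterFilterConfig",
    "BaselineConfig",
    "ChangePointsConfig",
    "SetToZeroConfig",
    "NormalizationConfig",
    "AlignmentConfig",
    "OutputRangeConfig",
    "AdditionalConfig",
    "blank_template",
    "interpret_template",
]


@dataclass
class SetReferenceConfig:
    enabled: bool = False
    reference_ppm: float = 4.75


@dataclass
class ApodizeConfig:
    enabled: bool = False
    shape: str = "Lorentzian"
    linewidth_hz: float = 0.0


@dataclass
class WaterFilterConfig:
    enabled: bool = False
    n_lorentzians: int = 8
    regions: list = field(default_factory=list)


@dataclass
class BaselineConfig:
    enabled: bool = False
    regions: list = field(default_factory=list)


@dataclass
class ChangePointsConfig:
    enabled: bool = False
    target_points: int = 512
    range: Optional[PpmRange] = None


@dataclass
class SetToZeroConfig:
    enabled: bool = False
    intervals: list = field(default_factory=list)


@dataclass
class NormalizationConfig:
    enabled: bool = False


@dataclass
class AlignmentConfig:
    """Alignment inputs; peaks come either from the manual list or, when
    ``brain_1p5T_preset`` is set, from a user-supplied peaks file (one ppm
    value per line).  No built-in brain peak list ships with the package."""

    enabled: bool = False
    peaks: list = field(default_factory=list)
    noise_range: Optional[PpmRange] = None
    brain_1p5T_preset: bool = False
    preset_peaks_file: Optional[str] = None

    def resolve_peaks(self) -> list:
        if self.brain_1p5T_preset:
            if not self.preset_peaks_file:
                raise ValidationError(
                    "brain preset requires a user-supplied peaks file "
                    "(no built-in peak list ships with the package)"
                )
            with open(self.preset_peaks_file) as fh:
                peaks = [float(line) for line in fh if line.strip()]
            if not peaks:
                raise ValidationError(f"peaks file {self.preset_peaks_file} is empty")
            return peaks
        if not self.peaks:
            raise ParameterError("alignment enabled but no theoretical peaks given")
        return list(self.peaks)


@dataclass
class OutputRangeConfig:
    enabled: bool = False
    range: Optional[PpmRange] = None


@dataclass
class AdditionalConfig:
    """Export metadata fields (Step X).  Name and place may be left empty in
    a stored template and filled in at processing time; export refuses empty
    values."""

    name: str = ""
    place: str = ""
    label: str = "***"
    keywords: list = field(default_factory=list)
    include_snr: bool = False
    snr_noise_range: Optional[PpmRange] = None


@dataclass
class ConfigTemplate:
    set_reference: SetReferenceConfig = field(default_factory=SetReferenceConfig)
    apodize: ApodizeConfig = field(default_factory=ApodizeConfig)
    water_filter: WaterFilterConfig = field(default_factory=WaterFilterConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    change_points: ChangePointsConfig = field(default_factory=ChangePointsConfig)
    set_to_zero: SetToZeroConfig = field(default_factory=SetToZeroConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    output_range: OutputRangeConfig = field(default_factory=OutputRangeConfig)
    additional: AdditionalConfig = field(default_factory=AdditionalConfig)

    def with_identity(self, name: str, place: str) -> "ConfigTemplate":
        """Copy of this template with the compulsory identity fields set."""
        return replace(self, additional=replace(self.additional, name=name, place=place))


def blank_template() -> ConfigTemplate:
    """A template with every step disabled (raw pass-through export)."""
    return ConfigTemplate()


def interpret_template() -> ConfigTemplate:
    """The canonical multi-centre pattern-recognition pipeline.

    Water reference at 4.75 ppm, residual-water HLSVD filtering around
    4.7 ppm, exactly 512 points over the closed window [7.1, -2.7] ppm
    (first output point at 7.1 ppm), unit-length normalisation, alignment
    onto the three major proton-brain singlets (Cho 3.21, Cr 3.03,
    NAA 2.01 ppm — this package's manual peak choice), and the output
    cropped to the same window.
    """
    noise = PpmRange(upper=-1.0, lower=-2.6)
    return ConfigTemplate(
        set_reference=SetReferenceConfig(enabled=True, reference_ppm=4.75),
        water_filter=WaterFilterConfig(
            enabled=True, n_lorentzians=8, regions=[PpmRange(upper=5.2, lower=4.2)]
        ),
        change_points=ChangePointsConfig(
            enabled=True, target_points=512, range=PpmRange(upper=7.1, lower=-2.7)
        ),
        normalization=NormalizationConfig(enabled=True),
        alignment=AlignmentConfig(
            enabled=True, peaks=[3.21, 3.03, 2.01], noise_range=noise
        ),
        output_range=OutputRangeConfig(enabled=True, range=PpmRange(upper=7.1, lower=-2.7)),
        additional=AdditionalConfig(include_snr=True, snr_noise_range=noise),
    )
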