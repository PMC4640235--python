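"""The ordered preprocessing operators and the template-driven pipeline.

Nine operators act on a single spectrum/FID, always in the same fixed
order (the lower step numbers run first):

  I    set_reference          relabel the ppm axis to a new carrier shift
  II   apodize                Gaussian/Lorentzian line broadening (time domain)
  III  hlsvd_filter           subtract fitted components, e.g. residual water
  IV   baseline_correct       subtract the mean of per-region mean heights
  V    change_points_in_range enforce an exact point count in a ppm window
  VI   set_to_zero            zero up to two ppm intervals
  VII  l2_normalize           unit-length (l2) normalisation
  VIII align                  integer shift (<= 10 points) onto theoretical peaks
  IX   output_range           crop the output to a ppm window

Each operator optionally appends a :class:`~mrsxml.model.StepRecord` to a
provenance record; ``apply_steps`` replays such a record deterministically,
and ``run_pipeline`` drives the whole thing from a :class:`ConfigTemplate`
for a single voxel or uniformly across a multi-voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import hlsvd
from .config import ConfigTemplate
from .errors import (
    DegenerateNoiseError,
    MrsError,
    NumericsError,
    ParameterError,
    ValidationError,
)
from .model import (
    AdditionalInfo,
    Dataset,
    GridRecord,
    NoiseRegion,
    PpmAxis,
    PpmRange,
    PreprocessingRecord,
    SnrResult,
    Spectrum,
    StepId,
    StepRecord,
    TimeSignal,
    VoxelRecord,
    to_frequency_domain,
    to_time_domain,
)

__all__ = [
    "AlignmentSpec",
    "set_reference",
    "apodize",
    "hlsvd_filter",
    "baseline_correct",
    "change_points_in_range",
    "set_to_zero",
    "l2_normalize",
    "compute_snr",
    "align",
    "output_range",
    "resolve_steps",
    "apply_steps",
    "run_pipeline",
]

#: search radius of the alignment correction, in spectral points
ALIGNMENT_MAX_SHIFT = 10


@dataclass
class AlignmentSpec:
    """Inputs of the alignment correction.

    ``peaks`` are theoretical chemical shifts (ppm); the spectrum is shifted
    so that the peak with the highest SNR lands exactly on its theoretical
    index.  The search radius is fixed at +-10 points.
    """

    peaks: list
    noise: NoiseRegion
    max_shift: int = ALIGNMENT_MAX_SHIFT
    brain_1p5T_preset: bool = False

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ParameterError("alignment requires at least one theoretical peak")
        if self.max_shift != ALIGNMENT_MAX_SHIFT:
            raise ParameterError(
                f"alignment search radius is fixed at {ALIGNMENT_MAX_SHIFT} points"
            )


def _record(record, step_id, parameters) -> None:
    if record is not None:
        record.append(StepRecord(step_id, parameters))


# ---------------------------------------------------------------------------
# Step I

def set_reference(spec: Spectrum, new_reference: float, record=None) -> Spectrum:
    """Relabel the ppm axis so the carrier (centre index) reads ``new_reference``.

    Intensities are untouched; only the axis (and the stored reference) move.
    For proton spectra the usual choice is 4.75 ppm for unsuppressed water.
    """
    centre = spec.axis.values[len(spec) // 2]
    delta = new_reference - centre
    axis = PpmAxis(spec.axis.values + delta)
    params = replace(spec.params, reference_ppm=spec.params.reference_ppm + delta)
    _record(record, StepId.SetReference, {"reference_ppm": float(new_reference)})
    return Spectrum(spec.intensities.copy(), axis, params)


# ---------------------------------------------------------------------------
# Step II

def apodize(sig: TimeSignal, shape: str, linewidth: float, record=None) -> TimeSignal:
    """Line broadening: multiply the FID by a decaying window.

    ``shape`` is ``"Lorentzian"`` (w(t) = exp(-pi*LW*t), adds LW Hz to the
    FWHM of a Lorentzian line) or ``"Gaussian"``
    (w(t) = exp(-(pi*LW*t)^2 / (4 ln 2)), itself a Gaussian line of FWHM LW Hz).
    ``linewidth`` is in Hz and must be non-negative.
    """
    if shape not in ("Gaussian", "Lorentzian"):
        raise ParameterError(f"apodization shape must be Gaussian or Lorentzian, got {shape!r}")
    if linewidth < 0:
        raise ParameterError("apodization linewidth must be >= 0 Hz")
    t = sig.times
    if shape == "Lorentzian":
        w = np.exp(-np.pi * linewidth * t)
    else:
        w = np.exp(-((np.pi * linewidth * t) ** 2) / (4.0 * np.log(2.0)))
    _record(record, StepId.Apodize, {"shape": shape, "linewidth_hz": float(linewidth)})
    return TimeSignal(sig.samples * w, sig.params)


# ---------------------------------------------------------------------------
# Step III

def hlsvd_filter(sig: TimeSignal, n_lorentzians: int, regions: list, record=None) -> TimeSignal:
    """Subtract fitted damped sinusoids whose shift falls in the given regions.

    Up to three closed ppm regions may be filtered simultaneously (the usual
    single one covers residual water around 4.7 ppm in proton spectra).
    """
    if not 1 <= len(regions) <= 3:
        raise ParameterError("water filtering accepts between 1 and 3 ppm regions")
    comps = hlsvd.fit_components(sig, n_lorentzians)
    selected = hlsvd.select_in_regions(comps, regions, sig.params)
    out = sig.samples.copy()
    if selected:
        out = out - hlsvd.reconstruct(selected, sig.params).samples
    _record(
        record,
        StepId.WaterFiltering,
        {
            "n_lorentzians": int(n_lorentzians),
            "regions": [[r.upper, r.lower] for r in regions],
        },
    )
    return TimeSignal(out, sig.params)


# ---------------------------------------------------------------------------
# Step IV

def baseline_correct(spec: Spectrum, regions: list, record=None) -> Spectrum:
    """Subtract the mean of the per-region mean heights from every point.

    With regions of unequal size this nested mean (mean of means) differs
    from a pooled mean over all in-region points; the nested form is used.
    Works only for flat (non-sloped) baselines.
    """
    if not 1 <= len(regions) <= 3:
        raise ParameterError("baseline correction accepts between 1 and 3 ppm regions")
    means = []
    for r in regions:
        mask = spec.axis.mask_range(r)
        if not mask.any():
            raise ParameterError(f"baseline region [{r.lower}, {r.upper}] ppm contains no points")
        means.append(spec.intensities[mask].mean())
    offset = np.mean(means)
    _record(
        record,
        StepId.BaselineCorrection,
        {"regions": [[r.upper, r.lower] for r in regions]},
    )
    return Spectrum(spec.intensities - offset, spec.axis, spec.params)


# ---------------------------------------------------------------------------
# Step V

def _zero_fill_double(sig: TimeSignal) -> TimeSignal:
    n = sig.params.num_points
    params = replace(sig.params, num_points=2 * n)
    return TimeSignal(np.concatenate([sig.samples, np.zeros(n, dtype=complex)]), params)


def change_points_in_range(
    spec: Spectrum, target_points: int, rng: PpmRange, record=None
) -> Spectrum:
    """Enforce exactly ``target_points`` spectral points inside ``rng``.

    Too many points: undersample by skipping values — a uniform target grid
    of ``target_points`` coordinates spans the closed range, and each target
    coordinate takes the nearest original point (ties break toward the lower
    index, i.e. the higher ppm).  No interpolation is performed.  Too few:
    zero filling in the time domain doubles the grid until the range holds
    enough points, then the same skipping rule yields the exact count.
    The full original ppm span is retained (extended with the same target
    spacing outside the range) until an output range is applied.
    """
    if target_points < 2:
        raise ParameterError("target point count must be >= 2")
    eps = spec.axis.step
    if rng.upper > spec.axis.values[0] + eps or rng.lower < spec.axis.values[-1] - eps:
        raise ParameterError(
            f"range [{rng.lower}, {rng.upper}] ppm falls outside the spectral axis"
        )
    params_rec = {"target_points": int(target_points), "range": [rng.upper, rng.lower]}

    n_in = int(spec.axis.mask_range(rng).sum())
    if n_in == target_points:
        _record(record, StepId.ChangePoints, params_rec)
        return spec.copy()

    while n_in < target_points:
        sig = _zero_fill_double(to_time_domain(spec))
        spec = to_frequency_domain(sig)
        n_in = int(spec.axis.mask_range(rng).sum())

    # Uniform target grid over the closed range; linspace keeps the range
    # endpoints exact so the first in-range point sits exactly at rng.upper.
    step = (rng.upper - rng.lower) / (target_points - 1)
    in_vals = np.linspace(rng.upper, rng.lower, target_points)
    guard = 1e-9 * step
    n_above = int(np.floor((spec.axis.values[0] - rng.upper) / step + guard))
    n_below = int(np.floor((rng.lower - spec.axis.values[-1]) / step + guard))
    above = rng.upper + step * np.arange(n_above, 0, -1)
    below = rng.lower - step * np.arange(1, n_below + 1)
    new_vals = np.concatenate([above, in_vals, below])

    # Nearest original point for each target coordinate (ties -> lower index).
    frac = (spec.axis.values[0] - new_vals) / spec.axis.step
    idx = np.ceil(frac - 0.5).astype(int)
    idx = np.clip(idx, 0, len(spec) - 1)

    _record(record, StepId.ChangePoints, params_rec)
    return Spectrum(spec.intensities[idx], PpmAxis(new_vals), spec.params)


# ---------------------------------------------------------------------------
# Step VI

def set_to_zero(spec: Spectrum, intervals: list, record=None) -> Spectrum:
    """Zero the spectral points inside up to two closed ppm intervals."""
    if not 1 <= len(intervals) <= 2:
        raise ParameterError("set-to-zero accepts between 1 and 2 ppm intervals")
    out = spec.intensities.copy()
    for r in intervals:
        out[spec.axis.mask_range(r)] = 0.0
    _record(
        record,
        StepId.SetToZero,
        {"intervals": [[r.upper, r.lower] for r in intervals]},
    )
    return Spectrum(out, spec.axis, spec.params)


# ---------------------------------------------------------------------------
# Step VII

def l2_normalize(spec: Spectrum, record=None) -> Spectrum:
    """Divide the spectral vector by its l2 norm (unit-length normalisation).

    Scanner amplitudes are arbitrary units; after this step every spectrum
    satisfies sqrt(sum_k |x_k|^2) == 1, putting multi-scanner data on a
    common intensity scale.
    """
    norm = float(np.sqrt(np.sum(np.abs(spec.intensities) ** 2)))
    if norm == 0.0:
        raise NumericsError("cannot l2-normalize an all-zero spectrum")
    _record(record, StepId.Normalization, {})
    return Spectrum(spec.intensities / norm, spec.axis, spec.params)


# ---------------------------------------------------------------------------
# SNR (used by Step VIII and the per-voxel export option)

def compute_snr(spec: Spectrum, noise: NoiseRegion, peak_scope=None) -> SnrResult:
    """SNR = Max Peak / (2 * STD(noise)).

    ``Max Peak`` is the highest magnitude either over the whole spectrum
    (``peak_scope=None``) or inside a window given as
    ``(center_ppm, halfwidth_points)``.  The noise standard deviation is the
    sample standard deviation (ddof=1) of the real part of the points in the
    user-designated noise region.
    """
    noise_idx = noise.indices(spec.axis)
    noise_std = float(np.std(spec.intensities[noise_idx].real, ddof=1))
    if noise_std == 0.0:
        raise DegenerateNoiseError("noise region has zero variance; SNR undefined")
    if peak_scope is None:
        max_peak = float(np.max(np.abs(spec.intensities)))
    else:
        center_ppm, halfwidth = peak_scope
        i = spec.axis.nearest_index(center_ppm)
        lo, hi = max(0, i - halfwidth), min(len(spec), i + halfwidth + 1)
        max_peak = float(np.max(np.abs(spec.intensities[lo:hi])))
    return SnrResult(snr=max_peak / (2.0 * noise_std), max_peak=max_peak, noise_std=noise_std)


# ---------------------------------------------------------------------------
# Step VIII

def align(spec: Spectrum, alignment: AlignmentSpec, record=None) -> Spectrum:
    """Shift the spectrum onto its theoretical peak positions.

    For each theoretical peak the local maximum within +-10 points of its
    index is located and scored by SNR; the best-scoring peak drives an
    integer shift (never more than 10 points) that places its maximum on
    the theoretical index.  The <=10 wrapped edge points are zeroed rather
    than wrapped around, so no data is invented at the edges.
    """
    noise_idx = alignment.noise.indices(spec.axis)
    noise_std = float(np.std(spec.intensities[noise_idx].real, ddof=1))
    if noise_std == 0.0:
        raise DegenerateNoiseError("noise region has zero variance; cannot score peaks")

    mag = np.abs(spec.intensities)
    best = None  # (snr, theoretical index, found index)
    for p in alignment.peaks:
        i_t = spec.axis.nearest_index(float(p))
        lo = max(0, i_t - alignment.max_shift)
        hi = min(len(spec), i_t + alignment.max_shift + 1)
        j = lo + int(np.argmax(mag[lo:hi]))
        snr = mag[j] / (2.0 * noise_std)
        if best is None or snr > best[0]:
            best = (snr, i_t, j)

    shift = best[1] - best[2]
    out = np.roll(spec.intensities, shift)
    if shift > 0:
        out[:shift] = 0.0
    elif shift < 0:
        out[shift:] = 0.0
    _record(
        record,
        StepId.AlignmentCorrection,
        {
            "peaks": [float(p) for p in alignment.peaks],
            "noise_range": [alignment.noise.range.upper, alignment.noise.range.lower],
            "max_shift": alignment.max_shift,
        },
    )
    return Spectrum(out, spec.axis, spec.params)


# ---------------------------------------------------------------------------
# Step IX

def output_range(spec: Spectrum, rng: PpmRange, record=None) -> Spectrum:
    """Crop the spectrum to the points inside a closed ppm range.

    Needed when exporting data from scanners with different ppm spans:
    cropping every spectrum to the same range (after Step V fixed the point
    density) makes the output vectors directly comparable.
    """
    mask = spec.axis.mask_range(rng)
    if not mask.any():
        raise ParameterError(f"output range [{rng.lower}, {rng.upper}] ppm contains no points")
    _record(record, StepId.OutputRange, {"range": [rng.upper, rng.lower]})
    return Spectrum(spec.intensities[mask], PpmAxis(spec.axis.values[mask]), spec.params)


# ---------------------------------------------------------------------------
# Template-driven execution

def resolve_steps(config: ConfigTemplate) -> list:
    """The ordered list of step records a config will execute.

    The order is fixed by the step numbering, never by config authoring
    order.  This is also what a dry run prints.
    """
    steps = []
    c = config
    if c.set_reference.enabled:
        steps.append(StepRecord(StepId.SetReference, {"reference_ppm": float(c.set_reference.reference_ppm)}))
    if c.apodize.enabled:
        steps.append(StepRecord(StepId.Apodize, {"shape": c.apodize.shape, "linewidth_hz": float(c.apodize.linewidth_hz)}))
    if c.water_filter.enabled:
        if not 1 <= len(c.water_filter.regions) <= 3:
            raise ParameterError("water filtering accepts between 1 and 3 ppm regions")
        steps.append(StepRecord(StepId.WaterFiltering, {
            "n_lorentzians": int(c.water_filter.n_lorentzians),
            "regions": [[r.upper, r.lower] for r in c.water_filter.regions],
        }))
    if c.baseline.enabled:
        steps.append(StepRecord(StepId.BaselineCorrection, {"regions": [[r.upper, r.lower] for r in c.baseline.regions]}))
    if c.change_points.enabled:
        steps.append(StepRecord(StepId.ChangePoints, {"target_points": int(c.change_points.target_points), "range": [c.change_points.range.upper, c.change_points.range.lower]}))
    if c.set_to_zero.enabled:
        steps.append(StepRecord(StepId.SetToZero, {"intervals": [[r.upper, r.lower] for r in c.set_to_zero.intervals]}))
    if c.normalization.enabled:
        steps.append(StepRecord(StepId.Normalization, {}))
    if c.alignment.enabled:
        peaks = c.alignment.resolve_peaks()
        steps.append(StepRecord(StepId.AlignmentCorrection, {
            "peaks": [float(p) for p in peaks],
            "noise_range": [c.alignment.noise_range.upper, c.alignment.noise_range.lower],
            "max_shift": ALIGNMENT_MAX_SHIFT,
        }))
    if c.output_range.enabled:
        steps.append(StepRecord(StepId.OutputRange, {"range": [c.output_range.range.upper, c.output_range.range.lower]}))
    return steps


def _ranges(pairs) -> list:
    return [PpmRange(upper=float(u), lower=float(l)) for u, l in pairs]


def apply_steps(data, steps) -> Spectrum:
    """Execute step records in order on a FID or spectrum.

    Steps II, III and the zero-filling half of Step V act in the time
    domain; everything else in the frequency domain.  Domain conversions
    are inserted automatically.  Replaying the same records on the same
    input reproduces the output bit for bit (every operator is
    deterministic).
    """
    ids = [s.step_id for s in steps]
    if any(b < a for a, b in zip(ids, ids[1:])):
        raise ValidationError("step records must be ordered by step number")

    current = data  # TimeSignal or Spectrum

    def as_time(obj):
        return obj if isinstance(obj, TimeSignal) else to_time_domain(obj)

    def as_freq(obj):
        return obj if isinstance(obj, Spectrum) else to_frequency_domain(obj)

    for step in steps:
        p = step.parameters
        sid = step.step_id
        if sid == StepId.SetReference:
            # In the time domain this is a pure relabelling of the reference.
            if isinstance(current, TimeSignal):
                current = TimeSignal(
                    current.samples,
                    replace(current.params, reference_ppm=float(p["reference_ppm"])),
                )
            else:
                current = set_reference(current, float(p["reference_ppm"]))
        elif sid == StepId.Apodize:
            current = apodize(as_time(current), p["shape"], float(p["linewidth_hz"]))
        elif sid == StepId.WaterFiltering:
            current = hlsvd_filter(as_time(current), int(p["n_lorentzians"]), _ranges(p["regions"]))
        elif sid == StepId.BaselineCorrection:
            current = baseline_correct(as_freq(current), _ranges(p["regions"]))
        elif sid == StepId.ChangePoints:
            u, l = p["range"]
            current = change_points_in_range(as_freq(current), int(p["target_points"]), PpmRange(upper=float(u), lower=float(l)))
        elif sid == StepId.SetToZero:
            current = set_to_zero(as_freq(current), _ranges(p["intervals"]))
        elif sid == StepId.Normalization:
            current = l2_normalize(as_freq(current))
        elif sid == StepId.AlignmentCorrection:
            u, l = p["noise_range"]
            spec_al = AlignmentSpec(
                peaks=list(p["peaks"]),
                noise=NoiseRegion(PpmRange(upper=float(u), lower=float(l))),
                max_shift=int(p.get("max_shift", ALIGNMENT_MAX_SHIFT)),
            )
            current = align(as_freq(current), spec_al)
        elif sid == StepId.OutputRange:
            u, l = p["range"]
            current = output_range(as_freq(current), PpmRange(upper=float(u), lower=float(l)))
        else:  # pragma: no cover - StepId is exhaustive
            raise ValidationError(f"unknown step {sid!r}")
    return as_freq(current)


def run_pipeline(data, config: ConfigTemplate, meta_data: str = "", date=None) -> Dataset:
    """Run the full template on one FID (single voxel) or a grid (multi voxel).

    For a grid, the identical step sequence is applied to every voxel;
    per-voxel SNR (whole-spectrum Max Peak) is attached when the template's
    ``include_snr`` flag is set.  Existing voxel labels are preserved.
    """
    steps = resolve_steps(config)
    info = AdditionalInfo(
        name=config.additional.name,
        place=config.additional.place,
        date=date,
        label=config.additional.label,
        keywords=list(config.additional.keywords),
        include_snr=config.additional.include_snr,
        meta_data=meta_data,
    )
    record = PreprocessingRecord(additional_info=info, steps=steps)

    def process_one(obj, position=None):
        try:
            spec = apply_steps(obj, steps)
            snr = None
            if config.additional.include_snr:
                if config.additional.snr_noise_range is None:
                    raise ValidationError("include_snr requires an SNR noise range")
                snr = compute_snr(spec, NoiseRegion(config.additional.snr_noise_range))
            return spec, snr
        except MrsError as err:
            if position is not None:
                err.args = (f"voxel [row {position[0]}, col {position[1]}]: {err.args[0]}",)
            raise

    if isinstance(data, GridRecord):
        rows = []
        for r in range(data.rows):
            row = []
            for c in range(data.cols):
                vox = data.voxels[r][c]
                spec, snr = process_one(vox.spectrum, position=(r + 1, c + 1))
                row.append(VoxelRecord(spectrum=spec, label=vox.label, snr=snr,
                                       position=(c + 1, r + 1, 1)))
            rows.append(row)
        payload = GridRecord(rows)
    elif isinstance(data, (TimeSignal, Spectrum)):
        spec, snr = process_one(data)
        payload = VoxelRecord(spectrum=spec, label=config.additional.label, snr=snr)
    else:
        raise ParameterError(f"cannot process input of type {type(data).__name__}")
    return Dataset(preprocessing=record, payload=payload)
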