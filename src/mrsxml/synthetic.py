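"""Synthetic proton-MRS signals with known ground truth.

Every generator is a pure function of its parameters and a seed, so tests
and examples never need acquired data: an FID is a sum of exponentially
damped complex sinusoids (one per spectral peak) plus i.i.d. circular
complex Gaussian noise — the standard MRS noise model, which keeps the
frequency-domain noise Gaussian too.

``gen_brain_like_sv`` emulates a short-TE proton brain spectrum: a dominant
residual-water resonance near 4.7 ppm over a handful of metabolite singlets
(NAA, Cr, Cho, mI, Lac) at their textbook shifts.  The peak positions and
amplitudes are fixture choices for exercising water filtering and
alignment, not a quantitative metabolite model.  ``gen_mv_grid`` tiles such
voxels into an m x n grid, optionally perturbing a "lesion" subset
(NAA down, Cho and Lac up, the usual tumour-like pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .model import (
    AcquisitionParams,
    GridRecord,
    TimeSignal,
    VoxelRecord,
    ppm_to_hz,
    to_frequency_domain,
)

__all__ = ["PeakModel", "gen_fid", "gen_brain_like_sv", "gen_mv_grid", "BRAIN_PEAKS"]


@dataclass(frozen=True)
class PeakModel:
    """One spectral peak: position, intensity, decay and phase.

    ``damping`` is the Lorentzian decay rate in 1/s for ``shape="lorentzian"``
    (spectral FWHM = damping / pi Hz) or the Gaussian envelope rate for
    ``shape="gaussian"`` (envelope exp(-(damping * t)^2)).
    """

    ppm: float
    amplitude: float
    damping: float
    phase: float = 0.0
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("peak amplitude must be >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ParameterError(f"unknown peak shape {self.shape!r}")


#: Default short-TE proton-brain fixture peaks (residual water + metabolites).
BRAIN_PEAKS = (
    PeakModel(ppm=4.70, amplitude=10.0, damping=12.0),  # residual water
    PeakModel(ppm=3.56, amplitude=0.40, damping=10.0),  # myo-inositol
    PeakModel(ppm=3.21, amplitude=0.80, damping=8.0),   # choline
    PeakModel(ppm=3.03, amplitude=0.70, damping=8.0),   # creatine
    PeakModel(ppm=2.01, amplitude=1.00, damping=8.0),   # NAA
    PeakModel(ppm=1.31, amplitude=0.30, damping=10.0),  # lactate
)


def gen_fid(peaks, params: AcquisitionParams, noise_sd: float = 0.0, seed: int = 0) -> TimeSignal:
    """Sum of damped complex sinusoids plus complex Gaussian noise.

    Peak positions in ppm convert to baseband frequencies through the
    carrier convention (a peak at ``reference_ppm`` sits exactly on the
    carrier, i.e. the centre of the spectrum).  ``noise_sd`` is the
    standard deviation of each of the real and imaginary noise components
    per FID sample.  Deterministic for a fixed seed.
    """
    t = np.arange(params.num_points) * (1.0 / params.sweep_width)
    fid = np.zeros(params.num_points, dtype=complex)
    for p in peaks:
        f = float(ppm_to_hz(p.ppm, params))
        carrier = np.exp(1j * (2 * np.pi * f * t + p.phase))
        if p.shape == "lorentzian":
            env = np.exp(-p.damping * t)
        else:
            env = np.exp(-((p.damping * t) ** 2))
        fid += p.amplitude * carrier * env
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fid += noise_sd * (
            rng.standard_normal(params.num_points)
            + 1j * rng.standard_normal(params.num_points)
        )
    return TimeSignal(fid, params)


def gen_brain_like_sv(
    params: AcquisitionParams,
    seed: int = 0,
    noise_sd: float = 0.02,
    amplitude_jitter: float = 0.1,
    peaks=BRAIN_PEAKS,
):
    """A brain-like single-voxel FID plus its ground-truth peak table.

    Amplitudes are jittered multiplicatively (uniform within
    ``1 +- amplitude_jitter``) so repeated voxels differ realistically;
    the returned peak table carries the jittered values actually used.

    Returns
    -------
    (TimeSignal, list of PeakModel)
    """
    rng = np.random.default_rng(seed)
    jitter = 1.0 + amplitude_jitter * rng.uniform(-1.0, 1.0, size=len(peaks))
    truth = [replace(p, amplitude=p.amplitude * float(j)) for p, j in zip(peaks, jitter)]
    noise_seed = int(rng.integers(0, 2**31 - 1))
    fid = gen_fid(truth, params, noise_sd=noise_sd, seed=noise_seed)
    return fid, truth


def gen_mv_grid(
    rows: int,
    cols: int,
    params: AcquisitionParams,
    lesion_mask=None,
    seed: int = 0,
    noise_sd: float = 0.02,
):
    """An m x n grid of brain-like voxels with optional lesion alterations.

    ``lesion_mask`` is an optional (rows, cols) boolean array; masked voxels
    get reduced NAA and elevated Cho/Lac amplitudes.  All labels start at
    the default ``"***"``.  Deterministic for a fixed seed (per-voxel
    sub-seeds are spawned from it).

    Returns
    -------
    (GridRecord, dict) — the grid and a ground-truth map
    ``{(row, col): [PeakModel, ...]}`` with 1-based positions.
    """
    if rows < 1 or cols < 1:
        raise ParameterError("grid must have at least one row and one column")
    if lesion_mask is not None:
        lesion_mask = np.asarray(lesion_mask, dtype=bool)
        if lesion_mask.shape != (rows, cols):
            raise ParameterError(
                f"lesion mask shape {lesion_mask.shape} != grid shape {(rows, cols)}"
            )
    child_seeds = np.random.SeedSequence(seed).spawn(rows * cols)
    truth = {}
    grid_rows = []
    for r in range(rows):
        row = []
        for c in range(cols):
            peaks = BRAIN_PEAKS
            if lesion_mask is not None and lesion_mask[r, c]:
                altered = []
                for p in peaks:
                    if abs(p.ppm - 2.01) < 0.01:      # NAA loss
                        p = replace(p, amplitude=p.amplitude * 0.3)
                    elif abs(p.ppm - 3.21) < 0.01:    # Cho increase
                        p = replace(p, amplitude=p.amplitude * 1.8)
                    elif abs(p.ppm - 1.31) < 0.01:    # Lac increase
                        p = replace(p, amplitude=p.amplitude * 3.0)
                    altered.append(p)
                peaks = altered
            sub = int(child_seeds[r * cols + c].generate_state(1)[0] % (2**31 - 1))
            fid, vox_truth = gen_brain_like_sv(params, seed=sub, noise_sd=noise_sd, peaks=peaks)
            truth[(r + 1, c + 1)] = vox_truth
            row.append(
                VoxelRecord(spectrum=to_frequency_domain(fid), position=(c + 1, r + 1, 1))
            )
        grid_rows.append(row)
    return GridRecord(grid_rows), truth
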