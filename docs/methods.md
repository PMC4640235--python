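# Methods

## Signal model and conventions

A free-induction decay (FID) is a complex time series sampled at dwell
time 1/SW (SW = sweep width, Hz). The discrete Fourier transform (forward
unscaled, inverse 1/n — numpy's convention) with a half-spectrum rotation
gives the spectrum with index 0 at the highest chemical shift, the
standard MRS display order. The canonical ppm axis of an n-point
acquisition is

    ppm(k) = reference_ppm + (n/2 − k) · SW / (f0 · n),    k = 0 … n−1,

with f0 the transmitter frequency in MHz, so the centre index sits exactly
on the carrier and a baseband offset of f Hz maps to
`reference_ppm − f/f0` ppm. Parseval's identity under this scaling
(Σ|FID|² = Σ|spec|²/n) is verified in the tests.

ppm ranges are closed intervals, `lower ≤ ppm ≤ upper`, applied literally
with no epsilon. Where exact endpoint membership matters — the resampled
grid of the change-points step, and the output crop that follows it — the
target axis is built with `np.linspace`, whose endpoints are exact floats,
so e.g. 7.1 ppm is the first in-window point by construction rather than
by tolerance.

## The operators

Steps run in a fixed order (I–IX); each appends one record with the exact
call parameters, and re-executing the records on the same input
reproduces the output bit for bit (all operators are deterministic).

* **Set reference (I)** relabels the axis so the carrier reads the given
  shift; intensities are untouched. Whether the original tool also moved
  intensities is unknowable from its description; pure relabelling is the
  conservative reading and is what this package does.
* **Apodization (II)** multiplies the FID by w(t): Lorentzian
  `w(t) = exp(−π·LW·t)` (adds LW Hz to a Lorentzian line's FWHM — verified
  against a measured-FWHM oracle) or Gaussian
  `w(t) = exp(−(π·LW·t)²/(4 ln 2))` (itself a Gaussian line of FWHM LW Hz).
  These are the standard NMR forms; LW ≥ 0 in Hz.
* **Water filtering (III)** subtracts fitted damped sinusoids whose shift
  falls in up to three closed ppm regions (see HLSVD below).
* **Baseline correction (IV)** subtracts the mean of the per-region mean
  heights (a nested mean, *not* a pooled mean — the two differ for unequal
  region sizes; the nested form is the implemented rule). Only flat
  baselines are handled.
* **Change points in range (V)**: if the window already holds exactly the
  target count the spectrum is returned unchanged. With too few points the
  time-domain signal is zero-filled, doubling n until the window holds
  enough (power-of-two friendly). Then a uniform grid of exactly
  `target_points` coordinates spans the closed window and each coordinate
  takes the *nearest original point* (ties toward higher ppm) — skipping,
  never interpolating, so raw values are preserved. The grid is extended
  at the same spacing to cover the full original span, which is retained
  until Step IX crops it.
* **Set to zero (VI)**: up to two closed intervals zeroed, e.g. a poorly
  suppressed water residue that would otherwise dominate normalisation.
* **Normalization (VII)**: unit length, xₖ → xₖ/‖x‖ with
  ‖x‖ = √(Σ|xₖ|²); idempotent, norm 1 to 1e−12. Performed before the
  output crop, so the final vector's norm can be slightly below 1 by the
  energy outside the output window (~0.6 % in the worked example).
* **Alignment (VIII)**: for each theoretical peak, the local maximum
  within ±10 points of its index is scored by SNR; the winner drives an
  integer shift (never more than 10 points) placing its maximum on the
  theoretical index. The shift is circular with the wrapped ≤10 edge
  points zeroed, so no data is invented. The "brain at 1.5 T" preset is a
  user-supplied peaks file (one ppm per line) referenced from the config;
  the package ships no built-in list. The stock canonical template instead
  uses an explicit manual list (Cho 3.21, Cr 3.03, NAA 2.01 ppm) — this
  package's own choice of the three major proton-brain singlets.
* **Output range (IX)** crops to a closed window; with Step V fixing the
  density first, spectra from scanners with different spans come out with
  identical lengths.

**SNR** = MaxPeak / (2·STD(noise)). MaxPeak is the highest magnitude
(|complex|) over the whole spectrum, or over a restricted window for
alignment scoring. STD is the *sample* standard deviation (ddof = 1) of
the real part of the user-designated noise region — the estimator is a
package choice (the defining ratio does not pin it down), recorded here
and in the provenance semantics. A zero-variance noise region is an error,
not an infinite SNR.

## HLSVD

The FID is arranged in a near-square Hankel matrix (⌊n/2⌋ rows — maximal
rank, standard in the HSVD literature). A rank-k truncated SVD gives the
signal subspace; the shift-invariance of the top-k left singular vectors
yields (least squares) a matrix whose eigenvalues are the signal poles
zⱼ = exp((2πifⱼ − dⱼ)·dt); amplitudes and phases follow from a linear
least-squares fit of the k damped exponentials to the FID. `model_order`
*is* the truncation rank (no automatic order selection). Dense SVD is used
up to 640 Hankel rows; above that a Lanczos truncated SVD
(`scipy.sparse.linalg.svds`) with a fixed all-ones start vector keeps long
FIDs fast *and* bit-reproducible. No FID point weighting or first-point
scaling is applied. On noiseless synthetic FIDs with ≤ 5 separated
components, parameters are recovered to 1e−6 relative error; with noise at
SNR ≈ 50, frequencies are recovered within half a spectral bin (seeded
test). Negative fitted dampings can occur on noise components and are
flagged (`is_physical`), not rejected.

## Synthetic data

Generators are pure functions of (parameters, seed). An FID is a sum of
exponentially damped complex sinusoids plus i.i.d. circular complex
Gaussian noise on the samples — the standard MRS noise model, which keeps
frequency-domain noise Gaussian for the SNR tests. The brain-like fixture
places a dominant residual-water peak (4.70 ppm, amplitude 10, damping
12 s⁻¹ ≈ 3.8 Hz linewidth) over five metabolite singlets at textbook
shifts (mI 3.56, Cho 3.21, Cr 3.03, NAA 2.01, Lac 1.31; amplitudes
0.3–1.0, dampings 8–10 s⁻¹), with ±10 % per-voxel amplitude jitter and
time-domain noise sd 0.02 — numbers chosen once as a plausible short-TE
1.5 T proton scenario. Grids spawn per-voxel sub-seeds from one master
seed; an optional lesion mask lowers NAA and raises Cho/Lac (the usual
tumour-like pattern). The generator emulates peak positions, relative
intensities and noise, **not** J-coupled multiplets, macromolecular
baselines, eddy-current or phase distortions; tests passing on it show
the operators implement their definitions, not that the pipeline is
clinically validated.

Default problem sizes throughout tests and examples (512–2048 points,
grids up to 16×16) were chosen to exercise every code path, including the
Lanczos branch, at interactive runtimes.

## Exchange format

One `DATASET` per file: a `Preprocessing` node (one element per applied
step — absence means "not performed" — plus the always-required
`AdditionalInformation` with non-empty `Name` and `Place`, auto-assigned
ISO-8601 `Date`, `Label` defaulting to `***`, keywords of at most 45
characters, and verbatim free-text `MetaData`), and exactly one payload:
`Voxel` or `Grid`. Grid voxels carry 1-based `Xaxis` (column) / `Yaxis`
(row) / `Zaxis` attributes; matrix notation puts the top-left voxel at
[1,1], and `Zaxis` is fixed at 1 (single-slice; the attribute exists for
future multi-slice use). The element vocabulary is frozen in the shipped
XSD (`src/mrsxml/data/mrsxml.xsd`), which lxml enforces on both export
and read; a few rules XSD cannot express (grid completeness, duplicate
positions, data length vs. declared point count, identical grid axes) are
checked in Python. Because the schema rejects unknown elements and has no
identifier fields, exports are anonymized by construction.

Numbers are printed with 17 significant digits (exact double round trip);
spectra are stored as alternating real/imaginary pairs
(`storage="complex"`; a `real` variant is read but never written — whether
the historical files were complex or real-only is not documented, so the
lossless choice is the default). The axis is stored as
`(ppm_first, ppm_step, points)` — compact and exactly reconstructible
under the uniform-grid invariant. A flat-ASCII writer emits the canonical
512-value space-separated layout (real parts, first value at 7.1 ppm) for
interoperability with legacy pattern-recognition pipelines.

Config templates are a separate small XML dialect mirroring the template
dataclass one-to-one and round-tripping losslessly. Templates carry the
Step I–X parameters including the export-metadata fields, but deliberately
not the free-text metadata or per-voxel labels, which are
dataset-specific (labels are supplied as a `row,col,label` CSV on the
command line).

## Degenerate inputs and tie-breaks

All-zero spectra cannot be normalised (error, not NaN); all-zero FIDs have
no signal subspace (error). Nearest-point ties in resampling and axis
lookup resolve toward the lower index (higher ppm). Alignment SNR ties
keep the first-listed peak. A 1×1 grid stays a grid — it is never silently
converted to single-voxel. Errors raised while processing a grid are
annotated with the 1-based voxel position.

## Known limitations

No zero/first-order phasing, frequency-domain filtering or eddy-current
correction (recorded manually in the metadata notebook instead, as the
workflow intends); no vendor raw formats or DICOM; no multi-slice
processing beyond storing `Zaxis`; baseline correction assumes a flat
baseline; the change-points step requires the requested window to lie
inside the acquired span.
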