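"""Hankel-SVD modelling of an FID as damped complex sinusoids.

The FID is arranged into a near-square Hankel matrix, the signal subspace is
taken from a rank-``model_order`` truncated SVD, and the signal poles follow
from the shift-invariance of the top left-singular subspace (least squares).
Frequencies and dampings come from the pole angles and magnitudes; complex
amplitudes from a final linear least-squares fit against the FID.  Selected
components (typically residual water in proton spectra) can then be
reconstructed and subtracted from the time-domain signal.

Small problems use a dense SVD; larger ones a Lanczos truncated SVD with a
fixed start vector so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .errors import NumericsError, ParameterError
from .model import AcquisitionParams, PpmRange, TimeSignal, hz_to_ppm

__all__ = ["DampedSinusoid", "fit_components", "reconstruct", "select_in_regions"]

# Hankel row counts above this use the Lanczos (svds) path instead of a
# dense SVD; purely a speed trade-off, the contract is on the parameters.
_DENSE_SVD_MAX_ROWS = 640


@dataclass(frozen=True)
class DampedSinusoid:
    """One Lorentzian component: a * exp(i*phase) * exp((i*2*pi*f - d) t).

    ``frequency`` is the signed baseband offset from the carrier in Hz;
    ``damping`` is in 1/s.  Negative damping (a growing component) can occur
    when fitting noise and is permitted but flagged via :attr:`is_physical`.
    """

    amplitude: float
    phase: float
    frequency: float
    damping: float

    @property
    def is_physical(self) -> bool:
        return self.damping >= 0

    def ppm(self, params: AcquisitionParams) -> float:
        """Chemical shift of this component under the carrier convention."""
        return float(hz_to_ppm(self.frequency, params))


def _hankel(x: np.ndarray) -> np.ndarray:
    n = len(x)
    rows = n // 2
    cols = n - rows + 1
    return scipy.linalg.hankel(x[:rows], x[rows - 1 :])[:, :cols]


def fit_components(sig: TimeSignal, model_order: int) -> list:
    """Estimate ``model_order`` damped sinusoids from an FID.

    Parameters
    ----------
    sig
        The time-domain signal to model.
    model_order
        Number of Lorentzian components, i.e. the SVD truncation rank.
        Must satisfy ``1 <= model_order < n/2``.

    Returns
    -------
    list of DampedSinusoid, sorted by decreasing amplitude.
    """
    n = sig.params.num_points
    if model_order < 1:
        raise ParameterError("model_order must be >= 1")
    if model_order >= n // 2:
        raise ParameterError(
            f"model_order {model_order} too large for {n}-point FID (needs < n/2)"
        )
    x = sig.samples
    if not np.any(x):
        raise NumericsError("all-zero FID has no signal subspace")

    H = _hankel(x)
    rows = H.shape[0]
    if rows <= _DENSE_SVD_MAX_ROWS:
        U, s, _ = np.linalg.svd(H, full_matrices=False)
        Uk = U[:, :model_order]
        s_k = s[:model_order]
    else:
        # Lanczos with a fixed start vector keeps provenance replay exact.
        v0 = np.ones(min(H.shape), dtype=complex)
        U, s, _ = scipy.sparse.linalg.svds(H, k=model_order, v0=v0)
        order = np.argsort(s)[::-1]
        Uk = U[:, order]
        s_k = s[order]
    if s_k[-1] <= 1e-12 * max(s_k[0], 1e-300):
        raise NumericsError(
            f"signal subspace rank-deficient: order {model_order} exceeds signal rank"
        )

    # Shift invariance: Uk without last row times Z ~= Uk without first row.
    Z, *_ = np.linalg.lstsq(Uk[:-1], Uk[1:], rcond=None)
    poles = np.linalg.eigvals(Z)

    dt = sig.dwell_time
    freqs = np.angle(poles) / (2 * np.pi * dt)
    with np.errstate(divide="ignore"):
        dampings = -np.log(np.abs(poles)) / dt

    # Complex amplitudes by linear least squares against the full FID.
    t = sig.times
    basis = np.exp(np.outer(t, 1j * 2 * np.pi * freqs - dampings))
    coeffs, *_ = np.linalg.lstsq(basis, x, rcond=None)

    comps = [
        DampedSinusoid(
            amplitude=float(np.abs(c)),
            phase=float(np.angle(c)),
            frequency=float(f),
            damping=float(d),
        )
        for c, f, d in zip(coeffs, freqs, dampings)
    ]
    comps.sort(key=lambda c: -c.amplitude)
    return comps


def reconstruct(components: list, params: AcquisitionParams) -> TimeSignal:
    """Sum of damped complex sinusoids sampled on the acquisition grid."""
    t = np.arange(params.num_points) * (1.0 / params.sweep_width)
    fid = np.zeros(params.num_points, dtype=complex)
    for c in components:
        fid += c.amplitude * np.exp(1j * c.phase) * np.exp(
            (1j * 2 * np.pi * c.frequency - c.damping) * t
        )
    return TimeSignal(fid, params)


def select_in_regions(components: list, regions: list, params: AcquisitionParams) -> list:
    """Components whose chemical shift falls inside any closed ppm region."""
    for r in regions:
        if not isinstance(r, PpmRange):
            raise ParameterError("regions must be PpmRange instances")
    return [
        c for c in components if any(r.contains(c.ppm(params)) for r in regions)
    ]
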