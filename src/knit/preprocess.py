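"""Signal conditioning between upstream-denoised BOLD and FC computation.

Fixed stage order (asserted by the pipeline driver):
discard initial timepoints -> spatial smoothing -> temporal low-pass ->
per-voxel z-scoring.  Pearson correlation is invariant to the z-score step;
it is kept explicit so intermediate volumes are inspectable on the scale FC
is computed on.

Defaults follow resting-state practice for fast-TR neonatal acquisitions:
discard 5 volumes, 3 mm FWHM Gaussian smoothing, 0.08 Hz low-pass.  The
low-pass is a 4th-order Butterworth applied forward-backward (zero phase);
the filter family/order is a package default, configurable.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage, signal

from .io_formats import BoldSeries

#: FWHM-to-sigma conversion for a Gaussian kernel
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def discard_initial(bold: BoldSeries, n_discard: int = 5) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (signal steady-state settling)."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if bold.n_timepoints <= n_discard:
        raise ValueError(
            f"cannot discard {n_discard} of {bold.n_timepoints} timepoints")
    if n_discard == 0:
        return bold.with_data(bold.data)
    return bold.with_data(bold.data[..., n_discard:])


def smooth_spatial(bold: BoldSeries, fwhm_mm: float = 3.0) -> BoldSeries:
    """Gaussian-smooth each volume with the given FWHM (mm).

    Sigma is converted to voxel units per axis from the affine, so anisotropic
    grids smooth isotropically in world space.  Boundary handling is reflect;
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return bold.with_data(bold.data)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / bold.voxel_sizes()
    out = ndimage.gaussian_filter(bold.data, sigma=tuple(sigma_vox) + (0.0,),
                                  mode="reflect")
    return bold.with_data(out)


def butterworth_lowpass(cutoff_hz: float, tr: float, order: int = 4):
    """SOS coefficients of the default low-pass design."""
    nyquist = 0.5 / tr
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:.4f}) Hz")
    return signal.butter(order, cutoff_hz, btype="low", fs=1.0 / tr, output="sos")


def lowpass_temporal(bold: BoldSeries, cutoff_hz: float = 0.08,
                     order: int = 4) -> BoldSeries:
    """Zero-phase temporal low-pass, per voxel; series length preserved."""
    sos = butterworth_lowpass(cutoff_hz, bold.tr, order)
    out = signal.sosfiltfilt(sos, bold.data, axis=-1)
    return bold.with_data(out)


def zscore_timeseries(bold: BoldSeries, mask: np.ndarray | None = None) -> BoldSeries:
    """Standardize every voxel series to mean 0, SD 1 (population SD).

    Constant series inside the analysis mask are an error (their correlation
    is undefined); constant series outside it are silently zeroed.  With no
    mask every voxel counts as in-mask.
    """
    data = bold.data
    mean = data.mean(axis=-1, keepdims=True)
    sd = data.std(axis=-1, keepdims=True)
    flat = sd[..., 0] == 0
    if mask is None:
        n_bad = int(flat.sum())
    else:
        n_bad = int((flat & mask).sum())
    if n_bad:
        raise ValueError(f"{n_bad} constant voxel time series inside the analysis mask")
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (data - mean) / safe_sd
    out[flat] = 0.0
    return bold.with_data(out)


def preprocess(bold: BoldSeries, n_discard: int = 5, fwhm_mm: float = 3.0,
               cutoff_hz: float = 0.08, mask: np.ndarray | None = None,
               zscore: bool = True) -> BoldSeries:
    """The fixed conditioning chain: discard -> smooth -> low-pass -> z-score.

    When ``mask`` is given, the temporal stages (low-pass, z-score) are
    applied to in-mask voxels only and everything outside the mask is zeroed
    — downstream FC never reads those voxels, and filtering them would
    dominate runtime on long acquisitions.  Without a mask the full grid is
    processed.
    """
    out = discard_initial(bold, n_discard)
    out = smooth_spatial(out, fwhm_mm)
    if mask is None:
        if cutoff_hz is not None:
            out = lowpass_temporal(out, cutoff_hz)
        if zscore:
            out = zscore_timeseries(out, None)
        return out

    mask = np.asarray(mask, dtype=bool)
    series = out.data[mask]
    if cutoff_hz is not None:
        sos = butterworth_lowpass(cutoff_hz, out.tr)
        series = signal.sosfiltfilt(sos, series, axis=-1)
    if zscore:
        mean = series.mean(axis=-1, keepdims=True)
        sd = series.std(axis=-1, keepdims=True)
        n_bad = int((sd == 0).sum())
        if n_bad:
            raise ValueError(
                f"{n_bad} constant voxel time series inside the analysis mask")
        series = (series - mean) / sd
    data = np.zeros_like(out.data)
    data[mask] = series
    return out.with_data(data)
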