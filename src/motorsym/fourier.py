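"""Fourier-space volume operations: low-pass filtering and FSC.

Fourier shell correlation uses shells one Fourier voxel wide; the 0.5
(map-model) and 0.143 (half-map) resolution thresholds are the named
constants :data:`FSC_MAP_MODEL` and :data:`FSC_HALF_MAP`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

FSC_MAP_MODEL = 0.5
FSC_HALF_MAP = 0.143


def _freq_radius(n: int, voxel_size: float) -> np.ndarray:
    """|k| in 1/Å for every FFT sample of an n^3 grid."""
    k = np.fft.fftfreq(n, d=voxel_size)
    return np.sqrt(
        k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2
    )


def lowpass(v: Volume, resolution: float) -> Volume:
    """Low-pass filter with a raised-cosine rolloff one shell wide.

    The rolloff band is centred at 1/resolution with total width one
    Fourier voxel, 1/(n * voxel).  The DC term passes, so the mean density
    is preserved.  ``resolution`` must be coarser than twice the voxel
    size (the Nyquist limit).
    """
    if resolution <= 2.0 * v.voxel_size:
        raise ValueError(
            f"resolution {resolution} Å at or beyond Nyquist ({2 * v.voxel_size} Å)"
        )
    n = v.n
    kc = 1.0 / resolution
    dk = 1.0 / (n * v.voxel_size)
    kr = _freq_radius(n, v.voxel_size)
    h = np.clip((kr - (kc - dk / 2.0)) / dk, 0.0, 1.0)
    filt = 0.5 * (1.0 + np.cos(np.pi * h))
    out = np.fft.ifftn(np.fft.fftn(v.grid) * filt).real
    return Volume(out, v.voxel_size, v.origin)


@dataclass
class FSCCurve:
    """Per-shell correlation between the Fourier transforms of two maps.

    freq : shell-centre spatial frequency, 1/Å, shells one Fourier voxel
    wide from DC to Nyquist; correlation in [-1, 1].
    """

    freq: np.ndarray
    correlation: np.ndarray
    shell_width: float


def fsc(a: Volume, b: Volume) -> FSCCurve:
    """Fourier shell correlation between two maps on the same grid."""
    if a.grid.shape != b.grid.shape or a.voxel_size != b.voxel_size:
        raise ValueError("FSC requires identical grids and voxel sizes")
    n = a.n
    fa = np.fft.fftn(a.grid)
    fb = np.fft.fftn(b.grid)
    ki = np.fft.fftfreq(n) * n
    rad = np.sqrt(
        ki[:, None, None] ** 2 + ki[None, :, None] ** 2 + ki[None, None, :] ** 2
    )
    shell = np.rint(rad).astype(int)
    nshell = n // 2 + 1
    keep = (shell < nshell).ravel()
    idx = shell.ravel()[keep]
    cross = np.bincount(idx, weights=(fa * np.conj(fb)).real.ravel()[keep], minlength=nshell)
    pa = np.bincount(idx, weights=(np.abs(fa) ** 2).ravel()[keep], minlength=nshell)
    pb = np.bincount(idx, weights=(np.abs(fb) ** 2).ravel()[keep], minlength=nshell)
    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cross / denom, 0.0)
    dk = 1.0 / (n * a.voxel_size)
    return FSCCurve(freq=np.arange(nshell) * dk, correlation=corr, shell_width=dk)


def resolution_at(curve: FSCCurve, threshold: float) -> float | None:
    """Resolution (Å) at the first downward crossing of ``threshold``.

    Linear interpolation between shells; returns None when the curve never
    drops below the threshold before Nyquist ("beyond Nyquist").
    """
    c = curve.correlation
    f = curve.freq
    for i in range(len(c) - 1):
        if c[i] >= threshold and c[i + 1] < threshold:
            frac = (c[i] - threshold) / (c[i] - c[i + 1])
            fx = f[i] + frac * (f[i + 1] - f[i])
            return float(1.0 / fx)
    return None
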