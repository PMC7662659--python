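"""Wavelet denoising of absorbance spectra and per-class mean spectra.

Each spectrum is decomposed with an orthogonal Daubechies wavelet (Db3 by
default) to a fixed depth (4 by default), every detail level is shrunk
with the universal threshold ``sigma * sqrt(2 ln N)`` — sigma estimated
once from the median absolute coefficient of the finest detail level,
which carries essentially no signal for a smooth spectrum — and the
signal is reconstructed.  Approximation coefficients are never touched, so smooth
baseline structure survives while high-frequency noise is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt

from .spectra_io import SpectralDataset

__all__ = ["WaveletConfig", "denoise_spectrum", "denoise_dataset",
           "class_mean_spectra"]


@dataclass(frozen=True)
class WaveletConfig:
    basis: str = "db3"
    level: int = 4
    threshold_rule: str = "universal_soft"  # or "universal_hard"
    boundary_mode: str = "symmetric"
    threshold: float | None = None  # fixed threshold overriding the estimate

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.threshold_rule not in ("universal_soft", "universal_hard"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")


def _universal_threshold(finest_detail: np.ndarray, n_total: int) -> float:
    """sigma_hat * sqrt(2 ln N); sigma estimated by MAD from the finest
    detail level, which is essentially noise for a smooth spectrum."""
    mad = np.median(np.abs(finest_detail))
    sigma = mad / 0.6745
    return sigma * np.sqrt(2.0 * np.log(max(n_total, 2)))


def denoise_spectrum(x: np.ndarray, cfg: WaveletConfig = WaveletConfig()) -> np.ndarray:
    """Denoise one spectrum; output has the same length as the input."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("denoise_spectrum expects a 1-D vector")
    wav = pywt.Wavelet(cfg.basis)
    if x.size < wav.dec_len:
        raise ValueError(
            f"signal length {x.size} shorter than {cfg.basis} filter "
            f"({wav.dec_len})")
    max_level = pywt.dwt_max_level(x.size, wav.dec_len)
    if cfg.level > max_level:
        raise ValueError(
            f"decomposition level {cfg.level} too deep for signal length "
            f"{x.size}; maximum admissible level is {max_level}")
    coeffs = pywt.wavedec(x, wav, mode=cfg.boundary_mode, level=cfg.level)
    mode = "soft" if cfg.threshold_rule == "universal_soft" else "hard"
    thr = cfg.threshold if cfg.threshold is not None \
        else _universal_threshold(coeffs[-1], x.size)
    out = [coeffs[0]]  # approximation untouched
    for d in coeffs[1:]:
        out.append(pywt.threshold(d, thr, mode=mode))
    rec = pywt.waverec(out, wav, mode=cfg.boundary_mode)
    return rec[: x.size]


def denoise_dataset(ds: SpectralDataset,
                    cfg: WaveletConfig = WaveletConfig()) -> SpectralDataset:
    """Row-wise denoising; labels and axis unchanged."""
    den = np.vstack([denoise_spectrum(row, cfg) for row in ds.absorbance])
    return SpectralDataset(
        absorbance=den, wavenumbers=ds.wavenumbers.copy(),
        origin=ds.origin, variety=ds.variety, sample_id=ds.sample_id,
    )


def class_mean_spectra(ds: SpectralDataset, by: str = "origin"):
    """Column-wise mean spectrum per class; returns (classes, matrix)."""
    labels = ds.labels(by)
    classes = sorted(set(map(str, labels)))
    means = np.vstack([
        ds.absorbance[np.asarray([str(l) == c for l in labels])].mean(axis=0)
        for c in classes
    ])
    return classes, means
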