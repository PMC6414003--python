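"""Spectral conditioning: baseline removal, smoothing, normalization.

The conditioning chain is the standard one for serum Raman work: an
iteratively re-fitted 5th-order polynomial removes the broad fluorescence
background, a Savitzky-Golay filter (2nd-order local polynomials) suppresses
shot noise and cosmic-ray residue without distorting band shapes, and each
spectrum is normalized to the phenylalanine band at 1002 cm^-1 so that
intensities are comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import savgol_filter

from .records import (
    ConfigurationError,
    DegenerateSpectrumError,
    InputError,
    SpectrumRecord,
    same_grid,
)

#: Serum band catalog: (wavenumber or (lo, hi) range in cm^-1, assignment).
BAND_CATALOG: list[tuple[float | tuple[float, float], str]] = [
    (509.0, "tryptophan"),
    (622.0, "phenylalanine"),
    (642.0, "tyrosine"),
    (714.0, "polysaccharides"),
    (760.0, "tryptophan"),
    (828.0, "tyrosine"),
    (853.0, "tyrosine"),
    (938.0, "skeletal str alpha"),
    (1002.0, "phenylalanine"),
    (1028.0, "phenylalanine"),
    (1063.0, "phenylalanine"),
    (1103.0, "phenylalanine"),
    (1160.0, "beta-carotene"),
    (1208.0, "tryptophan"),
    ((1230.0, 1282.0), "amide III"),
    (1447.0, "phospholipid"),
    (1523.0, "beta-carotene"),
    (1556.0, "tryptophan"),
    (1603.0, "tyrosine"),
    (1620.0, "tryptophan"),
    (1654.0, "amide I"),
]


@dataclass
class PreprocessConfig:
    baseline_degree: int = 5
    sg_polyorder: int = 2
    sg_window: int = 11
    norm_peak: float = 1002.0
    norm_window: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline_degree < 0:
            raise ConfigurationError("baseline_degree must be >= 0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigurationError("sg_window must be odd and > sg_polyorder")
        if self.norm_window <= 0:
            raise ConfigurationError("norm_window must be > 0")


def correct_baseline(
    spectrum: SpectrumRecord,
    degree: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> SpectrumRecord:
    """Subtract an iteratively re-fitted polynomial fluorescence baseline.

    Modified-polyfit scheme: fit a degree-``degree`` polynomial, clip the
    working spectrum to the pointwise minimum of itself and the fit, and
    refit until the fit stops changing (relative tolerance ``tol``) or
    ``max_iter`` passes.  Clipping pulls the fit under the peaks, so narrow
    bands survive the subtraction while the smooth background is removed.
    Negative residuals are kept (not clipped) so that distances computed
    downstream are unbiased.
    """
    y = spectrum.intensities
    if y.size <= degree + 1:
        raise InputError(
            f"spectrum of length {y.size} too short for degree-{degree} baseline"
        )
    x = spectrum.wavenumbers
    scale = max(float(np.abs(y).max()), 1e-300)
    work = y.astype(float)
    fit = Polynomial.fit(x, work, degree)(x)
    for _ in range(max_iter):
        work = np.minimum(work, fit)
        new_fit = Polynomial.fit(x, work, degree)(x)
        if np.max(np.abs(new_fit - fit)) < tol * scale:
            fit = new_fit
            break
        fit = new_fit
    return spectrum.with_intensities(y - fit)


def smooth(
    spectrum: SpectrumRecord, polyorder: int = 2, window: int = 11
) -> SpectrumRecord:
    """Savitzky-Golay smoothing on the same grid."""
    if window % 2 == 0 or window <= polyorder or window < 3:
        raise ConfigurationError("window must be odd, >= 3 and > polyorder")
    return spectrum.with_intensities(
        savgol_filter(spectrum.intensities, window_length=window, polyorder=polyorder)
    )


def normalize(
    spectrum: SpectrumRecord, norm_peak: float = 1002.0, norm_window: float = 5.0
) -> SpectrumRecord:
    """Divide by the maximum intensity within ``norm_peak +/- norm_window``.

    A windowed maximum around the 1002 cm^-1 phenylalanine band is used
    rather than the global maximum so that a residual cosmic-ray spike
    elsewhere cannot become the reference.
    """
    wn = spectrum.wavenumbers
    mask = (wn >= norm_peak - norm_window) & (wn <= norm_peak + norm_window)
    if not mask.any():
        raise DegenerateSpectrumError(
            f"no grid points within {norm_peak} +/- {norm_window} cm^-1"
        )
    ref = float(spectrum.intensities[mask].max())
    if ref <= 0:
        raise DegenerateSpectrumError("non-positive reference maximum")
    return spectrum.with_intensities(spectrum.intensities / ref)


def preprocess(
    spectrum: SpectrumRecord, config: PreprocessConfig | None = None
) -> SpectrumRecord:
    """Full conditioning chain: baseline -> smooth -> normalize."""
    cfg = config or PreprocessConfig()
    out = correct_baseline(spectrum, cfg.baseline_degree)
    out = smooth(out, cfg.sg_polyorder, cfg.sg_window)
    return normalize(out, cfg.norm_peak, cfg.norm_window)


def preprocess_cohort(
    spectra: Sequence[SpectrumRecord], config: PreprocessConfig | None = None
) -> list[SpectrumRecord]:
    return [preprocess(s, config) for s in spectra]


def mean_spectrum(spectra: Sequence[SpectrumRecord]) -> SpectrumRecord:
    """Pointwise arithmetic mean of spectra sharing one grid."""
    if not spectra:
        raise InputError("empty spectrum list")
    if not same_grid(spectra):
        raise InputError("spectra are not on a common grid")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return SpectrumRecord(wavenumbers=spectra[0].wavenumbers, intensities=mean)


def annotate_bands(
    spectrum: SpectrumRecord, half_width: float = 5.0
) -> list[tuple[float | tuple[float, float], str, float]]:
    """Local intensity at every catalog band of a (normalized) spectrum.

    Single bands report the maximum within ``band +/- half_width``; the
    amide-III range reports the maximum over the whole range.  Returns
    ``(band, assignment, intensity)`` triples in catalog order.
    """
    wn = spectrum.wavenumbers
    out = []
    for band, assignment in BAND_CATALOG:
        if isinstance(band, tuple):
            lo, hi = band
        else:
            lo, hi = band - half_width, band + half_width
        mask = (wn >= lo) & (wn <= hi)
        intensity = float(spectrum.intensities[mask].max()) if mask.any() else float("nan")
        out.append((band, assignment, intensity))
    return out
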