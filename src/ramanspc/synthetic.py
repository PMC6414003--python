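"""Synthetic serum-Raman cohort generator.

Emulates a three-class cohort of serum spectra (breast cancer, cervical
cancer, leukemia) on the 400-1800 cm^-1 fingerprint region.  Each class
shares a common catalog of serum bands (phenylalanine, tyrosine, amide I/III,
beta-carotene, tryptophan, phospholipid, polysaccharide, skeletal modes) and
differs by class-specific band suppressions:

* leukemia lacks the amide-I region and its neighbours
  (1654, 1620, 1603, 1556, 1523 cm^-1) and the 1447 cm^-1 phospholipid band;
* breast and cervical lack the low-wavenumber amide-III shoulder and the
  938 cm^-1 skeletal region;
* cervical additionally lacks the 714 cm^-1 polysaccharide band;
* breast flattens the bulged 1040-1100 cm^-1 phenylalanine/phospholipid
  region.

Spectra are sums of Lorentzian lines scaled by per-(patient, band) log-normal
factors, plus a random positive polynomial fluorescence baseline, Gaussian
shot noise, and sparse cosmic-ray spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ConfigurationError, SpectrumRecord

CLASS_NAMES = ("breast", "cervical", "leukemia")

# (center cm^-1, FWHM cm^-1, relative amplitude, assignment)
# Amplitudes are free parameters of the simulator, chosen so that the
# 1002 cm^-1 phenylalanine band is globally maximal before normalization.
_COMMON_BANDS: list[tuple[float, float, float, str]] = [
    (509.0, 8.0, 0.20, "tryptophan"),
    (622.0, 8.0, 0.25, "phenylalanine"),
    (642.0, 8.0, 0.22, "tyrosine"),
    (714.0, 8.0, 0.30, "polysaccharides"),
    (760.0, 8.0, 0.30, "tryptophan"),
    (828.0, 8.0, 0.25, "tyrosine"),
    (853.0, 8.0, 0.30, "tyrosine"),
    (938.0, 10.0, 0.30, "skeletal str alpha"),
    (1002.0, 8.0, 1.00, "phenylalanine"),
    (1028.0, 8.0, 0.30, "phenylalanine"),
    (1063.0, 10.0, 0.35, "phenylalanine"),
    (1070.0, 45.0, 0.70, "phenylalanine/phospholipid envelope"),
    (1103.0, 10.0, 0.30, "phenylalanine"),
    (1160.0, 8.0, 0.25, "beta-carotene"),
    (1208.0, 8.0, 0.28, "tryptophan"),
    (1240.0, 25.0, 0.45, "amide III (low shoulder)"),
    (1270.0, 25.0, 0.45, "amide III (high shoulder)"),
    (1447.0, 10.0, 0.55, "phospholipid"),
    (1523.0, 8.0, 0.30, "beta-carotene"),
    (1556.0, 8.0, 0.25, "tryptophan"),
    (1603.0, 8.0, 0.35, "tyrosine"),
    (1620.0, 8.0, 0.30, "tryptophan"),
    (1654.0, 12.0, 0.75, "amide I"),
]


@dataclass
class BandProfile:
    """One Raman line: Lorentzian center, FWHM, and relative amplitude."""

    center: float
    width: float
    amplitude: float
    assignment: str = ""

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ConfigurationError("band width must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError("band amplitude must be >= 0")
        if not (400.0 <= self.center <= 1800.0):
            raise ConfigurationError("band center must lie in 400-1800 cm^-1")


@dataclass
class ClassTemplate:
    """A class-specific spectral template.

    ``suppressed_bands`` lists ``(lo, hi, factor)`` wavenumber ranges whose
    overlapping bands are attenuated by ``factor`` in [0, 1]; a factor of 0
    removes a band completely.
    """

    class_name: str
    bands: list[BandProfile]
    suppressed_bands: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ConfigurationError(f"unknown class {self.class_name!r}")
        for lo, hi, factor in self.suppressed_bands:
            if not (0.0 <= factor <= 1.0):
                raise ConfigurationError("suppression factor must be in [0, 1]")
            if not any(lo <= b.center <= hi for b in self.bands):
                raise ConfigurationError(
                    f"suppressed range ({lo}, {hi}) overlaps no band"
                )

    def effective_amplitude(self, band: BandProfile) -> float:
        """Band amplitude after applying every overlapping suppression."""
        amp = band.amplitude
        for lo, hi, factor in self.suppressed_bands:
            if lo <= band.center <= hi:
                amp *= factor
        return amp


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings.

    Defaults mirror the reference cohort design: 2330-point spectra on
    400-1800 cm^-1 (~0.6 cm^-1 spacing), 160/150/42 spectra from 16/21/7
    breast/cervical/leukemia patients.
    """

    n_points: int = 2330
    wn_min: float = 400.0
    wn_max: float = 1800.0
    n_spectra_per_class: tuple[int, int, int] = (160, 150, 42)
    n_patients_per_class: tuple[int, int, int] = (16, 21, 7)
    baseline_degree: int = 5
    baseline_scale: float = 2.0
    noise_sd: float = 0.06
    spike_rate: float = 0.2
    patient_effect_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ConfigurationError("n_points must be >= 2")
        if not self.wn_min < self.wn_max:
            raise ConfigurationError("wn_min must be < wn_max")
        if any(c < 1 for c in self.n_spectra_per_class) or any(
            c < 1 for c in self.n_patients_per_class
        ):
            raise ConfigurationError("all counts must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.spike_rate < 0 or self.patient_effect_sd < 0:
            raise ConfigurationError("rates and spreads must be >= 0")
        if self.baseline_degree < 0:
            raise ConfigurationError("baseline_degree must be >= 0")

    def grid(self) -> np.ndarray:
        return np.linspace(self.wn_min, self.wn_max, self.n_points)


def default_templates() -> list[ClassTemplate]:
    """The three class templates (breast, cervical, leukemia).

    All share the common serum band catalog; class identity comes from the
    suppression lists described in the module docstring.
    """
    bands = [BandProfile(c, w, a, label) for c, w, a, label in _COMMON_BANDS]
    breast = ClassTemplate(
        "breast",
        bands=[BandProfile(b.center, b.width, b.amplitude, b.assignment) for b in bands],
        suppressed_bands=[
            (1225.0, 1252.0, 0.15),  # low amide-III shoulder
            (925.0, 950.0, 0.2),  # skeletal 938 region
            (1040.0, 1100.0, 0.1),  # flattened bulge
        ],
    )
    cervical = ClassTemplate(
        "cervical",
        bands=[BandProfile(b.center, b.width, b.amplitude, b.assignment) for b in bands],
        suppressed_bands=[
            (1225.0, 1252.0, 0.15),
            (925.0, 950.0, 0.2),
            (705.0, 725.0, 0.05),  # polysaccharide band vanishes
        ],
    )
    leukemia = ClassTemplate(
        "leukemia",
        bands=[BandProfile(b.center, b.width, b.amplitude, b.assignment) for b in bands],
        suppressed_bands=[
            (1648.0, 1660.0, 0.0),  # amide I completely absent
            (1615.0, 1625.0, 0.05),
            (1598.0, 1608.0, 0.05),
            (1551.0, 1561.0, 0.05),
            (1518.0, 1528.0, 0.05),
            (1440.0, 1454.0, 0.1),  # phospholipid vanishes
        ],
    )
    return [breast, cervical, leukemia]


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Peak-normalized Lorentzian line shape."""
    half = fwhm / 2.0
    return 1.0 / (1.0 + ((x - center) / half) ** 2)


def template_signal(
    template: ClassTemplate,
    grid: np.ndarray,
    band_factors: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free band superposition for a template on a grid.

    ``band_factors`` optionally scales each band (the per-patient effect);
    default is all ones.
    """
    signal = np.zeros_like(grid)
    if band_factors is None:
        band_factors = np.ones(len(template.bands))
    for band, factor in zip(template.bands, band_factors):
        amp = template.effective_amplitude(band) * factor
        if amp > 0:
            signal += amp * _lorentzian(grid, band.center, band.width)
    return signal


def _patient_band_factors(
    template: ClassTemplate, config: SimulationConfig, patient_rng: np.random.Generator
) -> np.ndarray:
    if config.patient_effect_sd == 0:
        return np.ones(len(template.bands))
    return np.exp(
        patient_rng.normal(0.0, config.patient_effect_sd, size=len(template.bands))
    )


def simulate_spectrum(
    template: ClassTemplate,
    patient_id: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    band_factors: np.ndarray | None = None,
    cohort_index: int | None = None,
) -> SpectrumRecord:
    """Simulate one raw spectrum for a patient of the template's class.

    signal = sum of Lorentzians x patient band factors
             + random polynomial fluorescence baseline
             + Gaussian shot noise
             + Poisson-placed cosmic-ray spikes,
    clipped at zero.
    """
    grid = config.grid()
    signal = template_signal(template, grid, band_factors)
    peak_scale = max(float(signal.max()), 1e-12)

    # fluorescence: random positive polynomial, ~baseline_scale x peak scale
    if config.baseline_scale > 0 and config.baseline_degree >= 0:
        x = np.linspace(-1.0, 1.0, grid.size)
        coeffs = rng.normal(0.0, 1.0, size=config.baseline_degree + 1)
        coeffs /= np.arange(1, config.baseline_degree + 2) ** 1.5
        poly = np.polynomial.polynomial.polyval(x, coeffs)
        poly = poly - poly.min()  # non-negative, varies across the grid
        baseline = config.baseline_scale * peak_scale * (0.25 + poly)
    else:
        baseline = np.zeros_like(grid)

    noise = rng.normal(0.0, config.noise_sd, size=grid.size) if config.noise_sd else 0.0

    spikes = np.zeros_like(grid)
    n_spikes = rng.poisson(config.spike_rate) if config.spike_rate > 0 else 0
    for _ in range(n_spikes):
        pos = rng.integers(0, grid.size)
        width = rng.integers(1, 4)  # 1-3 points
        amp = rng.uniform(5.0, 10.0) * peak_scale
        lo, hi = pos, min(pos + width, grid.size)
        spikes[lo:hi] += amp

    intensities = np.clip(signal + baseline + noise + spikes, 0.0, None)
    return SpectrumRecord(
        wavenumbers=grid,
        intensities=intensities,
        class_label=template.class_name,
        patient_id=patient_id,
        cohort_index=cohort_index,
    )


def simulate_cohort(
    config: SimulationConfig, templates: list[ClassTemplate] | None = None
) -> list[SpectrumRecord]:
    """Simulate the full labeled cohort, deterministically from ``config.seed``.

    Spectra are ordered breast, then cervical, then leukemia, with 1-based
    cohort indices; each class's spectra are split near-evenly across its
    patients (earlier patients take the remainder).
    """
    if templates is None:
        templates = default_templates()
    by_name = {t.class_name: t for t in templates}
    root = np.random.SeedSequence(config.seed)
    # one child stream per class: patient effects + spectrum noise
    class_seeds = root.spawn(len(CLASS_NAMES))

    cohort: list[SpectrumRecord] = []
    index = 1
    for ci, name in enumerate(CLASS_NAMES):
        template = by_name[name]
        n_spec = config.n_spectra_per_class[ci]
        n_pat = config.n_patients_per_class[ci]
        patient_seeds = class_seeds[ci].spawn(n_pat)
        base, extra = divmod(n_spec, n_pat)
        for pi in range(n_pat):
            rng = np.random.default_rng(patient_seeds[pi])
            factors = _patient_band_factors(template, config, rng)
            count = base + (1 if pi < extra else 0)
            pid = f"{name}_{pi + 1:02d}"
            for _ in range(count):
                cohort.append(
                    simulate_spectrum(
                        template, pid, config, rng,
                        band_factors=factors, cohort_index=index,
                    )
                )
                index += 1
    return cohort
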