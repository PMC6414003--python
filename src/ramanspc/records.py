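"""Core spectrum container and delimited-text I/O.

A Raman spectrum is a pair of equal-length arrays: a strictly increasing
wavenumber grid (cm^-1) and the measured (or simulated) intensities at those
Raman shifts.  Class and patient labels are optional metadata carried through
the pipeline so that clustering output can be scored against known cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Raised when input data violates a precondition."""


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of range."""


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum is unusable (e.g. flat zero at normalization)."""


@dataclass
class SpectrumRecord:
    """One spectrum: wavenumber grid, intensities, and optional labels.

    Parameters
    ----------
    wavenumbers : array of float
        Strictly increasing Raman shifts in cm^-1.
    intensities : array of float
        Intensity at each shift, same length as ``wavenumbers``.
    class_label : str, optional
        Diagnostic class (e.g. ``"breast"``, ``"cervical"``, ``"leukemia"``).
    patient_id : str, optional
        Identifier of the patient the spectrum was acquired from.
    cohort_index : int, optional
        1-based position of the spectrum in the cohort (column of the data
        matrix).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    class_label: str | None = None
    patient_id: str | None = None
    cohort_index: int | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise InputError("wavenumbers and intensities must be 1-D arrays")
        if self.wavenumbers.shape != self.intensities.shape:
            raise InputError(
                f"grid length {self.wavenumbers.size} != intensity length "
                f"{self.intensities.size}"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise InputError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise InputError("intensities must be finite")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumRecord":
        """Copy of this record with new intensities on the same grid."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavenumber_cm-1": self.wavenumbers, "intensity": self.intensities}
        )


def same_grid(spectra: Sequence[SpectrumRecord], atol: float = 1e-9) -> bool:
    """True if all spectra share one wavenumber grid (within ``atol``)."""
    if not spectra:
        return True
    ref = spectra[0].wavenumbers
    return all(
        s.wavenumbers.size == ref.size and np.allclose(s.wavenumbers, ref, atol=atol)
        for s in spectra
    )


def write_spectrum_csv(spectrum: SpectrumRecord, path: str | Path) -> None:
    spectrum.to_frame().to_csv(path, index=False)


def read_spectrum_csv(
    path: str | Path,
    class_label: str | None = None,
    patient_id: str | None = None,
    cohort_index: int | None = None,
) -> SpectrumRecord:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected at least two columns")
    return SpectrumRecord(
        wavenumbers=df.iloc[:, 0].to_numpy(float),
        intensities=df.iloc[:, 1].to_numpy(float),
        class_label=class_label,
        patient_id=patient_id,
        cohort_index=cohort_index,
    )


def write_cohort(
    spectra: Iterable[SpectrumRecord], out_dir: str | Path
) -> pd.DataFrame:
    """Write one CSV per spectrum plus a cohort manifest.

    Returns the manifest (index, class, patient_id, filename) as a DataFrame;
    it is also written to ``manifest.csv`` in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(spectra):
        idx = s.cohort_index if s.cohort_index is not None else i + 1
        fname = f"spectrum_{idx:04d}.csv"
        write_spectrum_csv(s, out / fname)
        rows.append(
            {
                "index": idx,
                "class": s.class_label,
                "patient_id": s.patient_id,
                "filename": fname,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_cohort(in_dir: str | Path) -> list[SpectrumRecord]:
    """Read a cohort written by :func:`write_cohort` (via its manifest)."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    spectra = []
    for _, row in manifest.iterrows():
        spectra.append(
            read_spectrum_csv(
                in_dir / row["filename"],
                class_label=None if pd.isna(row["class"]) else str(row["class"]),
                patient_id=None if pd.isna(row["patient_id"]) else str(row["patient_id"]),
                cohort_index=int(row["index"]),
            )
        )
    return spectra


def write_wide_matrix(spectra: Sequence[SpectrumRecord], path: str | Path) -> None:
    """Write a cohort as a single wide CSV: wavenumber column + one column per spectrum."""
    if not spectra:
        raise InputError("empty cohort")
    if not same_grid(spectra):
        raise InputError("cohort spectra are not on a common grid")
    data = {"wavenumber_cm-1": spectra[0].wavenumbers}
    for i, s in enumerate(spectra):
        idx = s.cohort_index if s.cohort_index is not None else i + 1
        data[f"s{idx:04d}"] = s.intensities
    pd.DataFrame(data).to_csv(path, index=False)
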