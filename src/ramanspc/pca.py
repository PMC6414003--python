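"""PCA cross-check: score scatter and loading-vs-wavenumber curves.

Spectra (the columns of the data matrix) are the observations; Raman shifts
are the variables.  Data are mean-centered but not scaled -- spectra are
already normalized to a common reference peak, so unit-variance scaling
would inflate flat spectral regions.  Component signs are fixed so the
largest-magnitude loading of each component is positive, making results
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .graph import SpectraMatrix
from .records import ConfigurationError


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_spectra, k)
    loadings: np.ndarray  # (n_points, k), unit-norm columns
    explained_variance: np.ndarray  # fraction per component
    grid: np.ndarray | None = None


def run_pca(matrix: SpectraMatrix | np.ndarray, k: int = 3) -> PCAResult:
    """PCA of the spectra-as-observations covariance, deterministic signs."""
    if isinstance(matrix, SpectraMatrix):
        values = matrix.values
        grid = matrix.grid
    else:
        values = np.asarray(matrix, dtype=float)
        grid = None
    n_points, n_spectra = values.shape
    if not (1 <= k <= min(n_points, n_spectra)):
        raise ConfigurationError(f"k={k} out of range for {n_points}x{n_spectra} matrix")

    X = values.T  # observations = spectra
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # (n_points, k), unit-norm columns

    # sign convention: largest-|loading| entry positive per component
    for c in range(k):
        idx = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[idx, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1

    ev = pca.explained_variance_ratio_.copy()
    if np.allclose(pca.explained_variance_, 0.0):
        warnings.warn("degenerate input: zero variance across spectra", stacklevel=2)
        ev = np.zeros_like(ev)
    return PCAResult(scores=scores, loadings=loadings, explained_variance=ev, grid=grid)


def loading_curve(
    result: PCAResult, component_index: int = 0, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Loading values paired with wavenumbers for one component."""
    if component_index >= result.loadings.shape[1]:
        raise ConfigurationError("component index out of range")
    g = grid if grid is not None else result.grid
    if g is None:
        g = np.arange(result.loadings.shape[0], dtype=float)
    return pd.DataFrame(
        {"wavenumber_cm-1": g, "loading": result.loadings[:, component_index]}
    )


def loading_peaks(
    result: PCAResult,
    component_index: int = 0,
    grid: np.ndarray | None = None,
    n_peaks: int = 5,
) -> np.ndarray:
    """Wavenumbers of the ``n_peaks`` largest |loading| values (descending)."""
    curve = loading_curve(result, component_index, grid)
    order = np.argsort(-np.abs(curve["loading"].to_numpy()))[:n_peaks]
    return curve["wavenumber_cm-1"].to_numpy()[order]


def write_pca(result: PCAResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = result.scores.shape[1]
    pd.DataFrame(
        result.scores, columns=[f"PC{c + 1}" for c in range(k)]
    ).to_csv(out / "pca_scores.csv", index=False)
    load = pd.DataFrame(result.loadings, columns=[f"PC{c + 1}" for c in range(k)])
    if result.grid is not None:
        load.insert(0, "wavenumber_cm-1", result.grid)
    load.to_csv(out / "pca_loadings.csv", index=False)
    pd.DataFrame(
        {"component": np.arange(1, k + 1), "explained_variance": result.explained_variance}
    ).to_csv(out / "pca_variance.csv", index=False)
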