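"""Spectral preprocessing and the 1D-to-2D outer-product transform.

The processing chain applied before modelling is: Savitzky-Golay five-point
smoothing of every acquired point spectrum, cropping to the informative
1038-2475 nm range, averaging (the four points of each direction, and
optionally the four direction means), per-spectrum min-max normalisation to
[0, 1], and finally the rank-1 spectral-information matrix S = x x^T that a
convolutional network consumes as a single-channel image.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .synth import wavelengths_from_columns

META_COLUMNS = ["sample_id", "class", "adulterant", "proportion", "direction", "point"]


def sg_smooth(values: np.ndarray, window: int = 5, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing.

    Edges are handled by evaluating the polynomial fitted to the first/last
    window beyond its centre (scipy's ``mode="interp"``), so polynomials of
    degree <= ``polyorder`` are reproduced exactly everywhere.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if values.shape[-1] < window:
        raise ValueError("spectrum shorter than the smoothing window")
    return savgol_filter(values, window, polyorder, axis=-1, mode="interp")


def crop(wavelengths: np.ndarray, values: np.ndarray,
         lo: float = 1038.0, hi: float = 2475.0) -> tuple[np.ndarray, np.ndarray]:
    """Retain channels with ``lo <= lambda <= hi``, preserving order."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"no channels inside [{lo}, {hi}] nm")
    return wavelengths[mask], values[..., mask]


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Per-spectrum min-max scaling to [0, 1].

    Raises on a constant spectrum, whose range is undefined.
    """
    values = np.asarray(values, dtype=float)
    vmin = values.min(axis=-1, keepdims=True)
    vmax = values.max(axis=-1, keepdims=True)
    if np.any(vmax - vmin <= 0):
        raise ValueError("constant spectrum: min-max normalisation undefined")
    return (values - vmin) / (vmax - vmin)


def _check_complete(df: pd.DataFrame, n_directions: int = 4, n_points: int = 4):
    counts = df.groupby(["sample_id", "direction"], sort=False).size()
    if (counts != n_points).any():
        bad = counts[counts != n_points].index[0]
        raise ValueError(f"sample {bad[0]} direction {bad[1]}: expected "
                         f"{n_points} points, got {counts[bad]}")
    per_sample = df.groupby("sample_id", sort=False)["direction"].nunique()
    if (per_sample != n_directions).any():
        bad = per_sample[per_sample != n_directions].index[0]
        raise ValueError(f"sample {bad}: expected {n_directions} directions")


def mean_per_direction(df: pd.DataFrame, n_directions: int = 4,
                       n_points: int = 4) -> pd.DataFrame:
    """Average the point spectra within each direction of each sample.

    A complete table of N samples yields 4N direction-mean spectra.
    """
    _check_complete(df, n_directions, n_points)
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    keys = ["sample_id", "class", "adulterant", "proportion", "direction"]
    out = df.groupby(keys, sort=False, as_index=False)[wl_cols].mean()
    return out


def mean_of_directions(df_dir: pd.DataFrame, n_directions: int = 4) -> pd.DataFrame:
    """Average the four direction means of each sample into one spectrum."""
    counts = df_dir.groupby("sample_id", sort=False).size()
    if (counts != n_directions).any():
        bad = counts[counts != n_directions].index[0]
        raise ValueError(f"sample {bad}: expected exactly {n_directions} "
                         "direction means")
    wl_cols = [c for c in df_dir.columns if c not in META_COLUMNS]
    keys = ["sample_id", "class", "adulterant", "proportion"]
    return df_dir.groupby(keys, sort=False, as_index=False)[wl_cols].mean()


def to_matrix(x: np.ndarray) -> np.ndarray:
    """Spectral-information matrix S = x x^T of a normalised spectrum.

    S is symmetric and rank <= 1 with S[i][j] = x[i] * x[j]; its entries lie
    in [0, 1] because x does.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single 1-D spectrum")
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("spectrum must be normalised to [0, 1] first")
    return np.outer(x, x)


def preprocess_table(df: pd.DataFrame, scheme: str = "per-direction",
                     window: int = 5, polyorder: int = 2,
                     lo: float = 1038.0, hi: float = 2475.0) -> pd.DataFrame:
    """Full chain from point spectra to normalised averaged spectra.

    ``scheme`` selects the averaging level: ``"per-direction"`` keeps four
    spectra per sample, ``"four-direction"`` keeps one.  Smoothing and
    cropping act on raw reflectance; averaging precedes normalisation.
    Returns a table with metadata columns plus cropped wavelength columns.
    """
    if scheme not in ("per-direction", "four-direction"):
        raise ValueError(f"unknown averaging scheme {scheme!r}")
    wl = wavelengths_from_columns(df)
    vals = df[[c for c in df.columns if c not in META_COLUMNS]].to_numpy(float)
    vals = sg_smooth(vals, window, polyorder)
    wl_c, vals = crop(wl, vals, lo, hi)

    spec = pd.DataFrame(vals, columns=[f"{w:.4f}" for w in wl_c],
                        index=df.index)
    smoothed = pd.concat([df[META_COLUMNS], spec], axis=1)

    out = mean_per_direction(smoothed)
    if scheme == "four-direction":
        out = mean_of_directions(out)
    wl_cols = [c for c in out.columns if c not in META_COLUMNS]
    out[wl_cols] = minmax_normalize(out[wl_cols].to_numpy(float))
    return out


def matrices_from_table(df_spectra: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Outer-product matrices for every row of a normalised spectra table.

    Returns ``(stack of C x C matrices, metadata frame)`` in row order.
    """
    wl_cols = [c for c in df_spectra.columns if c not in META_COLUMNS]
    meta_cols = [c for c in df_spectra.columns if c in META_COLUMNS]
    X = df_spectra[wl_cols].to_numpy(float)
    mats = np.einsum("ni,nj->nij", X, X)
    return mats, df_spectra[meta_cols].reset_index(drop=True)


def plot_matrix(matrix: np.ndarray, ax=None, cmap: str = "jet"):
    """Render a spectral-information matrix in jet colour (visual aid only).

    Classification always consumes the single-channel matrix itself.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(matrix, cmap=cmap, vmin=0.0, vmax=1.0)
    ax.figure.colorbar(im, ax=ax)
    return ax
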