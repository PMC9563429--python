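"""Calibration/validation partitioning by joint x-y distances (SPXY).

SPXY extends Kennard-Stone sample selection by combining a spectral
distance with a response distance, so the calibration set covers both the
feature space and the label space.  For the categorical labels used here
the response distance is the Euclidean distance between one-hot encodings
(0 within a class, sqrt(2) across classes), which avoids imposing an
arbitrary ordering on the classes.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist


@dataclass(frozen=True)
class SplitResult:
    """Sample-level membership plus its propagation to spectra."""

    calibration_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]

    def membership(self) -> dict[str, str]:
        m = {sid: "cal" for sid in self.calibration_ids}
        m.update({sid: "val" for sid in self.validation_ids})
        return m


def _combined_distance(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    dx = squareform(pdist(X, metric="euclidean"))
    classes, codes = np.unique(labels, return_inverse=True)
    onehot = np.eye(len(classes))[codes]
    dy = squareform(pdist(onehot, metric="euclidean"))
    if dx.max() == 0:
        raise ValueError("all feature vectors identical: SPXY distance degenerate")
    d = dx / dx.max()
    if dy.max() > 0:
        d = d + dy / dy.max()
    return d


def spxy_select(distance: np.ndarray, n_calibration: int) -> list[int]:
    """Kennard-Stone greedy selection on a precomputed distance matrix.

    Seeds with the pair at maximal distance, then repeatedly adds the
    sample whose minimum distance to the selected set is largest.  All
    ties break towards the lowest sample index.
    """
    n = distance.shape[0]
    if not 2 <= n_calibration < n:
        raise ValueError(f"n_calibration must be in [2, {n}), got {n_calibration}")
    # argmax of the upper triangle, row-major => lowest-index tie-break
    iu = np.triu_indices(n, k=1)
    k = int(np.argmax(distance[iu]))
    selected = [int(iu[0][k]), int(iu[1][k])]
    remaining = [i for i in range(n) if i not in selected]
    mindist = distance[remaining][:, selected].min(axis=1)
    while len(selected) < n_calibration:
        j = int(np.argmax(mindist))
        selected.append(remaining[j])
        remaining.pop(j)
        mindist = np.delete(mindist, j)
        if remaining:
            mindist = np.minimum(mindist, distance[remaining, selected[-1]])
    return selected


def spxy_split(features: np.ndarray, labels, sample_ids,
               n_calibration: int) -> SplitResult:
    """Split samples into calibration/validation by joint x-y distances.

    Parameters
    ----------
    features
        One feature vector per sample (typically the mean spectrum over the
        four directions), shape (N, C).
    labels
        One class label per sample.
    sample_ids
        Identifiers, aligned with ``features`` rows.
    n_calibration
        Number of calibration samples; must lie in [2, N).
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    sample_ids = np.asarray(sample_ids)
    if not (len(X) == len(labels) == len(sample_ids)):
        raise ValueError("features, labels and sample_ids must be aligned")
    d = _combined_distance(X, labels)
    sel = spxy_select(d, n_calibration)
    mask = np.zeros(len(X), dtype=bool)
    mask[sel] = True
    cal = tuple(sample_ids[mask])
    val = tuple(sample_ids[~mask])
    present = set(np.unique(labels))
    covered = set(np.unique(labels[mask]))
    if n_calibration >= len(present) and covered != present:
        warnings.warn("calibration set is missing classes "
                      f"{sorted(present - covered)}", stacklevel=2)
    return SplitResult(calibration_ids=cal, validation_ids=val)


def propagate(split: SplitResult, table: pd.DataFrame) -> pd.Series:
    """Assign every spectrum row its sample's membership ("cal"/"val").

    All spectra of one sample stay on the same side of the split, so no
    sample leaks information across the calibration/validation boundary.
    """
    m = split.membership()
    orphans = set(table["sample_id"]) - set(m)
    if orphans:
        raise ValueError(f"spectra reference samples absent from the split: "
                         f"{sorted(orphans)[:5]}")
    return table["sample_id"].map(m)
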