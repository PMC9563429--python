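"""Reading and writing the spectra CSV dialect and model archives.

The spectra dialect is one row per acquired point spectrum: the header is
``sample_id,class,adulterant,proportion,direction,point`` followed by one
column per wavelength in nm; UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ["sample_id", "class", "adulterant", "proportion",
                "direction", "point"]
_FLOAT_FORMAT = "%.10g"


def write_spectra_csv(df: pd.DataFrame, path) -> None:
    """Persist a point-spectrum table; byte-identical for identical tables."""
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


def read_spectra_csv(path) -> pd.DataFrame:
    """Load and validate a point-spectrum table.

    Rejects malformed headers, non-numeric reflectance values and duplicate
    (sample, direction, point) rows, naming the offending row.
    """
    df = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=False,
                     na_values=[])
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectra CSV is missing columns: {missing}")
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not wl_cols:
        raise ValueError("spectra CSV has no wavelength columns")
    try:
        [float(c) for c in wl_cols]
    except ValueError as e:
        raise ValueError(f"non-numeric wavelength column in header: {e}") from e
    for col in wl_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].astype(str).ne("")
        if bad.any() or coerced.isna().any():
            row = int(np.argmax(coerced.isna().to_numpy()))
            raise ValueError(f"non-numeric reflectance at row {row + 2}, "
                             f"column {col}")
        df[col] = coerced
    df["proportion"] = pd.to_numeric(df["proportion"])
    df["direction"] = pd.to_numeric(df["direction"], downcast="integer")
    df["point"] = pd.to_numeric(df["point"], downcast="integer")
    dup = df.duplicated(subset=["sample_id", "direction", "point"])
    if dup.any():
        row = int(np.argmax(dup.to_numpy()))
        raise ValueError(f"duplicate (sample, direction, point) at row {row + 2}")
    return df


def save_matrices(matrices: np.ndarray, meta: pd.DataFrame, prefix) -> None:
    """Store a matrix stack as .npy with a JSON provenance sidecar."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), matrices)
    prefix.with_suffix(".json").write_text(
        json.dumps({"n": len(matrices), "side": int(matrices.shape[1]),
                    "rows": meta.to_dict(orient="records")}, indent=1))


def load_matrices(prefix) -> tuple[np.ndarray, pd.DataFrame]:
    prefix = Path(prefix)
    matrices = np.load(prefix.with_suffix(".npy"))
    side = json.loads(prefix.with_suffix(".json").read_text())
    return matrices, pd.DataFrame(side["rows"])


def save_model_archive(cnn, path, extra: dict | None = None) -> None:
    """Single-archive persistence: CNN weights plus its spec as JSON."""
    from dataclasses import asdict

    path = Path(path)
    weights = cnn.get_weights()
    spec = asdict(cnn.spec)
    payload = {f"w{i}": w for i, w in enumerate(weights)}
    np.savez(path, __spec__=json.dumps({"spec": spec, "extra": extra or {}}),
             **payload)


def load_model_archive(path):
    from .nn import CNN, CNNSpec

    with np.load(Path(path), allow_pickle=False) as z:
        info = json.loads(str(z["__spec__"]))
        spec = CNNSpec(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in info["spec"].items()})
        cnn = CNN(spec)
        cnn.set_weights([z[f"w{i}"] for i in range(len(cnn.get_weights()))])
    return cnn, info["extra"]
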