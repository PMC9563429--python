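"""Synthetic online-NIRS reflectance datasets for minced-meat authentication.

Real acquisitions of this kind place minced-meat patties on a conveyor and
record point reflectance spectra at four positions along the run direction,
repeating the scan for four sample orientations 45 degrees apart.  The
experimental design emulated here covers five categories -- pure mutton,
pure pork, pure duck, and mutton adulterated with pork or duck at mass
fractions 10-50 % (w/w) in 10 % steps -- with a configurable number of
replicate samples per configuration.

The generator builds parametric species endmembers (a smooth reflectance
baseline depressed beyond ~1700 nm, minus Gaussian absorption bands near
1260, 1520, 1650 and 1840 nm attributed to fat and protein overtones),
mixes them convexly in reflectance, adds per-sample biological variability
as a perturbation of band depths, and corrupts each acquired point spectrum
with multiplicative scatter and additive channel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

SPECIES = ("mutton", "pork", "duck")
BAND_CENTERS_NM = (1260.0, 1520.0, 1650.0, 1840.0)

#: Class labels in canonical order (index = integer class code).
CLASS_LABELS = ("mutton", "pork", "duck", "mutton+pork", "mutton+duck")

# Baseline levels chosen so pork reflects most (leaner meats absorb more);
# the logistic drop models the broad combination-band absorption > 1700 nm.
# Species differ in drop depth and steepness so that composition changes
# survive per-spectrum min-max normalisation as shape changes.
_BASE_LEVEL = {"mutton": 0.52, "pork": 0.64, "duck": 0.45}
_DROP_DEPTH = {"mutton": 0.22, "pork": 0.27, "duck": 0.15}
_DROP_CENTER_NM = 1700.0
_DROP_SCALE_NM = {"mutton": 120.0, "pork": 100.0, "duck": 140.0}

# Band depths per species: fat bands (1260/1650/1840) deepest in pork,
# the 1520 nm protein band deepest in duck.  Widths in nm.
_BAND_DEPTHS = {
    "mutton": (0.060, 0.080, 0.070, 0.060),
    "pork": (0.110, 0.045, 0.120, 0.100),
    "duck": (0.035, 0.130, 0.035, 0.045),
}
_BAND_WIDTHS_NM = (30.0, 28.0, 25.0, 30.0)


def default_wavelengths(n_channels: int = 230, lo: float = 1038.0,
                        hi: float = 2475.0) -> np.ndarray:
    """Evenly spaced wavelength grid over the modelling range, in nm."""
    return np.linspace(lo, hi, n_channels)


@dataclass(frozen=True)
class EndmemberSet:
    """Parametric pure-species reflectance curves on a common grid.

    ``reflectance[species]`` holds the nominal curve; the band parameters
    are retained so per-sample variants can be rebuilt with perturbed
    depths.
    """

    wavelengths: np.ndarray
    reflectance: dict[str, np.ndarray]
    band_centers: tuple[float, ...]
    band_widths: tuple[float, ...]
    band_depths: dict[str, tuple[float, ...]]

    def curve(self, species: str, depth_scale: np.ndarray | None = None) -> np.ndarray:
        """Rebuild a species curve, optionally scaling each band depth."""
        depths = np.asarray(self.band_depths[species], dtype=float)
        if depth_scale is not None:
            depths = depths * np.asarray(depth_scale, dtype=float)
        return _endmember_curve(self.wavelengths, species, depths,
                                self.band_centers, self.band_widths)


def _endmember_curve(wl, species, depths, centers, widths):
    base = _BASE_LEVEL[species] - _DROP_DEPTH[species] / (
        1.0 + np.exp(-(wl - _DROP_CENTER_NM) / _DROP_SCALE_NM[species]))
    bands = np.zeros_like(wl)
    for c, w, d in zip(centers, widths, depths):
        bands += d * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return np.clip(base - bands, 1e-3, 1.0 - 1e-3)


def make_endmembers(seed: int | None = None,
                    wavelengths: np.ndarray | None = None) -> EndmemberSet:
    """Construct the three species endmembers on ``wavelengths``.

    Parameters
    ----------
    seed
        Accepted for interface uniformity; the nominal endmember shapes are
        deterministic design constants, so the seed does not alter them.
    wavelengths
        Strictly increasing grid in nm covering 1038-2475 nm.  Defaults to
        the 230-channel modelling grid.
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    if wl.ndim != 1 or wl.size < 8 or not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be 1-D and strictly increasing")
    if wl[0] > 1038.0 or wl[-1] < 2475.0:
        raise ValueError("wavelength grid must cover 1038-2475 nm")
    refl = {
        sp: _endmember_curve(wl, sp, np.asarray(_BAND_DEPTHS[sp]),
                             BAND_CENTERS_NM, _BAND_WIDTHS_NM)
        for sp in SPECIES
    }
    return EndmemberSet(wavelengths=wl, reflectance=refl,
                        band_centers=BAND_CENTERS_NM,
                        band_widths=_BAND_WIDTHS_NM,
                        band_depths={sp: _BAND_DEPTHS[sp] for sp in SPECIES})


@dataclass(frozen=True)
class DatasetDesign:
    """Experimental layout: which classes, proportions and replicate counts."""

    pure_classes: tuple[str, ...] = SPECIES
    adulterants: tuple[str, ...] = ("pork", "duck")
    proportions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    replicates_per_config: int = 35
    directions: int = 4
    points_per_direction: int = 4

    def __post_init__(self):
        if not all(0.0 < p < 1.0 for p in self.proportions):
            raise ValueError("adulteration proportions must lie strictly in (0, 1)")
        if self.replicates_per_config < 1:
            raise ValueError("replicates_per_config must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.replicates_per_config * (
            len(self.pure_classes) + len(self.adulterants) * len(self.proportions))


@dataclass(frozen=True)
class NoiseParams:
    """Acquisition and biological variability magnitudes (reflectance units)."""

    scatter_slope_sd: float = 0.02
    scatter_offset_sd: float = 0.005
    additive_sd: float = 0.005
    between_sample_sd: float = 0.05

    def __post_init__(self):
        for name in ("scatter_slope_sd", "scatter_offset_sd",
                     "additive_sd", "between_sample_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Noise presets.  "low" keeps classes cleanly separable for smoke tests;
#: "paper-like" is calibrated so the pipeline is challenged but still
#: reaches high accuracy, mimicking a well-controlled instrument.
NOISE_PRESETS = {
    "low": NoiseParams(0.005, 0.002, 0.001, 0.005),
    "paper-like": NoiseParams(0.02, 0.005, 0.005, 0.05),
    "none": NoiseParams(0.0, 0.0, 0.0, 0.0),
}


def mix_spectra(endmembers: EndmemberSet, base_species: str,
                adulterant_species: str, proportion: float,
                domain: str = "reflectance") -> np.ndarray:
    """Convex mixture ``(1-p)*base + p*adulterant``, channelwise.

    ``domain="absorbance"`` mixes in -log10(R) instead and converts back,
    for users who prefer Beer-Lambert-style additivity.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    base = endmembers.reflectance[base_species]
    adu = endmembers.reflectance[adulterant_species]
    if domain == "reflectance":
        return (1.0 - proportion) * base + proportion * adu
    if domain == "absorbance":
        a = (1.0 - proportion) * (-np.log10(base)) + proportion * (-np.log10(adu))
        return 10.0 ** (-a)
    raise ValueError(f"unknown mixing domain {domain!r}")


def acquire_sample(true_spectrum: np.ndarray, noise: NoiseParams,
                   n_directions: int = 4, n_points: int = 4,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate one conveyor pass: point spectra for every direction/point.

    Each point spectrum is ``a*x + b + eps`` with per-point multiplicative
    scatter ``a ~ N(1, scatter_slope_sd)``, offset ``b ~ N(0,
    scatter_offset_sd)`` and channelwise noise ``eps ~ N(0, additive_sd)``,
    clipped to the physical range [0, 1].

    Returns an array of shape ``(n_directions * n_points, C)`` ordered by
    direction then point.
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(true_spectrum, dtype=float)
    n = n_directions * n_points
    a = rng.normal(1.0, noise.scatter_slope_sd, size=(n, 1))
    b = rng.normal(0.0, noise.scatter_offset_sd, size=(n, 1))
    eps = rng.normal(0.0, noise.additive_sd, size=(n, x.size))
    return np.clip(a * x[None, :] + b + eps, 0.0, 1.0)


def _sample_true_spectrum(endmembers, class_label, adulterant, proportion,
                          noise, rng, mixing_domain):
    """Nominal spectrum of one physical sample, with biological variability
    realised as a per-sample perturbation of every band depth."""
    if noise.between_sample_sd > 0:
        nb = len(endmembers.band_centers)
        scales = {sp: np.clip(rng.normal(1.0, noise.between_sample_sd, nb), 0.1, None)
                  for sp in SPECIES}
        em = replace(endmembers, reflectance={
            sp: endmembers.curve(sp, scales[sp]) for sp in SPECIES})
    else:
        em = endmembers
    if adulterant is None:
        return em.reflectance[class_label]
    return mix_spectra(em, "mutton", adulterant, proportion, domain=mixing_domain)


def generate_dataset(design: DatasetDesign | None = None,
                     endmembers: EndmemberSet | None = None,
                     noise: NoiseParams | None = None,
                     seed: int = 0,
                     mixing_domain: str = "reflectance") -> pd.DataFrame:
    """Generate the full point-spectrum table for an experimental design.

    One row per (sample, direction, point); deterministic for a fixed seed.
    Columns: ``sample_id, class, adulterant, proportion, direction, point``
    followed by one column per wavelength (nm, formatted with up to four
    significant decimals).
    """
    design = DatasetDesign() if design is None else design
    endmembers = make_endmembers() if endmembers is None else endmembers
    noise = NOISE_PRESETS["paper-like"] if noise is None else noise
    rng = np.random.default_rng(seed)
    wl = endmembers.wavelengths

    configs: list[tuple[str, str | None, float]] = []
    for sp in design.pure_classes:
        configs.append((sp, None, 0.0))
    for adu in design.adulterants:
        for p in design.proportions:
            configs.append((f"mutton+{adu}", adu, p))

    meta_rows = []
    spectra = []
    sample_idx = 0
    for class_label, adulterant, proportion in configs:
        for _ in range(design.replicates_per_config):
            sid = f"S{sample_idx:04d}"
            sample_idx += 1
            true = _sample_true_spectrum(endmembers, class_label, adulterant,
                                         proportion, noise, rng, mixing_domain)
            pts = acquire_sample(true, noise, design.directions,
                                 design.points_per_direction, rng)
            i = 0
            for d in range(1, design.directions + 1):
                for p_ in range(1, design.points_per_direction + 1):
                    meta_rows.append((sid, class_label,
                                      "" if adulterant is None else adulterant,
                                      proportion, d, p_))
                    spectra.append(pts[i])
                    i += 1

    meta = pd.DataFrame(meta_rows, columns=[
        "sample_id", "class", "adulterant", "proportion", "direction", "point"])
    spec = pd.DataFrame(np.asarray(spectra), columns=[f"{w:.4f}" for w in wl])
    return pd.concat([meta, spec], axis=1)


def wavelengths_from_columns(df: pd.DataFrame) -> np.ndarray:
    """Recover the wavelength grid from a point-spectrum table's columns."""
    meta = {"sample_id", "class", "adulterant", "proportion", "direction", "point"}
    return np.array([float(c) for c in df.columns if c not in meta])
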