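"""Disulfide-protection quantification from heavy/light labeled envelopes.

The labeling workflow: free cysteines are first carbamidomethylated with the
heavy reagent (iodoacetamide-13C2,2-D2), disulfides are then reduced, and
the newly freed cysteines are labeled with the light reagent.  A cysteine
that ends up light was therefore protected by a disulfide bond; the
disulfide-protected fraction f is the light-labeled mole fraction.

The by-eye "linear combination of control distributions" is formalized here
as non-negative least squares (NNLS) on the union of the light and heavy
isotope-envelope m/z grids: each control is normalized to unit total
intensity, the observed matched-intensity vector is fit as
w_L * light + w_H * heavy, and f = w_L / (w_L + w_H).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import (
    EmptyInputError,
    NoSignalError,
    ShapeError,
    SiteAmbiguityError,
)
from .peptides import IsotopeEnvelope, Peptide, elemental_composition, isotope_distribution

__all__ = [
    "PeakList",
    "ProtectionFit",
    "extract_envelope",
    "fit_protection_fraction",
    "quantify_site",
    "combined_label_grid",
    "merge_peaks",
]

DEFAULT_PPM_TOLERANCE = 10.0


def merge_peaks(
    mz: np.ndarray, intensity: np.ndarray, ppm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Coalesce peaks closer than ``ppm`` into single centroids.

    Peaks separated by less than the matching tolerance are unresolvable to
    the matcher (and to a centroider), so they are summed, with the merged
    position at the intensity-weighted mean m/z (plain mean for zero-sum
    groups).  Input must be sorted by m/z; merging is greedy left-to-right.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    out_mz: list[float] = []
    out_int: list[float] = []
    i = 0
    while i < mz.size:
        j = i + 1
        while j < mz.size and (mz[j] - mz[j - 1]) / mz[j - 1] * 1e6 < ppm:
            j += 1
        group_int = intensity[i:j]
        total = group_int.sum()
        if total > 0:
            out_mz.append(float(np.average(mz[i:j], weights=group_int)))
        else:
            out_mz.append(float(mz[i:j].mean()))
        out_int.append(float(total))
        i = j
    return np.asarray(out_mz), np.asarray(out_int)


@dataclass(frozen=True)
class PeakList:
    """Centroided peaks: strictly increasing m/z, non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or mz.shape != intensity.shape:
            raise ShapeError("mz and intensity must be equal-length 1-D arrays")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ShapeError("m/z values must be strictly increasing")
        if np.any(intensity < 0):
            raise ShapeError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return self.mz.size

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "PeakList":
        """Read a two-column ``mz,intensity`` CSV (header required)."""
        frame = pd.read_csv(path)
        if not {"mz", "intensity"} <= set(frame.columns):
            raise ShapeError(f"{path}: CSV must have 'mz' and 'intensity' columns")
        frame = frame.sort_values("mz")
        return cls(frame["mz"].to_numpy(), frame["intensity"].to_numpy(), label)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"mz": self.mz, "intensity": self.intensity}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class ProtectionFit:
    """Result of the two-component label fit.

    ``fraction_protected`` is w_L / (w_L + w_H); ``residual_norm`` is the
    fraction of observed intensity the fit leaves unexplained (L1 residual
    over total observed intensity).
    """

    fraction_protected: float
    light_weight: float
    heavy_weight: float
    residual_norm: float
    grid_mz: np.ndarray = field(default_factory=lambda: np.array([]))
    observed: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_json(self, path: str | Path, **metadata) -> None:
        payload = {
            "fraction_protected": self.fraction_protected,
            "light_weight": self.light_weight,
            "heavy_weight": self.heavy_weight,
            "residual_norm": self.residual_norm,
            "grid_mz": np.asarray(self.grid_mz).tolist(),
            "observed": np.asarray(self.observed).tolist(),
            **metadata,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)


def extract_envelope(
    peaks: PeakList,
    expected_mz: np.ndarray | IsotopeEnvelope,
    ppm_tolerance: float = DEFAULT_PPM_TOLERANCE,
) -> np.ndarray:
    """Matched intensity per expected peak position.

    Each expected position receives the intensity of the closest observed
    peak within ``ppm_tolerance`` (0 when none is in range).  Matching is
    globally greedy by ppm distance and each observed peak is assigned at
    most once, so two expected positions never share a centroid.
    """
    if ppm_tolerance <= 0:
        raise ValueError("ppm_tolerance must be positive")
    if len(peaks) == 0:
        raise EmptyInputError(f"peak list {peaks.label!r} is empty")
    if isinstance(expected_mz, IsotopeEnvelope):
        expected_mz = expected_mz.mz
    expected_mz = np.asarray(expected_mz, dtype=float)
    ppm = np.abs(peaks.mz[None, :] - expected_mz[:, None]) / expected_mz[:, None] * 1e6
    pairs = np.argwhere(ppm <= ppm_tolerance)
    order = np.argsort(ppm[pairs[:, 0], pairs[:, 1]], kind="stable")
    matched = np.zeros(expected_mz.size)
    used_expected = np.zeros(expected_mz.size, dtype=bool)
    used_observed = np.zeros(len(peaks), dtype=bool)
    for i, j in pairs[order]:
        if used_expected[i] or used_observed[j]:
            continue
        matched[i] = peaks.intensity[j]
        used_expected[i] = used_observed[j] = True
    return matched


def fit_protection_fraction(
    observed: np.ndarray,
    light_control: np.ndarray,
    heavy_control: np.ndarray,
) -> ProtectionFit:
    """NNLS fit of an observed intensity vector to the two label controls.

    All three vectors must live on the identical m/z grid.  Controls are
    normalized to unit total intensity first, so the fitted weights are a
    molar-fraction proxy and ``fraction_protected`` is scale-invariant.
    """
    observed = np.asarray(observed, dtype=float)
    light = np.asarray(light_control, dtype=float)
    heavy = np.asarray(heavy_control, dtype=float)
    if not observed.shape == light.shape == heavy.shape or observed.ndim != 1:
        raise ShapeError("observed and control vectors must share one m/z grid")
    if light.sum() <= 0 or heavy.sum() <= 0:
        raise NoSignalError("each control must carry nonzero total intensity")
    light = light / light.sum()
    heavy = heavy / heavy.sum()
    design = np.column_stack([light, heavy])
    weights, _ = nnls(design, observed)
    w_light, w_heavy = float(weights[0]), float(weights[1])
    if w_light + w_heavy == 0:
        raise NoSignalError("observed vector has no component along either control")
    residual = observed - design @ weights
    total = observed.sum()
    residual_norm = float(np.abs(residual).sum() / total) if total > 0 else 0.0
    return ProtectionFit(
        fraction_protected=w_light / (w_light + w_heavy),
        light_weight=w_light,
        heavy_weight=w_heavy,
        residual_norm=residual_norm,
        observed=observed,
    )


def combined_label_grid(
    peptide: Peptide,
    charge: int,
    max_peaks: int = 6,
    merge_ppm: float = DEFAULT_PPM_TOLERANCE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Union m/z grid of the light- and heavy-labeled envelopes of a peptide.

    Returns ``(grid_mz, light_template, heavy_template)`` where the
    templates hold each envelope's relative intensities zero-filled onto the
    sorted union grid.  Grid positions closer than ``merge_ppm`` — the light
    (k+4)-th isotopologue sits ~5-6 ppm from the heavy k-th at the charges
    used here — collapse into one slot whose templates are the sums, since
    such peaks are one centroid to the matcher; the linear fit then handles
    the overlap exactly.  The peptide must expose exactly one free cysteine.
    """
    sites = peptide.free_cysteines()
    if len(sites) != 1:
        raise SiteAmbiguityError(
            f"peptide {peptide.sequence} has {len(sites)} targetable cysteines; "
            "need exactly 1"
        )
    site = sites[0]
    light_env = isotope_distribution(
        elemental_composition(peptide.with_modification("cam", site)),
        charge,
        max_peaks,
    )
    heavy_env = isotope_distribution(
        elemental_composition(peptide.with_modification("heavy-cam", site)),
        charge,
        max_peaks,
    )
    union = np.unique(np.concatenate([light_env.mz, heavy_env.mz]))
    light_full = np.zeros(union.size)
    heavy_full = np.zeros(union.size)
    light_full[np.searchsorted(union, light_env.mz)] = light_env.relative_intensity
    heavy_full[np.searchsorted(union, heavy_env.mz)] = heavy_env.relative_intensity
    grid_mz: list[float] = []
    light_template: list[float] = []
    heavy_template: list[float] = []
    i = 0
    while i < union.size:
        j = i + 1
        while j < union.size and (union[j] - union[j - 1]) / union[j - 1] * 1e6 < merge_ppm:
            j += 1
        weights = light_full[i:j] + heavy_full[i:j]
        grid_mz.append(float(np.average(union[i:j], weights=weights)))
        light_template.append(float(light_full[i:j].sum()))
        heavy_template.append(float(heavy_full[i:j].sum()))
        i = j
    return np.asarray(grid_mz), np.asarray(light_template), np.asarray(heavy_template)


def quantify_site(
    observed: PeakList,
    light_control: PeakList,
    heavy_control: PeakList,
    peptide: Peptide,
    charge: int,
    ppm_tolerance: float = DEFAULT_PPM_TOLERANCE,
    max_peaks: int = 6,
) -> ProtectionFit:
    """End-to-end disulfide-protection fraction for one cysteine site.

    Predicts the light and heavy carbamidomethylated envelopes of the
    peptide at the given charge, extracts all three samples onto the union
    grid within ``ppm_tolerance``, and fits the observed vector to the
    extracted controls by NNLS.
    """
    grid, _, _ = combined_label_grid(peptide, charge, max_peaks, merge_ppm=ppm_tolerance)
    observed_vec = extract_envelope(observed, grid, ppm_tolerance)
    light_vec = extract_envelope(light_control, grid, ppm_tolerance)
    heavy_vec = extract_envelope(heavy_control, grid, ppm_tolerance)
    fit = fit_protection_fraction(observed_vec, light_vec, heavy_vec)
    return ProtectionFit(
        fraction_protected=fit.fraction_protected,
        light_weight=fit.light_weight,
        heavy_weight=fit.heavy_weight,
        residual_norm=fit.residual_norm,
        grid_mz=grid,
        observed=observed_vec,
    )
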