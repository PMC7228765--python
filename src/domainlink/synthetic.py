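"""Synthetic trajectories and labeled-peptide peak lists with known truth.

Real inputs for this pipeline are molecular-dynamics trajectories and
centroided LC-MS spectra, neither of which ships with the package.  The
generators here emulate the two experiments at the level the analyses see:

* multi-domain rigid-body motion — each domain is a rigid point cloud that
  translates by u_k(t) = lambda_k * s(t) + eta_k(t), with s a shared latent
  3-vector process and eta_k independent per-domain noise.  The loading
  lambda_k dials the inter-domain coupling that the distance correlation
  coefficient is meant to detect; a "locked" domain pair (emulating an
  engineered disulfide bridge) shares one fully common displacement.

* heavy/light carbamidomethylated isotope envelopes mixed at a known
  disulfide-protected fraction f, with ppm-scale m/z jitter, multiplicative
  intensity noise, and decoy peaks.

Every generator is deterministic for a given seed (seeds are mandatory),
and each returns a ground-truth record sufficient to recompute the analysis
quantity independently, so the generator doubles as the oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ConfigError
from .peptides import (
    IsotopeEnvelope,
    Peptide,
    elemental_composition,
    isotope_distribution,
)
from .quant import PeakList, merge_peaks
from .trajectory_io import DomainDefinition, Trajectory

__all__ = [
    "TrajectoryConfig",
    "SpectrumConfig",
    "make_geometry",
    "simulate_trajectory",
    "locked_pair_config",
    "simulate_peak_list",
    "domain_definitions_for",
]

#: Minimum centroid spacing between generated domains, angstrom.
DOMAIN_SPACING = 50.0


@dataclass(frozen=True)
class TrajectoryConfig:
    """Parameters of the multi-domain rigid-body trajectory generator.

    ``latent_loadings`` are the per-domain couplings lambda_k in [0, 1] to
    the shared latent displacement; ``independent_noise_sd`` (angstrom) is
    the per-step scale of each domain's private displacement process.  The
    latent and noise processes are mean-reverting by default (stationary,
    like an equilibrated production run); ``random-walk`` mimics a drifting
    trajectory.  ``locked_pairs`` lists domain index pairs that share one
    fully common displacement, as a disulfide bridge would enforce.
    """

    n_domains: int = 4
    atoms_per_domain: int = 25
    n_frames: int = 1000
    latent_loadings: tuple[float, ...] = (0.9, 0.7, 0.5, 0.3)
    independent_noise_sd: float = 0.5
    latent_type: Literal["mean-reverting", "random-walk"] = "mean-reverting"
    latent_step_sd: float = 1.0
    reversion_rate: float = 0.1
    per_atom_jitter_sd: float = 0.0
    global_rigid_motion: bool = False
    locked_pairs: tuple[tuple[int, int], ...] = ()
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory for the trajectory generator")
        if self.n_domains < 1 or self.atoms_per_domain < 1 or self.n_frames < 1:
            raise ConfigError("n_domains, atoms_per_domain, n_frames must be >= 1")
        if len(self.latent_loadings) != self.n_domains:
            raise ConfigError(
                f"need {self.n_domains} latent loadings, got {len(self.latent_loadings)}"
            )
        if any(not 0.0 <= lam <= 1.0 for lam in self.latent_loadings):
            raise ConfigError("latent loadings must lie in [0, 1]")
        if min(self.independent_noise_sd, self.latent_step_sd, self.per_atom_jitter_sd) < 0:
            raise ConfigError("standard deviations must be >= 0")
        if not 0.0 <= self.reversion_rate < 1.0:
            raise ConfigError("reversion_rate must be in [0, 1)")
        if self.latent_type not in ("mean-reverting", "random-walk"):
            raise ConfigError(f"unknown latent_type {self.latent_type!r}")
        for i, j in self.locked_pairs:
            if i == j:
                raise ConfigError(f"locked pair ({i}, {j}) repeats one domain")
            if not (0 <= i < self.n_domains and 0 <= j < self.n_domains):
                raise ConfigError(f"locked pair ({i}, {j}) out of range")


@dataclass(frozen=True)
class SpectrumConfig:
    """Parameters of the labeled-peptide peak-list generator."""

    peptide: Peptide
    true_fraction_protected: float
    charge: int = 2
    ppm_jitter_sd: float = 3.0
    intensity_noise_cv: float = 0.02
    baseline_peaks: int = 5
    max_peaks: int = 6
    total_intensity: float = 1e6
    #: Peaks closer than this are one centroid to the instrument and are
    #: summed before noise (light k+4 and heavy k isotopologues overlap so).
    centroid_merge_ppm: float = 10.0
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory for the spectrum generator")
        if not 0.0 <= self.true_fraction_protected <= 1.0:
            raise ConfigError("true_fraction_protected must lie in [0, 1]")
        if self.charge < 1:
            raise ConfigError("charge must be >= 1")
        if self.ppm_jitter_sd < 0 or self.intensity_noise_cv < 0:
            raise ConfigError("noise scales must be >= 0")
        if self.baseline_peaks < 0 or self.max_peaks < 1:
            raise ConfigError("baseline_peaks >= 0 and max_peaks >= 1 required")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators so optional stages don't shift others."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_geometry(cfg: TrajectoryConfig) -> Trajectory:
    """One-frame reference geometry: disjoint per-domain C-alpha clouds.

    Domain k occupies residues ``k*m+1 .. (k+1)*m`` (one CA per residue)
    centered at x = k * 50 A, with cloud jitter clipped so neighbouring
    domains stay >= 20 A apart.  Deterministic for a seed.
    """
    geom_rng = _streams(cfg.seed, 5)[0]
    m = cfg.atoms_per_domain
    coords = np.empty((cfg.n_domains * m, 3))
    for k in range(cfg.n_domains):
        center = np.array([k * DOMAIN_SPACING, 0.0, 0.0])
        cloud = np.clip(geom_rng.normal(scale=3.0, size=(m, 3)), -12.0, 12.0)
        coords[k * m : (k + 1) * m] = center + cloud
    atoms = pd.DataFrame(
        {
            "residue_number": np.arange(1, cfg.n_domains * m + 1),
            "residue_name": "ALA",
            "atom_name": "CA",
            "chain_id": "A",
        }
    )
    return Trajectory(coords[None, :, :], atoms)


def domain_definitions_for(cfg: TrajectoryConfig) -> list[DomainDefinition]:
    """Domain definitions matching the generator's residue numbering."""
    m = cfg.atoms_per_domain
    return [
        DomainDefinition(f"D{k + 1}", ((k * m + 1, (k + 1) * m),))
        for k in range(cfg.n_domains)
    ]


def _process(
    rng: np.random.Generator, cfg: TrajectoryConfig, step_sd: float
) -> np.ndarray:
    """A 3-vector latent process: mean-reverting (stationary) or random walk."""
    steps = rng.normal(scale=step_sd, size=(cfg.n_frames, 3))
    out = np.empty_like(steps)
    current = np.zeros(3)
    theta = cfg.reversion_rate if cfg.latent_type == "mean-reverting" else 0.0
    for t in range(cfg.n_frames):
        current = (1.0 - theta) * current + steps[t]
        out[t] = current
    return out


def simulate_trajectory(cfg: TrajectoryConfig) -> tuple[Trajectory, dict]:
    """Generate a coupled multi-domain trajectory plus its ground truth.

    Frame t displaces every atom of domain k rigidly by
    ``u_k(t) = lambda_k * s(t) + eta_k(t)``; locked domain pairs instead
    share one common displacement ``s_pair(t) + eta_pair(t)``.  When
    ``global_rigid_motion`` is set, a per-frame random rotation about the
    system centroid plus translation is applied on top (removable by
    superposition); per-atom Gaussian jitter is added last.

    The ground-truth dict carries the latent series and every per-domain
    displacement series, enough to recompute any DiCC independently.
    """
    geom_rng, latent_rng, noise_rng, rigid_rng, jitter_rng = _streams(cfg.seed, 5)
    reference = make_geometry(cfg)
    base = reference.coordinates[0]
    m = cfg.atoms_per_domain
    latent = _process(latent_rng, cfg, cfg.latent_step_sd)

    displacements = np.empty((cfg.n_domains, cfg.n_frames, 3))
    for k in range(cfg.n_domains):
        eta = _process(noise_rng, cfg, cfg.independent_noise_sd)
        displacements[k] = cfg.latent_loadings[k] * latent + eta
    # a locked pair shares one fully common displacement (loading 1 on a
    # pair-specific latent, private noise shared), overriding the base motion
    for i, j in cfg.locked_pairs:
        pair_latent = _process(noise_rng, cfg, cfg.latent_step_sd)
        pair_noise = _process(noise_rng, cfg, cfg.independent_noise_sd)
        displacements[i] = displacements[j] = pair_latent + pair_noise

    coords = np.empty((cfg.n_frames, base.shape[0], 3))
    for k in range(cfg.n_domains):
        coords[:, k * m : (k + 1) * m, :] = (
            base[None, k * m : (k + 1) * m, :] + displacements[k][:, None, :]
        )
    if cfg.global_rigid_motion:
        center = base.mean(axis=0)
        rotations = Rotation.random(cfg.n_frames, random_state=rigid_rng)
        translations = rigid_rng.normal(scale=5.0, size=(cfg.n_frames, 3))
        for t in range(cfg.n_frames):
            coords[t] = rotations[t].apply(coords[t] - center) + center + translations[t]
    if cfg.per_atom_jitter_sd > 0:
        coords += jitter_rng.normal(scale=cfg.per_atom_jitter_sd, size=coords.shape)

    truth = {
        "latent": latent,
        "displacements": displacements,
        "latent_loadings": np.asarray(cfg.latent_loadings),
        "locked_pairs": list(cfg.locked_pairs),
    }
    return Trajectory(coords, reference.atoms.copy()), truth


def locked_pair_config(
    base: TrajectoryConfig, pair: tuple[int, int]
) -> TrajectoryConfig:
    """Config variant in which one domain pair is disulfide-locked.

    The paired domains share one fully common displacement series, so their
    DiCC approaches 1 while all other couplings are unchanged — emulating an
    engineered inter-domain disulfide bridge.
    """
    i, j = pair
    if i == j:
        raise ConfigError(f"locked pair ({i}, {j}) repeats one domain")
    return dataclasses.replace(base, locked_pairs=base.locked_pairs + ((i, j),))


def _noisy_peaks(
    mz: np.ndarray,
    intensity: np.ndarray,
    cfg: SpectrumConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    jitter = rng.normal(scale=cfg.ppm_jitter_sd, size=mz.shape)
    noise = rng.normal(scale=cfg.intensity_noise_cv, size=intensity.shape)
    return mz * (1.0 + jitter * 1e-6), np.clip(intensity * (1.0 + noise), 0.0, None)


def _decoys(
    expected_mz: np.ndarray,
    scale: float,
    cfg: SpectrumConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Unrelated-ion peaks, rejected within 50 ppm of any expected position."""
    lo, hi = expected_mz.min() - 3.0, expected_mz.max() + 3.0
    out_mz: list[float] = []
    while len(out_mz) < cfg.baseline_peaks:
        candidate = rng.uniform(lo, hi)
        ppm = np.abs(candidate - expected_mz) / expected_mz * 1e6
        if ppm.min() >= 50.0:
            out_mz.append(candidate)
    intensities = rng.uniform(0.02, 0.3, size=len(out_mz)) * scale
    return np.asarray(out_mz), intensities


def _assemble(mz: np.ndarray, intensity: np.ndarray, label: str) -> PeakList:
    order = np.argsort(mz)
    return PeakList(mz[order], intensity[order], label)


def simulate_peak_list(
    cfg: SpectrumConfig,
) -> tuple[PeakList, PeakList, PeakList, float]:
    """Observed mixture + light/light and heavy/heavy controls, plus true f.

    The observed spectrum mixes the light and heavy carbamidomethylated
    envelopes of the peptide as ``f * light + (1 - f) * heavy``; every peak
    (controls included) receives Gaussian m/z jitter (ppm scale) and
    multiplicative intensity noise, and decoy peaks land >= 50 ppm from any
    expected position.  Returns ``(observed, light_control, heavy_control, f)``.
    """
    sites = cfg.peptide.free_cysteines()
    if len(sites) != 1:
        raise ConfigError(
            f"peptide {cfg.peptide.sequence} must carry exactly one free cysteine"
        )
    site = sites[0]
    light_env = isotope_distribution(
        elemental_composition(cfg.peptide.with_modification("cam", site)),
        cfg.charge,
        cfg.max_peaks,
    )
    heavy_env = isotope_distribution(
        elemental_composition(cfg.peptide.with_modification("heavy-cam", site)),
        cfg.charge,
        cfg.max_peaks,
    )
    f = cfg.true_fraction_protected
    expected_mz = np.concatenate([light_env.mz, heavy_env.mz])
    rng_obs, rng_light, rng_heavy, rng_decoy = _streams(cfg.seed, 4)

    def build(weights: tuple[float, float], rng, label: str) -> PeakList:
        w_light, w_heavy = weights
        mz = expected_mz.copy()
        intensity = cfg.total_intensity * np.concatenate(
            [w_light * light_env.relative_intensity, w_heavy * heavy_env.relative_intensity]
        )
        keep = intensity > 0
        order = np.argsort(mz[keep])
        mz, intensity = merge_peaks(
            mz[keep][order], intensity[keep][order], cfg.centroid_merge_ppm
        )
        mz, intensity = _noisy_peaks(mz, intensity, cfg, rng)
        decoy_mz, decoy_int = _decoys(expected_mz, cfg.total_intensity * 0.1, cfg, rng_decoy)
        return _assemble(
            np.concatenate([mz, decoy_mz]),
            np.concatenate([intensity, decoy_int]),
            label,
        )

    observed = build((f, 1.0 - f), rng_obs, "heavy/light")
    light_control = build((1.0, 0.0), rng_light, "light/light")
    heavy_control = build((0.0, 1.0), rng_heavy, "heavy/heavy")
    return observed, light_control, heavy_control, f
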