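"""Superposition, backbone RMSD, and inter-domain distance correlation.

The distance correlation coefficient (DiCC) between two positional vector
series {A} and {B} of n frames is

    DiCC = v(A, B) / sqrt(v(A, A) * v(B, B))

where v is the biased (1/n^2) V-statistic distance covariance

    v(A, B) = (1/n^2) * sum_ij a_ij b_ij,

a_ij the double-centered inter-frame Euclidean distance matrix of A
(d_ij minus row mean minus column mean plus grand mean), and b_ij the same
for B.  DiCC approaches 1 for concerted domain motion and 0 for independent
motion.  The 1/n^2 normalization is used exactly as stated, with no
unbiased-estimator correction, and no additional square root is applied to
the ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateSeriesError,
    DegenerateSuperpositionError,
    EmptySelectionError,
    LabelError,
    ShapeError,
)
from .trajectory_io import AtomSelection, DomainDefinition, Trajectory, select_atoms

__all__ = [
    "VectorSeries",
    "RmsdSeries",
    "DiccMatrix",
    "kabsch_superpose",
    "align_trajectory",
    "rmsd_series",
    "domain_vector_series",
    "double_centered_distances",
    "distance_covariance",
    "dicc",
    "dicc_matrix",
    "replica_average",
]

#: Atom names used for alignment and DiCC (positional vectors).
ALIGN_ATOMS = frozenset({"CA"})
#: Atom names constituting the protein backbone for RMSD.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class VectorSeries:
    """An n-frame series of d-dimensional position vectors (angstrom)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ShapeError(f"values must be 2-D (frames, dims), got {values.shape}")
        if not np.isfinite(values).all():
            raise ShapeError("vector series contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class RmsdSeries:
    """Per-frame RMSD (angstrom) of selected atoms against a reference frame."""

    frame_index: np.ndarray
    rmsd: np.ndarray
    selection_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "frame_index", np.asarray(self.frame_index, int))
        object.__setattr__(self, "rmsd", np.asarray(self.rmsd, float))
        if np.any(self.rmsd < 0):
            raise ValueError("RMSD cannot be negative")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("frame\trmsd_A\n")
            for i, value in zip(self.frame_index, self.rmsd):
                handle.write(f"{i}\t{value:.4f}\n")


@dataclass(frozen=True)
class DiccMatrix:
    """Symmetric matrix of distance correlation coefficients over domains."""

    labels: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=float)
        k = len(self.labels)
        if entries.shape != (k, k):
            raise ShapeError(f"entries must be {k}x{k}, got {entries.shape}")
        if not np.allclose(entries, entries.T, atol=1e-9):
            raise ShapeError("DiCC matrix must be symmetric")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "entries", entries)

    def max_off_diagonal_pair(self) -> tuple[str, str]:
        """The most correlated domain pair; ties broken lexicographically."""
        if len(self.labels) < 2:
            raise ShapeError("need at least 2 domains for an off-diagonal pair")
        best: tuple[str, str] | None = None
        best_value = -np.inf
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                pair = tuple(sorted((self.labels[i], self.labels[j])))
                value = self.entries[i, j]
                if value > best_value or (value == best_value and pair < best):
                    best, best_value = pair, value
        return best  # type: ignore[return-value]

    def to_tsv(self, path: str | Path) -> None:
        """Domain-labelled rows/columns at fixed 3-decimal precision."""
        with open(path, "w") as handle:
            handle.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.entries):
                handle.write(label + "\t" + "\t".join(f"{v:.3f}" for v in row) + "\n")

    def to_json(self, path: str | Path, **metadata) -> None:
        payload = {
            "labels": list(self.labels),
            "entries": self.entries.tolist(),
            "max_off_diagonal_pair": list(self.max_off_diagonal_pair())
            if len(self.labels) >= 2
            else None,
            **metadata,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)


def _check_nondegenerate(points: np.ndarray, what: str) -> None:
    if points.shape[0] < 3:
        raise DegenerateSuperpositionError(
            f"{what}: need >= 3 atoms for superposition, got {points.shape[0]}"
        )
    centered = points - points.mean(axis=0)
    scale = np.abs(centered).max()
    if scale == 0:
        raise DegenerateSuperpositionError(f"{what}: all atoms coincide")
    rank = np.linalg.matrix_rank(centered, tol=1e-8 * scale)
    if rank < 2:
        raise DegenerateSuperpositionError(f"{what}: selected atoms are collinear")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: AtomSelection | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords @ rotation.T + translation`` minimizes the RMSD of the selected
    atoms; the rotation is proper (det +1).  When ``selection`` is given the
    fit uses only those atoms, but the transform applies to any coordinates.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mob = mobile[selection.indices] if selection is not None else mobile
    ref = reference[selection.indices] if selection is not None else reference
    if mob.shape != ref.shape:
        raise ShapeError(
            f"selected atom counts differ: {mob.shape[0]} vs {ref.shape[0]}"
        )
    _check_nondegenerate(mob, "mobile")
    _check_nondegenerate(ref, "reference")
    mob_center = mob.mean(axis=0)
    ref_center = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_center, mob - mob_center)
    rotation = rot.as_matrix()
    translation = ref_center - rotation @ mob_center
    # measure the residual of the applied transform directly; scipy's rssd
    # loses precision to cancellation for near-exact rigid motions
    residual = mob @ rotation.T + translation - ref
    rmsd = np.sqrt((residual**2).sum() / mob.shape[0])
    return rotation, translation, float(rmsd)


def align_trajectory(
    traj: Trajectory,
    selection: AtomSelection,
    reference_frame: int = 0,
) -> Trajectory:
    """Superpose every frame onto the reference frame's selected atoms.

    Each frame gets its own best-fit rigid transform; atom metadata is
    unchanged.  Idempotent, and preserves all intra-frame atom distances.
    """
    if not 0 <= reference_frame < traj.n_frames:
        raise ShapeError(
            f"reference frame {reference_frame} outside 0..{traj.n_frames - 1}"
        )
    reference = traj.coordinates[reference_frame]
    aligned = np.empty_like(traj.coordinates)
    for t in range(traj.n_frames):
        try:
            rotation, translation, _ = kabsch_superpose(
                traj.coordinates[t], reference, selection
            )
        except DegenerateSuperpositionError as exc:
            raise DegenerateSuperpositionError(f"frame {t}: {exc}") from exc
        aligned[t] = traj.coordinates[t] @ rotation.T + translation
    return Trajectory(aligned, traj.atoms, traj.frame_times)


def rmsd_series(
    traj: Trajectory,
    selection: AtomSelection,
    reference_frame: int = 0,
    align_first: bool = False,
) -> RmsdSeries:
    """Per-frame RMSD over selected atoms against a reference frame.

    The trajectory is assumed superposed already; pass ``align_first`` to
    superpose on the same selection before measuring.
    """
    if align_first:
        traj = align_trajectory(traj, selection, reference_frame)
    coords = traj.coordinates[:, selection.indices, :]
    diff = coords - coords[reference_frame]
    rmsd = np.sqrt((diff**2).sum(axis=(1, 2)) / coords.shape[1])
    return RmsdSeries(np.arange(traj.n_frames), rmsd, selection.label)


def domain_vector_series(
    traj: Trajectory,
    domain: DomainDefinition,
    mode: Literal["centroid", "concatenated"] = "concatenated",
) -> VectorSeries:
    """Per-frame positional vector of a domain's C-alpha atoms.

    ``concatenated`` (default) stacks all domain C-alpha coordinates into an
    n x 3m series; ``centroid`` reduces each frame to the unweighted C-alpha
    centroid (n x 3).  The trajectory should be superposed first so the
    series reflects internal motion, not global rigid drift.
    """
    selection = select_atoms(traj, domain, ALIGN_ATOMS)
    coords = traj.coordinates[:, selection.indices, :]
    if mode == "centroid":
        values = coords.mean(axis=1)
    elif mode == "concatenated":
        values = coords.reshape(traj.n_frames, -1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return VectorSeries(values, label=domain.name)


def double_centered_distances(series: VectorSeries) -> np.ndarray:
    """Double-centered inter-frame Euclidean distance matrix.

    d_ij is the distance between frames i and j of the series; the centered
    elements are d_ij - rowmean_i - colmean_j + grandmean, so every row and
    column sums to zero.
    """
    if series.n < 2:
        raise ShapeError("need at least 2 frames for a distance matrix")
    d = squareform(pdist(series.values))
    row_mean = d.mean(axis=1, keepdims=True)
    col_mean = d.mean(axis=0, keepdims=True)
    return d - row_mean - col_mean + d.mean()


def _v_from_centered(a: np.ndarray, b: np.ndarray) -> float:
    return float((a * b).mean())


def distance_covariance(a: VectorSeries, b: VectorSeries) -> float:
    """Biased V-statistic distance covariance v(A, B) = (1/n^2) sum a_ij b_ij.

    Non-negative up to round-off for any pair of series of equal length.
    """
    if a.n != b.n:
        raise ShapeError(f"frame counts differ: {a.n} vs {b.n}")
    return _v_from_centered(
        double_centered_distances(a), double_centered_distances(b)
    )


def _dicc_from_v(vab: float, vaa: float, vbb: float) -> float:
    value = vab / np.sqrt(vaa * vbb)
    if -1e-12 < value < 0:
        value = 0.0
    if 1.0 < value < 1.0 + 1e-9:
        value = 1.0
    return float(value)


def dicc(a: VectorSeries, b: VectorSeries) -> float:
    """Distance correlation coefficient between two vector series.

    1 for perfectly concerted motion, near 0 for independent motion.
    Invariant to translation, proper rotation, and uniform positive scaling
    of either series.  A constant series has zero distance variance and
    raises :class:`DegenerateSeriesError`.
    """
    if a.n != b.n:
        raise ShapeError(f"frame counts differ: {a.n} vs {b.n}")
    ca = double_centered_distances(a)
    cb = double_centered_distances(b)
    vaa = _v_from_centered(ca, ca)
    vbb = _v_from_centered(cb, cb)
    for label, v in ((a.label, vaa), (b.label, vbb)):
        if v <= 0:
            raise DegenerateSeriesError(
                f"series {label or '<unnamed>'} is constant (zero distance variance)"
            )
    return _dicc_from_v(_v_from_centered(ca, cb), vaa, vbb)


def dicc_matrix(
    traj: Trajectory,
    domains: Sequence[DomainDefinition],
    mode: Literal["centroid", "concatenated"] = "concatenated",
) -> DiccMatrix:
    """Pairwise DiCC matrix over domains of a superposed trajectory.

    The diagonal is 1 by construction (not computed).  The trajectory should
    be superposed on all-protein C-alpha atoms first so only internal domain
    motion remains.  The strongest inter-domain pair is available from
    :meth:`DiccMatrix.max_off_diagonal_pair`.
    """
    if len(domains) < 2:
        raise ShapeError("need at least 2 domains")
    names = [d.name for d in domains]
    if len(set(names)) != len(names):
        raise LabelError(f"duplicate domain names in {names}")
    centered = []
    variances = []
    for domain in domains:
        series = domain_vector_series(traj, domain, mode)
        c = double_centered_distances(series)
        v = _v_from_centered(c, c)
        if v <= 0:
            raise DegenerateSeriesError(
                f"domain {domain.name} has constant positions (zero distance variance)"
            )
        centered.append(c)
        variances.append(v)
    k = len(domains)
    entries = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            entries[i, j] = entries[j, i] = _dicc_from_v(
                _v_from_centered(centered[i], centered[j]),
                variances[i],
                variances[j],
            )
    return DiccMatrix(tuple(names), entries)


def replica_average(matrices: Sequence[DiccMatrix]) -> DiccMatrix:
    """Element-wise mean of per-replica DiCC matrices (diagonal stays 1).

    All matrices must carry the same domain labels in the same order, as for
    averaging independent simulation replicas of one model.
    """
    if not matrices:
        raise ShapeError("need at least one matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise LabelError(f"label order mismatch: {m.labels} vs {labels}")
    mean = np.mean([m.entries for m in matrices], axis=0)
    np.fill_diagonal(mean, 1.0)
    return DiccMatrix(labels, mean)
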