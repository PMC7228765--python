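"""Trajectory containers, multi-model PDB I/O, and domain atom selection.

The portable interchange format is multi-model PDB (MODEL/ENDMDL blocks,
fixed columns, 3-decimal angstrom precision), read and written through
biotite.  Residue numbering is 1-based and taken verbatim from the file so
domain ranges can be quoted in the protein's own numbering (e.g. the NPC1
N-terminal domain as residues 23-259).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.file import InvalidFileError

from .errors import (
    ConfigError,
    EmptySelectionError,
    MalformedTrajectoryError,
    NumberingOverflowError,
    PdbParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "DomainDefinition",
    "AtomSelection",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_atoms",
    "load_domain_definitions",
]

ATOM_COLUMNS = ["residue_number", "residue_name", "atom_name", "chain_id"]


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (angstrom) with per-atom metadata.

    ``atoms`` is a DataFrame with columns ``residue_number`` (1-based int),
    ``residue_name``, ``atom_name``, ``chain_id`` in file order, shared by
    every frame.  ``frame_times`` (ns) is optional; analyses depend only on
    frame order.
    """

    coordinates: np.ndarray
    atoms: pd.DataFrame
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise MalformedTrajectoryError(
                f"coordinates must be (frames, atoms, 3), got {coords.shape}"
            )
        if coords.shape[0] < 1 or coords.shape[1] < 1:
            raise MalformedTrajectoryError("need at least 1 frame and 1 atom")
        if not np.isfinite(coords).all():
            raise MalformedTrajectoryError("coordinates contain non-finite values")
        if list(self.atoms.columns) != ATOM_COLUMNS:
            raise MalformedTrajectoryError(
                f"atom table must have columns {ATOM_COLUMNS}"
            )
        if len(self.atoms) != coords.shape[1]:
            raise MalformedTrajectoryError(
                f"atom table has {len(self.atoms)} rows but frames have "
                f"{coords.shape[1]} atoms"
            )
        self.coordinates = coords

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class DomainDefinition:
    """A named set of inclusive 1-based residue intervals.

    Overlapping or touching intervals are merged on construction, so
    ``[10-19] + [15-25]`` selects the same atoms as ``[10-25]``.  If
    ``chain_id`` is unset every chain matches (the systems this pipeline
    targets are single-chain).
    """

    name: str
    ranges: tuple[tuple[int, int], ...]
    chain_id: str | None = None

    def __post_init__(self):
        if not self.name:
            raise ConfigError("domain name must be non-empty")
        if not self.ranges:
            raise ConfigError(f"domain {self.name}: needs at least one interval")
        merged: list[list[int]] = []
        for start, end in sorted((int(a), int(b)) for a, b in self.ranges):
            if start > end:
                raise ConfigError(
                    f"domain {self.name}: interval {start}-{end} has start > end"
                )
            if merged and start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        object.__setattr__(
            self, "ranges", tuple((a, b) for a, b in merged)
        )

    @classmethod
    def from_strings(
        cls, name: str, ranges: Iterable[str], chain_id: str | None = None
    ) -> "DomainDefinition":
        """Build from ``"start-end"`` strings, e.g. ``["23-259"]``."""
        parsed = []
        for text in ranges:
            start, sep, end = str(text).partition("-")
            parsed.append((int(start), int(end) if sep else int(start)))
        return cls(name, tuple(parsed), chain_id)

    def contains(self, residue_numbers: np.ndarray) -> np.ndarray:
        """Boolean mask of residue numbers falling in any interval."""
        mask = np.zeros(len(residue_numbers), dtype=bool)
        for start, end in self.ranges:
            mask |= (residue_numbers >= start) & (residue_numbers <= end)
        return mask


@dataclass(frozen=True)
class AtomSelection:
    """Sorted unique atom indices into a trajectory's atom table."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1 or idx.size == 0:
            raise EmptySelectionError("selection is empty")
        if np.any(idx < 0):
            raise ConfigError("selection indices must be non-negative")
        if np.any(np.diff(idx) <= 0):
            raise ConfigError("selection indices must be sorted and unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    One frame per MODEL block (a single un-bracketed model gives one frame);
    atom metadata is taken from the first model.  Models that disagree in
    atom count or ordering raise :class:`MalformedTrajectoryError`; an
    unparsable coordinate field raises :class:`PdbParseError` with the line
    number.  Only the first altloc of each atom is kept (warning logged);
    insertion codes are not supported.
    """
    path = Path(path)
    try:
        pdb_file = PDBFile.read(path)
        stack = pdb_file.get_structure(model=None, altloc="first")
    except InvalidFileError as exc:
        raise MalformedTrajectoryError(str(exc)) from exc
    except ValueError as exc:
        raise _coordinate_parse_error(path, exc) from exc
    if isinstance(stack, struc.AtomArray):  # pragma: no cover - biotite API guard
        stack = struc.stack([stack])
    altlocs = getattr(stack, "altloc_id", None)
    if altlocs is not None and np.any(~np.isin(altlocs, ["", " ", ".", "A"])):
        logger.warning("%s: alternate locations present; first altloc kept", path)
    atoms = pd.DataFrame(
        {
            "residue_number": stack.res_id.astype(int),
            "residue_name": stack.res_name.astype(str),
            "atom_name": stack.atom_name.astype(str),
            "chain_id": stack.chain_id.astype(str),
        }
    )
    return Trajectory(np.asarray(stack.coord, dtype=float), atoms)


def _coordinate_parse_error(path: Path, exc: Exception) -> PdbParseError:
    """Locate the first ATOM/HETATM line whose coordinate columns fail."""
    with open(path) as handle:
        for line_number, line in enumerate(handle, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        return PdbParseError(
                            f"unparsable coordinate field {line[lo:hi].strip()!r}",
                            line_number=line_number,
                        )
    return PdbParseError(str(exc))


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB readable by the reader above.

    Coordinates are written at the format's fixed 3-decimal precision, so a
    round trip preserves them to 1e-3 angstrom and atom metadata exactly.
    """
    if int(traj.atoms["residue_number"].max()) > 9999:
        raise NumberingOverflowError(
            "residue numbers > 9999 cannot be written in fixed PDB columns"
        )
    if traj.n_atoms > 99999:
        raise NumberingOverflowError("atom serial numbers > 99999 not writable")
    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord = np.asarray(traj.coordinates, dtype=np.float32)
    stack.res_id = traj.atoms["residue_number"].to_numpy()
    stack.res_name = traj.atoms["residue_name"].to_numpy(dtype="U5")
    stack.atom_name = traj.atoms["atom_name"].to_numpy(dtype="U6")
    stack.chain_id = traj.atoms["chain_id"].to_numpy(dtype="U4")
    stack.set_annotation("element", struc.infer_elements(stack))
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    # a 1-frame stack is still a trajectory: keep the MODEL/ENDMDL bracket
    if not any(line.startswith("MODEL") for line in pdb_file.lines):
        pdb_file.lines = ["MODEL        1", *pdb_file.lines, "ENDMDL"]
    pdb_file.write(Path(path))


def select_atoms(
    traj: Trajectory,
    domain: DomainDefinition,
    atom_names: Iterable[str] = ("CA",),
) -> AtomSelection:
    """Indices of atoms inside the domain's residue ranges, in file order.

    An atom matches if its residue number lies in any interval, its atom
    name is in ``atom_names``, and (when the domain fixes a chain) its chain
    matches.  Selecting nothing is always a mistake in this pipeline and
    raises :class:`EmptySelectionError`.
    """
    atom_names = set(atom_names)
    if not atom_names:
        raise ConfigError("atom_names must be non-empty")
    residues = traj.atoms["residue_number"].to_numpy()
    mask = domain.contains(residues)
    mask &= traj.atoms["atom_name"].isin(atom_names).to_numpy()
    if domain.chain_id is not None:
        mask &= (traj.atoms["chain_id"] == domain.chain_id).to_numpy()
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise EmptySelectionError(
            f"domain {domain.name} with atoms {sorted(atom_names)} selects no atoms"
        )
    return AtomSelection(indices, label=domain.name)


def load_domain_definitions(path: str | Path) -> list[DomainDefinition]:
    """Load domain definitions from a YAML mapping.

    Accepted forms per domain name: a list of ``"start-end"`` strings, or a
    mapping ``{ranges: [...], chain: "A"}``.  Names must be unique (enforced
    by the mapping itself).
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or not raw:
        raise ConfigError(f"{path}: expected a non-empty mapping of domain names")
    domains = []
    for name, value in raw.items():
        if isinstance(value, dict):
            ranges = value.get("ranges")
            chain = value.get("chain")
        else:
            ranges, chain = value, None
        if not isinstance(ranges, (list, tuple)) or not ranges:
            raise ConfigError(f"domain {name}: 'ranges' must be a non-empty list")
        domains.append(DomainDefinition.from_strings(str(name), ranges, chain))
    return domains
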