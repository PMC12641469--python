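"""Coordinate, trajectory and results I/O.

PDB files go through MDAnalysis (CRYST1 record for the box, element
columns 77-78 with an atom-name fallback, 1-based serials).  XYZ files use
the plain element/x/y/z block with the box on the comment line as
``box LX LY LZ`` — a small convention of this package, since standard XYZ
carries no cell.  Energies and results are written as CSV/JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .system import ParticleSystem

__all__ = [
    "read_coordinates",
    "write_coordinates",
    "read_xyz",
    "write_xyz",
    "write_xyz_trajectory",
    "read_pdb",
    "write_pdb",
    "write_energy_csv",
    "write_result_json",
    "load_config",
    "MissingBoxError",
    "CoordinateParseError",
]

_DEFAULT_MASSES = {"W": 18.0, "S": 16.0, "V": 10.0, "H": 1.008,
                   "C": 12.011, "N": 14.007, "O": 15.999}


class MissingBoxError(ValueError):
    """A periodic run was requested but the file defines no box."""


class CoordinateParseError(ValueError):
    """Malformed coordinate file; carries the offending line number."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _masses_for(species):
    return np.array([_DEFAULT_MASSES.get(s, 12.0) for s in species])


def write_xyz(path, system: ParticleSystem, comment: str | None = None):
    """Write a single-frame XYZ file with a ``box LX LY LZ`` comment."""
    with open(path, "w") as fh:
        _write_xyz_frame(fh, system.positions, system.species, system.box,
                         comment)


def _write_xyz_frame(fh, positions, species, box, comment=None):
    fh.write(f"{len(positions)}\n")
    line = f"box {box[0]:.6f} {box[1]:.6f} {box[2]:.6f}"
    if comment:
        line += f" {comment}"
    fh.write(line + "\n")
    for s, (x, y, z) in zip(species, positions):
        fh.write(f"{s:<3s} {x:14.8f} {y:14.8f} {z:14.8f}\n")


def write_xyz_trajectory(path, frames, species, box, comments=None):
    """Multi-frame XYZ trajectory (one block per frame)."""
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            comment = comments[k] if comments is not None else f"frame {k}"
            _write_xyz_frame(fh, frame, species, box, comment)


def read_xyz(path, solute_indices=()) -> ParticleSystem:
    """Read the first frame of an XYZ file written by this package."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise CoordinateParseError(path, 1, "empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise CoordinateParseError(path, 1, "expected an atom count")
    if len(lines) < n + 2:
        raise CoordinateParseError(path, len(lines),
                                   f"expected {n} atom lines")
    comment = lines[1].split()
    if len(comment) >= 4 and comment[0].lower() == "box":
        try:
            box = np.array([float(x) for x in comment[1:4]])
        except ValueError:
            raise CoordinateParseError(path, 2, "malformed box line")
    else:
        raise MissingBoxError(
            f"{path}: no 'box LX LY LZ' comment line; a periodic system "
            "needs box lengths"
        )
    species, positions = [], []
    for k, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise CoordinateParseError(path, k, "expected 'element x y z'")
        try:
            positions.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise CoordinateParseError(path, k, "non-numeric coordinate")
        species.append(parts[0])
    species = np.array(species, dtype=object)
    return ParticleSystem(positions=np.array(positions), species=species,
                          masses=_masses_for(species), box=box,
                          solute_indices=frozenset(solute_indices))


def write_pdb(path, system: ParticleSystem):
    """Write a PDB file with a CRYST1 box record via MDAnalysis."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(system.n_atoms, trajectory=True)
        names = [f"{s}{k + 1}" for k, s in enumerate(system.species)]
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("elements", [str(s) for s in system.species])
        u.add_TopologyAttr("resids", [1])
        u.add_TopologyAttr("resnames", ["TOY"])
        u.atoms.positions = system.positions
        u.dimensions = [*system.box, 90.0, 90.0, 90.0]
        u.atoms.write(str(path))


def read_pdb(path, solute_indices=(), require_box: bool = True
             ) -> ParticleSystem:
    """Read a PDB file via MDAnalysis.

    Elements come from columns 77-78 when present, else from the first
    letter of the atom name.  A missing/degenerate CRYST1 record raises
    :class:`MissingBoxError` when ``require_box`` (periodic use) is set.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        raise CoordinateParseError(path, 0, f"unreadable PDB: {exc}")
    dims = u.dimensions
    if dims is None or np.any(np.asarray(dims[:3]) <= 0):
        if require_box:
            raise MissingBoxError(
                f"{path}: no CRYST1 box record; a periodic run needs box "
                "lengths"
            )
        box = np.full(3, 1e6)
    else:
        box = np.asarray(dims[:3], dtype=float)
    if hasattr(u.atoms, "elements") and all(u.atoms.elements):
        species = np.array([str(e) for e in u.atoms.elements], dtype=object)
    else:
        species = np.array([str(n)[0] for n in u.atoms.names], dtype=object)
    return ParticleSystem(
        positions=u.atoms.positions.astype(float),
        species=species, masses=_masses_for(species), box=box,
        solute_indices=frozenset(solute_indices),
    )


def read_coordinates(path, fmt=None, **kw) -> ParticleSystem:
    """Read PDB or XYZ, dispatching on extension unless ``fmt`` given."""
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return read_pdb(path, **kw)
    if fmt == "xyz":
        return read_xyz(path, **kw)
    raise ValueError(f"unsupported coordinate format {fmt!r}")


def write_coordinates(path, system, fmt=None):
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return write_pdb(path, system)
    if fmt == "xyz":
        return write_xyz(path, system)
    raise ValueError(f"unsupported coordinate format {fmt!r}")


def write_energy_csv(path, lambdas, frames, energies):
    """Per-frame energy table: lambda, frame, potential energy."""
    df = pd.DataFrame({
        "lambda": lambdas, "frame": frames,
        "potential_kcal_mol": energies,
    })
    df.to_csv(path, index=False)
    return df


def write_result_json(path, payload: dict):
    """JSON summary with plain-python types."""
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        json.dump(_clean(payload), fh, indent=2)


def load_config(path) -> dict:
    """Load a YAML run-configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
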