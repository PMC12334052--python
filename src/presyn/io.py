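"""Trajectory file readers/writers (multi-frame PDB and XYZ).

PDB parsing goes through biotite; XYZ is the minimal multi-frame flavour
(count line, comment line, ``name x y z`` rows per frame).  Both feed a
:class:`~presyn.trajectory.StructureTrajectory`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .trajectory import StructureTrajectory

# Rough atomic masses (Da) and van der Waals radii (Å) for common elements.
MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}


def _element_of(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return (stripped[:1] or "C").upper()


def read_pdb(path: str | Path) -> StructureTrajectory:
    """Read a (multi-model) PDB file into a trajectory, coordinates in Å."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    names = np.asarray(stack.atom_name if hasattr(stack, "atom_name") else [])
    elements = [(_element_of(n)) for n in names]
    return StructureTrajectory(
        coords,
        atom_names=names,
        residue_index=np.asarray(stack.res_id),
        masses=np.array([MASSES.get(e, 12.011) for e in elements]),
        radii=np.array([VDW_RADII.get(e, 1.7) for e in elements]),
        unit="angstrom",
    )


def read_xyz(path: str | Path, unit: str = "angstrom") -> StructureTrajectory:
    """Read a multi-frame XYZ file."""
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    names: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError("truncated XYZ frame")
        rows = [ln.split() for ln in block]
        if not frames:
            names = [r[0] for r in rows]
        frames.append(np.array([[float(x) for x in r[1:4]] for r in rows]))
        i += 2 + n
    if not frames:
        raise ValueError("no frames found in XYZ file")
    elements = [_element_of(n) for n in names]
    return StructureTrajectory(
        np.stack(frames),
        atom_names=np.array(names, dtype=object),
        masses=np.array([MASSES.get(e, 12.011) for e in elements]),
        radii=np.array([VDW_RADII.get(e, 1.7) for e in elements]),
        unit=unit,
    )


def write_xyz(traj: StructureTrajectory, path: str | Path, comment: str = "") -> None:
    """Write a trajectory as multi-frame XYZ."""
    names = (
        traj.atom_names
        if traj.atom_names is not None
        else np.array([f"C" for _ in range(traj.n_atoms)], dtype=object)
    )
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n{comment} frame {f}\n")
            for name, (x, y, z) in zip(names, traj.coords[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")
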