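"""Summary statistics for molecular coordinate trajectories.

Implements the standard post-simulation observables — Kabsch superposition
and RMSD, per-atom RMSF, radius of gyration, Shrake–Rupley solvent-accessible
surface area, geometric hydrogen-bond counting, coordinate PCA, and the
free-energy landscape over two projection axes — as plain array operations on
a :class:`StructureTrajectory`.  They apply equally to synthetic fixtures and
to parsed multi-frame PDB/XYZ files (see :mod:`presyn.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

#: Boltzmann constant in kJ/(mol·K) (gas constant R).
KB_KJ_PER_MOL_K = 8.31446261815324e-3


@dataclass
class StructureTrajectory:
    """Frames of labelled 3D coordinates with per-atom metadata.

    coords: (n_frames, n_atoms, 3); units tagged by ``unit`` ("angstrom" or
    "nm"); ``times_ns`` optional per-frame times.
    """

    coords: np.ndarray
    atom_names: np.ndarray | None = None
    residue_index: np.ndarray | None = None
    masses: np.ndarray | None = None
    radii: np.ndarray | None = None
    unit: str = "angstrom"
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.unit not in ("angstrom", "nm"):
            raise ValueError(f"unknown unit {self.unit!r}")
        n = self.n_atoms
        if self.masses is None:
            self.masses = np.ones(n)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n,):
            raise ValueError("masses must have one entry per atom")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, indices: np.ndarray | list[int] | None) -> np.ndarray:
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        if idx.size == 0:
            raise ValueError("empty atom selection")
        return idx


def select_atoms(traj: StructureTrajectory, expression: str) -> np.ndarray:
    """Resolve a small selection expression to atom indices.

    Supported clauses, joined by ``and``: ``all``; ``name N1 N2 …`` (atom
    names); ``resid A-B`` or ``resid A B C`` (residue indices, ranges
    inclusive); ``index A-B``.  Example: ``"name CA and resid 1-25"``.
    """
    mask = np.ones(traj.n_atoms, dtype=bool)
    for clause in expression.split(" and "):
        tokens = clause.split()
        if not tokens:
            continue
        kind, args = tokens[0].lower(), tokens[1:]
        if kind == "all":
            continue
        if kind == "name":
            if traj.atom_names is None:
                raise ValueError("trajectory has no atom names")
            mask &= np.isin(np.asarray(traj.atom_names, dtype=object), args)
        elif kind in ("resid", "index"):
            values = (traj.residue_index if kind == "resid"
                      else np.arange(traj.n_atoms))
            if values is None:
                raise ValueError("trajectory has no residue indices")
            hit = np.zeros(traj.n_atoms, dtype=bool)
            for a in args:
                m = re.fullmatch(r"(\d+)-(\d+)", a)
                if m:
                    hit |= (values >= int(m.group(1))) & (values <= int(m.group(2)))
                else:
                    hit |= values == int(a)
            mask &= hit
        else:
            raise ValueError(f"unknown selection clause {clause!r}")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"selection {expression!r} matches no atoms")
    return idx


def kabsch_align(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the weighted RMSD.
    The rotation is proper (determinant +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n_atoms, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 atoms are required for superposition")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if w.shape != (n,) or w.sum() <= 0:
        raise ValueError("weights must be per-atom and sum to a positive value")
    wn = w / w.sum()

    mu_m = wn @ mobile
    mu_r = wn @ reference
    a = mobile - mu_m
    b = reference - mu_r
    if np.linalg.matrix_rank(a.T @ np.diag(wn) @ a, tol=1e-12) < 2:
        raise ValueError("degenerate (collinear) coordinates; rotation ill-defined")
    # scipy solves the weighted Wahba problem with a proper rotation.
    rot, rssd = Rotation.align_vectors(b, a, weights=w, return_sensitivity=False)[:2]
    R = rot.as_matrix()
    t = mu_r - mu_m @ R.T
    aligned = mobile @ R.T + t
    rmsd = float(np.sqrt(np.sum(wn * np.sum((aligned - reference) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_series(
    traj: StructureTrajectory,
    reference_frame: int = 0,
    selection: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference frame after optimal superposition."""
    idx = traj.select(selection)
    ref = traj.coords[reference_frame][idx]
    w = weights if weights is not None else traj.masses[idx]
    return np.array(
        [kabsch_align(traj.coords[f][idx], ref, w)[2] for f in range(traj.n_frames)]
    )


def _aligned_stack(traj: StructureTrajectory, idx: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """All frames superposed onto the (iteratively refined) mean structure."""
    frames = traj.coords[:, idx, :].copy()
    w = traj.masses[idx]
    ref = frames[0]
    for _ in range(n_iter):
        aligned = np.empty_like(frames)
        for f in range(frames.shape[0]):
            R, t, _ = kabsch_align(frames[f], ref, w)
            aligned[f] = frames[f] @ R.T + t
        new_ref = aligned.mean(axis=0)
        if np.allclose(new_ref, ref, atol=1e-12):
            frames = aligned
            break
        ref = new_ref
        frames = aligned
    return frames


def rmsf_per_atom(
    traj: StructureTrajectory, selection: np.ndarray | None = None
) -> np.ndarray:
    """Root-mean-square fluctuation of each atom about its mean position.

    Frames are first superposed on their mean structure, so rigid-body
    motion does not register as fluctuation.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least two frames")
    idx = traj.select(selection)
    frames = _aligned_stack(traj, idx)
    mean = frames.mean(axis=0)
    return np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance of atoms from their centre of mass."""
    frame = np.asarray(frame, float)
    m = np.ones(frame.shape[0]) if masses is None else np.asarray(masses, float)
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (m[:, None] * frame).sum(axis=0) / total
    return float(np.sqrt(np.sum(m * np.sum((frame - com) ** 2, axis=1)) / total))


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    frame: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom is inflated by the probe radius and covered with a
    quasi-uniform point lattice; the accessible fraction is the share of
    points not buried inside any neighbour's inflated sphere.  Returns
    ``(total_area, per_atom_area)`` in squared input units.
    """
    frame = np.asarray(frame, float)
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise ValueError("atomic radii must be positive")
    if n_sphere_points < 92:
        raise ValueError("n_sphere_points must be at least 92")
    inflated = radii + probe_radius
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(frame)
    per_atom = np.zeros(frame.shape[0])
    r_max = inflated.max()
    for i in range(frame.shape[0]):
        pts = frame[i] + inflated[i] * unit
        neighbours = [j for j in tree.query_ball_point(frame[i], inflated[i] + r_max)
                      if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            centre_dist2 = np.sum((frame[i] - frame[j]) ** 2)
            if centre_dist2 < 1e-20 and inflated[j] >= inflated[i]:
                # exactly coincident duplicates: lower index wins, the rest
                # are fully buried so the pair contributes one sphere
                if j < i or inflated[j] > inflated[i]:
                    accessible[:] = False
                    break
                continue
            d2 = np.sum((pts - frame[j]) ** 2, axis=1)
            accessible &= d2 > inflated[j] ** 2 * (1.0 - 1e-12)
        per_atom[i] = accessible.mean() * 4.0 * np.pi * inflated[i] ** 2
    return float(per_atom.sum()), per_atom


def count_hydrogen_bonds(
    frame: np.ndarray,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 30.0,
) -> int:
    """Geometric hydrogen-bond count over (donor, hydrogen, acceptor) triples.

    A triple is counted when the donor–acceptor distance is within
    ``distance_cutoff`` (Å) and the hydrogen–donor–acceptor angle is within
    ``angle_cutoff`` (degrees) — the conventional 3.5 Å / 30° criterion.
    """
    frame = np.asarray(frame, float)
    donors = np.asarray(donors, int)
    hydrogens = np.asarray(hydrogens, int)
    acceptors = np.asarray(acceptors, int)
    if donors.shape != hydrogens.shape:
        raise ValueError("donor and hydrogen lists must pair one-to-one")
    count = 0
    for d, h in zip(donors, hydrogens):
        da = frame[acceptors] - frame[d]
        dist = np.linalg.norm(da, axis=1)
        dh = frame[h] - frame[d]
        ndh = np.linalg.norm(dh)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (da @ dh) / (dist * ndh)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = (dist <= distance_cutoff) & (ang <= angle_cutoff)
        ok &= acceptors != d  # an atom cannot accept from itself
        count += int(ok.sum())
    return count


@dataclass
class PCAModes:
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    projections: np.ndarray  # (n_frames, n_modes)
    mean_structure: np.ndarray


def pca_modes(
    traj: StructureTrajectory,
    selection: np.ndarray | None = None,
    n_modes: int = 2,
) -> PCAModes:
    """Principal components of the aligned coordinate covariance.

    Frames are superposed on the mean structure, flattened to 3N vectors,
    and the covariance eigendecomposed.  ``variance_fractions`` are each
    mode's share of total positional variance; projections are centred.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA requires at least two frames")
    idx = traj.select(selection)
    frames = _aligned_stack(traj, idx)
    flat = frames.reshape(traj.n_frames, -1)
    mean = flat.mean(axis=0)
    centred = flat - mean
    cov = centred.T @ centred / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    rank = int(np.sum(evals > evals[0] * 1e-12)) if evals[0] > 0 else 0
    if n_modes > rank:
        raise ValueError(f"requested {n_modes} modes but covariance rank is {rank}")
    fractions = evals / evals.sum()
    proj = centred @ evecs[:, :n_modes]
    return PCAModes(evals, fractions, proj, mean.reshape(-1, 3))


@dataclass
class FELGrid:
    """Free-energy landscape over two projection axes.

    ``delta_g`` is −k_B·T·ln(P/P_max) in kJ/mol; unoccupied bins are
    ``inf`` (unbounded); the modal bin sits at exactly 0.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy: np.ndarray
    delta_g: np.ndarray
    temperature: float


def free_energy_landscape(
    projections: np.ndarray,
    temperature: float = 300.0,
    n_bins: int = 32,
) -> FELGrid:
    """Gibbs free-energy surface from a 2D histogram of PC projections."""
    projections = np.asarray(projections, float)
    if projections.ndim != 2 or projections.shape[1] != 2:
        raise ValueError("projections must be (n_frames, 2)")
    if projections.shape[0] < 100:
        raise ValueError("at least 100 frames are required for a meaningful surface")
    hist, xe, ye = np.histogram2d(projections[:, 0], projections[:, 1], bins=n_bins)
    total = hist.sum()
    if total == 0:
        raise ValueError("no frames fell inside the histogram range")
    p = hist / total
    with np.errstate(divide="ignore"):
        dg = -KB_KJ_PER_MOL_K * temperature * np.log(p / p.max())
    return FELGrid(xe, ye, p, dg, temperature)
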