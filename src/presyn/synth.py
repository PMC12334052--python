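"""Synthetic fixtures with analytically known ground truth.

Every input the analysis surface consumes can be generated here: two-normal
docking-score populations (closed-form AUC), jittered toy coordinate
trajectories (closed-form RMSF, constructed RMSD steps), and ready-made
simulator configurations/worlds for engine calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .config import ModelConfig, load_config
from .screen import ScoredCompoundSet
from .trajectory import StructureTrajectory


def two_normal_auc(mean_separation: float) -> float:
    """Expected AUC for actives ~ N(sep, 1) vs decoys ~ N(0, 1): Φ(sep/√2)."""
    return float(norm.cdf(mean_separation / np.sqrt(2.0)))


def gen_score_set(
    n_actives: int,
    n_decoys: int,
    mean_separation: float = 1.0,
    seed: int = 0,
) -> ScoredCompoundSet:
    """Two-population docking-score set with controllable separation.

    Actives draw from N(``mean_separation``, 1), decoys from N(0, 1), so the
    expected AUC is Φ(sep/√2) — e.g. ≈0.760 at unit separation.  The default
    study-scale imbalance (548 actives vs 14,066 decoys) is the caller's
    choice of counts.
    """
    if n_actives < 1 or n_decoys < 1:
        raise ValueError("both populations need at least one compound")
    rng = np.random.default_rng(seed)
    scores = np.concatenate(
        [rng.normal(mean_separation, 1.0, n_actives), rng.normal(0.0, 1.0, n_decoys)]
    )
    labels = np.concatenate(
        [np.ones(n_actives, dtype=int), np.zeros(n_decoys, dtype=int)]
    )
    ids = np.array(
        [f"ACT{i:06d}" for i in range(n_actives)]
        + [f"DEC{i:06d}" for i in range(n_decoys)],
        dtype=object,
    )
    return ScoredCompoundSet(ids, scores, labels)


def gen_toy_trajectory(
    n_atoms: int,
    n_frames: int,
    per_atom_sigma: float | np.ndarray = 0.1,
    displacement_event: tuple[int, np.ndarray] | None = None,
    seed: int = 0,
) -> StructureTrajectory:
    """Grid-based coordinates with per-atom isotropic Gaussian jitter.

    Base positions sit on a 3D lattice with 4-unit spacing.  Atom *i* jitters
    with per-axis σᵢ, so its expected RMSF is σᵢ·√3.  An optional
    ``(frame_index, shift_vector)`` event rigidly displaces every atom from
    that frame onward, producing a known RMSD step.
    """
    if n_frames < 2:
        raise ValueError("a trajectory needs at least two frames")
    sigma = np.broadcast_to(np.asarray(per_atom_sigma, float), (n_atoms,)).copy()
    if sigma.shape != (n_atoms,):
        raise ValueError("per_atom_sigma must broadcast to one value per atom")
    rng = np.random.default_rng(seed)

    side = int(np.ceil(n_atoms ** (1 / 3)))
    grid = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
        dtype=float,
    )[:n_atoms] * 4.0
    coords = grid[None, :, :] + rng.normal(size=(n_frames, n_atoms, 3)) * sigma[None, :, None]
    if displacement_event is not None:
        frame0, shift = displacement_event
        coords[frame0:] += np.asarray(shift, float)
    return StructureTrajectory(
        coords, times_ns=np.arange(n_frames, dtype=float), unit="angstrom"
    )


_PRESETS = ("two_species_box", "frozen", "standard")


def gen_world_fixture(preset: str, seed: int = 0):
    """Ready-made simulator configuration + built world for engine tests.

    Returns ``(config, world)``.  ``two_species_box``: a single bimolecular
    channel (Ca + channel, nothing downstream) for rate-calibration checks;
    ``frozen``: all rates and diffusivities zero; ``standard``: the
    standard parameter set.
    """
    from .spatial import build_world

    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {_PRESETS}")
    cfg = _preset_config(preset, seed)
    return cfg, build_world(cfg, seed=seed)


def _preset_config(preset: str, seed: int) -> ModelConfig:
    if preset == "standard":
        return load_config({"seed": seed})
    if preset == "frozen":
        return load_config(
            {
                "kinetics": {
                    "k1": 0.0, "k2": 0.0, "k3": 0.0, "k4": 0.0,
                    "d_ca": 0.0, "d_drug": 0.0, "d_vesicle": 0.0, "d_complex": 0.0,
                    "release_rate": 0.0,
                },
                "seed": seed,
            }
        )
    # two_species_box: only the influx reaction is live.
    return load_config(
        {
            "kinetics": {
                "k2": 0.0, "k3": 0.0, "k4": 0.0, "release_rate": 0.0,
            },
            "counts": {"n_drug": 0, "n_vesicle": 0},
            "seed": seed,
        }
    )
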