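"""Condition-grid experiments: drug count × blocking-rate sweeps.

Reproduces the study design of the source simulations — released
calcium-ion–vesicle complex counts under varying drug load and blocking
rate constant k₂ — as tidy tables with replicate means and standard
deviations.  Per-condition seeds derive from a stable hash of the base seed
and the condition parameters, so results are independent of execution
order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .wellmixed import IDX, SPECIES, build_network, run_ssa
from .spatial import build_world, run_spatial


@dataclass(frozen=True)
class Condition:
    """One cell of the sweep grid."""

    n_drug: int
    k2: float
    engine: str = "wellmixed"
    n_reps: int = 10
    seed: int | None = None  # derived from the base seed when None

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if self.engine not in ("wellmixed", "spatial"):
            raise ValueError(f"unknown engine {self.engine!r}")


def condition_seed(base_seed: int, cond: Condition) -> int:
    """Stable, order-independent seed for one condition."""
    if cond.seed is not None:
        return cond.seed
    key = f"{base_seed}|{cond.n_drug}|{cond.k2:.6e}|{cond.engine}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little")


def _run_one(config: ModelConfig, cond: Condition, rep_seed: int, t_end: float):
    cfg = config.replace(**{"counts.n_drug": cond.n_drug, "kinetics.k2": cond.k2})
    if cond.engine == "wellmixed":
        net = build_network(cfg)
        return run_ssa(net, t_end, cfg.sample_dt, seed=np.random.default_rng(rep_seed))
    world = build_world(cfg, seed=rep_seed)
    return run_spatial(world, t_end, cfg.spatial_dt, cfg.sample_dt)


def run_condition_grid(
    config: ModelConfig,
    conditions: list[Condition],
    t_queries: list[float] | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Run every condition with independent replicate seeds.

    Returns one row per condition × query time × species with replicate
    ``mean``, ``sd`` and ``n_reps`` — the long-format analogue of the
    published released-complex table.
    """
    if not conditions:
        raise ValueError("conditions must be non-empty")
    t_queries = [0.1, 0.2] if t_queries is None else list(t_queries)
    t_end = max(max(t_queries), config.t_end)

    rows = []
    for cond in conditions:
        cseed = condition_seed(base_seed, cond)
        streams = np.random.SeedSequence(cseed).spawn(cond.n_reps)
        per_rep = np.empty((cond.n_reps, len(t_queries), len(SPECIES)))
        for i, ss in enumerate(streams):
            traj = _run_one(config, cond, ss.generate_state(1)[0], t_end)
            for j, tq in enumerate(t_queries):
                per_rep[i, j] = traj.at(tq)
        for j, tq in enumerate(t_queries):
            for s_i, sp in enumerate(SPECIES):
                vals = per_rep[:, j, s_i]
                rows.append(
                    {
                        "n_drug": cond.n_drug, "k2": cond.k2,
                        "engine": cond.engine, "t_query": tq, "species": sp,
                        "mean": vals.mean(),
                        "sd": vals.std(ddof=1) if cond.n_reps > 1 else 0.0,
                        "n_reps": cond.n_reps, "seed": cseed,
                    }
                )
    return pd.DataFrame(rows)


#: The source study's eight drug-present conditions plus the no-drug control.
STUDY_GRID: list[tuple[int, float]] = [
    (0, 0.0),
    (500, 0.5e6), (500, 1.0e7), (500, 5.0e7), (500, 1.0e8),
    (1500, 0.5e6), (1500, 1.0e7), (1500, 5.0e7), (1500, 1.0e8),
]


def study_conditions(n_reps: int = 10, engine: str = "wellmixed") -> list[Condition]:
    return [Condition(n, k2, engine, n_reps) for n, k2 in STUDY_GRID]


def headline_metrics(
    config: ModelConfig | None = None,
    n_reps: int = 200,
    base_seed: int = 0,
    t_query: float = 0.2,
) -> dict[str, float]:
    """The study's headline blockade effects from replicate SSA runs.

    Runs the no-drug control plus the four corner conditions of the drug ×
    k₂ grid and summarises, at ``t_query``:

    * ``released_baseline`` / ``released_500_high_k2`` /
      ``released_1500_high_k2`` — mean released-complex counts;
    * ``released_reduction_pct`` — percent fewer complexes released with
      1,500 drug molecules at k₂ = 1e8 vs no drug;
    * ``blocked_channels`` — mean drug–channel complexes under the strongest
      blockade;
    * ``k2_sensitivity_500_pct`` / ``k2_sensitivity_1500_pct`` — percent
      change in released complexes when k₂ rises from 0.5e6 to 1e8.
    """
    from .config import load_config

    config = load_config(None) if config is None else config
    corners = [(0, 0.0), (500, 0.5e6), (500, 1.0e8), (1500, 0.5e6), (1500, 1.0e8)]
    conds = [Condition(n, k2, "wellmixed", n_reps) for n, k2 in corners]
    table = run_condition_grid(config, conds, [t_query], base_seed=base_seed)

    def released(n, k2):
        return _lookup(table, Condition(n, k2), "D_out", t_query)["mean"]

    base = released(0, 0.0)
    hi_1500 = released(1500, 1.0e8)
    lo_1500 = released(1500, 0.5e6)
    hi_500 = released(500, 1.0e8)
    lo_500 = released(500, 0.5e6)
    blocked = _lookup(table, Condition(1500, 1.0e8), "E", t_query)["mean"]
    return {
        "released_baseline": float(base),
        "released_500_high_k2": float(hi_500),
        "released_1500_high_k2": float(hi_1500),
        "released_reduction_pct": float(100.0 * (base - hi_1500) / base),
        "blocked_channels": float(blocked),
        "k2_sensitivity_500_pct": float(100.0 * abs(hi_500 - lo_500) / lo_500),
        "k2_sensitivity_1500_pct": float(100.0 * abs(hi_1500 - lo_1500) / lo_1500),
        "n_reps": float(n_reps),
    }


def _lookup(table: pd.DataFrame, cond: Condition, species: str, t: float) -> pd.Series:
    m = (
        (table["n_drug"] == cond.n_drug)
        & np.isclose(table["k2"], cond.k2)
        & (table["species"] == species)
        & np.isclose(table["t_query"], t)
    )
    hit = table[m]
    if len(hit) != 1:
        raise KeyError(f"condition {cond} / {species} @ {t}s not uniquely in table")
    return hit.iloc[0]


def relative_change(
    table: pd.DataFrame,
    cond_a: Condition,
    cond_b: Condition,
    species: str = "D_out",
    t: float = 0.2,
) -> tuple[float, float]:
    """Percent change 100·(mean_a − mean_b)/mean_a with propagated SE."""
    a = _lookup(table, cond_a, species, t)
    b = _lookup(table, cond_b, species, t)
    if a["mean"] == 0:
        raise ZeroDivisionError("reference condition mean is zero")
    pct = 100.0 * (a["mean"] - b["mean"]) / a["mean"]
    se_a = a["sd"] / np.sqrt(a["n_reps"])
    se_b = b["sd"] / np.sqrt(b["n_reps"])
    # first-order propagation of f = 100(1 - b/a)
    se = 100.0 * np.sqrt(
        (a["mean"] and (b["mean"] * se_a / a["mean"] ** 2) ** 2 or 0.0)
        + (se_b / a["mean"]) ** 2
    )
    return float(pct), float(se)
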