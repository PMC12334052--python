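"""Well-mixed stochastic (Gillespie SSA) and mean-field (ODE) engines.

The synapse is reduced to mass-action kinetics over nine species:

====  =========  ====================================================
idx   name       meaning
====  =========  ====================================================
0     CA_CYT     Ca²⁺ in the extracellular (extra-synaptic) region
1     CA_Pre     Ca²⁺ inside the pre-synapse
2     A_free     open, unoccupied calcium channels
3     E          drug-blocked channels (drug–channel complex)
4     M          free drug molecules
5     V          free synaptic vesicles in the pre-synapse
6     D_pre      Ca²⁺–vesicle complexes still inside the pre-synapse
7     D_out      Ca²⁺–vesicle complexes released to the extra-synaptic
                 region (the quantity tabulated in the source study)
8     C_occ      channels retired after one transport (consumed mode)
====  =========  ====================================================

Five reaction channels:

R1  CA_CYT + A_free → CA_Pre (+ C_occ, or A_free back in catalytic mode)
R2  M + A_free → E                       (irreversible blockade)
R3  CA_Pre + V → D_pre                   (complex formation)
R4  CA_Pre → CA_CYT                      (pseudo-first-order pumping)
R5  D_pre → D_out                        (release through the active face)

Binding is irreversible throughout: neither a calcium ion nor a drug
molecule unbinds from a channel once bound, so E (and C_occ) absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import ModelConfig, per_pair_rate

SPECIES = ("CA_CYT", "CA_Pre", "A_free", "E", "M", "V", "D_pre", "D_out", "C_occ")
IDX = {name: i for i, name in enumerate(SPECIES)}

#: Fig-8-style column aliases used in CSV output.
CSV_ALIASES = {"M": "Mont_World", "D_pre": "VesC_Pre", "D_out": "VesC_CYT"}


@dataclass
class Reaction:
    """One reaction channel.

    Propensity is mass action, ``rate × Π counts(reactants)``, optionally
    damped by a delivery-limitation factor ``1/(1 + gate_saturation·n_gate)``
    where the gate is the last reactant.  ``gate_saturation = c·V/G_diff``
    encodes the Collins–Kimball series resistance of diffusive transport to
    a reactive face with conductance ``G_diff`` (0 recovers pure mass
    action).
    """

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate: float  # s⁻¹ (per pair for bimolecular, per molecule for unary)
    name: str = ""
    gate_saturation: float = 0.0


@dataclass
class ReactionNetwork:
    """Species, stoichiometry and initial counts for the well-mixed engines."""

    reactions: list[Reaction]
    initial_state: np.ndarray
    species: tuple[str, ...] = SPECIES
    channel_mode: str = "catalytic"

    def __post_init__(self) -> None:
        self.initial_state = np.asarray(self.initial_state, dtype=np.int64)
        if self.initial_state.shape != (len(self.species),):
            raise ValueError("initial_state length must match species list")
        if any(r.rate < 0 or not np.isfinite(r.rate) for r in self.reactions):
            raise ValueError("reaction rates must be finite and non-negative")
        n = len(self.species)
        self.stoich = np.zeros((len(self.reactions), n), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for i in r.reactants:
                self.stoich[j, i] -= 1
            for i in r.products:
                self.stoich[j, i] += 1

    def propensities(self, state: np.ndarray) -> np.ndarray:
        a = np.empty(len(self.reactions))
        for j, r in enumerate(self.reactions):
            p = r.rate
            for i in r.reactants:
                p *= state[i]
            if r.gate_saturation:
                p /= 1.0 + r.gate_saturation * state[r.reactants[-1]]
            a[j] = p
        return a


@dataclass
class CountTrajectory:
    """Species counts sampled on a regular time grid."""

    times: np.ndarray
    counts: np.ndarray  # shape (n_times, n_species)
    species: tuple[str, ...] = SPECIES
    seed: int | None = None
    engine_tag: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.counts.shape != (len(self.times), len(self.species)):
            raise ValueError("counts shape must be (n_times, n_species)")

    def at(self, t: float) -> np.ndarray:
        """Counts at the grid point nearest to ``t`` (must be within grid)."""
        if t > self.times[-1] + 1e-12:
            raise ValueError(f"t={t} beyond trajectory end {self.times[-1]}")
        return self.counts[int(np.argmin(np.abs(self.times - t)))]

    def __getitem__(self, species: str) -> np.ndarray:
        return self.counts[:, IDX[species]]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [CSV_ALIASES.get(s, s) for s in self.species]
        df = pd.DataFrame(self.counts, columns=cols)
        df.insert(0, "time_s", self.times)
        return df


def build_network(config: ModelConfig) -> ReactionNetwork:
    """Assemble the five-reaction network from a model configuration.

    Bimolecular per-pair rates use the compartment each reaction occurs in:
    influx and blockade sample the extracellular volume, vesicle binding the
    pre-synaptic volume.  Pumping is folded into a pseudo-first-order rate
    (pump count × per-pair rate) since pumps neither saturate nor deplete.
    """
    g, k, c = config.geometry, config.kinetics, config.counts
    mode = config.channel_mode
    ca, cap, a, e, m, v, dp, do, cocc = (IDX[s] for s in SPECIES)

    if mode == "consumed":
        r1_products: tuple[int, ...] = (cap, cocc)
    else:  # catalytic: the channel survives the transport event
        r1_products = (cap, a)

    def face_saturation(rate: float, volume: float, d_cm2: float, area: float) -> float:
        """``c·V / G_diff`` for diffusive delivery to a face disk of given area."""
        if not config.transport_limited or rate == 0.0 or d_cm2 == 0.0:
            return 0.0
        disk_radius = np.sqrt(area / np.pi)  # µm
        g_diff = 4.0 * (d_cm2 * 1e8) * disk_radius  # µm³/s
        return rate * volume / g_diff

    c1 = per_pair_rate(k.k1, g.extra_volume)
    c2 = per_pair_rate(k.k2, g.extra_volume)
    c4 = per_pair_rate(k.k4, g.pre_volume)
    pump_rate = c.n_pumps * c4
    pump_sat = face_saturation(c4, g.pre_volume, k.d_ca, g.pump_face_area)
    pump_rate /= 1.0 + pump_sat * c.n_pumps  # pump count is static; fold in

    reactions = [
        Reaction((ca, a), r1_products, c1, "influx",
                 face_saturation(c1, g.extra_volume, k.d_ca, g.channel_face_area)),
        Reaction((m, a), (e,), c2, "blockade",
                 face_saturation(c2, g.extra_volume, k.d_drug, g.channel_face_area)),
        Reaction((cap, v), (dp,), per_pair_rate(k.k3, g.pre_volume), "binding"),
        Reaction((cap,), (ca,), pump_rate, "pumping"),
        Reaction((dp,), (do,), k.release_rate, "release"),
    ]
    x0 = np.zeros(len(SPECIES), dtype=np.int64)
    x0[ca], x0[m], x0[v], x0[a] = c.n_ca, c.n_drug, c.n_vesicle, c.n_channels
    return ReactionNetwork(reactions, x0, channel_mode=mode)


def run_ssa(
    network: ReactionNetwork,
    t_end: float,
    sample_dt: float = 1e-3,
    seed: int | np.random.Generator = 0,
) -> CountTrajectory:
    """Exact Gillespie direct-method trajectory sampled on a regular grid.

    The jump chain is simulated event by event; counts are recorded at
    ``0, sample_dt, 2·sample_dt, …, t_end`` (value immediately before each
    grid time).  Deterministic for a fixed integer seed.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    state = network.initial_state.copy()
    n_steps = int(round(t_end / sample_dt))
    grid = np.arange(n_steps + 1) * sample_dt
    out = np.empty((n_steps + 1, len(network.species)), dtype=np.int64)
    out[0] = state

    # Flat views for a tight event loop.
    rates = np.array([r.rate for r in network.reactions])
    reactant_sets = [r.reactants for r in network.reactions]
    gates = [(r.reactants[-1], r.gate_saturation) for r in network.reactions]
    stoich = network.stoich

    t = 0.0
    gi = 1
    a = np.empty(len(rates))
    while gi <= n_steps:
        for j, rs in enumerate(reactant_sets):
            p = rates[j]
            for i in rs:
                p *= state[i]
            gate, sat = gates[j]
            if sat:
                p /= 1.0 + sat * state[gate]
            a[j] = p
        a_total = a.sum()
        if not np.isfinite(a_total):
            raise FloatingPointError("propensity overflow/NaN in SSA")
        if a_total <= 0.0:
            out[gi:] = state  # frozen system
            break
        t += rng.exponential(1.0 / a_total)
        while gi <= n_steps and grid[gi] <= t:
            out[gi] = state
            gi += 1
        if gi > n_steps:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0, a_total), side="left"))
        state += stoich[j]

    tag = f"ssa/{network.channel_mode}"
    return CountTrajectory(grid[: n_steps + 1], out, network.species,
                           seed if isinstance(seed, int) else None, tag)


def run_ode(
    network: ReactionNetwork,
    t_end: float,
    dt: float = 1e-3,
    rtol: float = 1e-9,
    check_tol: float = 1e-6,
) -> CountTrajectory:
    """Deterministic mass-action integration of the same network.

    Serves as the large-copy-number oracle for the SSA.  The solution is
    validated by re-integrating at tightened tolerance; disagreement beyond
    ``check_tol`` (relative to total copy number) raises.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    grid = np.arange(int(round(t_end / dt)) + 1) * dt
    y0 = network.initial_state.astype(float)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return network.stoich.T @ network.propensities(y)

    def integrate(r: float) -> np.ndarray:
        sol = solve_ivp(rhs, (0, t_end), y0, t_eval=grid, method="LSODA",
                        rtol=r, atol=1e-9)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        return sol.y.T

    y = integrate(rtol)
    y_check = integrate(rtol * 1e-2)
    scale = max(float(y0.sum()), 1.0)
    if np.max(np.abs(y - y_check)) / scale > check_tol:
        raise RuntimeError("ODE solution not converged; tighten rtol or reduce dt")
    return CountTrajectory(grid, y, network.species, None, f"ode/{network.channel_mode}")


def replicate_summary(
    network: ReactionNetwork,
    t_query: float,
    n_reps: int,
    seed: int = 0,
    t_end: float | None = None,
    sample_dt: float = 1e-3,
) -> pd.DataFrame:
    """Mean ± sd per species at ``t_query`` over independent SSA replicates.

    Replicate streams derive from ``numpy.random.SeedSequence(seed).spawn``,
    so they are statistically independent and reproducible.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    t_end = t_query if t_end is None else t_end
    if t_query > t_end:
        raise ValueError("t_query beyond simulated horizon")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    samples = np.empty((n_reps, len(network.species)))
    for i, ss in enumerate(streams):
        traj = run_ssa(network, t_end, sample_dt, np.random.default_rng(ss))
        samples[i] = traj.at(t_query)
    return pd.DataFrame(
        {
            "species": network.species,
            "mean": samples.mean(axis=0),
            "sd": samples.std(axis=0, ddof=1),
            "n_reps": n_reps,
            "t_query": t_query,
        }
    )
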