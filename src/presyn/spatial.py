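"""Particle-based Brownian-dynamics Monte Carlo engine.

Positions of every mobile molecule are simulated explicitly in three
axis-aligned compartments (extracellular box stacked on the pre-synapse,
inert post-synapse below).  Each step displaces particles by independent
Gaussian increments (per-axis σ = √(2·D·dt)), reflects them at walls, and
resolves reactive events:

* the **channel face** — a sub-square of the pre-synapse top shared with the
  extracellular box — transports Ca²⁺ inward or binds drug with per-hit
  probabilities calibrated so the dilute well-mixed limit recovers the
  configured rate constants;
* the **pump face** (also on the top plane) returns intra-synaptic Ca²⁺ to
  the extracellular box;
* the **active face** on the pre-synapse bottom is transparent, one way, to
  Ca²⁺–vesicle complexes, which count as released once through;
* Ca²⁺ + vesicle pairs closer than a binding radius react with a
  probability matched to k₃ (Doi scheme, reaction-limited regime).

Channels and pumps are realised as discrete surface sites; a face hit
samples a site uniformly, so the effective rate scales with the free-site
fraction.  Blocked (drug) and, in consumed mode, transported-through sites
never free up again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .wellmixed import SPECIES, IDX, CountTrajectory

#: Site states on the channel face.
FREE, DRUG_BLOCKED, CA_OCCUPIED = 0, 1, 2

#: Doi binding radius for the Ca–vesicle volume reaction, µm.
BINDING_RADIUS = 0.01

#: Hard cap on per-event probabilities; beyond this the first-order
#: (probability ∝ dt) regime breaks down and dt must shrink.
PROB_CAP = 0.2

_KM = 1e15 / 6.02214076e23  # (M⁻¹s⁻¹) → µm³/s per molecular pair


def _cm2_to_um2(d: float) -> float:
    return d * 1e8


def reaction_probability(k: float, dt: float, context: dict) -> float:
    """Per-encounter reaction probability for a rate constant ``k``.

    Surface form (``context = {"tile_area": µm², "diffusion": cm²/s}``):
    probability that a wall hit on one site's tile reacts, calibrated from
    the one-sided diffusive wall-collision flux so that the dilute
    well-mixed limit reproduces ``k``:  p = k̂·√(π·dt/D)/A_tile.

    Volume form (``context = {"binding_radius": µm, "diffusion_sum": cm²/s}``):
    probability that a pair within the binding radius reacts this step,
    p = k̂·dt/V_binding — valid in the reaction-limited regime, which is
    checked against the Smoluchowski rate 4π·(D₁+D₂)·r_b.
    """
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    km = k * _KM  # µm³/s
    if "tile_area" in context:
        d = _cm2_to_um2(context["diffusion"])
        if d == 0.0:
            return 0.0 if km == 0.0 else float("nan")
        p = km * np.sqrt(np.pi * dt / d) / context["tile_area"]
    elif "binding_radius" in context:
        rb = context["binding_radius"]
        v_bind = 4.0 / 3.0 * np.pi * rb**3
        p = km * dt / v_bind
        d_sum = _cm2_to_um2(context["diffusion_sum"])
        k_smol = 4.0 * np.pi * d_sum * rb
        if km > 0.5 * k_smol:
            raise ValueError(
                "reaction not diffusion-dilute: intrinsic rate approaches the "
                "Smoluchowski limit; reduce k or enlarge the binding radius"
            )
    else:
        raise ValueError("context must carry tile_area or binding_radius")
    if p > PROB_CAP:
        raise ValueError(
            f"per-event probability {p:.3f} exceeds {PROB_CAP}; reduce dt"
        )
    return float(p)


@dataclass
class Box:
    lo: np.ndarray
    hi: np.ndarray

    def contains(self, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        return np.all((pts >= self.lo - tol) & (pts <= self.hi + tol), axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=(n, 3))


@dataclass
class SpatialStepReport:
    n_transported: int = 0
    n_blocked: int = 0
    n_pumped: int = 0
    n_bound: int = 0
    n_released: int = 0
    n_boundary_reflections: int = 0
    dt: float = 0.0


@dataclass
class World:
    """Spatial state: compartment boxes, particle positions, surface sites."""

    config: ModelConfig
    extra: Box
    pre: Box
    post: Box
    channel_face: tuple[np.ndarray, np.ndarray]  # (lo_xy, hi_xy) on z = pre top
    pump_face: tuple[np.ndarray, np.ndarray]
    active_face: tuple[np.ndarray, np.ndarray]  # on z = pre bottom
    ca_extra: np.ndarray
    ca_pre: np.ndarray
    drug: np.ndarray
    vesicles: np.ndarray
    complexes_pre: np.ndarray
    site_states: np.ndarray
    n_released: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def counts(self) -> np.ndarray:
        out = np.zeros(len(SPECIES), dtype=np.int64)
        out[IDX["CA_CYT"]] = len(self.ca_extra)
        out[IDX["CA_Pre"]] = len(self.ca_pre)
        out[IDX["A_free"]] = int(np.sum(self.site_states == FREE))
        out[IDX["E"]] = int(np.sum(self.site_states == DRUG_BLOCKED))
        out[IDX["C_occ"]] = int(np.sum(self.site_states == CA_OCCUPIED))
        out[IDX["M"]] = len(self.drug)
        out[IDX["V"]] = len(self.vesicles)
        out[IDX["D_pre"]] = len(self.complexes_pre)
        out[IDX["D_out"]] = self.n_released
        return out


def _centred_square(cx: float, cy: float, area: float) -> tuple[np.ndarray, np.ndarray]:
    h = np.sqrt(area) / 2.0
    return np.array([cx - h, cy - h]), np.array([cx + h, cy + h])


def build_world(config: ModelConfig, seed: int = 0, max_particles: int = 2_000_000) -> World:
    """Construct the boxed synapse with uniformly scattered particles.

    Compartment boxes are near-cubes holding exactly the configured volumes
    (shapes are not part of the published description; volumes and reactive
    face areas are what control the kinetics).  Ca²⁺ and drug scatter
    uniformly through the extracellular box, vesicles through the
    pre-synapse.
    """
    g, c = config.geometry, config.counts
    total = c.n_ca + c.n_drug + c.n_vesicle
    if total > max_particles:
        raise ValueError(f"{total} particles exceed the cap {max_particles}")

    s_pre = g.pre_volume ** (1.0 / 3.0)
    need = max(g.channel_face_area + g.pump_face_area, g.active_face_area)
    side = max(s_pre, np.sqrt(need) * 1.05)  # footprint must host the faces
    h_pre = g.pre_volume / side**2
    s_extra = g.extra_volume ** (1.0 / 3.0)
    s_extra = max(s_extra, side)
    h_extra = g.extra_volume / s_extra**2
    s_post = g.post_volume ** (1.0 / 3.0)

    # pre-synapse spans z ∈ [0, h_pre]; extracellular sits on top, centred.
    pre = Box(np.array([-side / 2, -side / 2, 0.0]),
              np.array([side / 2, side / 2, h_pre]))
    extra = Box(np.array([-s_extra / 2, -s_extra / 2, h_pre]),
                np.array([s_extra / 2, s_extra / 2, h_pre + h_extra]))
    post = Box(np.array([-s_post / 2, -s_post / 2, -s_post]),
               np.array([s_post / 2, s_post / 2, 0.0]))

    # channel face centred on the top plane; pump face tucked beside it.
    ch = _centred_square(0.0, 0.0, g.channel_face_area)
    pump_cx = ch[1][0] + np.sqrt(g.pump_face_area)  # just right of the channels
    if pump_cx + np.sqrt(g.pump_face_area) / 2 > side / 2:
        pump_cx = (ch[1][0] + side / 2) / 2.0
    pm = _centred_square(pump_cx, 0.0, g.pump_face_area)
    af = _centred_square(0.0, 0.0, g.active_face_area)

    rng = np.random.default_rng(seed)
    world = World(
        config=config, extra=extra, pre=pre, post=post,
        channel_face=ch, pump_face=pm, active_face=af,
        ca_extra=extra.sample(c.n_ca, rng),
        ca_pre=np.empty((0, 3)),
        drug=extra.sample(c.n_drug, rng),
        vesicles=pre.sample(c.n_vesicle, rng),
        complexes_pre=np.empty((0, 3)),
        site_states=np.zeros(c.n_channels, dtype=np.int8),
        rng=rng,
    )
    return world


def _reflect(pts: np.ndarray, box: Box) -> int:
    """In-place reflection at all six walls; returns reflection count."""
    n = 0
    for ax in range(3):
        lo, hi = box.lo[ax], box.hi[ax]
        span = hi - lo
        under = pts[:, ax] < lo
        over = pts[:, ax] > hi
        n += int(under.sum() + over.sum())
        # fold once (steps are small relative to box sizes)
        pts[under, ax] = 2 * lo - pts[under, ax]
        pts[over, ax] = 2 * hi - pts[over, ax]
        np.clip(pts[:, ax], lo, hi, out=pts[:, ax])
    return n


def _in_rect(xy: np.ndarray, rect: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    lo, hi = rect
    return np.all((xy >= lo) & (xy <= hi), axis=1)


def _plane_hit_xy(old: np.ndarray, new: np.ndarray, z_plane: float) -> np.ndarray:
    """(x, y) where each segment old→new crosses the z plane."""
    frac = (z_plane - old[:, 2]) / (new[:, 2] - old[:, 2])
    return old[:, :2] + frac[:, None] * (new[:, :2] - old[:, :2])


def step_world(world: World, dt: float) -> SpatialStepReport:
    """Advance the world by one Brownian step; mutates ``world`` in place."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    rep = SpatialStepReport(dt=dt)
    if dt == 0.0:
        return rep
    cfg = world.config
    k, g = cfg.kinetics, cfg.geometry
    rng = world.rng
    z_top = world.pre.hi[2]
    z_bot = world.pre.lo[2]
    tile = 1.0 / k.channel_density if k.channel_density > 0 else np.inf
    n_sites = len(world.site_states)

    p_ca = reaction_probability(k.k1, dt, {"tile_area": tile, "diffusion": k.d_ca}) \
        if n_sites and k.k1 > 0 and k.d_ca > 0 else 0.0
    p_drug = reaction_probability(k.k2, dt, {"tile_area": tile, "diffusion": k.d_drug}) \
        if n_sites and k.k2 > 0 and k.d_drug > 0 else 0.0
    pump_tile = 1.0 / k.pump_density if k.pump_density > 0 else np.inf
    p_pump = reaction_probability(k.k4, dt, {"tile_area": pump_tile, "diffusion": k.d_ca}) \
        if cfg.counts.n_pumps and k.k4 > 0 and k.d_ca > 0 else 0.0
    p_bind = reaction_probability(
        k.k3, dt, {"binding_radius": BINDING_RADIUS, "diffusion_sum": k.d_ca + k.d_vesicle}
    ) if k.k3 > 0 else 0.0

    def diffuse(pts: np.ndarray, d_cm2: float) -> np.ndarray:
        if len(pts) == 0 or d_cm2 == 0.0:
            return pts.copy()
        sigma = np.sqrt(2.0 * _cm2_to_um2(d_cm2) * dt)
        return pts + rng.normal(0.0, sigma, pts.shape)

    # --- Ca in the extracellular box: may transport through a free channel.
    old = world.ca_extra
    new = diffuse(old, k.d_ca)
    transported = np.zeros(len(new), dtype=bool)
    if len(new):
        crossing = new[:, 2] < z_top  # attempts to leave through the bottom wall
        if crossing.any() and p_ca > 0.0:
            xy = _plane_hit_xy(old[crossing], new[crossing], z_top)
            on_face = _in_rect(xy, world.channel_face)
            idx = np.flatnonzero(crossing)[on_face]
            if len(idx):
                sites = rng.integers(0, n_sites, len(idx))
                accept = (world.site_states[sites] == FREE) & (rng.random(len(idx)) < p_ca)
                hit_idx = idx[accept]
                transported[hit_idx] = True
                if cfg.channel_mode == "consumed":
                    # mark sites; duplicate site draws both consume one state
                    world.site_states[sites[accept]] = CA_OCCUPIED
                rep.n_transported += len(hit_idx)
        entered = new[transported].copy()
        if len(entered):
            entered[:, 2] = z_top - (z_top - entered[:, 2]) % max(world.pre.hi[2] - world.pre.lo[2], 1e-12)
            entered[:, 2] = np.clip(entered[:, 2], z_bot, z_top)
            # x, y must fall inside the narrower pre-synapse footprint
            entered[:, 0] = np.clip(entered[:, 0], world.pre.lo[0], world.pre.hi[0])
            entered[:, 1] = np.clip(entered[:, 1], world.pre.lo[1], world.pre.hi[1])
        stay = new[~transported]
        rep.n_boundary_reflections += _reflect(stay, world.extra)
        world.ca_extra = stay
    else:
        entered = np.empty((0, 3))

    # --- drug in the extracellular box: may block a free channel.
    old = world.drug
    new = diffuse(old, k.d_drug)
    if len(new):
        bound = np.zeros(len(new), dtype=bool)
        crossing = new[:, 2] < z_top
        if crossing.any() and p_drug > 0.0:
            xy = _plane_hit_xy(old[crossing], new[crossing], z_top)
            on_face = _in_rect(xy, world.channel_face)
            idx = np.flatnonzero(crossing)[on_face]
            if len(idx):
                sites = rng.integers(0, n_sites, len(idx))
                accept = (world.site_states[sites] == FREE) & (rng.random(len(idx)) < p_drug)
                world.site_states[sites[accept]] = DRUG_BLOCKED
                bound[idx[accept]] = True
                rep.n_blocked += int(accept.sum())
        stay = new[~bound]
        rep.n_boundary_reflections += _reflect(stay, world.extra)
        world.drug = stay

    # --- Ca inside the pre-synapse: pumping out, else reflect.
    old = world.ca_pre
    new = diffuse(old, k.d_ca)
    pumped = np.zeros(len(new), dtype=bool)
    if len(new):
        crossing = new[:, 2] > z_top
        if crossing.any() and p_pump > 0.0:
            xy = _plane_hit_xy(old[crossing], new[crossing], z_top)
            on_face = _in_rect(xy, world.pump_face)
            idx = np.flatnonzero(crossing)[on_face]
            accept = rng.random(len(idx)) < p_pump
            pumped[idx[accept]] = True
            rep.n_pumped += int(accept.sum())
        out = new[pumped].copy()
        if len(out):
            out[:, 2] = z_top + (out[:, 2] - z_top)
            out[:, 2] = np.clip(out[:, 2], world.extra.lo[2], world.extra.hi[2])
        stay = new[~pumped]
        rep.n_boundary_reflections += _reflect(stay, world.pre)
        world.ca_pre = np.vstack([stay, entered]) if len(entered) else stay
        world.ca_extra = np.vstack([world.ca_extra, out]) if len(out) else world.ca_extra
    elif len(entered):
        world.ca_pre = entered

    # --- vesicles: plain reflected diffusion in the pre-synapse.
    if len(world.vesicles):
        new = diffuse(world.vesicles, k.d_vesicle)
        rep.n_boundary_reflections += _reflect(new, world.pre)
        world.vesicles = new

    # --- complexes: may exit through the active face, one way.
    old = world.complexes_pre
    new = diffuse(old, k.d_complex)
    if len(new):
        released = np.zeros(len(new), dtype=bool)
        crossing = new[:, 2] < z_bot
        if crossing.any():
            xy = _plane_hit_xy(old[crossing], new[crossing], z_bot)
            on_face = _in_rect(xy, world.active_face)
            released[np.flatnonzero(crossing)[on_face]] = True
        rep.n_released += int(released.sum())
        world.n_released += int(released.sum())
        stay = new[~released]
        rep.n_boundary_reflections += _reflect(stay, world.pre)
        world.complexes_pre = stay

    # --- volume reaction Ca_pre + V → D within the binding radius.
    if p_bind > 0.0 and len(world.ca_pre) and len(world.vesicles):
        from scipy.spatial import cKDTree

        tree = cKDTree(world.vesicles)
        pairs = tree.query_ball_point(world.ca_pre, BINDING_RADIUS)
        used_v: set[int] = set()
        react_ca, react_v = [], []
        for ca_i, cands in enumerate(pairs):
            for v_i in cands:
                if v_i in used_v:
                    continue
                if rng.random() < p_bind:
                    used_v.add(v_i)
                    react_ca.append(ca_i)
                    react_v.append(v_i)
                    break
        if react_ca:
            rep.n_bound = len(react_ca)
            new_complexes = world.vesicles[react_v]
            keep_ca = np.ones(len(world.ca_pre), bool)
            keep_ca[react_ca] = False
            keep_v = np.ones(len(world.vesicles), bool)
            keep_v[react_v] = False
            world.ca_pre = world.ca_pre[keep_ca]
            world.vesicles = world.vesicles[keep_v]
            world.complexes_pre = (
                np.vstack([world.complexes_pre, new_complexes])
                if len(world.complexes_pre) else new_complexes
            )

    for arr in (world.ca_extra, world.ca_pre, world.drug, world.vesicles,
                world.complexes_pre):
        if len(arr) and not np.all(np.isfinite(arr)):
            raise FloatingPointError("NaN particle position")
    return rep


def run_spatial(
    world: World,
    t_end: float,
    dt: float | None = None,
    sample_dt: float = 1e-3,
) -> CountTrajectory:
    """Step the world to ``t_end`` and sample counts on a regular grid.

    Spatial states map onto the well-mixed species columns (CA_CYT = Ca in
    the extracellular box, VesC_CYT = complexes released through the active
    face, …), so trajectories from both engines are directly comparable.
    """
    cfg = world.config
    dt = cfg.spatial_dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(t_end / dt))
    stride = max(int(round(sample_dt / dt)), 1)
    grid_times = [0.0]
    samples = [world.counts()]
    for step in range(1, n_steps + 1):
        step_world(world, dt)
        if step % stride == 0:
            grid_times.append(step * dt)
            samples.append(world.counts())
    return CountTrajectory(
        np.array(grid_times), np.array(samples), SPECIES,
        None, f"spatial/{cfg.channel_mode}",
    )
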