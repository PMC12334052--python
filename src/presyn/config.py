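"""Model parameterisation: synapse geometry, kinetics, counts.

The simulated system is a three-compartment chemical synapse (extracellular
region, pre-synapse, post-synapse).  Voltage-gated calcium channels sit on the
upper face of the pre-synapse, calcium pumps on its membrane, and an "active"
face on its bottom releases calcium-ion--vesicle complexes toward the cleft.
A channel-blocking drug competes with calcium for the open channels.

All quantities carry the units stated in the field docstrings: volumes in
µm³, areas in µm², bimolecular rates in M⁻¹s⁻¹, diffusion coefficients in
cm²/s, surface densities in µm⁻², times in seconds.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Avogadro constant, mol^-1 (CODATA 2018 exact value).
AVOGADRO = 6.02214076e23

#: Litres per cubic micrometre.
L_PER_UM3 = 1e-15


class ConfigError(ValueError):
    """Raised when a configuration document fails validation."""


@dataclass
class GeometrySpec:
    """Compartment volumes/areas and the reactive sub-faces of the pre-synapse.

    The compartment volumes and total surface areas follow the synapse model
    of the source study (pre-synapse 0.21 µm³ / 2.27 µm², post-synapse
    0.15 µm³ / 2.13 µm², extracellular 4.63 µm³ / 16.04 µm²).  The three
    reactive sub-face areas (channel-bearing, active-release and pump faces)
    are not observable from the published description and act as the
    calibration knobs that set absolute channel/pump counts.
    """

    pre_volume: float = 0.21  # µm³
    pre_area: float = 2.27  # µm²
    post_volume: float = 0.15  # µm³
    post_area: float = 2.13  # µm²
    extra_volume: float = 4.63  # µm³
    extra_area: float = 16.04  # µm²
    channel_face_area: float = 0.0755  # µm² (calibrated; see docs/methods.md)
    active_face_area: float = 0.5  # µm²
    pump_face_area: float = 0.001  # µm² (calibrated)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ConfigError(f"geometry.{f.name} must be strictly positive, got {v!r}")
        if self.channel_face_area > self.pre_area:
            raise ConfigError("channel_face_area exceeds total pre-synaptic area")
        if self.active_face_area > self.pre_area:
            raise ConfigError("active_face_area exceeds total pre-synaptic area")


@dataclass
class KineticParams:
    """Rate constants, diffusion coefficients and surface densities.

    k1: Ca²⁺ influx through an open channel; k2: drug blocking a channel;
    k3: Ca²⁺ binding a vesicle in the pre-synapse; k4: Ca²⁺ extrusion by a
    pump.  ``release_rate`` is the first-order rate at which a calcium-ion--
    vesicle complex escapes through the active face in the well-mixed engine
    (a surrogate for its diffusive transit; calibrated).
    """

    k1: float = 1.0e8  # M⁻¹s⁻¹
    k2: float = 1.0e8  # M⁻¹s⁻¹ (grid value; 0 means drug absent)
    k3: float = 1.0e7  # M⁻¹s⁻¹
    k4: float = 1.0e7  # M⁻¹s⁻¹
    d_ca: float = 6.0e-6  # cm²/s
    d_drug: float = 1.0e-6  # cm²/s
    d_vesicle: float = 1.2e-6  # cm²/s
    d_complex: float = 1.0e-6  # cm²/s
    channel_density: float = 1.0e4  # µm⁻²
    pump_density: float = 1.0e4  # µm⁻²
    release_rate: float = 17.0  # s⁻¹ (calibrated; see docs/methods.md)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v >= 0):
                raise ConfigError(f"kinetics.{f.name} must be non-negative, got {v!r}")


@dataclass
class InitialCounts:
    """Initial copy numbers.  Channel/pump counts derive from density × area."""

    n_ca: int = 3000
    n_drug: int = 1500
    n_vesicle: int = 3000  # unprinted in the source; calibration-sensitive
    n_channels: int = 0  # derived unless explicitly overridden
    n_pumps: int = 0  # derived unless explicitly overridden

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, int) and v >= 0):
                raise ConfigError(f"counts.{f.name} must be a non-negative integer, got {v!r}")


@dataclass
class ModelConfig:
    """Complete parameterisation of one simulation.

    ``channel_mode`` resolves an ambiguity in the influx reaction: in
    ``"consumed"`` mode a channel is permanently occupied after transporting
    one calcium ion; in ``"catalytic"`` mode it remains open and only the
    drug can retire it.  Both are implemented; ``"catalytic"`` is the default
    (see docs/methods.md for the calibration argument).

    ``transport_limited`` applies a Collins–Kimball correction to the two
    channel-face reactions in the well-mixed engine: the reaction conductance
    is the series combination of intrinsic binding (n_free·k/N_A) and
    diffusive delivery to the channel-face disk (4·D·a).  This captures the
    spatial simulations' delivery bottleneck — which throttles the slowly
    diffusing drug far more than Ca²⁺ — without simulating positions.
    """

    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    kinetics: KineticParams = field(default_factory=KineticParams)
    counts: InitialCounts = field(default_factory=InitialCounts)
    channel_mode: str = "catalytic"  # or "consumed"
    transport_limited: bool = True
    t_end: float = 0.2  # s
    sample_dt: float = 1e-3  # s
    engine: str = "wellmixed"  # or "spatial"
    spatial_dt: float = 1e-6  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_mode not in ("consumed", "catalytic"):
            raise ConfigError(f"unknown channel_mode {self.channel_mode!r}")
        if self.engine not in ("wellmixed", "spatial"):
            raise ConfigError(f"unknown engine {self.engine!r}")
        if not self.t_end > 0:
            raise ConfigError("t_end must be positive")
        if not 0 < self.sample_dt <= self.t_end:
            raise ConfigError("sample_dt must lie in (0, t_end]")
        if not self.spatial_dt > 0:
            raise ConfigError("spatial_dt must be positive")
        # Fill in derived surface counts unless the user pinned them.
        if self.counts.n_channels == 0:
            self.counts.n_channels = derive_surface_counts(self.geometry, self.kinetics)[0]
        if self.counts.n_pumps == 0:
            self.counts.n_pumps = derive_surface_counts(self.geometry, self.kinetics)[1]

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    def replace(self, **kwargs: Any) -> "ModelConfig":
        """Return a copy with nested fields overridden.

        Keyword names may be flat (``t_end``) or dotted (``kinetics.k2``).
        """
        doc = self.to_dict()
        for key, value in kwargs.items():
            node = doc
            *parents, leaf = key.split(".")
            for p in parents:
                node = node[p]
            if leaf not in node:
                raise ConfigError(f"unknown config key {key!r}")
            node[leaf] = value
        return load_config(doc)


_SECTIONS = {
    "geometry": GeometrySpec,
    "kinetics": KineticParams,
    "counts": InitialCounts,
}


def load_config(source: str | Path | Mapping[str, Any] | None = None) -> ModelConfig:
    """Build a validated :class:`ModelConfig` from a document.

    ``source`` may be a mapping, a path to a YAML/JSON file, a YAML string,
    or ``None``/empty for the standard parameter set.  Unknown keys raise
    :class:`ConfigError`; missing keys take their standard defaults.
    """
    if source is None:
        doc: Mapping[str, Any] = {}
    elif isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        try:
            parsed = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse configuration document: {exc}") from exc
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, Mapping):
            raise ConfigError("configuration document must be a key-value mapping")
        doc = parsed

    kwargs: dict[str, Any] = {}
    for key, value in doc.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            if not isinstance(value, Mapping):
                raise ConfigError(f"section {key!r} must be a mapping")
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - names
            if unknown:
                raise ConfigError(f"unknown keys in {key!r}: {sorted(unknown)}")
            coerced = {
                k: int(v) if cls is InitialCounts else float(v) for k, v in value.items()
            }
            kwargs[key] = cls(**coerced)
        elif key in {f.name for f in dataclasses.fields(ModelConfig)}:
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key {key!r}")
    return ModelConfig(**kwargs)


def derive_surface_counts(
    geometry: GeometrySpec, kinetics: KineticParams
) -> tuple[int, int]:
    """Channel and pump copy numbers from surface density × face area."""
    n_channels = int(round(kinetics.channel_density * geometry.channel_face_area))
    n_pumps = int(round(kinetics.pump_density * geometry.pump_face_area))
    if kinetics.channel_density > 0 and n_channels == 0:
        warnings.warn("channel face too small for one channel; count is 0")
    if kinetics.pump_density > 0 and n_pumps == 0:
        warnings.warn("pump face too small for one pump; count is 0")
    return n_channels, n_pumps


def per_pair_rate(k: float, volume_um3: float) -> float:
    """Convert a bimolecular rate constant to a per-reactant-pair rate.

    Standard mass-action conversion ``c = k / (N_A · V)`` with the
    compartment volume in litres; the result is the stochastic rate (s⁻¹)
    at which any specific reactant pair fires.
    """
    if volume_um3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_um3}")
    if k < 0:
        raise ValueError(f"rate constant must be non-negative, got {k}")
    return k / (AVOGADRO * volume_um3 * L_PER_UM3)


def count_to_concentration(n: float, volume_um3: float) -> float:
    """Copy number in a compartment → molar concentration."""
    if volume_um3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_um3}")
    if n < 0:
        raise ValueError(f"count must be non-negative, got {n}")
    return n / (AVOGADRO * volume_um3 * L_PER_UM3)
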