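"""Configuration model.

All simulations are driven by a single :class:`MSPConfig`, a bundle of five
sections (``network``, ``neuron``, ``growth``, ``schedule``, ``output``)
parsed from a TOML file.  Every field has a default corresponding to the
full-scale cortical-sheet setup: 320 excitatory + 80 inhibitory Izhikevich
neurons on a jittered 20x16 grid (150 um spacing), Gaussian growth curves
with a homeostatic calcium range [0.65, 0.75], and a focal deafferentation
of an 8x8 block of grid points after 8000 connectivity updates.

Unknown keys are rejected and invariants are checked eagerly so that a typo
in a config file fails loudly before a multi-hour run starts.
"""

from __future__ import annotations

import dataclasses
import io
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


class ConfigError(ValueError):
    """Raised when a configuration file fails to parse or validate."""


@dataclass(frozen=True)
class NetworkConfig:
    """Geometry of the neuronal sheet.

    Excitatory neurons sit on a ``grid_nx`` x ``grid_ny`` lattice with
    ``spacing_um`` micrometre pitch, each displaced by a uniform jitter of
    amplitude ``jitter_frac * spacing_um`` per coordinate.  Inhibitory
    neurons (one per 2x2 block of excitatory cells by default) are placed
    evenly on the interstitial sub-lattice.
    """

    grid_nx: int = 20
    grid_ny: int = 16
    spacing_um: float = 150.0
    jitter_frac: float = 0.1
    n_inhibitory: int = -1  # -1: one quarter of the excitatory count

    @property
    def n_excitatory(self) -> int:
        return self.grid_nx * self.grid_ny

    @property
    def n_in(self) -> int:
        if self.n_inhibitory < 0:
            return self.n_excitatory // 4
        return self.n_inhibitory

    @property
    def n_total(self) -> int:
        return self.n_excitatory + self.n_in

    def validate(self) -> None:
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ConfigError("network: grid must be at least 2x2")
        if self.spacing_um <= 0:
            raise ConfigError("network: spacing_um must be positive")
        if not 0 <= self.jitter_frac < 0.5:
            raise ConfigError("network: jitter_frac must lie in [0, 0.5)")
        if self.n_in <= 0:
            raise ConfigError("network: inhibitory count must be positive")


@dataclass(frozen=True)
class IzhikevichParams:
    """Membrane, synapse and calcium parameters of the point-neuron model.

    The quadratic membrane equation dv/dt = k1 v^2 + k2 v + k3 - u + I is
    integrated by forward Euler; a spike (v >= v_spike) resets v to c and
    increments u by d.  Synaptic input is an exponentially filtered train of
    fixed-amplitude pulses (syn_strength per synapse, decay mu).  Calcium, a
    low-pass filter of the spike train (increment beta per spike, decay
    tau_ca), serves as the activity read-out of the growth rules.
    """

    k1: float = 0.04  # mV^-1 ms^-1
    k2: float = 5.0  # ms^-1
    k3: float = 140.0  # mV ms^-1
    a: float = 0.1  # ms^-1
    b: float = 0.2  # ms^-1
    c: float = -65.0  # mV
    d: float = 2.0  # mV ms^-1
    v_spike: float = 30.0  # mV
    syn_strength: float = 1.0  # mV ms^-1 per synapse
    mu: float = 5.0  # ms, synaptic filter decay
    beta: float = 0.001  # ms^-1, calcium increment per spike
    tau_ca: float = 10000.0  # ms, calcium decay
    i_ext_mean: float = 5.0  # mV ms^-1, baseline external drive
    i_ext_sd: float = 1.0  # mV ms^-1, white-noise s.d.

    def validate(self) -> None:
        if self.tau_ca <= 0:
            raise ConfigError("neuron: tau_ca must be positive")
        if self.mu <= 0:
            raise ConfigError("neuron: mu must be positive")
        if self.v_spike <= self.c:
            raise ConfigError("neuron: v_spike must exceed the reset value c")
        if self.i_ext_sd < 0:
            raise ConfigError("neuron: i_ext_sd must be non-negative")


@dataclass(frozen=True)
class GrowthConfig:
    """Parameters of the activity-dependent element growth rules.

    Element counts follow a Gaussian growth curve of calcium with zero
    crossings at ``eta`` (minimum calcium for outgrowth; eta_a for axonal,
    eta_d for dendritic elements) and at the set-point ``eps_center``, peak
    rate ``nu`` at their midpoint, and limit -nu at high calcium.  Inside
    the homeostatic range [eps_lo, eps_hi] the rate is clamped to exactly
    zero so rewiring comes to a standstill near the set-point.  Vacant
    elements decay with time constant ``tau_vac`` (in connectivity updates).
    The formation kernel is either a Gaussian of width ``sigma_um`` in the
    squared-distance exponent (local, small-world-like connectivity) or
    flat (random connectivity).
    """

    nu: float = 1e-4  # elements ms^-1
    eta_a: float = 0.4
    eta_d: float = 0.1
    eps_center: float = 0.7
    eps_lo: float = 0.65
    eps_hi: float = 0.75
    tau_vac: float = 10.0  # connectivity updates
    kernel: str = "gaussian"  # or "flat"
    sigma_um: float = 150.0

    def validate(self) -> None:
        for name, eta in (("eta_a", self.eta_a), ("eta_d", self.eta_d)):
            if not 0 <= eta < self.eps_center:
                raise ConfigError(f"growth: need 0 <= {name} < eps_center")
        if not self.eps_lo < self.eps_hi:
            raise ConfigError("growth: need eps_lo < eps_hi")
        if self.tau_vac <= 0:
            raise ConfigError("growth: tau_vac must be positive")
        if self.kernel not in ("gaussian", "flat"):
            raise ConfigError("growth: kernel must be 'gaussian' or 'flat'")
        if self.sigma_um <= 0:
            raise ConfigError("growth: sigma_um must be positive")
        if self.nu <= 0:
            raise ConfigError("growth: nu must be positive")


@dataclass(frozen=True)
class ScheduleConfig:
    """Time course of the experiment, in units of connectivity updates.

    A network is grown from scratch under elevated external drive
    (``i_ext_growth`` for the first ``ramp_onset`` updates, then a logistic
    ramp of width ``ramp_tau`` down to the baseline drive).  At update
    ``lesion_onset`` the external input of every neuron inside ``lpz_rect``
    (x1, y1, x2, y2 in micrometres, closed rectangle) is permanently set to
    zero; the run continues until ``total_updates``.  ``updates_per_day``
    calibrates model time against post-lesion days (1000 updates = 14 days).
    """

    lesion_onset: int = 8000
    total_updates: int = 20000
    lpz_rect: tuple[float, float, float, float] = (750.0, 750.0, 1800.0, 1800.0)
    window_ms: float = 5000.0
    dt_ms: float = 1.0
    updates_per_day: float = 1000.0 / 14.0
    i_ext_growth: float = 8.0  # mV ms^-1, initial plateau
    ramp_onset: int = 500  # updates on the plateau
    ramp_tau: float = 200.0  # updates, logistic ramp width

    def validate(self, network: NetworkConfig | None = None) -> None:
        if not 0 < self.lesion_onset < self.total_updates:
            raise ConfigError("schedule: need 0 < lesion_onset < total_updates")
        x1, y1, x2, y2 = self.lpz_rect
        if not (x1 < x2 and y1 < y2):
            raise ConfigError("schedule: lpz_rect must have x1 < x2 and y1 < y2")
        if self.window_ms <= 0 or self.dt_ms <= 0:
            raise ConfigError("schedule: window_ms and dt_ms must be positive")
        if self.window_ms / self.dt_ms != round(self.window_ms / self.dt_ms):
            raise ConfigError("schedule: window_ms must be a multiple of dt_ms")
        if self.updates_per_day <= 0:
            raise ConfigError("schedule: updates_per_day must be positive")
        if network is not None:
            x_max = (network.grid_nx - 1) * network.spacing_um
            y_max = (network.grid_ny - 1) * network.spacing_um
            if x1 < 0 or y1 < 0 or x2 > x_max or y2 > y_max:
                raise ConfigError("schedule: lpz_rect lies outside the grid extent")

    @property
    def n_steps_per_window(self) -> int:
        return round(self.window_ms / self.dt_ms)

    def days_post_lesion(self, t: int) -> float:
        """Map a connectivity-update index to days after lesion onset."""
        return (t - self.lesion_onset) / self.updates_per_day


@dataclass(frozen=True)
class OutputConfig:
    """What the experiment driver records beyond the per-update series."""

    topology_every: int = 0  # 0: only on stored snapshots
    snapshot_pre_offset: int = 50  # snapshot at lesion_onset - offset
    er_replicates: int = 10  # Erdos-Renyi null graphs per evaluation

    def validate(self) -> None:
        if self.topology_every < 0:
            raise ConfigError("output: topology_every must be >= 0")
        if self.snapshot_pre_offset < 0:
            raise ConfigError("output: snapshot_pre_offset must be >= 0")
        if self.er_replicates < 1:
            raise ConfigError("output: er_replicates must be >= 1")


_SECTIONS = {
    "network": NetworkConfig,
    "neuron": IzhikevichParams,
    "growth": GrowthConfig,
    "schedule": ScheduleConfig,
    "output": OutputConfig,
}


@dataclass(frozen=True)
class MSPConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    neuron: IzhikevichParams = field(default_factory=IzhikevichParams)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def validate(self) -> "MSPConfig":
        self.network.validate()
        self.neuron.validate()
        self.growth.validate()
        self.schedule.validate(self.network)
        self.output.validate()
        return self


def _coerce(section: str, cls: type, raw: dict[str, Any]) -> Any:
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(f"{section}: unknown key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        f = known[key]
        if f.name == "lpz_rect":
            if not (isinstance(value, (list, tuple)) and len(value) == 4):
                raise ConfigError("schedule: lpz_rect must be a 4-element list")
            value = tuple(float(v) for v in value)
        elif f.type in ("int", int):
            if not isinstance(value, int) or isinstance(value, bool):
                raise ConfigError(f"{section}: {key} must be an integer")
        elif f.type in ("float", float):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"{section}: {key} must be a number")
            value = float(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict[str, Any]) -> MSPConfig:
    """Build a validated :class:`MSPConfig` from a nested plain dict."""
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        raw = data.get(name, {})
        if not isinstance(raw, dict):
            raise ConfigError(f"section '{name}' must be a table")
        kwargs[name] = _coerce(name, cls, raw)
    return MSPConfig(**kwargs).validate()


def load_config(path: str | Path) -> MSPConfig:
    """Load and validate a TOML configuration file.

    Missing sections/keys fall back to the full-scale defaults; unknown
    keys raise :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from None
    return config_from_dict(data)


def _toml_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (tuple, list)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {value!r}")


def serialize_config(cfg: MSPConfig) -> str:
    """Render a config as TOML text; ``load`` of the result round-trips."""
    out = io.StringIO()
    for name in _SECTIONS:
        section = getattr(cfg, name)
        out.write(f"[{name}]\n")
        for f in dataclasses.fields(section):
            out.write(f"{f.name} = {_toml_value(getattr(section, f.name))}\n")
        out.write("\n")
    return out.getvalue()


def growth_curve_width(eta: float, eps_center: float) -> float:
    """Width zeta of the Gaussian growth curve.

    Fixed by requiring the two zero crossings of
    nu * (2 exp(-((ca - xi)/zeta)^2) - 1) to fall exactly at eta and at the
    set-point eps_center, with xi their midpoint.
    """
    return (eta - eps_center) / (2.0 * math.sqrt(math.log(2.0)))
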