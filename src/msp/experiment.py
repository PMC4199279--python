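"""Deafferentation experiments: grow a network from scratch, silence the
external input of a focal region (the lesion projection zone, LPZ), and
follow the rewiring.

Three growth-parameter regimes are shipped as presets:

``physiological``
    axonal elements need more activity than dendritic ones
    (eta_a = 0.4, eta_d = 0.1): repair by ingrowth from the intact zone.
``recurrent``
    both element types grow at low activity (eta_a = eta_d = 0.1): repair
    by massive recurrent wiring inside the LPZ.
``no_repair``
    dendritic elements need more activity than axonal ones
    (eta_a = 0.1, eta_d = 0.4): deafferented neurons never recover.

Two scales are provided: ``full`` (20x16 excitatory grid, 8000 growth +
12000 post-lesion updates, the published geometry) and ``mini`` (10x8
grid, 2000 + 3000 updates, central 4x4 LPZ), a first-class scaled-down
configuration whose qualitative behaviour matches the full runs at a
fraction of the cost.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MSPConfig
from .plasticity import UpdateRecord, connectivity_update, kernel_matrix
from .state import ElementState, NetworkState, NeuronState, Population, RngStreams

logger = logging.getLogger(__name__)

PRESETS: dict[str, dict[str, float]] = {
    "physiological": {"eta_a": 0.4, "eta_d": 0.1},
    "recurrent": {"eta_a": 0.1, "eta_d": 0.1},
    "no_repair": {"eta_a": 0.1, "eta_d": 0.4},
}

_MINI_NETWORK = dict(grid_nx=10, grid_ny=8, n_inhibitory=20)
# central 4x4 block of grid points: x index 3..6, y index 2..5
_MINI_SCHEDULE = dict(
    lesion_onset=2000,
    total_updates=5000,
    lpz_rect=(450.0, 300.0, 900.0, 750.0),
)


@dataclass(frozen=True)
class ExperimentPreset:
    """Named growth-rule case plus kernel flavour and control switch."""

    name: str
    eta_a: float
    eta_d: float
    kernel: str = "gaussian"  # 'gaussian' (small-world) or 'flat' (random)
    control: bool = False  # control run: no lesion is applied

    @classmethod
    def from_name(
        cls, name: str, kernel: str = "gaussian", control: bool = False
    ) -> "ExperimentPreset":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(name=name, kernel=kernel, control=control, **PRESETS[name])


def preset_config(
    preset: ExperimentPreset, scale: str = "full", base: MSPConfig | None = None
) -> MSPConfig:
    """Resolve a preset and scale into a full configuration."""
    cfg = base if base is not None else MSPConfig()
    growth = dataclasses.replace(
        cfg.growth, eta_a=preset.eta_a, eta_d=preset.eta_d, kernel=preset.kernel
    )
    if scale == "full":
        network, schedule = cfg.network, cfg.schedule
    elif scale == "mini":
        network = dataclasses.replace(cfg.network, **_MINI_NETWORK)
        schedule = dataclasses.replace(cfg.schedule, **_MINI_SCHEDULE)
    else:
        raise ValueError("scale must be 'full' or 'mini'")
    return dataclasses.replace(
        cfg, network=network, growth=growth, schedule=schedule
    ).validate()


def build_population(config: MSPConfig, rng: np.random.Generator) -> Population:
    """Place neurons on the jittered lattice and flag LPZ membership.

    Excitatory neurons sit at the grid points plus a per-coordinate uniform
    jitter of amplitude ``jitter_frac * spacing``; inhibitory neurons are
    placed evenly on the interstitial sub-lattice (one per 2x2 block of
    excitatory cells), jittered the same way.  If the inhibitory count does
    not tile that sub-lattice, the positions fall back to uniform random
    interstitial locations (logged).  LPZ membership is decided by the
    jittered position falling inside the configured rectangle inflated by
    the jitter amplitude, so that every neuron anchored on an enclosed grid
    point is flagged regardless of its jitter draw.
    """
    net = config.network
    nx, ny, s = net.grid_nx, net.grid_ny, net.spacing_um
    amp = net.jitter_frac * s

    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ex_anchor = np.column_stack([gx.ravel() * s, gy.ravel() * s]).astype(float)

    n_in = net.n_in
    sub_nx, sub_ny = nx // 2, ny // 2
    if nx % 2 == 0 and ny % 2 == 0 and n_in == sub_nx * sub_ny:
        ix, iy = np.meshgrid(np.arange(sub_nx), np.arange(sub_ny), indexing="ij")
        in_anchor = np.column_stack(
            [(2 * ix.ravel() + 0.5) * s, (2 * iy.ravel() + 0.5) * s]
        ).astype(float)
    else:
        logger.warning(
            "inhibitory count %d does not tile the %dx%d interstitial lattice; "
            "falling back to uniform random interstitial placement",
            n_in, sub_nx, sub_ny,
        )
        in_anchor = np.column_stack(
            [
                rng.uniform(0.5 * s, (nx - 1.5) * s, size=n_in),
                rng.uniform(0.5 * s, (ny - 1.5) * s, size=n_in),
            ]
        )

    anchors = np.vstack([ex_anchor, in_anchor])
    pos = anchors + rng.uniform(-amp, amp, size=anchors.shape)
    pos = np.clip(pos, 0.0, None)

    x1, y1, x2, y2 = config.schedule.lpz_rect
    in_lpz = (
        (pos[:, 0] >= x1 - amp)
        & (pos[:, 0] <= x2 + amp)
        & (pos[:, 1] >= y1 - amp)
        & (pos[:, 1] <= y2 + amp)
    )
    is_ex = np.zeros(len(pos), dtype=bool)
    is_ex[: len(ex_anchor)] = True
    return Population(pos=pos, is_excitatory=is_ex, in_lpz=in_lpz)


def init_state(config: MSPConfig, seed: int | np.random.SeedSequence) -> NetworkState:
    """Fresh network: zero connectivity, zero elements, neurons at rest."""
    rng = RngStreams.from_seed(seed)
    pop = build_population(config, rng.jitter)
    n = pop.n
    return NetworkState(
        config=config,
        population=pop,
        neurons=NeuronState.resting(n, config.neuron.c, config.neuron.b),
        elements=ElementState.zeros(n),
        w=np.zeros((n, n), dtype=np.int64),
        kernel=kernel_matrix(pop.pos, config.growth),
        rng=rng,
    )


def apply_lesion(state: NetworkState) -> None:
    """Permanently remove external input (mean and noise) of LPZ neurons.

    Connectivity and element counts are untouched; all subsequent change is
    driven by the activity drop.
    """
    state.lesioned = True


def grow_network(
    state: NetworkState, records: list[UpdateRecord] | None = None
) -> NetworkState:
    """Run connectivity updates up to lesion onset (growth from scratch)."""
    onset = state.config.schedule.lesion_onset
    while state.t < onset:
        rec = connectivity_update(state)
        if records is not None:
            records.append(rec)
    return state


@dataclass
class ExperimentResult:
    """Per-update series, connectome snapshots, and the state at the end."""

    config: MSPConfig
    preset: ExperimentPreset
    series: pd.DataFrame
    snapshots: dict[int, np.ndarray]  # update index -> copy of full W
    state: NetworkState

    def w_exex_at(self, t: int) -> np.ndarray:
        ex = self.state.population.is_excitatory
        return self.snapshots[t][np.ix_(ex, ex)]

    @property
    def lpz_ex_mask(self) -> np.ndarray:
        pop = self.state.population
        return pop.in_lpz[pop.is_excitatory]


def _records_to_frame(records: list[UpdateRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "t": r.t,
            "mean_ca_lpz": r.mean_ca_lpz,
            "mean_ca_intact": r.mean_ca_intact,
            "total_synapses": r.total_synapses,
            "total_spikes": int(r.spike_counts.sum()),
        }
        for key, value in r.synapses_by_region.items():
            row[f"w_{key}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(
    preset: ExperimentPreset | str,
    seed: int | np.random.SeedSequence,
    scale: str = "full",
    base: MSPConfig | None = None,
    snapshot_times: tuple[int, ...] | None = None,
    progress: bool = False,
) -> ExperimentResult:
    """Grow a network, apply the lesion (unless control), continue, record.

    Snapshots of W default to shortly before lesion onset
    (``onset - snapshot_pre_offset``), at onset, and at the final update.
    The per-update series records region calcium means and excitatory
    synapse counts by region pair.
    """
    if isinstance(preset, str):
        preset = ExperimentPreset.from_name(preset)
    cfg = preset_config(preset, scale=scale, base=base)
    sched = cfg.schedule
    if snapshot_times is None:
        snapshot_times = (
            sched.lesion_onset - cfg.output.snapshot_pre_offset,
            sched.lesion_onset,
            sched.total_updates,
        )
    state = init_state(cfg, seed)
    records: list[UpdateRecord] = []
    snapshots: dict[int, np.ndarray] = {}

    while state.t < sched.total_updates:
        if state.t in snapshot_times:
            snapshots[state.t] = state.w.copy()
        if state.t == sched.lesion_onset and not preset.control:
            apply_lesion(state)
        records.append(connectivity_update(state))
        if progress and state.t % 500 == 0:
            logger.info(
                "T=%d  ca_lpz=%.3f  ca_intact=%.3f  synapses=%d",
                state.t, records[-1].mean_ca_lpz,
                records[-1].mean_ca_intact, records[-1].total_synapses,
            )
    if sched.total_updates in snapshot_times:
        snapshots[sched.total_updates] = state.w.copy()

    return ExperimentResult(
        config=cfg,
        preset=preset,
        series=_records_to_frame(records),
        snapshots=snapshots,
        state=state,
    )
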