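"""Shared data model: population geometry, neuron state, elements, connectome.

The connectome ``W`` is a dense integer matrix of synapse multiplicities
with ``W[i, j]`` = number of synapses from presynaptic neuron ``j`` onto
postsynaptic neuron ``i``.  Multiple synapses per ordered pair are counts,
not parallel edge objects, because both the deletion rule and the graph
weights operate on multiplicities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MSPConfig


@dataclass
class Population:
    """Neuron positions and type/region labels.

    ``pos`` holds absolute coordinates in micrometres on a 0-based plane.
    ``in_lpz`` marks membership of the lesion projection zone, fixed at
    build time from the configured rectangle (input removal only becomes
    effective at lesion onset).
    """

    pos: np.ndarray  # (n, 2) float, um
    is_excitatory: np.ndarray  # (n,) bool
    in_lpz: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.is_excitatory = np.asarray(self.is_excitatory, dtype=bool)
        self.in_lpz = np.asarray(self.in_lpz, dtype=bool)
        n = self.pos.shape[0]
        if self.pos.ndim != 2 or self.pos.shape[1] != 2:
            raise ValueError("pos must be an (n, 2) array")
        if self.is_excitatory.shape != (n,) or self.in_lpz.shape != (n,):
            raise ValueError("label arrays must match the number of neurons")
        if not np.all(np.isfinite(self.pos)) or np.any(self.pos < 0):
            raise ValueError("coordinates must be finite and non-negative")

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    @property
    def n_ex(self) -> int:
        return int(self.is_excitatory.sum())

    @property
    def n_in(self) -> int:
        return self.n - self.n_ex


@dataclass
class NeuronState:
    """Per-neuron electrical state carried across connectivity updates."""

    v: np.ndarray  # membrane potential, mV
    u: np.ndarray  # recovery variable, mV
    syn_drive_ex: np.ndarray  # filtered excitatory input, mV ms^-1
    syn_drive_in: np.ndarray  # filtered inhibitory input, mV ms^-1
    ca: np.ndarray  # calcium, dimensionless activity measure
    last_spiked: np.ndarray  # bool; spikes feed drives with a one-step delay

    @classmethod
    def resting(cls, n: int, c: float, b: float) -> "NeuronState":
        v = np.full(n, c, dtype=float)
        return cls(
            v=v,
            u=b * v.copy(),
            syn_drive_ex=np.zeros(n),
            syn_drive_in=np.zeros(n),
            ca=np.zeros(n),
            last_spiked=np.zeros(n, dtype=bool),
        )

    def copy(self) -> "NeuronState":
        return NeuronState(
            self.v.copy(),
            self.u.copy(),
            self.syn_drive_ex.copy(),
            self.syn_drive_in.copy(),
            self.ca.copy(),
            self.last_spiked.copy(),
        )


@dataclass
class ElementState:
    """Continuous per-neuron synaptic-element counts.

    ``a`` are axonal elements (boutons), ``d_ex``/``d_in`` excitatory and
    inhibitory dendritic elements (postsynaptic sites).  Integer capacity
    for binding synapses is the floor of the continuous count.
    """

    a: np.ndarray
    d_ex: np.ndarray
    d_in: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "ElementState":
        return cls(np.zeros(n), np.zeros(n), np.zeros(n))

    def copy(self) -> "ElementState":
        return ElementState(self.a.copy(), self.d_ex.copy(), self.d_in.copy())


@dataclass
class BoundCounts:
    """Synapses bound per neuron and element class, derived from W."""

    axonal: np.ndarray  # outgoing synapses of each neuron
    dendritic_ex: np.ndarray  # incoming synapses from excitatory sources
    dendritic_in: np.ndarray  # incoming synapses from inhibitory sources


def bound_counts(w: np.ndarray, is_excitatory: np.ndarray) -> BoundCounts:
    return BoundCounts(
        axonal=w.sum(axis=0),
        dendritic_ex=w[:, is_excitatory].sum(axis=1),
        dendritic_in=w[:, ~is_excitatory].sum(axis=1),
    )


@dataclass
class RngStreams:
    """Independent sub-streams of one seeded simulation.

    Splitting jitter/noise/deletion/formation keeps structural randomness
    reproducible independent of the activity noise consumption.
    """

    jitter: np.random.Generator
    noise: np.random.Generator
    deletion: np.random.Generator
    formation: np.random.Generator

    @classmethod
    def from_seed(cls, seed: int | np.random.SeedSequence) -> "RngStreams":
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        children = ss.spawn(4)
        return cls(*(np.random.default_rng(c) for c in children))


@dataclass
class NetworkState:
    """Full simulation state: who is where, wiring, activity, elements."""

    config: MSPConfig
    population: Population
    neurons: NeuronState
    elements: ElementState
    w: np.ndarray  # (n, n) int64, W[i, j] = synapses j -> i
    kernel: np.ndarray  # (n, n) float, formation kernel K[i, j]
    rng: RngStreams
    t: int = 0  # connectivity-update index
    lesioned: bool = False

    @property
    def n(self) -> int:
        return self.population.n

    def bound(self) -> BoundCounts:
        return bound_counts(self.w, self.population.is_excitatory)

    def active_mask(self) -> np.ndarray:
        """Neurons still receiving external input."""
        if self.lesioned:
            return ~self.population.in_lpz
        return np.ones(self.n, dtype=bool)

    def w_exex(self) -> np.ndarray:
        """Excitatory-to-excitatory sub-connectome (topology analysis view)."""
        ex = self.population.is_excitatory
        return self.w[np.ix_(ex, ex)]

    def check_invariants(self) -> None:
        """Raise if synapse bookkeeping is inconsistent (debug/testing aid)."""
        if np.any(self.w < 0):
            raise AssertionError("negative synapse multiplicity")
        if np.any(np.diag(self.w) != 0):
            raise AssertionError("autapse present")
        b = self.bound()
        if np.any(b.axonal > np.floor(self.elements.a)):
            raise AssertionError("outgoing synapses exceed axonal capacity")
        if np.any(b.dendritic_ex > np.floor(self.elements.d_ex)):
            raise AssertionError("incoming excitatory synapses exceed capacity")
        if np.any(b.dendritic_in > np.floor(self.elements.d_in)):
            raise AssertionError("incoming inhibitory synapses exceed capacity")
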