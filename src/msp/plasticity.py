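"""Homeostatic structural plasticity: element growth, synapse breaking and
synapse formation.

Each connectivity update runs four phases in order:

1. electrical simulation of one window (see :mod:`msp.activity`);
2. Euler integration of the Gaussian growth curves on the window-end
   calcium, followed by spontaneous decay of vacant elements;
3. deletion of surplus synapses where a neuron's bound synapses exceed the
   integer capacity floor(count) of the hosting element class, sampled
   proportionally to connection multiplicity;
4. formation of new synapses by randomly pairing vacant axonal with vacant
   dendritic elements of matching sign, biased by a distance kernel and
   capped by the per-pair and per-class vacancy bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import GrowthConfig, growth_curve_width
from .state import BoundCounts, ElementState, NetworkState
from . import activity


def growth_rate(
    ca: np.ndarray | float, kind: str, g: GrowthConfig
) -> np.ndarray | float:
    """Element growth rate dz/dt (elements/ms) as a function of calcium.

    A Gaussian bump ``nu * (2 exp(-((ca - xi)/zeta)^2) - 1)`` whose zero
    crossings sit exactly at the minimum calcium ``eta`` (eta_a for axonal,
    eta_d for dendritic elements) and at the set-point ``eps_center``:
    elements retract below eta (activity too low to sustain outgrowth) and
    above the set-point (activity too high), and grow in between with peak
    rate nu at the midpoint.  Inside the homeostatic range
    [eps_lo, eps_hi] the rate is overridden to exactly zero.
    """
    if kind == "axonal":
        eta = g.eta_a
    elif kind == "dendritic":
        eta = g.eta_d
    else:
        raise ValueError("kind must be 'axonal' or 'dendritic'")
    ca_arr = np.asarray(ca, dtype=float)
    xi = (eta + g.eps_center) / 2.0
    zeta = growth_curve_width(eta, g.eps_center)
    rate = g.nu * (2.0 * np.exp(-(((ca_arr - xi) / zeta) ** 2)) - 1.0)
    rate = np.where((ca_arr >= g.eps_lo) & (ca_arr <= g.eps_hi), 0.0, rate)
    if np.isscalar(ca):
        return float(rate)
    return rate


def integrate_elements(
    elements: ElementState,
    ca: np.ndarray,
    window_ms: float,
    g: GrowthConfig,
) -> ElementState:
    """Advance continuous element counts over one connectivity update.

    One Euler step of the growth curve (rate * window length), clamped at
    zero.  Spontaneous decay of vacant elements is a separate step
    (:func:`decay_vacant_elements`) applied at the end of the update
    cycle, because only elements left unused by synapse formation decay.
    """
    def advance(z: np.ndarray, kind: str) -> np.ndarray:
        return np.maximum(0.0, z + growth_rate(ca, kind, g) * window_ms)

    return ElementState(
        a=advance(elements.a, "axonal"),
        d_ex=advance(elements.d_ex, "dendritic"),
        d_in=advance(elements.d_in, "dendritic"),
    )


def decay_vacant_elements(
    elements: ElementState, bound: BoundCounts, g: GrowthConfig
) -> ElementState:
    """Spontaneous decay of vacant elements not used for synapse formation.

    The vacant portion (continuous count minus bound synapses) shrinks by
    exp(-1/tau_vac); tau_vac is expressed in connectivity updates, so one
    factor is applied per update, after the formation phase.
    """
    decay = math.exp(-1.0 / g.tau_vac)

    def dec(z: np.ndarray, bound_z: np.ndarray) -> np.ndarray:
        vacant = z - bound_z
        return np.where(vacant > 0, bound_z + vacant * decay, z)

    return ElementState(
        a=dec(elements.a, bound.axonal),
        d_ex=dec(elements.d_ex, bound.dendritic_ex),
        d_in=dec(elements.d_in, bound.dendritic_in),
    )


def distance_kernel(
    pos_i: np.ndarray, pos_j: np.ndarray, g: GrowthConfig
) -> np.ndarray | float:
    """Formation kernel K for a (postsynaptic, presynaptic) position pair.

    Gaussian flavour: exp(-d^2 / sigma^2) with d the Euclidean distance;
    flat flavour: 1.  Identical positions with i == j are excluded by the
    caller via :func:`kernel_matrix` (K = 0 on the diagonal).
    """
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    if g.kernel == "flat":
        shape = np.broadcast_shapes(pos_i.shape, pos_j.shape)[:-1]
        out = np.ones(shape)
        return float(out) if out.ndim == 0 else out
    d2 = ((pos_i - pos_j) ** 2).sum(axis=-1)
    out = np.exp(-d2 / g.sigma_um**2)
    return float(out) if np.ndim(out) == 0 else out


def kernel_matrix(pos: np.ndarray, g: GrowthConfig) -> np.ndarray:
    """Full n x n kernel with K[i, i] = 0 (no autapses); fixed for a run."""
    k = np.asarray(distance_kernel(pos[:, None, :], pos[None, :, :], g), dtype=float)
    np.fill_diagonal(k, 0.0)
    return k


# ---------------------------------------------------------------------------
# synapse deletion
# ---------------------------------------------------------------------------

def deletion_probabilities(
    w: np.ndarray,
    neuron: int,
    direction: str,
    sign: str,
    is_excitatory: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-connection deletion probabilities for one neuron and class.

    Every synapse of the class is equally likely to be picked, so a
    connection's probability is its multiplicity over the class total.
    Returns (partner indices, probabilities); the class must be non-empty.
    For ``direction='outgoing'`` the sign is fixed by the neuron's own type
    and partners range over all postsynaptic targets; for ``'incoming'``
    partners are the presynaptic sources of the requested sign.
    """
    if direction == "outgoing":
        counts = w[:, neuron]
        partners = np.flatnonzero(counts)
    elif direction == "incoming":
        source_mask = is_excitatory if sign == "excitatory" else ~is_excitatory
        counts = np.where(source_mask, w[neuron, :], 0)
        partners = np.flatnonzero(counts)
    else:
        raise ValueError("direction must be 'incoming' or 'outgoing'")
    total = counts[partners].sum()
    if total == 0:
        raise ValueError("neuron has no synapses of the requested class")
    return partners, counts[partners] / total


def _remove_surplus(
    counts: np.ndarray, surplus: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``surplus`` synapse units without replacement, proportionally
    to multiplicity; returns per-connection removal counts."""
    units = np.repeat(np.arange(counts.size), counts)
    chosen = rng.choice(units, size=surplus, replace=False)
    return np.bincount(chosen, minlength=counts.size)


def delete_surplus(state: NetworkState) -> None:
    """Break synapses wherever bound synapses exceed integer capacity.

    Processes the four classes sequentially (outgoing excitatory, outgoing
    inhibitory, incoming excitatory, incoming inhibitory), recomputing the
    bound counts as deletions from earlier classes take effect.  The
    partner's complementary element survives and becomes vacant.
    """
    w = state.w
    el = state.elements
    is_ex = state.population.is_excitatory
    rng = state.rng.deletion
    n = state.n

    cap_a = np.floor(el.a).astype(np.int64)
    cap_dex = np.floor(el.d_ex).astype(np.int64)
    cap_din = np.floor(el.d_in).astype(np.int64)

    # outgoing: sign is fixed by the presynaptic neuron's own type
    for out_mask in (is_ex, ~is_ex):
        for j in np.flatnonzero(out_mask):
            col = w[:, j]
            surplus = int(col.sum() - cap_a[j])
            if surplus > 0:
                w[:, j] -= _remove_surplus(col, surplus, rng)

    # incoming: restricted to the requested presynaptic sign
    for src_mask, cap in ((is_ex, cap_dex), (~is_ex, cap_din)):
        src = np.flatnonzero(src_mask)
        for i in range(n):
            row = w[i, src]
            surplus = int(row.sum() - cap[i])
            if surplus > 0:
                w[i, src] -= _remove_surplus(row, surplus, rng)


# ---------------------------------------------------------------------------
# synapse formation
# ---------------------------------------------------------------------------

@dataclass
class FormationDraw:
    """Outcome of one sign class's formation phase (diagnostics)."""

    probs: np.ndarray  # (n, n) per ordered-pair probabilities P[i, j]
    m_pot: int  # potential-synapse cap for the class
    accepted: np.ndarray  # (n, n) int increments applied to W


def vacant_counts(state: NetworkState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vacant (unbound) elements per neuron: (axonal, dendritic-ex, dendritic-in)."""
    b = state.bound()
    el = state.elements
    return (
        np.maximum(0, np.floor(el.a).astype(np.int64) - b.axonal),
        np.maximum(0, np.floor(el.d_ex).astype(np.int64) - b.dendritic_ex),
        np.maximum(0, np.floor(el.d_in).astype(np.int64) - b.dendritic_in),
    )


def formation_probabilities(
    a_vac: np.ndarray,
    d_vac: np.ndarray,
    source_mask: np.ndarray,
    kernel: np.ndarray,
) -> np.ndarray:
    """Per ordered-pair formation probabilities for one sign class.

    ``P[i, j] = A_vac[j] * D_vac[i] / (sum A_vac * sum D_vac) * K[i, j]``
    with presynaptic j restricted to ``source_mask`` and postsynaptic i
    over all neurons.  The total mass is <= 1 (K <= 1 and the diagonal is
    excluded by K); returns an all-zero matrix if either vacancy pool is
    empty.
    """
    a = np.where(source_mask, a_vac, 0).astype(float)
    tot_a = a.sum()
    tot_d = float(d_vac.sum())
    if tot_a == 0 or tot_d == 0:
        return np.zeros_like(kernel)
    return np.outer(d_vac, a) / (tot_a * tot_d) * kernel


def form_synapses(state: NetworkState) -> dict[str, FormationDraw]:
    """Recombine vacant elements into new synapses, one sign class at a time.

    For each class, at most M_pot = min(total vacant axonal, total vacant
    dendritic) uniform draws are compared against the accumulated pair
    probabilities (frozen for the whole update); a draw beyond the total
    mass forms nothing, and accepted draws are additionally capped per
    ordered pair by min(A_vac[j], D_vac[i]) evaluated at the start of the
    update — over-draws are rejected, not redirected.
    """
    w = state.w
    is_ex = state.population.is_excitatory
    rng = state.rng.formation
    a_vac, d_ex_vac, d_in_vac = vacant_counts(state)
    out: dict[str, FormationDraw] = {}

    for sign, src_mask, d_vac in (
        ("ex", is_ex, d_ex_vac),
        ("in", ~is_ex, d_in_vac),
    ):
        probs = formation_probabilities(a_vac, d_vac, src_mask, state.kernel)
        m_pot = int(min(np.where(src_mask, a_vac, 0).sum(), d_vac.sum()))
        accepted = np.zeros_like(w)
        if m_pot > 0 and probs.any():
            cum = np.cumsum(probs.ravel())
            total = cum[-1]
            draws = rng.random(m_pot)
            idx = np.searchsorted(cum, draws, side="left")
            idx = idx[draws < total]  # draws beyond the mass form nothing
            hits = np.bincount(idx, minlength=w.size).reshape(w.shape)
            cap = np.minimum(d_vac[:, None], np.where(src_mask, a_vac, 0)[None, :])
            accepted = np.minimum(hits, cap)
            w += accepted
        out[sign] = FormationDraw(probs=probs, m_pot=m_pot, accepted=accepted)
    return out


# ---------------------------------------------------------------------------
# full update cycle
# ---------------------------------------------------------------------------

@dataclass
class UpdateRecord:
    """Per-update diagnostics emitted by :func:`connectivity_update`."""

    t: int
    spike_counts: np.ndarray
    mean_ca_lpz: float
    mean_ca_intact: float
    synapses_by_region: dict[str, int]  # ex->ex counts by (source, target) region
    total_synapses: int


def region_synapse_counts(w_exex: np.ndarray, lpz_ex: np.ndarray) -> dict[str, int]:
    """Excitatory-to-excitatory synapse counts by (source, target) region."""
    lpz = lpz_ex
    intact = ~lpz_ex
    return {
        "lpz_lpz": int(w_exex[np.ix_(lpz, lpz)].sum()),
        "intact_lpz": int(w_exex[np.ix_(lpz, intact)].sum()),
        "lpz_intact": int(w_exex[np.ix_(intact, lpz)].sum()),
        "intact_intact": int(w_exex[np.ix_(intact, intact)].sum()),
    }


def connectivity_update(state: NetworkState) -> UpdateRecord:
    """One full update cycle.

    Phases, in order: (1) electrical activity over one window; (2) element
    growth on the window-end calcium; (3) breaking of surplus synapses;
    (4) formation of new synapses from vacant elements; (5) spontaneous
    decay of the vacant elements left unused by formation.  Advances
    ``state.t`` by one and returns diagnostics.
    """
    spike_counts = activity.simulate_window(state)
    g = state.config.growth
    state.elements = integrate_elements(
        state.elements, state.neurons.ca, state.config.schedule.window_ms, g
    )
    delete_surplus(state)
    form_synapses(state)
    state.elements = decay_vacant_elements(state.elements, state.bound(), g)

    pop = state.population
    lpz = pop.in_lpz
    ca = state.neurons.ca
    lpz_ex = lpz[pop.is_excitatory]
    record = UpdateRecord(
        t=state.t,
        spike_counts=spike_counts,
        mean_ca_lpz=float(ca[lpz].mean()) if lpz.any() else math.nan,
        mean_ca_intact=float(ca[~lpz].mean()) if (~lpz).any() else math.nan,
        synapses_by_region=region_synapse_counts(state.w_exex(), lpz_ex),
        total_synapses=int(state.w.sum()),
    )
    state.t += 1
    return record
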