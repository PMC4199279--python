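"""Electrical activity: Izhikevich membrane dynamics, synaptic filtering,
external-input schedule and the calcium activity trace.

One *window* of electrical simulation (default 500 ms at dt = 0.5 ms) is
run between consecutive connectivity updates.  All electrical state (v, u,
filtered drives, calcium, the one-step spike buffer) is carried across
windows, so the slow calcium trace (tau = 10 s) equilibrates over many
updates.

The window loop is compiled with numba for speed; the step-level functions
(`membrane_step`, `synaptic_drive`, `calcium_update`) are plain numpy and
define the semantics the kernel must match.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .config import IzhikevichParams, ScheduleConfig
from .state import NetworkState, Population


class NumericalError(RuntimeError):
    """Non-finite neuron state encountered during a window."""


# ---------------------------------------------------------------------------
# step-level operations (reference semantics, numpy)
# ---------------------------------------------------------------------------

def membrane_step(
    v: np.ndarray,
    u: np.ndarray,
    i_total: np.ndarray | float,
    dt: float,
    p: IzhikevichParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Euler step of the quadratic membrane model, original stepping.

    Following the source formulation of this neuron model, the membrane
    potential is advanced in two half-steps of dt/2 (the derivative
    re-evaluated in between, taming the stiff quadratic upstroke) while
    the recovery variable takes a single step of dt.  Returns
    ``(v, u, spiked)``; a spike (v >= v_spike after the update) resets v
    to c and adds d to u.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    h = 0.5 * dt
    v_new = v + h * (p.k1 * v * v + p.k2 * v + p.k3 - u + i_total)
    v_new = v_new + h * (p.k1 * v_new * v_new + p.k2 * v_new + p.k3 - u + i_total)
    u_new = u + dt * p.a * (p.b * v_new - u)
    spiked = v_new >= p.v_spike
    v_new = np.where(spiked, p.c, v_new)
    u_new = np.where(spiked, u_new + p.d, u_new)
    if not (np.all(np.isfinite(v_new)) and np.all(np.isfinite(u_new))):
        bad = int(np.flatnonzero(~(np.isfinite(v_new) & np.isfinite(u_new)))[0])
        raise NumericalError(f"non-finite membrane state at neuron {bad}")
    return v_new, u_new, spiked


def synaptic_drive(
    spikes: np.ndarray,
    w: np.ndarray,
    is_excitatory: np.ndarray,
    drive_ex: np.ndarray,
    drive_in: np.ndarray,
    dt: float,
    p: IzhikevichParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponentially filtered synaptic input, split by presynaptic sign.

    Each drive decays by exp(-dt/mu); every presynaptic spike adds the
    synapse multiplicity to the matching drive of the postsynaptic neuron.
    The net synaptic current is ``syn_strength * (drive_ex - drive_in)``.
    """
    decay = math.exp(-dt / p.mu)
    spikes = np.asarray(spikes, dtype=bool)
    ex_spikes = (spikes & is_excitatory).astype(np.int64)
    in_spikes = (spikes & ~is_excitatory).astype(np.int64)
    return (
        drive_ex * decay + w @ ex_spikes,
        drive_in * decay + w @ in_spikes,
    )


def calcium_update(
    ca: np.ndarray, spikes: np.ndarray, dt: float, p: IzhikevichParams
) -> np.ndarray:
    """Calcium trace: exponential decay plus a fixed increment per spike."""
    return ca * math.exp(-dt / p.tau_ca) + p.beta * np.asarray(spikes, dtype=float)


def input_mean(t: int, schedule: ScheduleConfig, p: IzhikevichParams) -> float:
    """Mean external drive at connectivity update ``t`` (non-LPZ neurons).

    Constant elevated drive during the initial growth plateau, then a
    logistic ramp from the plateau down to the baseline.  The plateau and
    the ramp disagree at the switch point; the printed piecewise form is
    kept as is.
    """
    if t < schedule.ramp_onset:
        return schedule.i_ext_growth
    x = (t - schedule.ramp_onset) / schedule.ramp_tau
    if x > 700.0:  # exp would overflow; the ramp has long converged
        return p.i_ext_mean
    span = schedule.i_ext_growth - p.i_ext_mean
    return span / (1.0 + math.exp(x)) + p.i_ext_mean


def external_input(
    t: int,
    neuron: int,
    population: Population,
    lesioned: bool,
    schedule: ScheduleConfig,
    p: IzhikevichParams,
    rng: np.random.Generator,
) -> float:
    """Sample the external input of one neuron at one integration step.

    LPZ neurons receive exactly zero (mean and noise) from lesion onset on.
    """
    if t < 0:
        raise ValueError("update index must be non-negative")
    if lesioned and population.in_lpz[neuron]:
        return 0.0
    return input_mean(t, schedule, p) + p.i_ext_sd * rng.standard_normal()


# ---------------------------------------------------------------------------
# compiled window loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def _window_kernel(  # pragma: no cover - exercised via simulate_window
    v, u, drive_ex, drive_in, ca, last_spiked, spike_counts,
    w, is_ex, active, noise, i_mean,
    dt, decay_mu, decay_ca,
    k1, k2, k3, a, b, c, d, v_spike, syn_strength, beta,
):
    n_steps = noise.shape[0]
    n = v.shape[0]
    inc_ex = np.zeros(n, dtype=np.int64)
    inc_in = np.zeros(n, dtype=np.int64)
    for t in range(n_steps):
        # drives: decay, then add last step's spikes (one-step delay);
        # increments are accumulated in exact integer arithmetic
        for i in range(n):
            inc_ex[i] = 0
            inc_in[i] = 0
        for j in range(n):
            if last_spiked[j]:
                if is_ex[j]:
                    for i in range(n):
                        inc_ex[i] += w[i, j]
                else:
                    for i in range(n):
                        inc_in[i] += w[i, j]
        for i in range(n):
            drive_ex[i] = drive_ex[i] * decay_mu + inc_ex[i]
            drive_in[i] = drive_in[i] * decay_mu + inc_in[i]
            i_syn = syn_strength * (drive_ex[i] - drive_in[i])
            i_ext = i_mean + noise[t, i] if active[i] else 0.0
            i_tot = i_syn + i_ext
            h = 0.5 * dt
            vi = v[i]
            vi = vi + h * (k1 * vi * vi + k2 * vi + k3 - u[i] + i_tot)
            vi = vi + h * (k1 * vi * vi + k2 * vi + k3 - u[i] + i_tot)
            u[i] = u[i] + dt * a * (b * vi - u[i])
            spiked = vi >= v_spike
            if spiked:
                vi = c
                u[i] += d
                spike_counts[i] += 1
            v[i] = vi
            last_spiked[i] = spiked
            ca[i] = ca[i] * decay_ca + (beta if spiked else 0.0)


def simulate_window(
    state: NetworkState,
    t: int | None = None,
    duration_ms: float | None = None,
    dt_ms: float | None = None,
) -> np.ndarray:
    """Advance the electrical state over one window; return spike counts.

    ``t`` defaults to the state's current connectivity-update index; the
    window length and step default to the configured schedule.  Noise is
    one Gaussian draw per neuron per integration step, pre-generated from
    the state's noise stream so the compiled loop stays deterministic.
    """
    cfg = state.config
    p = cfg.neuron
    sched = cfg.schedule
    if t is None:
        t = state.t
    duration_ms = sched.window_ms if duration_ms is None else duration_ms
    dt = sched.dt_ms if dt_ms is None else dt_ms
    n_steps = duration_ms / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("duration_ms must be a multiple of dt_ms")
    n_steps = round(n_steps)

    ns = state.neurons
    active = state.active_mask()
    noise = p.i_ext_sd * state.rng.noise.standard_normal((n_steps, state.n))
    spike_counts = np.zeros(state.n, dtype=np.int64)
    _window_kernel(
        ns.v, ns.u, ns.syn_drive_ex, ns.syn_drive_in, ns.ca,
        ns.last_spiked, spike_counts,
        state.w, state.population.is_excitatory, active, noise,
        input_mean(t, sched, p),
        dt, math.exp(-dt / p.mu), math.exp(-dt / p.tau_ca),
        p.k1, p.k2, p.k3, p.a, p.b, p.c, p.d, p.v_spike,
        p.syn_strength, p.beta,
    )
    if not np.all(np.isfinite(ns.v)):
        bad = int(np.flatnonzero(~np.isfinite(ns.v))[0])
        raise NumericalError(f"non-finite state at neuron {bad} in window T={t}")
    return spike_counts


def simulate_window_reference(
    state: NetworkState,
    t: int | None = None,
    duration_ms: float | None = None,
    dt_ms: float | None = None,
) -> np.ndarray:
    """Pure-numpy window loop composing the step-level operations.

    Bit-compatible with :func:`simulate_window` given identical state and
    noise stream; kept as the executable definition of the window
    semantics and used to validate the compiled kernel.
    """
    cfg = state.config
    p = cfg.neuron
    sched = cfg.schedule
    if t is None:
        t = state.t
    duration_ms = sched.window_ms if duration_ms is None else duration_ms
    dt = sched.dt_ms if dt_ms is None else dt_ms
    n_steps = round(duration_ms / dt)

    ns = state.neurons
    active = state.active_mask()
    noise = p.i_ext_sd * state.rng.noise.standard_normal((n_steps, state.n))
    mean = input_mean(t, sched, p)
    spike_counts = np.zeros(state.n, dtype=np.int64)
    for step in range(n_steps):
        ns.syn_drive_ex, ns.syn_drive_in = synaptic_drive(
            ns.last_spiked, state.w, state.population.is_excitatory,
            ns.syn_drive_ex, ns.syn_drive_in, dt, p,
        )
        i_syn = p.syn_strength * (ns.syn_drive_ex - ns.syn_drive_in)
        i_ext = np.where(active, mean + noise[step], 0.0)
        ns.v, ns.u, spiked = membrane_step(ns.v, ns.u, i_syn + i_ext, dt, p)
        ns.last_spiked = spiked
        ns.ca = calcium_update(ns.ca, spiked, dt, p)
        spike_counts += spiked
    return spike_counts
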