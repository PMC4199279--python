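# Methods

## Model overview

The simulator couples fast electrical dynamics to slow structural
dynamics. Electrical activity is computed in *windows* (default 5 s of
simulated time); after each window the structural rules run once — this
window-plus-rewiring cycle is one *connectivity update*, the unit in
which all schedules are expressed. One update cycle is, in order:

1. **Activity.** Izhikevich membrane dynamics for every neuron, with
   exponentially filtered synaptic input and a calcium trace.
2. **Element growth.** Continuous axonal/dendritic element counts take
   one Euler step of the calcium-dependent growth curve (rate × window
   length), clamped at zero.
3. **Synapse breaking.** Wherever a neuron's bound synapses exceed the
   integer capacity floor(count) of the hosting element class, surplus
   synapse units are removed, sampled proportionally to connection
   multiplicity; the partner's element survives and becomes vacant. The
   four classes are processed sequentially (outgoing excitatory,
   outgoing inhibitory, incoming excitatory, incoming inhibitory), each
   seeing the deletions of the previous ones.
4. **Synapse formation.** For each sign class, at most
   M = min(Σ vacant axonal, Σ vacant dendritic) inverse-CDF draws are
   made from the pair distribution P[i,j] ∝ A_vac[j]·D_vac[i]·K[i,j]
   (probabilities frozen within the update; a draw beyond the total mass
   forms nothing; accepted draws are capped per ordered pair by
   min(A_vac[j], D_vac[i]) at the start of the update).
5. **Vacancy decay.** The vacant portion of each element count left
   unused by formation shrinks by exp(−1/τ_vac). Decay deliberately runs
   *after* formation: only elements that were offered for binding and
   remained unused decay. Running it earlier destroys sub-integer growth
   progress and, at short windows, prevents any synapse from ever
   forming.

## Electrical integration

The membrane equations are advanced with the stepping scheme of the
original published formulation of this neuron model: per step of
dt = 1 ms, the membrane potential v takes two half-steps of dt/2 (the
quadratic term re-evaluated in between) and the recovery variable u one
full step; external noise is redrawn every step. This choice is
load-bearing. Plain single-step Euler (at 1, 0.5 or 0.1 ms) yields
f(I = 8 mV/ms) ≈ 83 Hz, i.e. calcium ≈ 0.83 — *above* the homeostatic
range — so the elevated growth-phase input would cause element removal
and no network could ever grow from scratch. The half-step scheme yields
f(8) ≈ 53 Hz (calcium ≈ 0.53, mid growth-zone) and f(5) ≈ 33 Hz, which
makes the growth protocol meaningful: networks must build substantial
recurrent drive (≈ 19 excitatory synapses per neuron at equilibrium) to
hold calcium in the range once the input has ramped down to 5 mV/ms.

Spike transmission has a one-step delay: spikes at step t enter the
postsynaptic filtered drives at step t+1, across window boundaries too.
The window loop is compiled with numba; the step-level functions
(`membrane_step`, `synaptic_drive`, `calcium_update`) are plain numpy
and a test verifies the compiled loop is bit-identical to their
composition.

## Window length

Nothing in the model pins how much electrical time elapses between
connectivity updates; it rescales the structural rates relative to the
fixed input-ramp schedule (which is expressed in updates). The default
is 5000 ms, for two reasons. First, growth must track the input ramp:
the ramp withdraws 3 mV/ms of drive over ~800 updates, and at windows of
≤1000 ms the peak growth ν·window ≤ 0.1 elements/update cannot replace
that drive with synapses fast enough — networks collapse to zero
connectivity mid-ramp. Second, 5000 ms is half the calcium time constant,
so the calcium a connectivity update acts on is a meaningful average of
the activity since the previous update. Growth uses the window-end
calcium (the trace itself is a 10 s low-pass, so end-of-window and
window-average differ little).

## Population geometry and the LPZ

Excitatory neurons sit on the grid points plus uniform jitter of
±0.1 × spacing per coordinate; inhibitory neurons sit on the interstitial
sub-lattice (one per 2×2 block, at the block centre), jittered the same
way; if a non-default inhibitory count does not tile that sub-lattice the
positions fall back to uniform random interstitial placement. LPZ
membership is decided at build time by the jittered position falling
inside the configured rectangle *inflated by the jitter amplitude*, so
that the set of flagged neurons is exactly the block of grid anchors the
rectangle encloses (the default rectangle, 750–1800 µm on both axes,
flags exactly the 8×8 block of grid columns/rows 5–12) and does not
depend on the jitter draw.

## Randomness

One seed spawns four independent generator streams — jitter, activity
noise, deletion, formation — so structural randomness is reproducible
independently of how much noise the electrical windows consume.
Identical seeds give bit-identical connectivity trajectories.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| ν | 1e-4 ms⁻¹ | peak element growth rate |
| η_A, η_D | 0.4, 0.1 | minimum calcium for axonal/dendritic outgrowth (preset-dependent) |
| ε, range | 0.7, [0.65, 0.75] | homeostatic set-point and dead-band |
| τ_vac | 10 updates | vacant-element decay constant |
| σ | 150 µm | Gaussian formation kernel width (flat kernel: random topology) |
| β, τ_Ca | 0.001, 10 s | calcium increment per spike and decay |
| μ | 5 ms | synaptic filter decay; ±1 mV/ms pulse per synapse per spike |
| window, dt | 5000 ms, 1 ms | electrical time per update, integration step |

## Scaled-down preset

`scale="mini"` is a first-class configuration used by the test suite and
the acceptance script: a 10×8 excitatory grid with 20 inhibitory
neurons, a central 4×4-grid-point LPZ, 2000 growth and 3000 post-lesion
updates. It reproduces the qualitative full-scale phenomenology (growth
to a dense in-range equilibrium, outside-in partial repair, the
three-regime ordering) at ~80 s per run instead of hours.

## Graph metrics

All measures act on the excitatory→excitatory multiplicity matrix with
edge length 1/W. Unreachable pairs are excluded from the characteristic
path length and their fraction reported alongside; efficiency counts
1/∞ = 0 and is defined on any graph. Clustering follows the weighted
directed triangle formalism (weights normalized by the maximum and
cube-rooted); nodes with fewer than two neighbours score zero. Local
efficiency of node i averages inverse distances among i's neighbours on
the neighbour-induced subgraph with i removed. Betweenness uses Brandes'
weighted-directed algorithm; because 1/W lengths are ratios of small
integers, genuinely equal path lengths differ by floating-point dust
(e.g. 1/3 + 1/6 vs 1/2), so equal-length paths are detected with a
relative tolerance of 1e-12 rather than exact comparison. Small-world
normalization draws Erdős–Rényi nulls by placing the same number of
synapses uniformly over ordered non-self pairs, multiplicities preserved;
10 replicates are averaged per evaluation and the spread is reported.

## Numerical choices

- Integer binding capacity = floor of the continuous element count.
- Both dendritic element classes share η_D.
- Formation probabilities are frozen within an update; the per-pair cap
  handles over-draws by rejection, not redirection.
- Growth-curve width ζ is fixed by requiring zero crossings exactly at η
  and ε: ζ = (η − ε)/(2√ln 2).
- Degenerate inputs: empty deletion classes are a caller error; empty
  vacancy pools simply form nothing; an edgeless graph yields NaN path
  length (flagged), zero clustering/efficiency.

## What the experiments do and do not show

The synthetic experiments emulate deafferentation of a cortical sheet:
homogeneous cell types, uniform synapse strength (multiplicity is the
only weight), 2-D geometry with a single isotropic kernel, and total,
instantaneous input loss in the LPZ. Passing tests therefore demonstrate
properties of the *model* — homeostatic convergence, outside-in versus
recurrent repair, increasing randomness of the excitatory graph — not
properties of cortical tissue; none of the biological heterogeneity
(cell-type diversity, conductance synapses, graded deafferentation,
distance-dependent delays) is represented.

## Known limitations

- **Partial LPZ repair in the physiological regime.** The neuron model
  has a hard rheobase (~4 mV/ms; below it, zero firing). After input
  removal, LPZ neurons whose recurrent drive falls below rheobase go
  completely silent; their calcium decays to zero, which is *below* the
  dendritic growth minimum η_D, so their dendritic scaffold is removed
  before ingrowth from the intact zone can reach them — an irreversible
  death, affecting the LPZ interior (more than one kernel width from the
  border). In scaled-down physiological runs roughly half of the LPZ
  recovers fully into the homeostatic range while the interior dies,
  leaving the final mean LPZ calcium near 0.3; at full scale the
  surviving fraction is smaller still. All other signatures (intact→LPZ
  ingrowth, pruning of LPZ efferents, recurrent-case ordering,
  decreasing small-worldness, λ ≈ 1) are robust to this. A dynamical
  regime with synchronized population bursts could entrain the interior
  and complete the repair, but does not arise under the parameterization
  implemented here (per-neuron white noise, asynchronous tonic firing);
  mean LPZ betweenness centrality consequently *falls* after the lesion
  in these runs (dead nodes carry none), instead of rising.
- Full-scale runs (20×16 grid, 20 000 updates) take ~45 minutes on one
  CPU; the betweenness implementation is pure Python and dominates when
  the metric battery is evaluated densely in time.
- The homeostatic range introduces a rate discontinuity at its edges, and
  the growth-phase input plateau meets the logistic ramp with a small
  step (8 → 6.5 mV/ms at update 500); both are implemented as specified
  by the protocol rather than smoothed.
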