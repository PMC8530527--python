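# Methods

## The two-state sensor

The sensor is a discrete-time Markov chain over {sensitive, insensitive}.
Per step of duration `1/fs`, a sensitive sensor spikes with probability
`P_B = clip((K1·s(t) + K2·s0)·λ*, 0, 1)` and becomes insensitive; an
insensitive sensor regenerates with probability `P_C = clip(K3·λ*, 0, 1)`
and cannot spike.  `λ* = f/fs` converts per-wavelength rates into per-step
probabilities, so that `s0` spikes per stimulus wavelength and `K3`
regenerations per wavelength come out correctly: `fs/f` steps span one
wavelength.  The construction is agnostic about mechanism; the insensitive
state can be read as a spent vesicle pool, the regeneration rate as pool
replenishment, and `K2` as cholinergic efferent inhibition, which acts only
on the spontaneous term.  Suppression of evoked spiking is emergent.

Step ordering: the spike decision is taken first; a sensor that regenerates
during a step can spike from the next step on.  This makes the stationary
spike rate under constant drive exactly `P_B·P_C/(P_B+P_C)` per step and
imposes a one-step refractory period, so in the instant-regeneration limit
(`P_C = 1`) the per-step rate is `P_B/(1+P_B)`, approaching independent
Bernoulli trials only for small `P_B`.  Both limits are covered by tests.

A single uniform random number per step decides both the spike (if
sensitive) and the regeneration (if insensitive); the two comparisons are
mutually exclusive, so independence is preserved while halving the random
stream.

### Canonical parameter sets

Two reference sets are shipped: `ADAPTING_SENSOR` (K1=4, K3=0.04, s0=40)
and `NONADAPTING_SENSOR` (K1=0.04, K3=4, s0=4).  The names come from the
package's own empirical classifier (`classify_parameter_set`): a set is
adapting when the exact expected evoked count over the last two stimulus
cycles falls below τ = 0.5 times the first two (gain far above regeneration
depletes the pool within the first cycle; fast regeneration cannot be
depleted).  Classification uses deterministic occupancy propagation, not
Monte Carlo, so it has no seed.

### Sessions and the re-equilibration segment

A simulated sweep is a stimulated segment of 20 stimulus wavelengths
(stimulus and inhibition on) followed by an equally long re-equilibration
segment.  By default (`requil_mode="off"`) all drive is switched off in the
second segment so the pool silently regenerates; this is what produces the
adapting set's strong first-cycle response each sweep.  The alternative
`requil_mode="release"` restores uninhibited spontaneous drive instead and
is the protocol that exhibits rebound spiking after release from
inhibition: during suppression the pool fills above its resting level, and
the restored drive discharges it as a transient rate overshoot.

Sweeps are chained (state carries over) and the first two sweeps of every
chain are discarded as burn-in.  For large Monte Carlo budgets the sweep
count is split across parallel chains of 10 sweeps (2 burn-in + 8 kept),
which vectorizes cleanly; after burn-in each chain is cycle-stationary, so
this layout is statistically equivalent to one long chain.

### Calibrating inhibition

`K2` is not `R_S`: the observed spontaneous suppression is nonlinear in the
constant.  `calibrate_inhibition` therefore inverts the *measured* ratio.
Three methods:

- `expected` (default): bisection on the ratio of exact expected
  spontaneous counts from occupancy propagation — deterministic, no Monte
  Carlo noise, matched to the session protocol;
- `session`: bisection on simulated session rates with common random
  numbers, for when a stochastic end-to-end calibration is wanted;
- `stationary`: closed-form inversion of the stationary rate
  `r(k2) = P_B(k2)·P_C/(P_B(k2)+P_C)`, appropriate when the sensor sits at
  its resting state (e.g. the pre-bout state in population simulations);
  the inverse is `k2 = t·P_C / (P_B(1) + P_C − t·P_B(1))` for target ratio
  `t`.

## Spike statistics

Phase is stored both as the fraction `t/T` and in radians (`2π·t/T`); all
trigonometry uses radians.  Vector strength is the mean resultant length;
circular variance is `−2·log VS` (+∞ at VS = 0).  Phase quantiles
(0.1/0.5/0.9) are ordinary linear-interpolation (type-7) quantiles computed
after unwrapping phases to `(−π, π]` around the cell's reference median —
valid because responses concentrate in the sense half-cycle, away from the
cut.  The reference median is the median phase of all CD-OFF spikes of that
cell at that frequency (computed once, after unwrapping around the circular
mean), which removes cell-specific conduction delays before cells are
compared.  Phases are pooled across sweeps before quantiles rather than
averaging per-sweep quantiles; with the low per-sweep counts typical here,
per-sweep quantiles would be dominated by small-sample bias.

Zero-spike intervals are reported with `n = 0` and missing phase fields
rather than zero-imputed, so summaries average over observed intervals.
PSTH bins exactly partition the sweep (the requested width is adjusted to
the nearest exact divisor), making rate × width × sweeps sum to the total
count.

## CD analysis

Spikes are labeled on two independent axes with half-open `[start, end)`
epochs: evoked/spontaneous by stimulus-on epochs, CD ON/OFF by swim bouts.
An epsilon of 1e-9 periods guards interval indexing against floating-point
boundary error.  `R_S` and `R_E` divide *exposure-time-normalized* rates
(spikes per second of time in each cell of the 2×2 label grid), since ON
and OFF observation times differ by an order of magnitude; this makes the
ratios invariant under uniform time rescaling.

Adaptation is the mean evoked count of the first two stimulus intervals
over the last two (both orientations reported), from CD-OFF spikes only;
at least four intervals are required.

Response types are found by k-means (k = 3, 50 restarts, fixed seed) on
(R_S, R_E) standardized to unit variance.  Groups are relabeled
canonically by ascending mean adaptation when adaptation values are
supplied — group 1 is always the weakest-adapting — otherwise a documented
heuristic places the divergent group (R_E ≫ R_S) last and orders the rest
by ascending R_S.  Per-group Δinhibition = mean(R_S − R_E) is reported; it
is ≈ 0 when spontaneous and evoked activity are suppressed alike.

The dependence of R_E on R_S and adaptation is summarized by ordinary
least squares of `R_E ~ 0 + R_S + adaptation + R_S:adaptation` with
approximate 95% confidence intervals.  The intercept is omitted so the
predictor CIs can be compared against zero.  This is a deliberate
fixed-effects simplification: no per-individual or per-frequency random
effects, no quasi-Poisson links, no spline smooths, and consequently
coefficients estimated from real recordings by mixed models are not
comparable quantities.

Swim-normalized time courses map each eligible swim to relative time
(bout = [0, 1], equal-duration post-swim window = (1, 2]) and average per
bin across swims.  Eligibility follows the labeling rules: fully inside a
stimulus epoch for evoked curves, fully outside for spontaneous ones,
straddling swims dropped.  Both the mean count per swim (scale-invariant)
and the mean rate in spikes/s are reported, with the number of
contributing swims as the bin weight; this weighted-binned-mean is a
simplification of weighted spline smoothing over the same quantity.

## Population simulations

A model fish has 30 independent sensors with `K1` and `K3` drawn
log-uniformly on [0.04, 4] — bracketing both canonical regimes — and
constant `s0 = 4`.  Ranges are configurable; log-uniform sampling spreads
sensors evenly across orders of magnitude of gain and regeneration.  Each
sensor's `k2` is calibrated per sensor to the common target `R_S`
(heterogeneous sensors need different constants for the same measured
suppression), using the stationary method because a bout starts from the
resting state.  Each fish is simulated for one 20-wavelength bout at 20 Hz
with stimulus and inhibition on together, sensors starting at their
stationary spontaneous occupancy; per-sensor trains are pooled per fish.

ISIs are computed within each fish and pooled across the 1,000 fish (not
per-fish densities averaged).  Coincident spikes from different sensors in
the same time step yield zero ISIs; these are dropped and counted.  The
ISI histogram uses 1-ms bins; peaks are local maxima above a configurable
prominence (default 10% of the density maximum), and the
integer-multiple fraction counts ISIs within ±10% of `n·T` for integer
n ≥ 1.

## The synthetic experiment generator

The generator emulates the recording protocol: 100 sweeps of 1 s stimulus
on / 2 s off at 5, 20 or 40 Hz, with spontaneous swim bouts during which
the CD is active.  Swim onsets follow a Poisson process (0.4 bouts/s,
matching roughly a hundred bouts per session) thinned so each bout is
followed by a free post-swim window of its own duration; durations are
log-normal (median 0.15 s, log-sd 0.5) clipped to [0.06, 1.0] s, the
observed range of larval bouts.  CD onset and offset are instantaneous at
bout boundaries; graded transmitter decay is out of scope.

Cells belong to three planted response types: group 1 weakly adapting with
strong inhibition (target R_S = 0.2), group 2 a mixture of the adaptation
regimes with weak inhibition (0.9), group 3 strongly adapting with strong
inhibition (0.2).  The presets (group 1: K1=0.6, K3=4, s0=20; adapting
preset: K1=12, K3=0.3, s0=0.4) are chosen to reproduce the qualitative
group structure — they are not fitted physiological values.  The adapting
preset sits on a genuine model trade-off: visible first-to-last-interval
adaptation requires the pool to refill between stimulus epochs, i.e. weak
spontaneous drive (`s0` small relative to `K3`), while a measurable `R_S`
requires spontaneous spikes; the preset balances the two (≈ 3 Hz
spontaneous rate, first/last ≈ 1.5).  Parameters get log-normal jitter
(sd 0.15) per cell and each cell has its own swim-bout train.

What the generator does *not* emulate: electrode noise, spike-sorting
errors, graded inhibition strength within a bout, slow drifts in
excitability, correlated swim kinematics, or inter-sensor correlations.
Passing recovery tests on these data therefore shows that the pipeline's
logic is correct under the model's own assumptions, not that it is robust
to every artifact of real recordings.

## Problem sizes and numerical choices

Simulated checks use 2,000 post-burn-in sweeps per inhibition level for
ratio measurements (standard errors of a few percent at the strongest
inhibition), 1,000 fish for population ISI statistics, and 30-cell
datasets for end-to-end recovery; these sizes give comfortable
signal-to-noise for every tested effect.  All randomness flows through
`numpy.random.default_rng` with seeds derived deterministically from a
single user seed via `SeedSequence.spawn`; identical seeds give
bit-identical spike tables.  Probability clipping is applied at the
transition-matrix level and flagged.  Ratio standard errors use the delta
method on per-sweep count dispersion.

## Known limitations

- The sensor is a single-vesicle caricature: it cannot represent graded
  pool sizes, so realistic combinations of strong adaptation and high
  spontaneous rate are unreachable (see the preset trade-off above).
- The CD constant multiplies only the spontaneous term, so a sensor with
  nonzero stimulus gain retains an inhibition-independent evoked floor;
  at strong inhibition this makes `R_E/R_S` of even a nonadapting sensor
  exceed 1 by a few percent rather than equal it exactly.
- Re-equilibration assumes either total silence or full release; partial
  post-swim states are not modeled.
- The interaction regression and binned time courses are fixed-effects
  simplifications of hierarchical analyses and inherit their biases when
  units are very unbalanced.
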