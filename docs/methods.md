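# Methods

## The measurement this package models

In a three-bead laser-trap assay an actin filament, strung between two
optically trapped microspheres, is lowered onto a pedestal bead coated
with a small team ("mini-ensemble", ~4–5 molecules) of single-headed
myosin motors. Motor binding drags the bead–actin–bead dumbbell away
from the trap center; the trap acts as a linear spring, so force is
`F = k_trap · x` with `x` the displacement (nm) and `k_trap` the summed
two-trap stiffness (pN/nm). Raising the laser power raises `k_trap`, so
the same displacement costs more force — that is how resistive load is
titrated. The analysis asks how the detachment rate of the ensemble
depends on that load, separately for a load-*accelerated* (slip)
pathway driven by phosphate rebinding and a load-*slowed* (catch-like)
pathway limited by ADP release, and summarizes each with the Bell
relation

    k_det(F) = k0 · exp(F · d / kT),

where `d` (nm) is the distance to the transition state (the slope of
`ln k` in units of kT per pN) and `k0` the unloaded rate. kT is fixed
at 4.116 pN·nm (298.15 K) from k_B = 1.380649e-2 pN·nm/K; a single
`thermal_energy()` function is the only source of this constant.

Because raw trap records for this kind of experiment are not publicly
deposited, the package carries a first-class synthetic-record generator
that plays the role of the instrument, with ground-truth event labels
for validating every downstream stage.

## Synthetic records (`simulate`)

**Bead noise.** The trapped dumbbell is an overdamped harmonic degree of
freedom: an Ornstein–Uhlenbeck process with stiffness `k` and drag
`gamma`. We use the exact discretization
`x[n+1] = µ + a(x[n] − µ) + σ√(1−a²)·z`, `a = exp(−k·dt/gamma)`,
`σ² = kT/k`, so the stationary variance equals the equipartition value
at any sampling rate and the lag-1 autocorrelation is `exp(−k·dt/gamma)`
exactly. Default `gamma = 1.9e-5 pN·s/nm` (a ~1 µm sphere in water)
gives a relaxation time of ~0.2–0.5 ms at the stiffnesses used —
resolved but not oversampled at 5 kHz.

**Mechanics of attachment.** Each attached head has completed one 7 nm
powerstroke and acts as a spring `k_head` in parallel with the other
attached heads, in series with the trap. With N heads attached and
cumulative strokes S (nm), the quasi-static mean bead position is
`µ = S·N·k_head/(k_trap + N·k_head)` and the bead's residual Brownian
motion runs at effective stiffness `k_trap + N·k_head` — reproducing the
two experimental signatures of binding, a mean shift and a variance
drop. `k_head = 0.6 pN/nm` (within the measured range of myosin
cross-bridge stiffness) keeps the bound-state mean close to S even when
only one head remains attached.

**Detachment kinetics.** Every attached head carries two independent
Bell pathways:

    h = k_adp0·exp(−load·d_adp/kT)  +  pi_mM·k_pi0_per_mM·exp(+load·d_pi/kT)

The first (ADP-release-limited, lumped with the subsequent fast
ATP-induced dissociation) is slowed by load (`d_adp = 0.9 nm` by
default); the second (phosphate rebinding to the AM.ADP state followed
by rapid dissociation) is proportional to [Pi] and accelerated by load
(`d_pi = 4.1 nm`, `k_pi0_per_mM = 2.5/30 s⁻¹mM⁻¹`, i.e. 2.5 s⁻¹
unloaded at 30 mM). `load` is the full ensemble force `F = k_trap·µ` by
default (`load_sharing="total"` — at peak force every attached head
experiences the resistive load); `"equal"` (F/N) is available as an
option. "total" is the default because with it the condition-level
Bell fit of the pipeline estimates the generating `d` directly, whereas
equal division makes the ensemble fit report roughly `d/N̄`, which would
disconnect the generator's parameters from what the analysis measures.

**Attachment.** Three features that a bare constant-rate attach/detach
chain lacks, all standard in motor-ensemble modelling:

* *slow initiation* — a detached filament finds the motor field at
  `k_init = 2 s⁻¹`, setting the ~0.5 s dwell between events seen in
  records;
* *cooperative in-event binding* — once one head holds the filament
  down, the remaining available heads bind at `k_attach = 40 s⁻¹` each,
  Bell-suppressed by load with `d_attach = 1.5 nm` (binding a strained
  site is harder: this is the stall mechanism). Without this
  suppression the chain is *transient* at 0 mM Pi: the catch pathway
  plus unbounded step accumulation lets force ratchet up until
  detachment effectively stops and runs never end;
* *refractory recovery* — a head that detaches must process its bound
  nucleotide and re-prime before rebinding (`k_recover = 1 s⁻¹`), and
  the whole pool resets during the detached dwell. Events are therefore
  nearly one-shot (≤ n_heads strokes with occasional rebinds), which
  concentrates the per-event step count and makes the mean displacement
  roughly stiffness-independent — the pattern real records show.

These kinetic defaults were frozen once against the reported
phenomenology of the assay (mean peak displacements ≈ 25–30 nm ≈ 4
powerstrokes; lifetimes 0.1–0.35 s, rising ~25–50% from 0.04 to
0.10 pN/nm without Pi and falling below half the control with 30 mM Pi;
peak forces ~1–2.8 pN; condition detachment rates 5–30 s⁻¹) and against
the requirement that the pipeline's Bell fit recover the generating
`d_pi` — the generator's own calibration.

**Painting and truth.** Head transitions are simulated exactly
(Gillespie); between transitions the bead runs the OU recursion at the
current (µ, k_eff), sampled segment-wise with `scipy.signal.lfilter`.
Transition times are rounded to the nearest sample when painting;
events shorter than one sample are dropped from the truth (no detector
could see them). A `simulate_event_metrics` fast path runs the kinetics
only and returns per-event noiseless measurements (lifetime, peak µ,
peak force, time from the final plateau to detachment) for experiments
needing 10⁵ events.

**What the generator does not emulate.** Instrument drift, low-frequency
noise and filament compliance; bead inertia (overdamped limit);
per-head strain bookkeeping (a detached head's strain redistributes
instantly through the mean-field spring); assistive loads between heads.
Passing tests therefore demonstrate correctness of the analysis under
the model's assumptions, not robustness to instrument pathologies.

## Trap calibration (`calibration`)

Equipartition: `k̂ = kT / var(x)` with the unbiased (n−1) variance after
mean subtraction (tolerates trap-center offset). 10 s at 5 kHz
(n = 50 000 correlated samples, ~2 000 effective) recovers k within a
few percent; the acceptance checks use 5%. The positional histogram
(density=True) and its Gaussian fit provide the energy-well view and an
internal consistency check (fitted σ² vs sample variance). No
power-spectrum calibration is provided — the workflow being reproduced
uses equipartition only.

## Event detection (`detect`)

1. **Window features**: running mean and (n−1) variance over 100-sample
   windows advanced by 25 samples (one-quarter of the width; the
   three-quarter-overlap reading, step 75, is supported via
   `--window-step`). Trailing partial windows are dropped.
2. **Two-state HMM**: Gaussian emissions over (mean, log(variance+1e-6))
   with diagonal covariance, fitted by Baum–Welch (tol 1e-6, ≤ 500
   iterations; `hmmlearn`). The EM start point is a deterministic 1-D
   2-means on the log-variance feature, which makes decodes independent
   of the RNG seed on separated data and avoids local optima that split
   on the mean feature. States are relabeled so state 0 is unbound
   (larger log-variance mean). If the two states are closer than 3
   within-state SDs of the tighter state in log-variance the record is
   declared single-regime (a chance split of one Gaussian produces a
   ~2.7 SD gap; genuine bound/unbound regimes separate by ≥ 8) and the
   decode is all-unbound with a warning.
3. **Decoding**: Viterbi. A maximal run of bound windows [i, j] maps to
   coarse sample bounds [starts[i], starts[j] + width). Runs shorter
   than `min_event_windows` (default 1 window = 20 ms) are discarded.
4. **Changepoint refinement**: within ±2 window widths of each coarse
   boundary, the boundary is re-estimated as the split maximizing the
   exact two-segment Gaussian log-likelihood (each segment its own mean
   and MLE variance, cumulative-sum implementation, minimum segment 5
   samples, variance floor 1e-12, earliest-tie). A running 50-sample
   two-window variant (the likelihood-ratio gain of splitting the
   surrounding 100 samples) is available as `--cp-method window`.
   Degenerate neighborhoods (< 10 samples a side) or refinements that
   would invert an event keep the coarse bounds with a warning.

Coordinates are 0-based, intervals half-open. On simulated ensembles
the detector reaches ≥ 0.9 recall on truth events ≥ 2 window widths,
precision ≈ 1, and median boundary error of a few samples.

## Per-event mechanics (`features`)

Peak displacement is the maximum 5 ms (25-sample; rounded for other
rates) running mean inside the event, ties to the earliest window;
events shorter than the window fall back to the whole-event mean with a
warning. Peak force is `k_trap` (metadata, or the calibrated estimate
with `--use-calibration`) times peak displacement. `T_PF` runs from the
start of the maximal window to the event end; `k_det = 1/T_PF`.

Condition summaries report means ± SEM and the condition detachment
rate as `1/mean(T_PF)` — the rate of the mean dwell — rather than the
mean of per-event rates, which is badly biased upward by short dwells;
the mean-of-rates is also reported for comparison. SEM of the rate
follows by first-order propagation. Single-event groups carry SEM 0 and
an explicit flag.

## Bell fitting (`bell`)

Weighted nonlinear least squares in (ln k0, d) (positivity of k0 for
free, well-conditioned), seeded by the exact log-linear solution, so
noiseless points are recovered to machine precision. Weights default to
1/SEM² when all rate SEMs are present. When force SEMs are supplied the
weights use the effective variance `sem_k² + (dk/dF)²·sem_F²` with one
re-weighting pass at the fitted slope — condition means carry sampling
noise on both axes, and ignoring the x-noise makes the CIs under-cover
(≈65% observed instead of 95%). Standard errors come from the Jacobian
at the optimum (absolute sigma when weighted, residual-variance scaled
otherwise); CIs are normal-theory ±1.96 SE, mirroring how such fits are
usually summarized; a bootstrap-over-events alternative (2000 seeded
resamples) is provided. Negative `d` is allowed — the catch pathway
requires it. `compare_fits` reports CI overlap and the d ratio.

## Head counting and reach geometry (`ensemble_table`, `storm`)

Derived columns: heads = displacement/7 nm (one powerstroke per head),
force = k_trap × displacement (or the mean of per-event forces when
event-level data exist — the two differ in the second decimal because
averaging and multiplying do not commute), force/head = force/heads,
which algebraically equals k_trap × 7 nm when both columns derive from
the same displacement. Display rounding is half-up at the printed
precisions (heads 1 dp, forces 3 significant figures); full precision
is kept internally and in the TSVs (`float_precision="round_trip"` on
read).

Surface spacing: per-point nearest-neighbor distances (k-d tree,
verified against an all-pairs oracle), histogram with Freedman–Diaconis
bins, least-squares Gaussian fit for the center (median fallback if the
fit diverges or leaves the data range). Reach: a filament touching a
pedestal bead of radius R can be reached by motors within height h of
the surface, along a chord `2√(2Rh − h²)`; at R = 1500 nm, h = 20 nm
(the height of a myosin head) that is 488.3 nm, and dividing by a
119 nm spacing gives ≈ 4.1 heads — the 1-D estimate; a 2-D
area-density variant is reported alongside.

## Self-checks and problem sizes

The canonical experiments live in `trapforge.experiments` and run at
desk scale: equipartition recovery on 10 s records; detector scoring on
3 × 60 s ensembles (~200 truth events); end-to-end `d` recovery through
the full painted-trace pipeline at 3 × 400 s (~1600 detected events);
CI calibration over 100 replicates of 3 × 500 kinetics-only events;
directionality at 500 events per condition. The whole battery runs in
well under a minute.

## Known limitations

* The condition-level rate-of-mean estimator over a heterogeneous
  ensemble carries a small structural bias in `d̂` — the post-peak
  detachment cascade composition (how many heads remain, hence the
  harmonic factor on the rate) varies slightly across stiffness. The
  ground-truth route over-estimates by ≈ +3%, the full pipeline
  under-estimates by ≈ −10% (detection selection and peak noise);
  95% CI coverage of the generating value sits at ≈ 90%.
* Events shorter than one window (20 ms) are intentionally discarded;
  lifetime summaries are therefore left-truncated relative to the
  generator's truth.
* The equal-division load-sharing option exists but is not what the
  fits assume; using it with the default pipeline recovers an
  ensemble-effective `d` roughly N̄-fold smaller than the per-head one.
* The Gaussian histogram fit for the nearest-neighbor center is biased
  a few percent low on jittered-lattice geometries (min-of-neighbors
  selection); the Poisson-field closed form is used as the unbiased
  cross-check in the tests.
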