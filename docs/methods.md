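# Methods

This note records the models implemented by `aquaskinner`, the defaults
and why they were chosen, the numerical choices, and what the synthetic
fixtures can and cannot establish about real recordings.

## Coordinate conventions and geometry

Image coordinates are 0-based pixels, x right, y down, matching raster
I/O. Dish coordinates are millimetres, origin at the dish centre, y up,
so the physics is right-handed. The default arena is a standard
60 × 15 mm petri dish (radius 30 mm) imaged at 240 × 240 px,
0.25 mm/px. Quadrant sectors are half-open, `[k·90°, (k+1)·90°)` from
the divider angle, and the exact centre belongs to Q1: the boundary
rules are arbitrary, but punishment decisions must be deterministic, so
ties are broken once and for all. Six electrode contacts sit flush with
the wall at 0°, 60°, …, 300°. The contact arc width is not published;
it defaults to 10° and is a config parameter (the homogeneity result is
checked at 5–15°, see below).

## Tracker

Three stages per frame.

**Stage 1 — image to blobs.** The background model is the per-pixel
median of the empty-dish capture frames. Each tick, every quadrant
region *not* occupied by the animal blends toward the current frame,
`B ← (1−w)B + wF` with `w = 0.1`: at that weight the model tracks a
drifting background with a lag of ten ticks while never updating under
the animal. Occupancy is defined by the accepted blob's bounding box
(+2 px pad), not just its centroid — an animal straddling a divider
vane would otherwise be blended into the neighbouring quadrant's
background and drag its own centroid estimate by a pixel or two. The
absolute difference image is stretched so that its
`100·(1 − 2A/N)`-th percentile maps to full scale (`A` = expected
animal area in px, `N` = frame pixels; the factor 2 is headroom), which
makes the binarization that follows invariant to overall contrast. The
threshold is `mean + 3σ` computed over the dish interior only. Blobs
are 8-connected components (thin elongated animals fragment under
4-connectivity at this resolution) above a 50 px minimum area; the
largest is the animal candidate.

**Stage 2 — frame QC.** A candidate is rejected if its displacement
from the last accepted raw position exceeds `dq_threshold` dish
diameters per tick (default 0.2 — a 60 mm dish crossing in under five
ticks is not locomotion), if its area leaves `[60, 500]` px, or if
there is no candidate. Rejected ticks coast the state and suppress
punishment: an artifact must never train the animal.

**Stage 3 — smoothing.** Holt double-exponential smoothing with
α = 0.5, β = 0.3 (method fixed by the original design; constants are
not published and are exposed in config). x and y are smoothed jointly,
which for these linear recurrences equals componentwise smoothing. The
speed estimate is ‖trend‖ × tick rate. The first accepted observation
initializes level = raw, trend = 0.

## Controller

The loop runs in simulated time on a tick counter (default 10 Hz,
capped at the device's 25 Hz ceiling); nothing depends on wall clock,
so identical inputs give byte-identical logs. Each tick and channel:
observe (track a frame, or accept a simulator position directly),
compute the current lighting (levels are integers 0–10 per colour per
quadrant; rotations of 90° or 180° occur at `interval, 2·interval, …`
into the phase — none at t = 0), evaluate shock rules on the smoothed
position, apply yoked pairing, log.

Shock rule semantics: trigger sub-conditions (quadrant membership,
edge/centre distance, trailing-mean speed over a window) AND together;
independent rules express OR. Quadrant triggers are named in the
configuration frame and follow the lighting as it rotates. A triggered
rule waits out its onset delay (continuously triggered, or the pending
timer resets) and its refractory interval (onset-to-onset). Durations
are floored to the 48 ms rotation grid with a one-rotation minimum —
never more charge than requested, never less than one full rotation.
Currents live on the 0.2–20 mA grid in 0.2 mA steps; waveforms are
square, 10–1000 Hz. The rotating excitation schedule drives, in phase
p, electrodes {p, p+1} as sources and {p+3, p+4} as sinks; over the six
8 ms phases each electrode sources twice and sinks twice, so the
delivered charge is net balanced.

Yoked control replaces an even channel's stimuli with those computed
from its odd partner's behaviour (or vice versa); the yoked animal's
own position never influences what it receives.

## Shock-field model

The dish is treated as a thin homogeneous conductor: the electrodes
span the full water depth, so the field is vertically uniform and the
problem is 2-D. Inactive electrodes are modelled as insulating wall
(floating-conductor coupling is a second-order effect at this
geometry). The Laplace problem is discretized by finite differences on
a regular grid with an embedded-boundary disk mask: interior cells use
the 5-point stencil, cells missing a neighbour across the wall get the
mirror (zero-flux) closure, and wall cells under an active arc are held
at ±20 V. The sparse system is solved directly and the residual checked
against 1e−8. J = −∇V by central differences, falling back to one-sided
differences at the rim so that *every* dish cell carries a value: the
homogeneity statistic is quoted as a fraction of dish area, so the
averaging domain is the whole dish. Default spacing h = 0.25 mm
(240 cells across the dish); refining 2× moves the rotating-average
homogeneity fraction by under 2 points, and the observed interior
convergence is ≈ second order away from arc edges.

With the defaults, the fraction of dish area whose phase-averaged |J|
lies within ±30% of its mean is 0.848, against ≈0.55 for an antipodal
dipole and ≈0.77 for one frozen phase; the value stays within the
82 ± 5% band for contact arcs of 5–15°.

A note on the dipole oracle used in tests: with fixed-voltage wall
contacts the centre field depends on contact size. For a wall strip of
arc length L the effective (logarithmic-capacity) contact radius is
L/4, giving |J|center ≈ 2V₀ / (R·ln(8R/L)) — 0.349 V/mm for 10° arcs —
which matches the Richardson-extrapolated numerics within a few
percent. The cruder parallel-plate form 2V₀/(πR) overestimates by
~18% at this arc width and is not used.

## Analytics

Statistics are computed over accepted ticks only; QC-rejected rows are
retained in the log but never enter a denominator. Time segments are
half-open `[k·bin, (k+1)·bin)` with a flagged trailing partial bin.
Punished fraction counts ticks with a shock onset. "Edge" time defaults
to within 5 mm of the wall and the explored-area grid to 2 mm cells
(≈ two body widths of a small planarian); neither discretization is
published, so both are parameters. Region preference labels each tick
by the *logged* light levels of the quadrant the animal occupied
(dominant colour wins, ties count as red background), so rotations are
scored exactly as experienced. Occupancy maps stamp a disc per accepted
tick; colour breakpoints sit at count quantiles {0.5, 0.75, 0.9} of
visited cells, preserving rank order.

## Synthetic data

The renderer emulates what the camera sees through its 632 nm filter: a
dark ellipse (default 6 × 2 mm, aligned with heading, intensity 100) on
a brighter background (180) with a quadratic edge-shadow ramp over the
outer 4 mm (gain 0.25), Gaussian sensor noise (σ = 2), optional bright
bubble discs, and a linear background drift emulating meniscus motion
under microevaporation. Rendered frames never depend on the blue-light
state — the red filter removes it — so "dark" and "lit" trials produce
identical video. The drift fixture uses 10 gray levels per 1000 ticks
(≈30 over a 3000-frame run): a compressed but proportionate version of
multi-day drift, slow enough that per-dwell staleness in the occupied
quadrant stays below sensor noise, which is the regime real
microevaporation occupies. Under it, the healing background keeps
100% frame acceptance while a frozen background collapses below 10%.

The agent is a stochastic point animal: persistent heading with
Gaussian turn noise, constant cruise speed, optional pausing,
thigmotaxis as an outward radial drift, negative phototaxis down the
blue-intensity gradient (quadrant levels interpolated linearly in
angle), an escape burst on shock (default 25 mm/s for 1.5 s plus a
random reorientation), and specular reflection at the wall — tangential
velocity is preserved, so the agent wall-follows like real animals
instead of dithering. One PRNG stream per channel is derived from
(master seed, channel index), making every channel's trajectory
independent of channel count and ordering.

Beyond the reactive repertoire the agent carries one scalar memory: a
shock-conditioned association. Each shock adjusts a conditioned drive
along the blue gradient by `rate·(1 − 2b)` where b is the local
normalized blue level — shocks received under dim light push the agent
toward blue-seeking, shocks under bright blue toward blue-avoidance
(clipped at ±`conditioning_max`). This is the minimal mechanism that
lets a trained agent *retain* a preference after punishment stops,
which is what the post-test of a conditioning protocol measures; a
purely reactive agent reverts to indifference the moment shocks cease.
It is a test oracle, not a learning model: no claim is made that real
tadpole memory is a one-dimensional drive.

The red-aversion demonstration (`protocols.run_red_aversion_demo`) runs
the full protocol — 30 min preference, 4 × 30 min training with 90 min
rests, 30 min post-test, 90° clockwise rotation every 10 min, red half
punished at 1.2 mA with 10 s refractory — at 10 Hz in position mode
(ground-truth positions feed the controller directly; the vision
pipeline is validated separately on the tracking fixtures). One run is
≈324 000 ticks ≈ 10 s of compute. The agent starts at the dish centre,
as a freshly loaded animal would. The per-session escape baseline is
the first 30 s of the *initial* training session, when the agent is
still naive; later sessions begin with an already-conditioned agent
whose early punished time is near zero, so a per-session baseline would
be degenerate.

## What the fixtures do and do not show

Passing the fixture suite shows the pipeline recovers known ground
truth under the modelled disturbances (drift, edge shadow, noise,
bubbles) and that the control loop implements its stated semantics
exactly. It does not show robustness to disturbances outside the
renderer's vocabulary — animals leaving the focal plane, partial
occlusion by the divider vanes, reflections, conspecific debris — nor
anything about real animal learning: the conditioning demo validates
the loop, not a biological claim.

## Known limitations

- One animal per dish; no identity maintenance across crossings.
- The histogram-stretch formula of the original camera firmware is
  proprietary; the percentile scheme here is a reasoned stand-in with
  the same contract (area-aware, scale-invariant), not a reconstruction.
- The field model omits electrode electrochemistry, meniscus 3-D
  effects and conductivity heterogeneity; homogeneity statistics are
  scale-invariant, so the uniform-conductivity assumption only fixes
  units.
- Light-as-consequence protocols (reward by light change) are
  expressible only as phase switches, not per-tick closed-loop light
  levels.
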