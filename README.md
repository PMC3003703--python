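# aquaskinner

A software model of an automated aquatic Skinner box: twelve petri-dish
chambers in which small aquatic animals (planarians, *Xenopus* tadpoles,
zebrafish larvae) are tracked by machine vision and conditioned in closed
loop with quadrant lighting and electric shock. This package re-implements
the device's software stack — the tracker, the trial controller, the
shock-field physics model, and the behavioural analytics — and pairs it
with a synthetic arena/animal simulator so the whole system can be
exercised, tested and reproduced without hardware or animals.

For behavioural scientists it is a workbench for designing and dry-running
operant protocols; for software engineers it is a reference implementation
of a closed observe–decide–punish loop with full determinism.

## What is inside

| module | role |
| --- | --- |
| `aquaskinner.arena` | dish geometry, image↔dish coordinate maps, quadrant assignment |
| `aquaskinner.tracking` | 3-stage tracker: self-healing background subtraction → histogram stretch → statistical threshold → blob selection, frame QC, Holt smoothing |
| `aquaskinner.controller` | trial loop: quadrant lighting with scheduled rotation, shock rules (position / edge / centre / speed triggers, delay, refractory), yoked controls, CSV trial log |
| `aquaskinner.shockfield` | 2-D Laplace model of in-dish current density for any electrode excitation; homogeneity statistics |
| `aquaskinner.analysis` | log parsing, time-segment statistics, occupancy ("curiosity") maps, region preference, explored area |
| `aquaskinner.synthdata` | behavioural agent + arena renderer with ground truth; scripted trajectories |
| `aquaskinner.protocols` | ready-made red-aversion conditioning protocol and demo |

### The core models

**Tracking.** Each frame is compared against a background model that heals
itself: every quadrant not occupied by the animal blends toward the current
frame, `B ← (1−w)B + wF`, so the model follows slow meniscus drift without
absorbing the animal. The absolute difference image is contrast-stretched so
the brightest `k·A` pixels reach full scale (`A` = expected animal area,
`k` = 2), thresholded at `mean + 3σ` over the dish interior, and segmented
into 8-connected blobs with a minimum-area filter. Accepted centroids
(jump, area and presence QC) feed Holt double-exponential smoothing,

```
ℓ_t = α x_t + (1−α)(ℓ_{t−1} + b_{t−1}),    b_t = β(ℓ_t − ℓ_{t−1}) + (1−β) b_{t−1},
```

giving the best estimate of position ℓ and vector velocity b per tick.
While a frame is rejected the estimate coasts and punishment is suppressed.

**Shock field.** Six wall electrodes are excited in a rotating pattern:
phase *p* drives electrodes {p, p+1} at +V₀ and the opposite pair
{p+3, p+4} at −V₀; every 8 ms the pattern advances one electrode, so a full
rotation — the shortest deliverable shock — takes 48 ms, and each electrode
sources twice and sinks twice per rotation (net charge balance). The
potential solves ∇²V = 0 in the dish (depth-averaged; electrodes span the
full water column) with Dirichlet arcs and insulating walls; J = −σ∇V.
Averaged over the six phases, 84.8% of the dish area carries |J| within
±30% of its mean (vs ≈55% for a conventional 2-electrode dipole), the
published motivation for the rotating design.

**Analytics.** Trial logs are binned into user-chosen time segments;
per segment the package reports quadrant occupancy fractions, mean speed,
punished-time fraction, edge-vs-centre time, and cumulative explored area,
plus whole-trial occupancy maps on the classic blue→green→yellow→red ramp.

## Worked example

Compare the three electrode configurations on the default 60 mm dish
(0.5 mm grid for speed):

```
$ aquaskinner field --mode compare --h-mm 0.5
{
  "dipole": 0.5513,
  "static_quadrupole": 0.7675,
  "rotating_hexapole": 0.8438
}
```

The dipole leaves barely half the dish within the ±30% band around the
mean current density — an animal's perceived shock would depend strongly
on where it sits — while the rotating six-electrode excitation covers 84%.

Run the closed-loop red-aversion protocol on the synthetic conditioned
agent (30 min preference test, 4 × 30 min training sessions punishing the
red-lit half at 1.2 mA with 90 min rests, 30 min unpunished post-test,
lights rotating 90° clockwise every 10 min throughout):

```python
>>> from aquaskinner.protocols import run_red_aversion_demo
>>> r = run_red_aversion_demo(seed=0)
>>> round(r.first30_red_fraction, 3)      # red-half time, first 30 s of training
0.347
>>> [round(x, 3) for x in r.last_third_red_fraction]   # last 10 min of each session
[0.0, 0.0, 0.0, 0.0]
>>> r.shocks_per_session
[12, 1, 2, 1]
>>> [round(b, 2) for b in r.posttest_blue_by_bin]      # unpunished post-test, 5-min bins
[1.0, 1.0, 1.0, 1.0, 0.99, 1.0]
```

The agent samples the punished half freely at first (34.7% of the first
30 s), is shocked a dozen times in session one and only a handful of times
afterwards, and holds a strong blue-half preference through every 5-minute
bin of the post-test even though nothing is punished there — the signature
of the conditioned association rather than mere escape.

Simulate, run and analyse from the shell:

```
aquaskinner simulate --config trial.yaml --seed 5 --out sim_out/
aquaskinner analyze --log sim_out/trial_log.csv --bin 300 --out report/ --occupancy
aquaskinner field --mode rotating --band 0.3 --out field.json --fieldmap jmap.png
```

`config.fig_protocol_config()` builds the full red-aversion protocol as a
`TrialConfig`; an equivalent YAML layout is documented in
`aquaskinner/config.py`.

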