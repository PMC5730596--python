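# Methods

This note documents the models, parameters and numerical choices behind
`larvatrack`: what each stage assumes, why the defaults are what they are,
what the synthetic benchmark does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Background model

Each pixel is modelled by a mixture of up to `max_components` scalar
Gaussians. For a new sample `x`:

- a component *matches* when `(x − μ)² < λ²·σ²` (λ = `lambda_match`,
  default 3.0); the best match is the matched component of largest weight
  (ties: lowest index — components are kept sorted by descending weight);
- the sample is classified against the *pre-update* model: background
  components are the smallest descending-weight prefix with cumulative
  weight > `1 − c_f`; the sample is foreground iff it matches none of
  them;
- weights update as `w ← w + α(o − w) − α·c_T` with ownership `o ∈ {0,1}`;
  the matched component's mean and variance move toward the sample at
  rate `α/w`; negative weights are pruned; weights renormalise to sum 1;
- if nothing matches, a new component is spawned (weight α, mean `x`,
  variance `var_init`), replacing the weakest when the mixture is full.

Renormalising after every update keeps the weights an exact probability
vector; because the per-update weight deficit is only `M·α·c_T`, the decay
of an occluded background component still follows `(1 − α)^t` to first
order, and the re-absorption time of a newly static object remains
`log(1 − c_f)/log(1 − α)` frames. Measured empirically (a dark disc
appearing on a settled uniform background), re-absorption runs ≈ 5–10 %
above the closed form — the Dirichlet drag slightly delays the crossing —
comfortably inside the ±20 % band the absorption test asserts.

Two implementations exist: a scalar per-pixel reference (`update_pixel`)
and the vectorised whole-frame model; a test drives both over identical
random sample streams and asserts bit-level agreement of every weight,
mean, variance and foreground decision.

**Defaults.** `α = 0.001`, `c_f = 0.1`, `c_T = 0.05`, `max_components = 4`,
`λ = 3`, `var_init = 15²`, `var_floor = 4`, `T = 500` warm-up frames.
α and c_f control the absorption horizon (≈ 105 frames at the defaults);
the remaining values follow common practice for recursively-updated
mixtures. All are config-exposed (`bg.*`).

**Initialisation.** The first component of each pixel is seeded on the
temporal **0.95-quantile** of the first `init_frames = 45` warm-up frames,
with a per-pixel variance estimated as the squared scaled MAD around that
seed (clipped to `[var_floor, var_init]`). Two asymmetries motivate this
over seeding on the first frame:

- *Un-learning is ~20× slower than learning.* A full-weight component
  leaves the background prefix only when its weight decays below `c_f`,
  which takes ≈ `ln(1/c_f)/α` frames — far longer than any warm-up at a
  slow α. An organism present in frame 0 would therefore stay camouflaged
  (and punch holes in its own detections) essentially forever. The medium
  is brighter than the organisms in this imaging mode, so an upper
  quantile recovers the true background from as few as ~5 % organism-free
  frames while staying robust to sensor noise (a plain max is not).
  `init_quantile = 0.5` gives a polarity-free median; `init_frames = 1`
  restores first-sample seeding.
- *A blanket `var_init` matches anything within ±45 intensity units* and
  converges only at rate α, so a component seeded on a dark artifact
  (an ink dot, say) would swallow a larva resting over it. The empirical
  MAD gives static pixels their true noise scale immediately.

**Warm-up and reporting.** The model is estimated on the first `T` frames;
tracking output starts at frame `T` and is reported on original frame
indices. Clips shorter than `T` are padded *in front* with cyclic copies
of themselves (so warm-up motion statistics resemble the clip), and every
original frame is then tracked. Padding frames are never reported.

## Segmentation

Pipeline: gate the grayscale frame by the foreground mask (non-mask pixels
set to white — larvae are dark), 3×3 median filter, 3×3 grayscale erosion
(both with edge replication), Otsu's threshold computed over the masked
pixels only, keep the dark class, label 8-connected components, drop
regions below `size_fraction = 0.20` of the current frame's mean region
area. Otsu is the exhaustive 256-bin between-class-variance argmax with
ties resolved to the lowest threshold; a test asserts equality with an
independent naive search on every input, and agreement (±1 bin-boundary
convention) with `skimage.filters.threshold_otsu`.

Keeping the *dark* side of the Otsu split doubles as ghost suppression:
when a long-stationary larva finally moves, the vacated pixels are flagged
foreground until the model re-adapts, but they now show bright water and
fall on the discarded side of the threshold.

The mean-area filter is computed per frame (not a running average). With a
single region the mean equals its own area and nothing is removed.

## Association and bridging

Costs are squared centroid distances (no square root). The association
gate is the maximum frame-to-frame displacement in the tracking ground
truth, `max(dist_GT)`; because the costs are squared, the gate enters as
`max²` so both thresholds share squared-pixel units (a config switch
`gate_is_squared=False` applies the pixel value to the squared costs for
the alternative unit reading). Without ground truth the user supplies
`track.max_displacement_px`.

**Measurement allowance.** Ground truth bounds *true* displacement;
measured steps add two centroid localisation errors, and a partially
segmented body (inside an edge shadow, or mid-burst when the bright
motion trail compresses the Otsu histogram) biases the centroid by up to a
quarter body length. `gate_slack_px` (default 3 px ≈ L/4 at the benchmark
larva size) is added to the displacement bound before it enters either
gate. Without it, burst-onset frames break tracks and spawn duplicate
fragments; with it, the gate still rejects debris, which sits far beyond
one body length away. Set it to 0 to recover the raw bound.

**Fragment folding.** After assignment, a leftover detection within the
gate of an already-claimed one is treated as a split piece of the same
animal: it is folded into the claimed detection by area-weighted centroid
averaging rather than founding a duplicate track. This both recovers the
true body centre when segmentation splits a body and prevents phantom
twin tracks.

**Bridging.** Fragments are visited chronologically by start frame; each
is joined to the spatially nearest earlier-ending trajectory if the
squared endpoint distance is within `bridge_ratio × (max + slack)²`
(`bridge_ratio = 1.2`, a 20 % rebound margin). Bridged gaps are filled by
linear interpolation and flagged `bridged` in the output table; a fragment
with candidates but none within the condition starts a new trajectory and
its first frame is flagged `error`. Fragments with no earlier-ending
candidate are genuine appearances, not errors. Interpolation is trusted
precisely because the distance condition certifies the endpoints are
close; during a stationary-absorption gap the filled positions lie at the
rest site, where the animal actually is.

Assignment uses `scipy.optimize.linear_sum_assignment` with Inf entries
replaced by a dominating finite cost and the affected pairs dropped, so
the solver maximises the number of feasible pairs and minimises cost among
those; equal-cost optima resolve deterministically by the solver's fixed
pivoting, and tests compare against an exhaustive-permutation oracle on
cost (tie sets share the optimum by definition).

## Evaluation

CLEAR-MOT correspondence persists from the previous frame while a pair
stays within the match radius; the remainder match by minimum-distance
assignment (reusing the gated Hungarian solver); unmatched ground truth
counts as misses, unmatched detections as false positives, and a
ground-truth object whose matched track identity changes contributes a
mismatch in the frame of the change. MOTP is the mean (non-squared)
Euclidean distance over matches; MOTA is `1 − Σ(m+fp+mme)/Σg` and may be
negative. The match radius defaults to the tracking gate in pixels.

For the Similarity Index, a ground-truth object counts as found when any
predicted centroid lies within the match radius. The miss penalty
`Num_miss/(2·Num_GT)` is computed per frame and averaged by default;
`eval.per_video_counts` switches to pooled per-video totals.

## Synthetic benchmark

The generator renders grayscale well scenes with exact per-frame larva
masks and a trajectory table. What it emulates: round and square wells;
a darkened rim outside the well; a 6-px edge-shadow band; 2-px ink-label
strokes; single-pixel drifting dark particles; bright-rimmed bubbles;
larvae as oriented capsules (length 11 px, width 4 px) with a dark core
fading to a semi-transparent periphery (35 % of core contrast at the
edge); Gaussian sensor noise (σ = 2); low larva/background contrast
(core 70 on water 200). What it does not: body flexion and tail-beat
kinematics, refraction and photorealistic optics, water ripples as
extended moving textures, compression artifacts. Passing the benchmark
therefore demonstrates the pipeline's handling of static clutter, bursty
motion, dropouts and occlusion geometry — not of articulated-shape or
refraction effects in real optics.

**Locomotion** is a two-state Markov model: rest with sub-pixel jitter
(σ = 0.05 px/frame), burst onset with probability `p_burst = 0.02` per
frame, bursts of 4 frames at 2–4 px/frame along a diffusing heading —
a long-run active fraction of ≈ 0.074, matching the low activity
proportion reported for larvae. Recording starts with an escape dart of
at least 2.2 body lengths headed toward open water (handling startles the
animals), which also guarantees the drop-in pixels show plain water early
in the recording. Larvae steer apart below 16 px (~1.5 body lengths,
relaxing half the violation per frame), so bodies never fuse outside the
dedicated occlusion scene; real larvae do exhibit collision avoidance.
High-frame-rate presets (117 fps) model evoked escape episodes: 10-frame
bursts at the same 2–4 px/frame (tens of body lengths per second at that
shutter speed) and nearly frozen rest jitter.

The 10-scene suite grades conditions from a clean round well to a scene
combining shadow, particles, bubbles and labels at high frame rate, with
single- and multi-larva scenes, both well shapes, 14/15 fps and 117 fps
presets, and one scripted head-on crossing (at 75 % of the clip) that
produces a genuine multi-frame occlusion. Labels and bubbles are placed
off the larvae's swim path (best-effort resampling) so that false
positives are unambiguously attributable to artifacts in tests. A scene
manifest (YAML) records every parameter and seed; regeneration is
bit-identical.

**Benchmark configuration.** Scenes are 120×120 px, 340 frames: 200
warm-up + a 140-frame evaluation window, run with `α = 3·10⁻⁴`
(`benchmark.benchmark_background_params()`). Two inequalities shape this
choice: the absorption horizon must exceed the rest bouts the clip can
contain (geometric rests, mean 50 frames; horizon ≈ 350 frames at this α,
so a resting larva survives the whole clip), and the warm-up must absorb
every static artifact (it does — artifacts are present from frame 0 and
enter the quantile seed directly). The library default α = 0.001 suits
longer recordings where a ~105-frame absorption horizon is wanted; for
the short benchmark clips the slower α is the appropriate setting of the
same dial. Scene sizes keep the full suite (render + track + score) under
half a minute.

## Known limitations

- Centroid-only identity: after a failed bridge the new trajectory has a
  new identity; appearance models are out of scope, so crossing-induced
  identity exchanges are recorded (as errors/mismatches) rather than
  repaired.
- The dark-object polarity assumption (binarisation side, init quantile)
  matches bright-field larva imaging; inverted-contrast data needs the
  config switches (`init_quantile = 0.5` and an inverted frame).
- The fixed bridge condition does not scale with gap length; fragments
  that drift more than `√1.2·(max+slack)` px during a dropout are split
  with an error record, by design.
- A larva that never moves during an entire recording is indistinguishable
  from a static artifact for any background-subtraction method and will
  not be detected.
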