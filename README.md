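# larvatrack

Automatic tracking of multiple zebrafish larvae in microscopy video under
unconstrained imaging conditions.

Zebrafish (*Danio rerio*) larvae are a standard vertebrate model in
toxicology, drug screening and behavioural science, and quantifying their
locomotion means tracking them in video. Larvae are hard targets: they are
small and semi-transparent (low contrast against the water), they move in
*bursts* — long quiescent periods punctuated by brief fast swims, with a
mean activity fraction below 0.075 — and realistic recordings are full of
confounders at the same spatial scale as the animals themselves: well-edge
shadows, ink labels drawn on the dish, drifting water particles, bubbles
and ripples. Systems built for continuously swimming, high-contrast adult
fish (or requiring a pristine container) fail under these conditions.

`larvatrack` implements a detection-based tracking pipeline designed for
exactly this regime, together with the standard evaluation metrics and a
synthetic scene generator that renders benchmark videos with pixel-exact
ground truth.

## Pipeline

1. **Background subtraction** — a per-pixel adaptive Gaussian mixture with
   a data-driven number of components. Weights update recursively,
   `w ← w + α(o − w) − α·c_T`, with a slow decay factor α; components whose
   weight falls below zero are discarded. The background at a pixel is the
   smallest set of top-weight components whose cumulative weight exceeds
   `1 − c_f`. A larva that halts is only re-absorbed into the background
   after ≈ `log(1 − c_f)/log(1 − α)` frames, so briefly-resting animals
   stay detected while transient ripples are forgotten. The model is
   estimated on the first `T` frames (default 500; short clips are padded
   with cyclic duplicates of themselves).
2. **Segmentation** — the foreground mask gates the grayscale frame; a 3×3
   median filter and grayscale erosion remove noise fragments; Otsu's
   threshold over the masked histogram binarises (larvae are the dark
   class); 8-connected components below 20 % of the mean region area are
   discarded as ripple debris.
3. **Association** — detections in consecutive frames are linked by
   Hungarian (Munkres) assignment on the cost matrix of *squared* centroid
   distances, `d_ij = (x_j − x_i)² + (y_j − y_i)²`. Entries beyond a
   distance gate — the maximum frame-to-frame displacement observed in
   tracking ground truth — are set to Inf and stay unmatched, so stray
   debris cannot capture a track.
4. **Gap bridging** — tracks interrupted by detection dropouts (occlusion,
   long-stationary absorption) leave fragments; a nearest-neighbour pass
   joins a fragment start to the closest earlier-ending trajectory when
   the squared distance is within `1.2 × max²(dist_GT)`, filling the gap
   by interpolation; gaps failing the condition are recorded as errors.

Evaluation implements pixel Recall/Precision/F-measure, the object-aware
**Similarity Index** `SI = F − Num_miss/(2·Num_GT)`, and the CLEAR-MOT
metrics `MOTP = Σ|D − GT| / Σ matches` and
`MOTA = 1 − Σ(m_t + fp_t + mme_t)/Σ g_t` with identity-swap counting.

## Worked example

Generate a benchmark scene (a round well with an edge shadow and two
larvae), track it, and score the result against the scene's own ground
truth:

```python
from larvatrack.benchmark import score_scene
from larvatrack.synthetic import suite_presets

spec = suite_presets(base_seed=1)[1]   # round well with edge shadow, two larvae
score, result = score_scene(spec)
print(f"tracks: {result.summary['n_tracks']}, "
      f"bridged gaps: {result.summary['n_bridged_gaps']}, "
      f"error frames: {result.summary['n_error_frames']}")
print(f"MOTA {score.scores.mota:.3f}  MOTP {score.scores.motp:.2f} px  "
      f"identity swaps {score.scores.id_swaps}")
```

```
tracks: 2, bridged gaps: 0, error frames: 0
MOTA 1.000  MOTP 0.17 px  identity swaps 0
```

Both larvae are followed through the full evaluation window with a mean
localisation error of 0.17 px and no identity confusion, despite the
larvae resting inside a shadowed, low-contrast well.

The same workflow is available from the shell:

```
larvatrack simulate --suite --out bench --seed 1
larvatrack track bench/seq02_shadow/frames \
    --gt bench/seq02_shadow/ground_truth.csv --out run
larvatrack evaluate --pred run/trajectories.csv \
    --gt bench/seq02_shadow/ground_truth.csv
```

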