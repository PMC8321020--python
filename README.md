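# macrotrack

Quantifying what migrating cells do after they touch.

`macrotrack` analyses two-channel fluorescence time-lapse movies of
migrating cells — nuclei labelled in red, microtubules in green — and
measures how cells change direction after cell–cell contact (contact
inhibition of locomotion). It was written for movies of *Drosophila*
embryonic macrophages, where control cells are compared with *Shot3*
spectraplakin mutants, but the pipeline is generic: any movie in which a
compact nuclear marker rides inside a larger cytoplasmic halo will do.

## The method

1. **Segmentation.** Each channel of each frame is binarised with a
   hysteresis threshold whose levels derive from the Otsu criterion:
   connected components of pixels ≥ the low level are kept only if they
   contain a pixel ≥ the high level (high = Otsu level, low = α·high,
   default α = 0.5). Small components are discarded and the rest labelled.
2. **Tracking.** Red-channel nucleus centroids are linked frame to frame
   with a keyhole gate: a candidate continues track *r* if it falls inside
   a wedge opened along the track's last displacement or a fallback circle
   around its last position. Each track *T_r* carries positions **x**_t,
   velocities **v**_t and per-frame clump membership.
3. **Clump detection.** A *clump* is a green component containing ≥ 2
   nucleus centroids: halos merged, nuclei still separate. A membership set
   {r, q, …} (r > q > …) is named by its base-1000 code c(r, q) — tracks 2
   and 1 form clump 2001; if tracks 3 and 5 join, the code evolves to
   5003002001. A maximal run of frames t_k0 … t_kC with constant membership
   is one clump instance; the same pair meeting again later is a new
   instance.
4. **Interaction analysis.** Instances with exactly two members where a
   cell fully enters and exits are selected. For each such cell, with
   **u** = **x**(t_k0) − **x**(t_k0 − S) and **w** = **x**(t_kC + S) −
   **x**(t_kC), the direction change θ_x ∈ (−π, π] is the signed angle from
   **u** to **w**; time in clump is T_C = t_kC − t_k0 (10 s per frame); S is
   3–5 frames (30–50 s). Tracks are rigidly mapped into a canonical frame
   (pre-contact path entering the origin along +x′) for comparison and for
   the exit distance (how far the cell gets from the origin in the S frames
   after contact).
5. **Group statistics.** Interactions are counted per dataset
   (mean ± sample SD), and pooled θ_x, T_C and exit distances are compared
   between groups with a two-sample t-test (Student's pooled-variance by
   default, Welch optional), either over the full signed range or as |θ_x|
   restricted to |θ_x| < 90°.

A synthetic movie generator plants cells with programmed contact intervals
and post-contact turn angles and renders them into TIFF stacks, giving
exact ground truth for every stage.

## Worked example

Simulate two cells that meet at frame 24, stay in contact for 12 frames,
and leave turned by +60° and −60°, then run the full pipeline:

```python
import math
from macrotrack import Scenario, PipelineConfig, run_pipeline

scenario = Scenario(
    n_cells=2, n_frames=60, frame_shape=(360, 440),
    contact_events=[(0, 1, 24, 36, math.radians(60), math.radians(-60))],
    seed=7,
)
result = run_pipeline(PipelineConfig(output_dir="demo_out", scenario=scenario))
print(result.tables["interactions"].round(2).to_string(index=False))
```

```
dataset_id   group  code  tk0  tkC  TC_frames  TC_seconds  track_id  theta_deg  exit_distance_px  S
 dataset01 control  2001   24   36         12       120.0         1      59.66             19.94  5
 dataset01 control  2001   24   36         12       120.0         2     -59.66             19.88  5
```

The pipeline segments 120 nuclei across 60 frames, links them into 2
tracks, finds the single clump 2001 exactly on the programmed frames 24–36
(T_C = 12 frames = 120 s), and recovers both planted turn angles to within
0.4° of ±60°. The exit distance ≈ 20 px is the S·speed = 5 × 4 px the cells
were programmed to travel after separating. `demo_out/` also receives
`tracks.csv`, `clumps.csv`, `ground_truth.csv`, a plain-text summary and
the resolved configuration.

The same stages are available from a shell:

```bash
macrotrack simulate --n-cells 2 --n-frames 60 --frame-shape 360 440 \
    --event 0,1,24,36,60,-60 --seed 7 --out movie.tif
macrotrack interactions movie.tif --s 5 --out-dir out/
macrotrack compare --control a/interactions.csv --mutant b/interactions.csv \
    --mode absolute_lt90 --out report.csv
```

## Layout

- `src/macrotrack/synthgen.py` — scenario/ground-truth types, choreographed
  contact simulation, disk renderer
- `src/macrotrack/segmentation.py` — Otsu level, hysteresis mask, per-frame
  segmentation, centroids
- `src/macrotrack/tracking.py` — keyhole linking, velocities
- `src/macrotrack/clumps.py` — clump codes, per-frame detection, timeline
- `src/macrotrack/interactions.py` — selection, θ_x, alignment, exit
  distance
- `src/macrotrack/stats.py` — group summaries, t-tests, angle comparison
- `src/macrotrack/io.py`, `cli.py` — TIFF/CSV I/O, pipeline driver, CLI

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
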