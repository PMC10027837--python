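# rok — random-object kinematogram engine

A headless, fully seedable Python implementation of the **random-object
kinematogram (ROK)**: a motion/orientation-coherence stimulus in which the
moving elements are *oriented objects* rather than dots. Because each object
carries both a movement direction and an orientation, the display can vary
**task difficulty** (coherence of the judged feature) and **stimulus
interference** (congruency of the irrelevant feature) independently and
continuously — a kinematogram analogue of Stroop/flanker congruency
manipulations. The package is aimed at visual-psychophysics researchers who
want to generate such stimuli, pilot designs, and validate analysis
pipelines without a browser or display loop.

## What it computes

For a layer of *N* objects with coherence *p*, opposite-coherence *q*
(*p + q ≤ 1*), and congruency level *c*:

- **Assignment** — largest-remainder apportionment turns (*p, q, 1−p−q*)
  into exact integer class counts (realized fractions within 1/*N* of
  nominal); in congruency mode a fraction *c* of the scoped objects gets the
  coherent target direction on its irrelevant feature, the rest its 180°
  opposite.
- **Kinematics** — constant-speed frame-by-frame translation (speed per
  object uniform on [*v*(1−r), *v*(1+r)]), optional per-frame redraw of
  random directions, opposite-locus boundary reinsertion, and linear edge
  fade; all lengths in % of aperture width or pixels.
- **Rendering** — deterministic Pillow rasters (triangles / circles /
  squares / keyframed sprites, rotation or axis-mirror orientation), PNG
  sequences and animated GIFs.
- **Trials** — a responder-callback trial loop emitting the standard data
  record (`rt`, `key_press`, `correct`, `frame_rate`, `number_of_frames`,
  `frame_rate_array`, canvas size, full parameter echo).
- **Designs** — the two reference factorial experiments (10 blocks × 72
  trials: 3 coherence × 4 congruency × 6 repetitions, plus fixed-level
  distractor blocks with a 70-object distractor layer on 10% of trials), a
  logistic/log-normal synthetic observer, and the usual exclusion filters.
- **Diagnostics** — an independent audit that re-derives coherence,
  congruency, and speed from trajectory-log displacements.

## Worked example

```python
import numpy as np, rok

aperture = rok.ApertureSpec(width=600, height=600)
layer = rok.LayerSpec(
    number_of_oobs=600,
    coherence_movement=0.65, coherence_movement_opposite=0.35,
    coherence_orientation=0.65, coherence_orientation_opposite=0.35,
    coherent_movement_direction=90, coherent_orientation=90,  # up
    movement_speed=3.0, oob_size=1.0,      # % of aperture width (per s)
    oob_color=(128, 0, 128),
)
scene = rok.SceneSpec(apertures=[(aperture, layer)])
run = rok.simulate_scene(scene, n_frames=120, rng=np.random.default_rng(1))
print(rok.audit_log(run.log, scene))
```

prints

```
CoherenceReport(realized_movement_coherence=0.65, realized_opposite=0.35,
                realized_orientation_coherence=0.65, realized_congruency=0.65,
                realized_mean_speed=3.0000000000000053, n_objects=600)
```

i.e. the audit recovers the nominal display exactly: 390 of 600 objects
move up, 210 move down, and the mean displacement is 3% of the aperture
width per second with no drift from boundary handling. The scripts in
`examples/` walk through assignment arithmetic, animation + audit,
rendering, and a full simulated experiment.

A thin CLI wraps the same functions:

```bash
rok render  --config scene.json --seed 1 --frames 120 --out anim.gif --format gif --log traj.csv
rok design  --experiment exp1 --seed 1 --out design.json
rok simulate --design design.json --seed 2 --out trials.csv
rok audit   --log traj.csv --config scene.json
```

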