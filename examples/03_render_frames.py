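"""Render a short animation to an animated GIF (and one PNG).

Writes scratch output under ./scratch/ — a 2-layer display with the purple
target triangles plus the turquoise/yellow distractor layer.
"""

from pathlib import Path

import numpy as np

import rok

rng = np.random.default_rng(42)
design = rok.build_experiment("exp1", rng=rng)
trial = next(t for t in design.blocks[0].trials if t.meta["distractor"])

rasters = []
rok.simulate_scene(
    trial.scene, 30, np.random.default_rng(7), fps=60, record=False,
    on_frame=lambda states, clock: rasters.append(
        rok.rasterize_frame(trial.scene, states, clock)
    ),
)
out = Path("scratch")
out.mkdir(exist_ok=True)
rok.write_frames(rasters, out / "distractor_trial.gif", "animated_gif", fps=60)
rok.write_frames(rasters[:1], out / "first_frame", "png_sequence")
print(f"wrote {len(rasters)} frames: scratch/distractor_trial.gif")
print("layers drawn:", len(trial.scene.apertures), "(target + distractor)")
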