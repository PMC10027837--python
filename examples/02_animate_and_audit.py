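"""Animate a scene headlessly and audit its trajectory log.

The audit is an independent oracle: it re-derives movement classes from
finite-difference displacements (excluding boundary-reinsertion jumps) and
should recover the nominal coherence, opposite-coherence, and speed exactly.
"""

import numpy as np

import rok

aperture = rok.ApertureSpec(width=600, height=600)
layer = rok.LayerSpec(
    number_of_oobs=600,
    coherence_movement=0.65, coherence_movement_opposite=0.35,
    coherence_orientation=0.65, coherence_orientation_opposite=0.35,
    coherent_movement_direction=90, coherent_orientation=90,
    movement_speed=3.0,   # % of aperture width per second
    oob_size=1.0,         # % of aperture width
    oob_color=(128, 0, 128),
)
scene = rok.SceneSpec(apertures=[(aperture, layer)])

run = rok.simulate_scene(scene, n_frames=120, rng=np.random.default_rng(1), fps=60)
report = rok.audit_log(run.log, scene)
print(f"frames logged:        {run.log.frame_index.nunique()}")
print(f"realized coherence:   {report.realized_movement_coherence:.3f} (nominal 0.650)")
print(f"realized opposite:    {report.realized_opposite:.3f} (nominal 0.350)")
print(f"realized mean speed:  {report.realized_mean_speed:.3f} % width/s (nominal 3.000)")
# Exact recovery (0.650 / 0.350 / 3.000) shows the assignment and kinematics
# implement the nominal parameters with no drift from boundary handling.
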