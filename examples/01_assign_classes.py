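"""Partition a 600-object field into movement/orientation classes.

Builds the two-direction display used in the reference experiments (65%
coherent, 35% opposite) and a 90/75 coherence-congruency cell, and prints
the exact integer class counts the largest-remainder apportionment yields.
"""

import numpy as np

import rok

rng = np.random.default_rng(0)

counts = rok.partition_counts(600, 0.65, 0.35)
print(f"65/35 display: {counts.n_coherent} coherent, {counts.n_opposite} opposite, "
      f"{counts.n_random} random")

layer = rok.LayerSpec(
    number_of_oobs=600,
    coherence_orientation=0.90,      # orientation task at 90% coherence
    coherence_orientation_opposite=0.10,
    coherent_orientation=90, coherent_movement_direction=90,
    coherence_movement=0.75,         # 75% congruency level
    experiment_congruency_mode=rok.CongruencyMode.random_rest,
    experiment_main_task=rok.MainTask.orientation,
    congruency_scope=rok.CongruencyScope.all_objects,
)
a = rok.build_layer_assignment(layer, 600, rng)
up_movers = int(np.sum(a.movement_direction == 90))
print(f"orientation task, 75% congruency: {up_movers} of 600 objects move toward the target")
# -> 390/210/0 for the 65/35 display, and 450 target-direction movers at 75%
#    congruency: proportions always land on exact, reproducible integer counts.
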