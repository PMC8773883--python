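"""Map source detectability over a cortical source grid.

Seeds a 100-nAm patch source (vertex + 1-ring neighbours, dipoles along
the local surface normals) at every vertex of two small hemisphere
grids, evaluates each through unregularized and 2%-regularized montages,
and prints detectability summaries plus a per-vertex SNR table ready for
any surface renderer.
"""

import numpy as np
import pandas as pd

import megmontage as mm

LEVELS = 2  # 66 patches per hemisphere; raise to 5 for the full 4098

geom = mm.StudyGeometry.default(seed=0, grid_levels=LEVELS)
lf = mm.build_leadfield(geom.sources, geom.array, geom.sphere)
noise = mm.NoiseModel.from_array(geom.array)
ops = {lam: mm.build_montage(lf, noise, lam) for lam in (0.0, 0.02)}

spec = mm.ScenarioSpec(scenario="cortical_grid", seed=0)
reports = {lam: [] for lam in ops}
for rec, truth in mm.run_scenario(spec, geom):
    for lam, op in ops.items():
        reports[lam].append(mm.evaluate_recording(rec, op, geom.sources))

summary = mm.summarize_scenario([r for reps in reports.values() for r in reps])
print(summary.round(1).to_string())
print()
print(mm.detectable_counts(reports[0.02]).to_string())

# per-vertex map for the left hemisphere at lambda = 2%
left = geom.grids[0]
snr2 = np.array([r.best_snr2 for r in reports[0.02] if r.extra.get("hemisphere") == "left"])
table = mm.snr_map_export(left, {"SNR2@0.02": snr2})
print()
print(table.head(5).round(2).to_string())

# Deeper vertices (bottom of each grid, far from the helmet) fall below
# the 15-dB visual-detectability threshold; regularization at 2% lifts
# borderline patches above it, enlarging the detectable fraction.
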