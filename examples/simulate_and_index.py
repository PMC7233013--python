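"""Simulate one two-color still pattern and recover its orientation.

Builds the worked example: a triclinic protein crystal oriented at Euler
angles (10, 20, 30) degrees, illuminated at 7 and 9 keV, recorded on a
1440x1440 detector at 0.1 m.  The indexer sees only pixel coordinates and
the prior unit cell.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from tcindex import IndexerParams, build_table, index_two_color
from tcindex.evaluate import orientation_error
from tcindex.simulate import SimulationConfig, simulate_pattern

cfg = SimulationConfig()
U_true = Rotation.from_euler("ZYX", [10, 20, 30], degrees=True).as_matrix()
pattern = simulate_pattern(cfg, U_true)
print(f"simulated pattern: {pattern.n_peaks} peaks "
      f"({(pattern.true_color == 1).sum()} at 7 keV, "
      f"{(pattern.true_color == 2).sum()} at 9 keV, "
      f"{pattern.dual_excitable.sum()} excitable under both)")

table = build_table(cfg.cell, d_min=5.0)
print(f"reference table: {table.n_reflections} reflections to "
      f"{table.d_min} Angstrom")

solution = index_two_color(pattern.fs, pattern.ss, pattern.snr,
                           pattern.intensity, table, cfg.geom, cfg.setup,
                           IndexerParams())
total, per_euler = orientation_error(solution.rotation, U_true)
print(f"indexed: score S = {solution.score} of {pattern.n_peaks} peaks "
      f"matched under either color")
print(f"orientation error: {total:.4f} deg total, per Euler angle "
      + np.array2string(per_euler, precision=4))
print(f"color groups: {len(solution.group_1)} peaks -> 7 keV, "
      f"{len(solution.group_2)} -> 9 keV")
print("(S counts peaks whose fractional Miller index is within 0.25 of "
      "integers under at least one wavelength; an error well below 0.2 deg "
      "means the rotation is accurate enough for downstream merging)")
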