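"""Simulate a seeded Poisson acquisition of the 9-position phantom.

The acquisition protocol is 10 repeats of 8 s exposure.  Expected counts
per pixel are the source fingerprints scaled by activity and exposure,
plus a uniform septal-penetration background (7.5 % of source counts leak
through the thin collimator walls); each repeat is an independent Poisson
draw.
"""

from pathlib import Path

from slnf import (
    AcquisitionConfig,
    build_system_matrix,
    generate_grid_phantom,
    profile_geometry,
    simulate_acquisition,
)
from slnf.io import write_tiff_stack

model = profile_geometry("default")
A = build_system_matrix(model)

phantom = generate_grid_phantom(spacing=20.0, origin_offset=(0.0, 0.0, 120.0))
print("phantom positions (x, y, z mm):")
for i, s in enumerate(phantom, 1):
    print(f"  {i}: {s.position}, {s.activity} MBq")

cfg = AcquisitionConfig(exposure=8.0, n_repeats=10, seed=1)
stack, truth = simulate_acquisition([phantom[4]], A, model.grid, cfg)
det = model.detector
out = Path("scratch/example_stack")
write_tiff_stack(stack.reshape(-1, det.n_rows, det.n_cols), out)

print(f"\nsimulated {cfg.n_repeats} repeats of position 5 "
      f"({truth['true_positions_mm'][0]} mm)")
print("total counts per repeat:", stack.sum(axis=1).tolist())
print(f"wrote 16-bit TIFFs to {out}/")
print("Counts vary repeat-to-repeat by Poisson statistics (~sqrt(N)); the "
      "fingerprint pixels carry ~1000 counts each, far above the ~0.02-count "
      "penetration floor.")
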