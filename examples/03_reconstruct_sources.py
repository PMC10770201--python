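"""Localize two simultaneous sources in one noisy detector image.

The greedy fingerprint search scores every voxel column against the
observed image by a plain inner product (counts collected on the
footprint), takes the best voxel, masks its footprint pixels to zero so
the next-strongest source dominates, and repeats.  The number of sources
is assumed known.
"""

from slnf import (
    AcquisitionConfig,
    build_system_matrix,
    generate_grid_phantom,
    l2_error,
    match_sources,
    profile_geometry,
    simulate_acquisition,
    slnf_reconstruct,
    voxel_to_position,
)

model = profile_geometry("default")
A = build_system_matrix(model)
phantom = generate_grid_phantom(origin_offset=(0.0, 0.0, 120.0))

sources = [phantom[0], phantom[8]]  # positions 1 and 9, diagonal extremes
cfg = AcquisitionConfig(n_repeats=1, seed=42)
stack, truth = simulate_acquisition(sources, A, model.grid, cfg)

recon = slnf_reconstruct(stack[0], A, n_sources=2, grid=model.grid)
estimates = voxel_to_position(recon, model.grid)
pairs, errors = match_sources(estimates, truth["true_positions_mm"])

for est in recon.sources:
    print(f"extraction {est.rank}: voxel {est.voxel} at {est.position} mm, "
          f"score {est.score:.0f} counts, {est.n_ties} tie(s)")
for k, (t, e) in enumerate(zip(truth["true_positions_mm"], errors)):
    print(f"truth {k}: {t} mm -> error {e:.2f} mm")
print("The score is the observed counts captured by the voxel's fingerprint; "
      "masking removes the first source's pixels so the weaker source wins "
      "round two.  Errors of 0.00 mm mean both sources landed on their exact "
      "grid voxels.")
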