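"""Rank candidate source positions by expected localization difficulty.

The assessability score of a position with fingerprint d is
trace(d (d^T d)^-2 d^T) = 1 / nnz(d): the fewer detector pixels see the
position, the higher the score and the harder the localization.  This is
an A-optimal-design statistic — it depends only on the collimator
geometry, so difficult spots can be mapped before any measurement.
"""

from slnf import build_system_matrix, generate_grid_phantom, profile_geometry, rank_positions

model = profile_geometry("default")
A = build_system_matrix(model)
phantom = generate_grid_phantom(origin_offset=(0.0, 0.0, 120.0))

table = rank_positions(phantom, A, model.grid).table
print(table[["index", "y_mm", "z_mm", "nnz", "score", "rank"]].to_string(index=False))
hardest = table.loc[table["rank"].idxmin()]
print(f"\nhardest position: index {int(hardest['index'])} "
      f"({hardest['nnz']} fingerprint pixels, score {hardest['score']:.4f})")
print("Positions whose rays miss edge pinholes keep fewer fingerprint "
      "pixels (nnz < 9), score higher, and rank as harder to localize.")
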