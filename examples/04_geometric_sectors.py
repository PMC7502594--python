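"""Geometric-sector controls: transposing a real sector shape onto another blade.

A "geometric sector" is a sector outline moved rigidly to a random position
inside a different cotyledon — a shape-matched control that carries no
transgene influence.  The shape and area are preserved exactly; placements
that would stick out of the blade are rejected.
"""

from space_stomata import synth_cotyledon, synth_sector, transpose_outline

donor = synth_cotyledon(seed=1)
sector = synth_sector(25_000, donor, seed=2)
target = synth_cotyledon(width=1800, height=1100, seed=10)

for seed in range(3):
    moved = transpose_outline(sector, target, seed=seed)
    cx, cy = moved.vertices.mean(axis=0)
    print(
        f"placement {seed}: centred at ({cx:7.1f}, {cy:7.1f}) µm, "
        f"area {moved.area:,.0f} µm² (original {sector.area:,.0f})"
    )
print("\nareas are identical: the control keeps the sector's exact geometry.")
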