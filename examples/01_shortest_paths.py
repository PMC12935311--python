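"""Shortest paths on voxel terrain with asymmetric vertical costs.

Builds a small ramped terrain, prices a few single steps, and shows
that climbing a slope costs more than descending it, so the Dijkstra
distance is direction-dependent.
"""

import numpy as np

from voxelnav import MovementRules, TerrainMap, dijkstra, octile_distance

# a 10x6 terrain: flat plain rising into a 3-block ridge on the right
elevation = np.ones((10, 6), dtype=np.int64)
elevation[6:, :] += np.arange(1, 5)[:, None]  # x=6..9 rise to height 5
terrain = TerrainMap(elevation, np.zeros((10, 6), dtype=bool))

rules = MovementRules(alpha_up=2.0, alpha_down=1.0, max_climb=2, max_fall=3)

flat = dijkstra(terrain, rules, terrain.block_at(0, 0), terrain.block_at(5, 5))
print(f"flat crossing (0,0)->(5,5):  cost {flat.distance:.4f} "
      f"(octile closed form: {octile_distance(5, 5):.4f})")

up = dijkstra(terrain, rules, terrain.block_at(0, 2), terrain.block_at(9, 2))
down = dijkstra(terrain, rules, terrain.block_at(9, 2), terrain.block_at(0, 2))
print(f"onto the ridge  (0,2)->(9,2): cost {up.distance:.4f}")
print(f"off the ridge   (9,2)->(0,2): cost {down.distance:.4f}")
print(f"asymmetry: {up.distance - down.distance:.4f} "
      "(4 blocks climbed at +2.0 each vs descended at +1.0 each)")
print("ridge path:", " ".join(f"({b.x},{b.y},z{b.z})" for b in up.blocks))
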