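"""Emulate a 1D linear array from plane-wave matrix data.

A plane-wave acquisition with a 2D matrix probe can be re-beamformed as
if a 1D linear array had been used: cylindrical delays along the imaging
plane, with the orthogonal axis collimated on a fixed focal line.  This
is how 2D and 3D imaging are compared on identical data.
"""

import numpy as np

import umi

geom = umi.matrix_probe(n_x=12, n_y=12, pitch=0.5, reference_sound_speed=1.4)
angles = np.array(
    [(tx, ty) for tx in (-12, -6, 0, 6, 12) for ty in (-12, -6, 0, 6, 12)],
    dtype=float,
)
target = (0.0, 1.0, 20.0)
raw = umi.simulate_acquisition(
    geom, umi.point_target_medium(target), basis="planewave", seed=1, angles_deg=angles
)
print(f"plane-wave acquisition: {len(angles)} incidences, "
      f"{geom.n_elements} receive elements")

grid3 = umi.ImagingGrid.regular((-1.5, 1.5), (-0.5, 2.5), (19.0, 21.0), pitch=0.5)
img3 = umi.confocal_image(umi.beamform_focused_matrix(raw, grid3, drho_max=5.0))
iz, iy, ix = np.unravel_index(np.argmax(img3), img3.shape)
print(f"3D beamforming: peak at (x, y, z) = "
      f"({grid3.x[ix]}, {grid3.y[iy]}, {grid3.z[iz]}) mm — target {target}")

f2 = umi.emulate_linear_array(
    raw,
    focus_line=(0.0, 20.0),
    grid_y=np.arange(-0.5, 2.51, 0.5),
    grid_z=np.arange(19.0, 21.01, 0.5),
    axis="y",
    drho_max=5.0,
)
img2 = umi.confocal_image(f2)
iz2, iy2, _ = np.unravel_index(np.argmax(img2), img2.shape)
print(f"emulated 1D array (collimated at x = 0 mm, z = 20 mm): "
      f"peak at (y, z) = ({f2.grid.y[iy2]}, {f2.grid.z[iz2]}) mm")
print("the emulated image collapses the x-dimension: one transverse axis "
      "remains, as with a physical linear probe")
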