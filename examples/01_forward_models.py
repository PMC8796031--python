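"""Build a three-shell spherical head, sensors, a source grid and leadfields.

Shows the physical sanity checks a user should expect: skull attenuation of
scalp potentials, radial-dipole silence in MEG, and the average reference.
"""

import numpy as np

from spikebeam import (build_sphere_head, build_source_grid,
                       eeg_sphere_leadfield, meg_sphere_leadfield,
                       place_sensors)

# brain 0.33, skull 0.01, skin 0.43 S/m; radii in mm
head = build_sphere_head([80, 85, 92], [0.33, 0.01, 0.43], "3C-standard")
eeg = place_sensors(head, "eeg", 70, 0.0, "hemisphere")
meg = place_sensors(head, "meg", 271, 20.0, "hemisphere")
grid = build_source_grid(head, spacing=8.0, margin=2.0)
print(f"{grid.n_sources} source points at {grid.spacing} mm spacing")

eeg_lf = eeg_sphere_leadfield(head, eeg, grid)
meg_lf = meg_sphere_leadfield(meg, grid)

# a lateral, mostly tangential dipole of 100 nA.m
p = grid.nearest_index([24.0, 0.0, 48.0])
q = 100.0 * np.array([1.0, 0.0, 0.0])
v = eeg_lf.point(p) @ q
b = meg_lf.point(p) @ q
print(f"peak scalp potential : {np.abs(v).max():8.2f} uV")
print(f"peak magnetic field  : {np.abs(b).max():8.2f} fT")
print(f"average reference    : max column sum {np.abs(v.sum()):.2e} uV")

pos = grid.points[p]
radial = pos / np.linalg.norm(pos)
print(f"radial-moment MEG field: {np.abs(meg_lf.point(p) @ radial).max():.2e} fT"
      " (a radial dipole in a sphere is magnetically silent)")
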