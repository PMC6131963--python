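"""Maximum-principal-stress trajectories of the shear-loaded pad model.

Solves the non-optimised ventral-collagen-layer model (ventral face bonded,
3.815 mN proximal pull) and integrates streamlines of the largest principal
stress direction from the proximal face: the load arcs from the proximal
surface down to the ventral surface, reaching further distally the more
dorsal the seed - the same curved pattern as the collagen fibres.
"""

import numpy as np
from scipy.stats import spearmanr

import frogpad as fp
from frogpad import fem

params = fp.PadGeometryParams()
domain = fp.build_design_domain(params, (30, 20, 9))
material = fp.Material()
load = fem.LoadCase(tractions=(fem.FaceTraction("proximal", (-3.815e-3, 0, 0)),))

u = fp.solve(domain, material, load)
stress = fp.recover_stress(domain, material, u)
trajectories = fp.trace_trajectories(stress, domain)

print(f"{len(trajectories)} trajectories seeded on the proximal face")
print(" seed height z (mm)   mean distal reach x (mm)")
seed_z = np.array([t.seed[2] for t in trajectories])
max_x = np.array([t.max_x for t in trajectories])
for z in np.unique(np.round(seed_z, 3)):
    print(f"        {z:6.3f}          {max_x[np.isclose(seed_z, z)].mean():8.3f}")
rho, _ = spearmanr(seed_z, max_x)
near_ventral = np.mean([t.end[2] <= 2 * domain.voxel_size[2] for t in trajectories])
print(f"rank correlation (seed height vs distal reach): {rho:+.2f}")
print(f"fraction ending at the ventral surface: {near_ventral:.0%}")
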