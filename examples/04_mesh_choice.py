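"""Choosing the initial lattice resolution.

The initial voxel size h must sit in a window: below the mean
inter-particle distance d = (V/N)^(1/3) so each voxel starts locally
well-mixed, but above the critical size pi*sigma (sigma the reaction
radius) so in-voxel reactions are not missed.  For a 1 um box this rules
out the admissible eight-octant meshes (512^3 too coarse, 1024^3 too
fine) while a twenty-seven-voxel 729^3 mesh fits — the reason both merge
operations exist.

The reaction radius here is the 0.36 nm configuration value for the
electron recombination (pi*sigma = 1.13 nm).
"""

import math

from radiolysim import (
    build_merge_schedule,
    load_chemistry,
    mean_interparticle_distance,
    mesh_resolution,
)

sigma = 0.36e-9
chem = load_chemistry(
    {
        "species": [{"name": "e_aq", "D": 4.9e-9, "charge": -1}],
        "reactions": [
            {
                "reactants": ["e_aq", "e_aq"],
                "products": [],
                "rate": 0.636e10,
                "radius": sigma,
            }
        ],
    }
)

# molecules generated in the central voxel of the 21^3 reference mesh
h_ref = 0.2e-6 / 21
d = mean_interparticle_distance(200, h_ref**3)
print(f"mean inter-particle distance d = {d * 1e9:.2f} nm")
print(f"critical voxel size pi*sigma  = {math.pi * sigma * 1e9:.2f} nm\n")

box = 1e-6
for n in (512, 1024, 729):
    h = mesh_resolution(box, n)
    verdict = (
        "too coarse (h > d)"
        if h > d
        else "too fine (h < pi*sigma)"
        if h < math.pi * sigma
        else "admissible"
    )
    print(f"{n:5d}^3 voxels over 1 um: h = {h * 1e9:6.3f} nm  -> {verdict}")

print("\ncoarsening schedule for the admissible choice:")
print(build_merge_schedule(729, box, chem, t1=1e-9).describe())
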