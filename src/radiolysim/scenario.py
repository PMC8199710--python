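"""Synthetic initial conditions for the chemical stage, plus dose/energy
bookkeeping.

The physical and physico-chemical stages (track-structure transport,
sub-picosecond electron physics) are out of scope: the generators here
produce the *chemical-stage starting state* directly — molecules placed in
a central voxel for the diffusion and reaction-diffusion benchmarks, or a
synthetic track of Gaussian spurs standing in for an electron track, with
a declared deposited energy so that G-values are computable.  The
synthetic track is a documented stand-in, not a track-structure
calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sbs import ParticleSet, apply_reflective_boundary

ELECTRONVOLT = 1.602177e-19  # J
WATER_DENSITY = 1000.0  # kg m^-3


def central_voxel_injection(
    n: int, species: str, n_per_side: int, box: float, species_names, rng
) -> ParticleSet:
    """``n`` molecules of one species placed uniformly at random inside the
    central voxel of an (odd) ``n_per_side``^3 mesh over the box."""
    if n_per_side % 2 == 0:
        raise ValueError(
            "central-voxel injection needs an odd mesh side so that a "
            f"central voxel exists (got {n_per_side})"
        )
    h = box / n_per_side
    lo = (n_per_side // 2) * h
    positions = lo + rng.random((n, 3)) * h
    return ParticleSet.from_names(
        positions.reshape(n, 3), [species] * n, species_names, box
    )


@dataclass
class TrackSpec:
    """A straight segment of Gaussian spurs: a synthetic stand-in for the
    energy-deposition pattern of a fast electron crossing the box.

    Each spur deposits ``energy_per_spur`` eV and releases
    ``spur_composition[name]`` molecules of each species, drawn from an
    isotropic Gaussian of width ``spur_sigma`` about the spur centre.
    The default composition (2 e_aq, 2 OH, 2 H3O+, 1 H per 40 eV spur)
    gives early G-values of 5 (e_aq, OH, H3O+) and 2.5 (H) molecules per
    100 eV — typical low-LET early-chemical-stage yields.
    """

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    n_spurs: int
    spur_sigma: float = 2e-9
    energy_per_spur: float = 40.0  # eV
    spur_composition: dict[str, int] = field(
        default_factory=lambda: {"e_aq": 2, "OH": 2, "H3O+": 2, "H": 1}
    )


def synthetic_track(
    spec: TrackSpec, box: float, species_names, rng
) -> tuple[ParticleSet, float]:
    """Generate molecules along a spur track; returns the particle set and
    the total deposited energy (eV).

    Spur centres are evenly spaced along the segment; Gaussian tails
    falling outside the box are reflected back inside so the configured
    multiplicities are conserved.
    """
    start = np.asarray(spec.start, dtype=float)
    end = np.asarray(spec.end, dtype=float)
    for p in (start, end):
        if p.min() < 0 or p.max() > box:
            raise ValueError("track segment must lie inside the box")
    if spec.n_spurs < 1:
        raise ValueError("need at least one spur")
    fractions = (
        np.linspace(0.0, 1.0, spec.n_spurs)
        if spec.n_spurs > 1
        else np.array([0.5])
    )
    centres = start + fractions[:, None] * (end - start)
    positions, names = [], []
    for centre in centres:
        for name, mult in spec.spur_composition.items():
            if mult <= 0:
                continue
            pts = centre + rng.normal(0.0, spec.spur_sigma, (mult, 3))
            positions.append(apply_reflective_boundary(pts, box))
            names.extend([name] * mult)
    if not positions:
        particles = ParticleSet.from_names(
            np.empty((0, 3)), [], species_names, box
        )
    else:
        particles = ParticleSet.from_names(
            np.vstack(positions), names, species_names, box
        )
    return particles, spec.n_spurs * spec.energy_per_spur


def dose_to_energy(
    dose: float, box: float, density: float = WATER_DENSITY
) -> float:
    """Deposited energy (eV) for an absorbed dose (Gy) in a cubic water box
    of side ``box`` (m): dose * density * box^3 / e."""
    if dose < 0 or box < 0 or density < 0:
        raise ValueError("dose, box and density must be nonnegative")
    return dose * density * box**3 / ELECTRONVOLT


def energy_to_n_spurs(energy_ev: float, energy_per_spur: float = 40.0) -> int:
    """Number of spurs whose summed deposits best match a target energy."""
    return max(1, round(energy_ev / energy_per_spur))
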