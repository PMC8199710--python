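"""Hierarchical RDME: scheduled mesh coarsening down to a single voxel.

As the species homogenize by diffusion, the lattice is merged in place —
either eight octant-adjacent voxels into one (mesh side divided by 2) or
twenty-seven voxels into one (side divided by 3).  Each merge happens
after a transfer time

    dt_n = 20 h_n^2 / (6 D_min)

long enough for the slowest-diffusing species to mix across the new,
coarser voxel (h_n is the post-merge voxel size; D_min the lowest
diffusion coefficient in the chemistry table).  Once a single voxel
remains, the dynamics reduce to the chemical master equation and only
reactive events are sampled (direct-method Gillespie).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .analysis import YieldRecorder, YieldSeries, log_time_grid
from .chemistry import ChemistryTable
from .nsm import Mesh, reaction_propensity, sample_event_time


def transfer_time(h_n: float, d_min: float) -> float:
    """Mixing time 20 h_n^2 / (6 D_min) allotted on the mesh with voxel
    size h_n before the next merge."""
    if not h_n > 0:
        raise ValueError("h_n must be > 0")
    if not d_min > 0:
        raise ValueError("d_min must be > 0")
    return 20.0 * h_n**2 / (6.0 * d_min)


def merge_mesh(mesh: Mesh, factor: int) -> Mesh:
    """Merge factor^3 fine voxels into each coarse voxel (factor 2 or 3).

    Every species total is conserved exactly; the time stamp is unchanged.
    """
    if factor not in (2, 3):
        raise ValueError("merge factor must be 2 or 3")
    if mesh.n_per_side % factor:
        raise ValueError(
            f"mesh of {mesh.n_per_side}^3 voxels is not divisible by {factor}"
        )
    coarse = Mesh(
        mesh.n_per_side // factor, mesh.box, mesh.species_names, mesh.time
    )
    for index, vec in mesh.counts.items():
        ix, iy, iz = mesh.coords(index)
        ci = coarse.index(ix // factor, iy // factor, iz // factor)
        for code, s in enumerate(vec):
            if s:
                coarse.add(ci, code, int(s))
    return coarse


def _pure_power(n: int, base: int) -> bool:
    while n % base == 0:
        n //= base
    return n == 1


@dataclass
class MergeSchedule:
    """Sequence of mesh sizes and the absolute times of the merges.

    ``mesh_sizes[k]`` is in force on ``[merge_times[k-1], merge_times[k])``
    (with t1 before the first merge); after the last merge a single voxel
    remains and the CME stage begins at ``merge_times[-1]``.
    """

    operation: str  # "eight-octant" | "twenty-seven-voxel"
    mesh_sizes: list[int]
    transfer_times: list[float]
    t1: float

    @property
    def factor(self) -> int:
        return 2 if self.operation == "eight-octant" else 3

    @property
    def merge_times(self) -> list[float]:
        return list(self.t1 + np.cumsum(self.transfer_times))

    def describe(self) -> str:
        lines = [f"merge schedule ({self.operation}), t1 = {self.t1:.3e} s"]
        for size, t in zip(self.mesh_sizes[1:], self.merge_times):
            lines.append(f"  -> {size}^3 at t = {t:.4e} s")
        return "\n".join(lines)


def build_merge_schedule(
    initial_size: int,
    box: float,
    chem: ChemistryTable,
    t1: float,
) -> MergeSchedule:
    """Coarsening plan from ``initial_size``^3 voxels down to one voxel.

    The merge operation is inferred from the size: a power of 2 uses
    eight-octant merging, a power of 3 twenty-seven-voxel merging.  Merge
    ``n`` occurs at ``t1 + sum_{k<=n} dt_k`` with ``dt_k`` the transfer
    time of the post-merge voxel size.  Warns when the initial voxel is
    below the critical size pi*sigma_max.
    """
    if initial_size == 1:
        return MergeSchedule("eight-octant", [1], [], t1)
    if _pure_power(initial_size, 2):
        operation, factor = "eight-octant", 2
    elif _pure_power(initial_size, 3):
        operation, factor = "twenty-seven-voxel", 3
    else:
        admissible = sorted(
            {2**m for m in range(1, 11)} | {3**m for m in range(1, 7)}
        )
        raise ValueError(
            f"initial mesh size {initial_size} is not a pure power of 2 or 3;"
            f" admissible sizes: {admissible}"
        )
    sigma_max = chem.max_reaction_radius()
    h0 = box / initial_size
    if sigma_max > 0 and h0 < math.pi * sigma_max:
        warnings.warn(
            f"initial voxel size {h0:.3e} m is below the critical size "
            f"pi*sigma = {math.pi * sigma_max:.3e} m",
            stacklevel=2,
        )
    sizes = [initial_size]
    while sizes[-1] > 1:
        sizes.append(sizes[-1] // factor)
    d_min = chem.min_diffusion_coefficient()
    transfer_times = [transfer_time(box / size, d_min) for size in sizes[1:]]
    return MergeSchedule(operation, sizes, transfer_times, t1)


# ---------------------------------------------------------------------------
# Homogeneous (single-voxel CME) stage


def cme_run(
    mesh: Mesh,
    chem: ChemistryTable,
    t_end: float,
    observers: YieldRecorder | None = None,
    rng=None,
) -> tuple[Mesh, YieldSeries]:
    """Direct-method Gillespie over reactions only, on a single-voxel mesh.

    Statistically identical to :func:`radiolysim.nsm.nsm_run` on one voxel
    (a single voxel has no diffusion channels).  Stops at ``t_end`` or when
    no reaction can fire.
    """
    if mesh.n_voxels != 1:
        raise ValueError("cme_run requires a single-voxel mesh")
    if t_end <= mesh.time:
        raise ValueError("t_end must exceed the mesh time")
    if rng is None:
        rng = np.random.default_rng()
    if observers is None:
        observers = YieldRecorder(
            log_time_grid(mesh.time if mesh.time > 0 else t_end * 1e-6, t_end),
            mesh.species_names,
        )
    vol = mesh.voxel_volume
    n_rxn = len(chem.reactions)
    while True:
        vec = mesh.get(0)
        props = np.array(
            [reaction_propensity(vec, r, chem, vol) for r in range(n_rxn)]
        )
        a0 = props.sum()
        tau = sample_event_time(a0, mesh.time, rng)
        if tau > t_end:
            break
        observers.fill_until(tau, mesh.totals())
        r_idx = int(np.searchsorted(np.cumsum(props), rng.random() * a0))
        rxn = chem.reactions[r_idx]
        for name in rxn.reactants:
            mesh.add(0, chem.species_index[name], -1)
        for name in rxn.products:
            mesh.add(0, chem.species_index[name], +1)
        mesh.time = tau
    mesh.time = t_end
    return mesh, observers.finish(mesh.totals())
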