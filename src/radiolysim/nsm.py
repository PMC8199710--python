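"""Compartment-based RDME engine on a uniform Cartesian mesh, advanced by
the next sub-volume method (NSM).

The cubic volume is split into M^3 voxels of size h.  Within a voxel,
molecules are well-mixed and react with Gillespie propensities

    a_r = S_m * S_l * k' (distinct reactants)
    a_r = 1/2 * S_m * (S_m - 1) * k' (identical reactants)

with k' the per-pair rate in the voxel volume.  Diffusion is a jump to one
of the (up to six) face-adjacent voxels at rate lambda = D / h^2 per
molecule per channel; the walls are reflective, implemented by simply
omitting out-of-box channels.

The NSM keeps one pending event per active voxel in an indexed priority
queue keyed by its exponential firing time and repeatedly executes the
globally earliest event, redrawing fresh event times for the affected
voxels from their updated propensities.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .analysis import YieldRecorder, YieldSeries, log_time_grid
from .chemistry import ChemistryTable, rate_to_per_molecule

INFINITY = math.inf


class Mesh:
    """Uniform cubic voxel grid with sparse per-voxel, per-species counts.

    Voxels use 0-based x-fastest linear indexing:
    ``i = ix + M*iy + M^2*iz``.  Only occupied voxels carry storage.
    """

    def __init__(self, n_per_side: int, box: float, species_names, time: float = 0.0):
        if n_per_side < 1:
            raise ValueError("n_per_side must be >= 1")
        self.n_per_side = int(n_per_side)
        self.box = float(box)
        self.species_names = list(species_names)
        self.time = float(time)
        self.counts: dict[int, np.ndarray] = {}
        self._totals = np.zeros(len(self.species_names), dtype=np.int64)

    # -- geometry -----------------------------------------------------------

    @property
    def h(self) -> float:
        """Voxel edge length (m)."""
        return self.box / self.n_per_side

    @property
    def voxel_volume(self) -> float:
        return self.h**3

    @property
    def n_voxels(self) -> int:
        return self.n_per_side**3

    def coords(self, index: int) -> tuple[int, int, int]:
        m = self.n_per_side
        return index % m, (index // m) % m, index // (m * m)

    def index(self, ix: int, iy: int, iz: int) -> int:
        m = self.n_per_side
        return ix + m * iy + m * m * iz

    def neighbors(self, index: int) -> list[int]:
        """Face-adjacent voxels inside the box (3 at a corner, 6 interior)."""
        ix, iy, iz = self.coords(index)
        m = self.n_per_side
        out = []
        if ix > 0:
            out.append(index - 1)
        if ix < m - 1:
            out.append(index + 1)
        if iy > 0:
            out.append(index - m)
        if iy < m - 1:
            out.append(index + m)
        if iz > 0:
            out.append(index - m * m)
        if iz < m - 1:
            out.append(index + m * m)
        return out

    def voxel_center(self, index: int) -> np.ndarray:
        return (np.array(self.coords(index)) + 0.5) * self.h

    # -- state --------------------------------------------------------------

    def get(self, index: int) -> np.ndarray:
        vec = self.counts.get(index)
        if vec is None:
            vec = np.zeros(len(self.species_names), dtype=np.int64)
        return vec

    def add(self, index: int, species_code: int, amount: int) -> None:
        vec = self.counts.get(index)
        if vec is None:
            vec = np.zeros(len(self.species_names), dtype=np.int64)
            self.counts[index] = vec
        vec[species_code] += amount
        if vec[species_code] < 0:
            raise RuntimeError(
                f"negative count for {self.species_names[species_code]} in "
                f"voxel {index}: stale event queue?"
            )
        self._totals[species_code] += amount
        if not vec.any():
            del self.counts[index]

    def totals(self) -> np.ndarray:
        """Whole-mesh per-species molecule totals."""
        return self._totals.copy()

    def radial_distances(self, species: str | None = None):
        """(voxel-centre radii, per-voxel counts) — for radial histograms."""
        sel = (
            slice(None)
            if species is None
            else self.species_names.index(species)
        )
        radii, weights = [], []
        centre = self.box / 2.0
        for idx, vec in self.counts.items():
            w = vec.sum() if species is None else vec[sel]
            if w > 0:
                radii.append(
                    float(np.linalg.norm(self.voxel_center(idx) - centre))
                )
                weights.append(float(w))
        return np.array(radii), np.array(weights)

    def copy(self) -> "Mesh":
        out = Mesh(self.n_per_side, self.box, self.species_names, self.time)
        out.counts = {i: v.copy() for i, v in self.counts.items()}
        out._totals = self._totals.copy()
        return out


def particles_to_mesh(particles, n_per_side: int, box: float | None = None) -> Mesh:
    """Bin explicit molecules onto a mesh (handoff from the particle
    engine).  Half-open voxel intervals [k h, (k+1) h); a coordinate exactly
    on the far box face goes to the last voxel.  Counts are conserved."""
    if box is None:
        box = particles.box
    if particles.positions.size and (
        particles.positions.min() < 0 or particles.positions.max() > box
    ):
        raise ValueError("particles must lie inside the box")
    mesh = Mesh(n_per_side, box, particles.species_names, particles.time)
    h = mesh.h
    ijk = np.clip(
        (particles.positions // h).astype(int), 0, n_per_side - 1
    )
    for (ix, iy, iz), code in zip(ijk, particles.species_codes):
        mesh.add(mesh.index(ix, iy, iz), int(code), 1)
    return mesh


# ---------------------------------------------------------------------------
# Propensities


def reaction_propensity(
    counts, reaction_index: int, chem: ChemistryTable, volume: float
) -> float:
    """Propensity (s^-1) of one reaction in a voxel with the given counts."""
    rxn = chem.reactions[reaction_index]
    k_pair = rate_to_per_molecule(rxn.rate, volume)
    ia = chem.species_index[rxn.reactants[0]]
    ib = chem.species_index[rxn.reactants[1]]
    if rxn.identical_reactants:
        s = counts[ia]
        return 0.5 * s * (s - 1) * k_pair if s >= 2 else 0.0
    return float(counts[ia] * counts[ib]) * k_pair


def diffusion_propensity(s_k: int, diffusion_coefficient: float, h: float) -> float:
    """Propensity (s^-1) of one (voxel, neighbor) hop channel:
    lambda * S_k with lambda = D / h^2."""
    if not h > 0:
        raise ValueError("voxel size h must be > 0")
    return diffusion_coefficient / h**2 * s_k


def voxel_total_propensity(mesh: Mesh, index: int, chem: ChemistryTable) -> float:
    """Sum of all reaction and diffusion propensities of one voxel.

    Diffusion counts one channel per existing face neighbor; reflective
    walls contribute nothing."""
    vec = mesh.get(index)
    if not vec.any():
        return 0.0
    total = 0.0
    vol = mesh.voxel_volume
    for r_idx in range(len(chem.reactions)):
        total += reaction_propensity(vec, r_idx, chem, vol)
    n_nb = len(mesh.neighbors(index))
    h = mesh.h
    for code, s in enumerate(vec):
        if s > 0:
            d = chem.species[code].diffusion_coefficient
            total += n_nb * diffusion_propensity(int(s), d, h)
    return total


# ---------------------------------------------------------------------------
# Event sampling


def sample_event_time(a_i: float, now: float, rng) -> float:
    """Absolute firing time now + Exp(a_i); +inf for an inactive voxel
    (tau_i = -ln(xi)/a_i with xi uniform)."""
    if a_i <= 0.0:
        return INFINITY
    xi = 1.0 - rng.random()  # in (0, 1]
    return now - math.log(xi) / a_i


def select_event_type(mesh: Mesh, index: int, chem: ChemistryTable, rng):
    """Categorical draw over the voxel's channels, each weighted by its
    propensity.

    Returns ``("reaction", r_idx)`` or ``("diffusion", species_code, j)``.
    Diffusion weight is identical across a voxel's neighbors, so the
    species is drawn propensity-weighted and the destination uniformly.
    """
    vec = mesh.get(index)
    weights = []
    channels = []
    vol = mesh.voxel_volume
    for r_idx in range(len(chem.reactions)):
        a = reaction_propensity(vec, r_idx, chem, vol)
        if a > 0:
            weights.append(a)
            channels.append(("reaction", r_idx))
    nbs = mesh.neighbors(index)
    h = mesh.h
    for code, s in enumerate(vec):
        if s > 0:
            d = chem.species[code].diffusion_coefficient
            a = len(nbs) * diffusion_propensity(int(s), d, h)
            if a > 0:
                weights.append(a)
                channels.append(("diffusion", code))
    if not weights:
        raise RuntimeError(
            f"select_event_type called on voxel {index} with zero propensity"
        )
    weights = np.asarray(weights)
    pick = channels[
        int(np.searchsorted(np.cumsum(weights), rng.random() * weights.sum()))
    ]
    if pick[0] == "reaction":
        return pick
    j = nbs[int(rng.integers(len(nbs)))]
    return ("diffusion", pick[1], j)


def apply_event(mesh: Mesh, event, chem: ChemistryTable):
    """Execute one event in place; returns the set of affected voxels.

    A reaction eliminates its reactants and creates its products in the
    same voxel; a diffusion moves one molecule to the destination voxel.
    """
    if event[0] == "reaction":
        _, index, r_idx = event
        rxn = chem.reactions[r_idx]
        for name in rxn.reactants:
            mesh.add(index, chem.species_index[name], -1)
        for name in rxn.products:
            mesh.add(index, chem.species_index[name], +1)
        return {index}
    if event[0] == "diffusion":
        _, index, code, j = event
        mesh.add(index, code, -1)
        mesh.add(j, code, +1)
        return {index, j}
    raise ValueError(f"unknown event {event!r}")


# ---------------------------------------------------------------------------
# NSM driver


class _EventQueue:
    """Indexed min-priority queue with lazy invalidation: one live entry per
    active voxel, keyed (tau, voxel) so simultaneous events resolve to the
    lower voxel index."""

    def __init__(self):
        self._heap: list[tuple[float, int, int]] = []
        self._version: dict[int, int] = {}

    def schedule(self, voxel: int, tau: float) -> None:
        version = self._version.get(voxel, 0) + 1
        self._version[voxel] = version
        if tau < INFINITY:
            heapq.heappush(self._heap, (tau, voxel, version))

    def pop(self):
        while self._heap:
            tau, voxel, version = heapq.heappop(self._heap)
            if self._version.get(voxel) == version:
                return tau, voxel
        return None


def nsm_run(
    mesh: Mesh,
    chem: ChemistryTable,
    t_end: float,
    observers: YieldRecorder | None = None,
    rng=None,
) -> tuple[Mesh, YieldSeries]:
    """Advance the mesh to ``t_end`` with the next sub-volume method.

    The mesh is evolved in place.  Pop the earliest voxel event, execute
    it, then redraw fresh firing times (and, on firing, channel choices)
    for every affected voxel from its updated propensity.
    """
    if t_end <= mesh.time:
        raise ValueError("t_end must exceed the mesh time")
    if rng is None:
        rng = np.random.default_rng()
    if observers is None:
        observers = YieldRecorder(
            log_time_grid(mesh.time if mesh.time > 0 else t_end * 1e-6, t_end),
            mesh.species_names,
        )
    queue = _EventQueue()
    for voxel in list(mesh.counts):
        a = voxel_total_propensity(mesh, voxel, chem)
        queue.schedule(voxel, sample_event_time(a, mesh.time, rng))

    while True:
        head = queue.pop()
        if head is None or head[0] > t_end:
            break
        tau, voxel = head
        observers.fill_until(tau, mesh.totals())
        event_kind = select_event_type(mesh, voxel, chem, rng)
        if event_kind[0] == "reaction":
            event = ("reaction", voxel, event_kind[1])
        else:
            event = ("diffusion", voxel, event_kind[1], event_kind[2])
        affected = apply_event(mesh, event, chem)
        mesh.time = tau
        for v in affected:
            a = voxel_total_propensity(mesh, v, chem)
            queue.schedule(v, sample_event_time(a, tau, rng))

    mesh.time = t_end
    return mesh, observers.finish(mesh.totals())
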