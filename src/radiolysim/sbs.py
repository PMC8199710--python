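"""Particle-based step-by-step (SBS) Brownian dynamics.

The microscopic sub-stage of the chemical phase: every molecule carries an
explicit 3D position, diffuses by isotropic Gaussian steps, and reacts on
encounter — the moment it comes within the reaction radius sigma of a
partner (diffusion-controlled reactions).  The step length is adaptive:
the "dynamic time step" is the largest step over which no reactive pair
can encounter with at least the configured confidence (95% by default),
floored at a minimum step (1 ps by default) to avoid grinding through tiny
steps.

Encounters inside a finite step are sampled per pair from the
absorbing-sphere first-passage probability (the same expression the
dynamic time step inverts), so the per-step reaction probability is exact
given the pair's current separation.

The walls of the cubic volume are reflective: a molecule leaving the box
is mirrored back inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.special import erfc, erfcinv

from .analysis import YieldRecorder, YieldSeries, log_time_grid
from .chemistry import ChemistryTable


@dataclass
class SbsConfig:
    """Step control for the particle engine.

    min_time_step: floor of the dynamic step (s); 1 ps default.
    max_time_step: cap when no reactive pair constrains the step (s).
    confidence: pair-encounter exclusion confidence of the dynamic step.
    """

    min_time_step: float = 1e-12
    max_time_step: float = 1e-9
    confidence: float = 0.95
    rng_seed: int | None = None

    def __post_init__(self):
        if not self.min_time_step > 0:
            raise ValueError("min_time_step must be > 0")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if self.max_time_step < self.min_time_step:
            raise ValueError("max_time_step must be >= min_time_step")


class ParticleSet:
    """Explicit molecules: positions (N, 3) in metres inside [0, box]^3 and
    a parallel array of species codes (indices into a chemistry table)."""

    def __init__(self, positions, species_codes, species_names, box, time=0.0):
        self.positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        self.species_codes = np.asarray(species_codes, dtype=np.intp)
        self.species_names = list(species_names)
        self.box = float(box)
        self.time = float(time)
        if self.positions.shape != (len(self.species_codes), 3):
            raise ValueError("positions and species arrays disagree in length")
        if self.positions.size and (
            self.positions.min() < 0 or self.positions.max() > self.box
        ):
            raise ValueError("positions must lie inside [0, box]^3")

    @classmethod
    def from_names(cls, positions, names, species_names, box, time=0.0):
        index = {n: i for i, n in enumerate(species_names)}
        codes = [index[n] for n in names]
        return cls(positions, codes, species_names, box, time)

    def __len__(self) -> int:
        return len(self.species_codes)

    def counts(self) -> np.ndarray:
        """Per-species molecule totals, aligned with ``species_names``."""
        return np.bincount(self.species_codes, minlength=len(self.species_names))

    def radial_distances(self, species: str | None = None):
        """(radii from box centre, unit weights) — for radial histograms."""
        mask = (
            slice(None)
            if species is None
            else self.species_codes == self.species_names.index(species)
        )
        pos = self.positions[mask]
        radii = np.linalg.norm(pos - self.box / 2.0, axis=1)
        return radii, np.ones(len(pos))

    def copy(self) -> "ParticleSet":
        return ParticleSet(
            self.positions.copy(),
            self.species_codes.copy(),
            self.species_names,
            self.box,
            self.time,
        )


# ---------------------------------------------------------------------------
# Elementary operations


def apply_reflective_boundary(position, box: float):
    """Mirror-fold coordinates into [0, box] (x < 0 -> -x; x > L -> 2L - x,
    repeated as often as needed).  Works element-wise on arrays."""
    folded = np.mod(np.asarray(position, dtype=float), 2.0 * box)
    return np.where(folded > box, 2.0 * box - folded, folded)


def brownian_step(
    particles: ParticleSet, chem: ChemistryTable, dt: float, rng
) -> ParticleSet:
    """Displace every molecule by an isotropic Gaussian with per-axis
    variance 2 D dt, then reflect off the walls."""
    if not dt > 0:
        raise ValueError("dt must be > 0")
    d_by_code = np.array([s.diffusion_coefficient for s in chem.species])
    sigma = np.sqrt(2.0 * d_by_code[particles.species_codes] * dt)
    new_pos = (
        particles.positions
        + rng.normal(size=particles.positions.shape) * sigma[:, None]
    )
    new_pos = apply_reflective_boundary(new_pos, particles.box)
    return ParticleSet(
        new_pos,
        particles.species_codes,
        particles.species_names,
        particles.box,
        particles.time + dt,
    )


def _pair_encounter_time(r, sigma, d_sum, p_target):
    """Largest t with encounter probability <= p_target for a pair at
    distance r (absorbing-sphere first-passage approximation
    P(t) = (sigma/r) erfc((r - sigma) / sqrt(4 D' t))).

    Returns +inf when the pair can never encounter with probability
    p_target (sigma/r < p_target), 0.0 at/inside contact.
    """
    if r <= sigma:
        return 0.0
    ratio = p_target * r / sigma
    if ratio >= 1.0:
        return math.inf
    u = erfcinv(ratio)
    return (r - sigma) ** 2 / (4.0 * d_sum * u * u)


def _channel_pairs(codes, ia: int, ib: int):
    """Index arrays (ii, jj) of all molecule pairs of a reactant channel."""
    idx_a = np.flatnonzero(codes == ia)
    if ia == ib:
        if len(idx_a) < 2:
            return None
        tri = np.triu_indices(len(idx_a), k=1)
        return idx_a[tri[0]], idx_a[tri[1]]
    idx_b = np.flatnonzero(codes == ib)
    if len(idx_a) == 0 or len(idx_b) == 0:
        return None
    return np.repeat(idx_a, len(idx_b)), np.tile(idx_b, len(idx_a))


def dynamic_time_step(
    particles: ParticleSet, chem: ChemistryTable, cfg: SbsConfig
) -> float:
    """Largest step such that no reactive pair encounters with at least the
    configured confidence, clipped to [min_time_step, max_time_step]."""
    t_star = math.inf
    p_target = 1.0 - cfg.confidence
    codes = particles.species_codes
    for (ia, ib), r_idxs in chem.pair_reactions.items():
        pairs = _channel_pairs(codes, ia, ib)
        if pairs is None:
            continue
        ii, jj = pairs
        r_min = float(
            np.min(
                np.linalg.norm(
                    particles.positions[ii] - particles.positions[jj], axis=1
                )
            )
        )
        for r_idx in r_idxs:
            rxn = chem.reactions[r_idx]
            sigma = chem.reaction_radius(r_idx)
            d_sum = chem.diffusion_coefficient(
                rxn.reactants[0]
            ) + chem.diffusion_coefficient(rxn.reactants[1])
            t_star = min(
                t_star, _pair_encounter_time(r_min, sigma, d_sum, p_target)
            )
    return float(min(max(t_star, cfg.min_time_step), cfg.max_time_step))


def _apply_pairs(particles: ParticleSet, chem: ChemistryTable, hits):
    """Greedily execute reactions, nearest pair first (ties broken by
    lowest particle indices); each molecule reacts at most once.  Reactants
    are removed; products appear at the reactants' midpoint, reflected into
    the box if necessary."""
    if not hits:
        return particles
    positions = particles.positions
    codes = particles.species_codes
    hits = sorted(hits)
    consumed: set[int] = set()
    removed: list[int] = []
    new_positions: list[np.ndarray] = []
    new_codes: list[int] = []
    name_to_code = {n: c for c, n in enumerate(particles.species_names)}
    for _, i, j, r_idx in hits:
        if i in consumed or j in consumed:
            continue
        consumed.update((i, j))
        removed.extend((i, j))
        midpoint = apply_reflective_boundary(
            (positions[i] + positions[j]) / 2.0, particles.box
        )
        for product in chem.reactions[r_idx].products:
            new_positions.append(midpoint)
            new_codes.append(name_to_code[product])

    keep = np.ones(len(particles), dtype=bool)
    keep[removed] = False
    out_pos = positions[keep]
    out_codes = codes[keep]
    if new_positions:
        out_pos = np.vstack([out_pos, np.array(new_positions)])
        out_codes = np.concatenate(
            [out_codes, np.array(new_codes, dtype=np.intp)]
        )
    return ParticleSet(
        out_pos, out_codes, particles.species_names, particles.box, particles.time
    )


def find_and_apply_reactions(
    particles: ParticleSet, chem: ChemistryTable, rng=None
) -> ParticleSet:
    """React every pair of molecules currently separated by less than its
    reaction radius (the encounter criterion applied to a static
    configuration, e.g. contacts present in the initial condition)."""
    codes = particles.species_codes
    positions = particles.positions
    hits = []
    for (ia, ib), r_idxs in chem.pair_reactions.items():
        pairs = _channel_pairs(codes, ia, ib)
        if pairs is None:
            continue
        ii, jj = pairs
        d = np.linalg.norm(positions[ii] - positions[jj], axis=1)
        for r_idx in r_idxs:
            sigma = chem.reaction_radius(r_idx)
            for k in np.flatnonzero(d < sigma):
                i, j = int(ii[k]), int(jj[k])
                hits.append((float(d[k]), min(i, j), max(i, j), r_idx))
    return _apply_pairs(particles, chem, hits)


def sample_encounter_reactions(
    particles: ParticleSet,
    chem: ChemistryTable,
    dt: float,
    rng,
) -> ParticleSet:
    """Sample diffusion-controlled encounters over the coming interval dt.

    Each reactive pair at separation d reacts with the absorbing-sphere
    first-passage probability

        P(dt) = min(1, (sigma/d) * erfc((d - sigma) / sqrt(4 D' dt)))

    (certain reaction for d <= sigma).  The dynamic time step caps this at
    1 - confidence for every pair, so per-step probabilities stay small and
    the scheme tracks the exact pair kinetics closely; an end-of-step
    overlap test alone would miss nearly all crossings once the step
    length exceeds sigma.
    """
    codes = particles.species_codes
    positions = particles.positions
    hits = []
    for (ia, ib), r_idxs in chem.pair_reactions.items():
        pairs = _channel_pairs(codes, ia, ib)
        if pairs is None:
            continue
        ii, jj = pairs
        d = np.linalg.norm(positions[ii] - positions[jj], axis=1)
        for r_idx in r_idxs:
            rxn = chem.reactions[r_idx]
            sigma = chem.reaction_radius(r_idx)
            d_sum = chem.diffusion_coefficient(
                rxn.reactants[0]
            ) + chem.diffusion_coefficient(rxn.reactants[1])
            with np.errstate(divide="ignore"):
                p = (sigma / d) * erfc(
                    np.maximum(d - sigma, 0.0) / math.sqrt(4.0 * d_sum * dt)
                )
            react = rng.random(len(d)) < p
            for k in np.flatnonzero(react):
                i, j = int(ii[k]), int(jj[k])
                hits.append((float(d[k]), min(i, j), max(i, j), r_idx))
    return _apply_pairs(particles, chem, hits)


# ---------------------------------------------------------------------------
# Driver


def run_sbs(
    initial: ParticleSet,
    chem: ChemistryTable,
    cfg: SbsConfig,
    t_end: float,
    observers: YieldRecorder | None = None,
    rng=None,
) -> tuple[ParticleSet, YieldSeries]:
    """Alternate dynamic step / Gaussian move / encounter check to t_end.

    Returns the final particle set (handoff state for the lattice engine)
    and the recorded yield series.
    """
    if t_end <= initial.time:
        raise ValueError("t_end must exceed the initial time")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    if observers is None:
        observers = YieldRecorder(
            log_time_grid(max(initial.time, cfg.min_time_step), t_end),
            initial.species_names,
        )
    # contacts present in the initial condition react before any step
    state = find_and_apply_reactions(initial, chem, rng)
    while state.time < t_end:
        dt = dynamic_time_step(state, chem, cfg)
        dt = min(dt, t_end - state.time)
        observers.fill_until(state.time + dt, state.counts())
        state = sample_encounter_reactions(state, chem, dt, rng)
        state = brownian_step(state, chem, dt, rng)
    return state, observers.finish(state.counts())
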