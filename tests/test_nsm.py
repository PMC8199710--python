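"""Lattice RDME engine: propensities, event sampling, the NSM loop, and
its agreement with an independently written direct-method SSA."""

import math

import numpy as np
import pytest
from scipy import stats

from radiolysim import (
    Mesh,
    apply_event,
    diffusion_propensity,
    load_chemistry,
    nsm_run,
    particles_to_mesh,
    rate_to_per_molecule,
    reaction_propensity,
    sample_event_time,
    select_event_type,
    voxel_total_propensity,
)
from radiolysim.analysis import YieldRecorder
from radiolysim.sbs import ParticleSet
from radiolysim.scenario import central_voxel_injection

BOX = 0.2e-6
H_REF = BOX / 21
D_EAQ = 4.9e-9


def direct_ssa_recombination(n0, k_pair, t_end, rng):
    """Independent direct-method Gillespie for 2A -> products in one
    well-mixed compartment; returns N(t_end)."""
    n = n0
    t = 0.0
    while n >= 2:
        a = 0.5 * n * (n - 1) * k_pair
        t += rng.exponential(1.0 / a)
        if t > t_end:
            break
        n -= 2
    return n


class TestParticlesToMesh:
    def test_central_injection_round_trip(self, e_aq_only, rng):
        ps = central_voxel_injection(200, "e_aq", 21, BOX, ["e_aq"], rng)
        mesh = particles_to_mesh(ps, 21)
        centre = mesh.index(10, 10, 10)
        assert mesh.get(centre)[0] == 200
        assert mesh.totals()[0] == 200
        assert len(mesh.counts) == 1

    def test_boundary_coordinate_goes_to_last_voxel(self):
        ps = ParticleSet.from_names([[BOX, BOX, BOX]], ["e_aq"], ["e_aq"], BOX)
        mesh = particles_to_mesh(ps, 4)
        assert mesh.get(mesh.index(3, 3, 3))[0] == 1

    def test_counts_conserved_for_random_positions(self, rng):
        pos = rng.random((517, 3)) * BOX
        ps = ParticleSet.from_names(pos, ["e_aq"] * 517, ["e_aq"], BOX)
        mesh = particles_to_mesh(ps, 8)
        assert mesh.totals()[0] == 517


class TestPropensities:
    def test_identical_reactant_pair_propensity(self, recombination_only):
        counts = np.zeros(len(recombination_only.species_names), dtype=int)
        counts[recombination_only.species_index["e_aq"]] = 2
        a = reaction_propensity(counts, 0, recombination_only, H_REF**3)
        assert a == pytest.approx(
            rate_to_per_molecule(0.636e10, H_REF**3)
        )
        assert a == pytest.approx(1.2226e7, rel=1e-4)

    def test_single_molecule_cannot_self_react(self, recombination_only):
        counts = np.zeros(len(recombination_only.species_names), dtype=int)
        counts[recombination_only.species_index["e_aq"]] = 1
        assert reaction_propensity(counts, 0, recombination_only, 1e-24) == 0.0

    def test_distinct_reactants_combinatorial_count(self, chem):
        r5 = next(
            i
            for i, r in enumerate(chem.reactions)
            if sorted(r.reactants) == ["H3O+", "e_aq"]
        )
        counts = np.zeros(chem.n_species, dtype=int)
        counts[chem.species_index["H3O+"]] = 3
        counts[chem.species_index["e_aq"]] = 4
        one = np.zeros(chem.n_species, dtype=int)
        one[chem.species_index["H3O+"]] = 1
        one[chem.species_index["e_aq"]] = 1
        v = 1e-24
        assert reaction_propensity(counts, r5, chem, v) == pytest.approx(
            12 * reaction_propensity(one, r5, chem, v)
        )

    def test_diffusion_rate_reference_value(self):
        assert diffusion_propensity(1, D_EAQ, H_REF) == pytest.approx(
            5.4022e7, rel=1e-4
        )
        assert diffusion_propensity(0, D_EAQ, H_REF) == 0.0
        assert diffusion_propensity(1, D_EAQ, H_REF / 2) == pytest.approx(
            4 * diffusion_propensity(1, D_EAQ, H_REF)
        )

    def test_empty_voxel_total_is_zero(self, chem):
        mesh = Mesh(3, BOX, chem.species_names)
        assert voxel_total_propensity(mesh, 13, chem) == 0.0

    def test_corner_voxel_has_three_channels(self, e_aq_only):
        mesh = Mesh(3, BOX, ["e_aq"])
        mesh.add(0, 0, 5)
        lam = D_EAQ / mesh.h**2
        assert voxel_total_propensity(mesh, 0, e_aq_only) == pytest.approx(
            3 * lam * 5
        )

    def test_interior_voxel_against_channel_enumeration(self, recombination_only):
        # brute-force oracle: sum every reaction and (species, neighbor)
        # diffusion channel explicitly
        chem = recombination_only
        mesh = Mesh(5, BOX, chem.species_names)
        centre = mesh.index(2, 2, 2)
        mesh.add(centre, chem.species_index["e_aq"], 200)
        mesh.add(centre, chem.species_index["OH-"], 7)
        expected = 0.0
        vec = mesh.get(centre)
        for r_idx, rxn in enumerate(chem.reactions):
            ia, ib = (chem.species_index[n] for n in rxn.reactants)
            k = rate_to_per_molecule(rxn.rate, mesh.voxel_volume)
            if ia == ib:
                expected += 0.5 * vec[ia] * (vec[ia] - 1) * k
            else:
                expected += vec[ia] * vec[ib] * k
        for code, s in enumerate(vec):
            d = chem.species[code].diffusion_coefficient
            for _ in mesh.neighbors(centre):
                expected += d / mesh.h**2 * s
        assert voxel_total_propensity(mesh, centre, chem) == pytest.approx(
            expected
        )


class _FixedUniform:
    """Stub generator whose random() returns a preset value."""

    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


class TestEventSampling:
    def test_inactive_voxel_never_fires(self, rng):
        assert sample_event_time(0.0, 5.0, rng) == math.inf

    def test_unit_exponential_inverse(self):
        # xi = e^-1  =>  tau - now = -ln(xi)/a = 1/a
        stub = _FixedUniform(1.0 - math.exp(-1.0))
        assert sample_event_time(1e6, 0.0, stub) == pytest.approx(1e-6)

    def test_exponential_mean(self, rng):
        draws = np.array(
            [sample_event_time(1.0, 0.0, rng) for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(1.0, abs=0.01)

    def test_single_channel_always_chosen(self, e_aq_only, rng):
        mesh = Mesh(3, BOX, ["e_aq"])
        mesh.add(13, 0, 1)
        kind = select_event_type(mesh, 13, e_aq_only, rng)
        assert kind[0] == "diffusion" and kind[1] == 0

    def test_zero_propensity_voxel_rejected(self, e_aq_only, rng):
        mesh = Mesh(3, BOX, ["e_aq"])
        with pytest.raises(RuntimeError):
            select_event_type(mesh, 13, e_aq_only, rng)

    def test_channel_selection_follows_propensity_ratio(self, rng):
        # two species with D_A = 3 D_B and one molecule each: the species
        # channels should be picked in proportion 3:1
        table = load_chemistry(
            {
                "species": [
                    {"name": "A", "D": 3e-9},
                    {"name": "B", "D": 1e-9},
                ],
                "reactions": [],
            }
        )
        mesh = Mesh(3, BOX, ["A", "B"])
        mesh.add(13, 0, 1)
        mesh.add(13, 1, 1)
        n = 100_000
        picks = sum(
            select_event_type(mesh, 13, table, rng)[1] == 0 for _ in range(n)
        )
        assert picks / n == pytest.approx(0.75, abs=0.01)

    def test_interior_neighbors_uniform(self, e_aq_only, rng):
        mesh = Mesh(3, BOX, ["e_aq"])
        mesh.add(13, 0, 1)
        n = 60_000
        dest = np.array(
            [select_event_type(mesh, 13, e_aq_only, rng)[2] for _ in range(n)]
        )
        freqs = np.bincount(dest, minlength=27)[mesh.neighbors(13)] / n
        np.testing.assert_allclose(freqs, 1 / 6, atol=0.012)


class TestApplyEvent:
    def test_diffusion_moves_one_molecule(self, e_aq_only):
        mesh = Mesh(3, BOX, ["e_aq"])
        mesh.add(13, 0, 4)
        affected = apply_event(mesh, ("diffusion", 13, 0, 14), e_aq_only)
        assert affected == {13, 14}
        assert mesh.get(13)[0] == 3 and mesh.get(14)[0] == 1
        assert mesh.totals()[0] == 4

    def test_hydroxyl_recombination_stoichiometry(self, chem):
        r8 = next(
            i
            for i, r in enumerate(chem.reactions)
            if r.reactants == ("OH", "OH")
        )
        mesh = Mesh(3, BOX, chem.species_names)
        mesh.add(0, chem.species_index["OH"], 2)
        apply_event(mesh, ("reaction", 0, r8), chem)
        assert mesh.get(0)[chem.species_index["OH"]] == 0
        assert mesh.get(0)[chem.species_index["H2O2"]] == 1

    def test_neutralization_drops_water_product(self, chem):
        r5 = next(
            i
            for i, r in enumerate(chem.reactions)
            if sorted(r.reactants) == ["H3O+", "e_aq"]
        )
        mesh = Mesh(3, BOX, chem.species_names)
        mesh.add(5, chem.species_index["H3O+"], 1)
        mesh.add(5, chem.species_index["e_aq"], 1)
        apply_event(mesh, ("reaction", 5, r5), chem)
        vec = mesh.get(5)
        assert vec[chem.species_index["H3O+"]] == 0
        assert vec[chem.species_index["e_aq"]] == 0
        assert vec[chem.species_index["H"]] == 1
        assert vec.sum() == 1  # no tracked water

    def test_reaction_with_absent_reactants_fails(self, chem):
        mesh = Mesh(3, BOX, chem.species_names)
        with pytest.raises(RuntimeError, match="stale"):
            apply_event(mesh, ("reaction", 0, 0), chem)


class TestNsmRun:
    def test_empty_mesh_returns_at_t_end(self, chem, rng):
        mesh = Mesh(3, BOX, chem.species_names)
        mesh, series = nsm_run(mesh, chem, 1e-6, rng=rng)
        assert mesh.time == 1e-6
        assert series.counts.sum() == 0

    def test_diffusion_conserves_counts(self, e_aq_only, rng):
        ps = central_voxel_injection(150, "e_aq", 21, BOX, ["e_aq"], rng)
        mesh = particles_to_mesh(ps, 21)
        mesh, series = nsm_run(mesh, e_aq_only, 100e-9, rng=rng)
        assert mesh.totals()[0] == 150
        assert (series.counts[:, 0] == 150).all()

    def test_hopping_msd_matches_einstein(self, e_aq_only, rng):
        # voxel random walk: MSD of voxel centres ~ 6 D t for t >> h^2/D
        n_rep = 300
        t = 50e-9
        msds = []
        for _ in range(n_rep):
            mesh = Mesh(21, BOX, ["e_aq"])
            centre = mesh.index(10, 10, 10)
            mesh.add(centre, 0, 1)
            mesh, _ = nsm_run(mesh, e_aq_only, t, rng=rng)
            (idx,) = mesh.counts
            msds.append(
                np.sum((mesh.voxel_center(idx) - mesh.voxel_center(centre)) ** 2)
            )
        msds = np.array(msds)
        expected = 6 * D_EAQ * t
        se = msds.std(ddof=1) / np.sqrt(n_rep)
        assert abs(msds.mean() - expected) < 3 * se

    def test_two_state_occupancy_relaxation(self, rng):
        # one molecule on a 2^3 mesh: each axis is an independent two-state
        # chain with relaxation rate 2 lambda;
        # P(same side as start) = (1 + exp(-2 lambda t)) / 2
        d = 1e-9
        table = load_chemistry(
            {"species": [{"name": "A", "D": d}], "reactions": []}
        )
        box = 1e-7
        lam = d / (box / 2) ** 2
        t = 0.4 / lam
        expected = 0.5 * (1 + math.exp(-2 * lam * t))
        n_rep = 1500
        same = 0
        for _ in range(n_rep):
            mesh = Mesh(2, box, ["A"])
            mesh.add(0, 0, 1)
            mesh, _ = nsm_run(mesh, table, t, rng=rng)
            (idx,) = mesh.counts
            same += int(mesh.coords(idx)[0] == 0)
        frac = same / n_rep
        se = math.sqrt(expected * (1 - expected) / n_rep)
        assert abs(frac - expected) < 3.5 * se

    def test_single_voxel_matches_direct_ssa(self, recombination_only, rng):
        # NSM on one voxel must reproduce the direct-method Gillespie law
        chem = recombination_only
        n0, v = 40, (20e-9) ** 3
        k_pair = rate_to_per_molecule(0.636e10, v)
        horizon = 2.0 / (0.5 * n0 * (n0 - 1) * k_pair) * 10
        box = v ** (1 / 3)
        n_rep = 600
        nsm_final, ssa_final = [], []
        for _ in range(n_rep):
            mesh = Mesh(1, box, chem.species_names)
            mesh.add(0, chem.species_index["e_aq"], n0)
            mesh, _ = nsm_run(mesh, chem, horizon, rng=rng)
            nsm_final.append(mesh.totals()[chem.species_index["e_aq"]])
            ssa_final.append(
                direct_ssa_recombination(n0, k_pair, horizon, rng)
            )
        nsm_final, ssa_final = np.array(nsm_final), np.array(ssa_final)
        se = math.sqrt(
            nsm_final.var(ddof=1) / n_rep + ssa_final.var(ddof=1) / n_rep
        )
        assert abs(nsm_final.mean() - ssa_final.mean()) < 3 * se
        # distributions agree, not just means
        _, p = stats.ks_2samp(nsm_final, ssa_final)
        assert p > 0.001
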