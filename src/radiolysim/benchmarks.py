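"""Engine-vs-engine benchmark drivers.

Three canonical checks of the lattice engine against the particle engine:

* pure diffusion of 200 solvated electrons from a central voxel, compared
  at a fixed horizon by a KS test on radial histograms;
* the e_aq + e_aq reaction-diffusion system run by both engines from the
  same initial condition;
* a full radiolysis scenario from a synthetic spur track through the
  hybrid driver, reported as G-values.

These functions are what the CLI subcommands, the acceptance checks and
the examples call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import analysis
from .analysis import YieldRecorder, YieldSeries, log_time_grid, radial_distribution
from .chemistry import ChemistryTable, load_chemistry
from .hybrid import RunConfig, run_hybrid
from .nsm import nsm_run, particles_to_mesh
from .sbs import SbsConfig, brownian_step, run_sbs
from .scenario import TrackSpec, central_voxel_injection, dose_to_energy, synthetic_track


def diffusion_only_chemistry(d: float = 4.9e-9) -> ChemistryTable:
    """A single-species (solvated electron), zero-reaction table."""
    return load_chemistry(
        {"species": [{"name": "e_aq", "D": d, "charge": -1}], "reactions": []}
    )


def electron_recombination_chemistry() -> ChemistryTable:
    """The bundled table reduced to e_aq + e_aq -> 2 OH- + H2 only."""
    chem = load_chemistry()
    (r9,) = [
        i
        for i, r in enumerate(chem.reactions)
        if r.reactants == ("e_aq", "e_aq")
    ]
    return chem.subset([r9])


@dataclass
class DiffusionBenchmarkResult:
    ks_statistic: float
    p_value: float
    n_molecules: int
    rdme_histogram: analysis.RadialHistogram
    sbs_histogram: analysis.RadialHistogram


def diffusion_benchmark(
    seed: int,
    n_molecules: int = 200,
    mesh_side: int = 21,
    box: float = 0.2e-6,
    t: float = 100e-9,
    n_bins: int = 21,
) -> DiffusionBenchmarkResult:
    """Pure diffusion: lattice engine vs one single Gaussian particle step.

    200 e_aq start uniformly inside the central voxel of a 21^3 mesh over a
    0.2 um box (D = 4.9e-9 m^2/s).  The lattice engine runs the NSM to the
    horizon; the particle engine takes a single free Gaussian step of the
    full horizon (valid while the spread stays far from the walls).  Radial
    histograms about the box centre are compared with the two-sample KS
    test on the per-bin counts.
    """
    rng = np.random.default_rng(seed)
    chem = diffusion_only_chemistry()
    names = chem.species_names

    initial = central_voxel_injection(
        n_molecules, "e_aq", mesh_side, box, names, rng
    )
    mesh = particles_to_mesh(initial, mesh_side)
    mesh, _ = nsm_run(mesh, chem, t, rng=rng)

    particles = central_voxel_injection(
        n_molecules, "e_aq", mesh_side, box, names, rng
    )
    particles = brownian_step(particles, chem, t, rng)

    hist_rdme = radial_distribution(mesh, n_bins)
    hist_sbs = radial_distribution(particles, n_bins)
    d, p = analysis.ks_two_sample(hist_rdme, hist_sbs)
    return DiffusionBenchmarkResult(d, p, n_molecules, hist_rdme, hist_sbs)


@dataclass
class ReactionDiffusionResult:
    times: np.ndarray
    sbs_mean: np.ndarray  # (n_times, n_species) mean over replicates
    sbs_sem: np.ndarray
    rdme_mean: np.ndarray
    rdme_sem: np.ndarray
    species_names: list[str]


def reaction_diffusion_benchmark(
    seed: int,
    n_molecules: int = 200,
    box: float = 0.2e-6,
    initial_mesh: int = 128,
    t1: float = 1e-9,
    t_end: float = 1e-6,
    n_replicates: int = 4,
    n_times: int = 12,
    max_time_step: float = 1e-9,
) -> ReactionDiffusionResult:
    """The e_aq + e_aq reaction-diffusion system by both engines.

    200 solvated electrons start in the central voxel of the 21^3
    reference mesh; the only reaction is the bimolecular electron
    recombination.  Each replicate evolves one shared microscopic particle
    stage to the handoff time t1 (the lattice description is not valid in
    the ultra-concentrated sub-ns regime) and then branches: the particle
    engine continues to t_end, while the lattice route bins the same state
    onto a fine mesh coarsened on the standard schedule.  Per-species
    yields on a common log-spaced grid are averaged over replicates.
    """
    chem = electron_recombination_chemistry()
    names = chem.species_names
    grid = log_time_grid(t1, t_end, n_times)
    sbs_runs, rdme_runs = [], []
    root = np.random.default_rng(seed)
    cfg = SbsConfig(max_time_step=max_time_step)
    for k in range(n_replicates):
        rng_init = np.random.default_rng(root.integers(2**31))
        initial = central_voxel_injection(
            n_molecules, "e_aq", 21, box, names, rng_init
        )
        handoff, _ = run_sbs(initial, chem, cfg, t1, rng=rng_init)

        _, series = run_sbs(
            handoff.copy(),
            chem,
            cfg,
            t_end,
            YieldRecorder(grid.copy(), names),
            np.random.default_rng(root.integers(2**31)),
        )
        sbs_runs.append(series.counts)

        run_cfg = RunConfig(
            t1=t1,
            initial_mesh=initial_mesh,
            t_end=t_end,
            seed=int(root.integers(2**31)),
            observer_times=grid.copy(),
        )
        series_rdme, _ = run_hybrid(handoff.copy(), chem, run_cfg)
        rdme_runs.append(series_rdme.counts)

    sbs_arr = np.array(sbs_runs)
    rdme_arr = np.array(rdme_runs)
    n = n_replicates
    return ReactionDiffusionResult(
        times=grid,
        sbs_mean=sbs_arr.mean(axis=0),
        sbs_sem=sbs_arr.std(axis=0, ddof=1) / np.sqrt(n),
        rdme_mean=rdme_arr.mean(axis=0),
        rdme_sem=rdme_arr.std(axis=0, ddof=1) / np.sqrt(n),
        species_names=names,
    )


def radiolysis_benchmark(
    seed: int,
    box: float = 0.2e-6,
    dose: float = 100.0,
    t1: float = 1e-9,
    initial_mesh: int = 32,
    t_end: float = 100e-6,
) -> YieldSeries:
    """Full hybrid radiolysis run from a synthetic spur track.

    A synthetic track deposits the energy corresponding to the requested
    absorbed dose (100 Gy in a 0.2 um box is about 5 keV); the hybrid
    driver runs particles to t1 = 1 ns, then the coarsening lattice, then
    the single-voxel CME to 100 us.  Returns the G-value-bearing yield
    series.
    """
    rng = np.random.default_rng(seed)
    chem = load_chemistry()
    energy = dose_to_energy(dose, box)
    spec = TrackSpec(
        start=(box / 2, box / 2, 0.0),
        end=(box / 2, box / 2, box),
        n_spurs=max(1, round(energy / 40.0)),
    )
    particles, deposited = synthetic_track(spec, box, chem.species_names, rng)
    config = RunConfig(
        t1=t1,
        initial_mesh=initial_mesh,
        t_end=t_end,
        seed=seed,
        deposited_energy=deposited,
    )
    series, _ = run_hybrid(particles, chem, config)
    return series
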