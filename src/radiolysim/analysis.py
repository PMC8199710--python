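"""Observables: yield time series, G-values, radial distributions, and the
Kolmogorov-Smirnov comparison used to benchmark the two engines.

G-value convention: molecules of a species per 100 eV of energy imparted
to the medium.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special


# ---------------------------------------------------------------------------
# Yield series


class YieldSeries:
    """Per-species molecule counts sampled on a time grid.

    Parameters
    ----------
    times : array of float
        Strictly increasing sample times (s).
    counts : array, shape (n_times, n_species)
    species_names : list[str]
    deposited_energy : float or None
        Energy imparted (eV); required for G-values.
    """

    def __init__(self, times, counts, species_names, deposited_energy=None):
        self.times = np.asarray(times, dtype=float)
        self.counts = np.asarray(counts, dtype=float)
        self.species_names = list(species_names)
        self.deposited_energy = deposited_energy
        if self.counts.shape != (len(self.times), len(self.species_names)):
            raise ValueError("counts shape must be (n_times, n_species)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def count(self, species: str, t: float) -> float:
        """Count of ``species`` at the sample time nearest to ``t``."""
        j = self.species_names.index(species)
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.counts[i, j])

    def gvalue(self, species: str, t: float) -> float:
        return gvalue(self, species, t)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per (time, species)."""
        rows = pd.DataFrame(
            self.counts, columns=self.species_names
        ).assign(time=self.times)
        tidy = rows.melt(id_vars="time", var_name="species", value_name="count")
        if self.deposited_energy:
            tidy["gvalue"] = tidy["count"] * 100.0 / self.deposited_energy
        return tidy.sort_values(["time", "species"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "YieldSeries":
        tidy = pd.read_csv(path)
        wide = tidy.pivot(index="time", columns="species", values="count")
        energy = None
        if "gvalue" in tidy.columns and tidy["gvalue"].notna().any():
            row = tidy[tidy["count"] > 0].iloc[0]
            energy = row["count"] * 100.0 / row["gvalue"]
        return cls(
            wide.index.to_numpy(),
            wide.to_numpy(),
            list(wide.columns),
            deposited_energy=energy,
        )

    @classmethod
    def concatenate(cls, pieces: list["YieldSeries"]) -> "YieldSeries":
        """Join consecutive stage series (identical species lists) into one,
        dropping duplicated boundary times from the later piece."""
        head = pieces[0]
        times = [head.times]
        counts = [head.counts]
        for piece in pieces[1:]:
            if piece.species_names != head.species_names:
                raise ValueError("species lists differ between pieces")
            keep = piece.times > times[-1][-1]
            times.append(piece.times[keep])
            counts.append(piece.counts[keep])
        return cls(
            np.concatenate(times),
            np.concatenate(counts),
            head.species_names,
            deposited_energy=head.deposited_energy,
        )


class YieldRecorder:
    """Incremental recorder used inside the event/step loops.

    ``fill_until(t, counts)`` records ``counts`` for every grid time in
    ``[cursor, t)`` — the state is piecewise constant between events.
    """

    def __init__(self, times, species_names, deposited_energy=None):
        self.grid = np.asarray(times, dtype=float)
        self.species_names = list(species_names)
        self.deposited_energy = deposited_energy
        self.samples = np.zeros((len(self.grid), len(self.species_names)))
        self._next = 0

    def fill_until(self, t: float, counts) -> None:
        while self._next < len(self.grid) and self.grid[self._next] < t:
            self.samples[self._next] = counts
            self._next += 1

    def finish(self, counts) -> "YieldSeries":
        self.fill_until(np.inf, counts)
        return YieldSeries(
            self.grid, self.samples, self.species_names, self.deposited_energy
        )


def log_time_grid(t_start: float, t_end: float, n: int = 60) -> np.ndarray:
    """Log-spaced observer grid (the conventional axis for radiolysis
    yields spanning ns to beyond 100 us)."""
    if t_start <= 0:
        t_start = t_end * 1e-6
    return np.geomspace(t_start, t_end, n)


# ---------------------------------------------------------------------------
# G-values


def gvalue(series: YieldSeries, species: str, t: float) -> float:
    """Molecules of ``species`` per 100 eV of deposited energy at time t."""
    if not series.deposited_energy or series.deposited_energy <= 0:
        raise ValueError("series has no deposited energy; G-value undefined")
    return series.count(species, t) * 100.0 / series.deposited_energy


# ---------------------------------------------------------------------------
# Radial distributions


@dataclass
class RadialHistogram:
    """Molecule counts binned by distance from the box centre."""

    edges: np.ndarray  # (n_bins + 1,) increasing, m
    counts: np.ndarray  # (n_bins,)
    total: float = field(init=False)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be increasing")
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        self.total = float(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def cdf(self) -> np.ndarray:
        """Cumulative fraction of molecules at each bin's upper edge."""
        return np.cumsum(self.counts) / self.total


def radial_distribution(state, n_bins: int = 21, species: str | None = None):
    """Radial histogram of molecule positions about the box centre.

    ``state`` is a particle set (continuous positions) or a mesh (each
    voxel's count placed at the voxel-centre radius).  Default 21 bins on
    [0, box/2 * sqrt(3)], covering centre to corner.
    """
    radii, weights, box = _radii_and_weights(state, species)
    if weights.sum() <= 0:
        raise ValueError("empty state: no molecules to bin")
    edges = np.linspace(0.0, box / 2.0 * math.sqrt(3.0), n_bins + 1)
    counts, _ = np.histogram(radii, bins=edges, weights=weights)
    return RadialHistogram(edges, counts)


def _radii_and_weights(state, species):
    centre_dist = getattr(state, "radial_distances", None)
    if centre_dist is None:
        raise TypeError(
            f"{type(state).__name__} does not expose radial_distances()"
        )
    radii, weights = state.radial_distances(species)
    return np.asarray(radii), np.asarray(weights, dtype=float), state.box


# ---------------------------------------------------------------------------
# Two-sample Kolmogorov-Smirnov comparison


def _ks_asymptotic_p(d: float, n: float, m: float) -> float:
    """Classical asymptotic two-sample p: Q_KS(sqrt(nm/(n+m)) * D)."""
    en = math.sqrt(n * m / (n + m))
    return float(special.kolmogorov(en * d))


def ks_two_sample(
    a: RadialHistogram,
    b: RadialHistogram,
    convention: str = "bins",
) -> tuple[float, float]:
    """Two-sample KS comparison of two radial histograms.

    Conventions
    -----------
    ``"bins"`` (default)
        The two samples are the per-bin count values (n = m = n_bins);
        D is the maximal ECDF gap between the two sets of bin heights and
        is a multiple of 1/n_bins.  This is the convention under which the
        benchmark tables of engine-vs-engine comparisons are computed.
    ``"molecules"``
        D is the maximal gap between the molecule-weighted radial CDFs
        evaluated at the bin edges; effective sample sizes are the
        histogram totals.

    Returns ``(D, p)`` with p from the asymptotic two-sample formula.
    """
    if a.n_bins != b.n_bins or not np.allclose(a.edges, b.edges):
        raise ValueError("histograms must share identical binning")
    if convention == "bins":
        xs = np.sort(np.concatenate([a.counts, b.counts]))
        fa = np.searchsorted(np.sort(a.counts), xs, side="right") / a.n_bins
        fb = np.searchsorted(np.sort(b.counts), xs, side="right") / b.n_bins
        d = float(np.max(np.abs(fa - fb)))
        return d, _ks_asymptotic_p(d, a.n_bins, b.n_bins)
    if convention == "molecules":
        d = float(np.max(np.abs(a.cdf() - b.cdf())))
        return d, _ks_asymptotic_p(d, a.total, b.total)
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# Mesh-choice diagnostics


def mean_interparticle_distance(n: int, volume: float) -> float:
    """(V/N)^(1/3): mean spacing of N molecules generated in volume V (m^3).

    The initial voxel size of the lattice engine should be below this so
    that each voxel starts out locally well-mixed.
    """
    if not n > 0:
        raise ValueError("n must be positive")
    if not volume > 0:
        raise ValueError("volume must be positive")
    return (volume / n) ** (1.0 / 3.0)


def mesh_resolution(
    box: float,
    n_per_side: int,
    sigma_max: float | None = None,
    interparticle_distance: float | None = None,
) -> float:
    """Voxel size h = box / n_per_side (m), with validity warnings.

    Warns when h is below the critical size pi*sigma (voxels comparable to
    the reaction radius miss reactions) or above the mean inter-particle
    distance (voxels no longer locally well-mixed at the start).
    """
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    h = box / n_per_side
    if sigma_max is not None and h < math.pi * sigma_max:
        warnings.warn(
            f"voxel size h={h:.3e} m is below the critical size "
            f"pi*sigma={math.pi * sigma_max:.3e} m; reactions may be missed",
            stacklevel=2,
        )
    if interparticle_distance is not None and h > interparticle_distance:
        warnings.warn(
            f"voxel size h={h:.3e} m exceeds the mean inter-particle "
            f"distance {interparticle_distance:.3e} m; initial voxels may "
            "not be well-mixed",
            stacklevel=2,
        )
    return h
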