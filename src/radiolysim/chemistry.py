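"""Species, reactions, rates and unit plumbing shared by both engines.

The chemistry of the radiolytic stage is a set of species with diffusion
coefficients and a set of bimolecular (second-order) reactions with
macroscopic rate constants in M^-1 s^-1.  Everything downstream works in
SI units (metres, seconds, molecule counts); rates are converted exactly
once, here.

Water is the continuum solvent.  ``H2O`` may appear in a configured
reaction as a reactant or product for notational fidelity (e.g. the
bimolecular recombination of two solvated electrons is conventionally
written with two water molecules) but it is stripped at load time and
never simulated.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

AVOGADRO = 6.02214076e23  # mol^-1

#: name of the spectator solvent, stripped from reactant/product lists
WATER = "H2O"


class ChemistryError(ValueError):
    """Raised for an invalid chemistry configuration."""


@dataclass(frozen=True)
class SpeciesDef:
    """A simulated species.

    Parameters
    ----------
    name : str
        Unique identifier, e.g. ``"e_aq"`` for the solvated electron.
    diffusion_coefficient : float
        Diffusion coefficient in m^2 s^-1; must be positive.
    charge : int
        Elementary-charge units; bookkeeping only (no electrostatics).
    """

    name: str
    diffusion_coefficient: float
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.diffusion_coefficient > 0:
            raise ChemistryError(
                f"species {self.name!r}: diffusion coefficient must be > 0, "
                f"got {self.diffusion_coefficient!r}"
            )


@dataclass(frozen=True)
class ReactionDef:
    """A second-order reaction between two (possibly identical) species.

    ``reaction_radius`` is the encounter distance sigma of the
    diffusion-controlled picture; when ``None`` it is derived from the
    rate by Smoluchowski inversion (see :func:`reaction_radius_from_rate`).
    """

    reactants: tuple[str, str]
    products: tuple[str, ...]
    rate: float  # M^-1 s^-1
    reaction_radius: float | None = None  # m

    def __post_init__(self) -> None:
        if len(self.reactants) != 2:
            raise ChemistryError(
                f"reaction {self.label()!r}: exactly two (non-water) reactants "
                f"required, got {list(self.reactants)}"
            )
        if not self.rate > 0:
            raise ChemistryError(f"reaction {self.label()!r}: rate must be > 0")
        if self.reaction_radius is not None and not self.reaction_radius > 0:
            raise ChemistryError(
                f"reaction {self.label()!r}: reaction radius must be > 0"
            )

    @property
    def identical_reactants(self) -> bool:
        return self.reactants[0] == self.reactants[1]

    def label(self) -> str:
        return " + ".join(self.reactants) + " -> " + (
            " + ".join(self.products) if self.products else "(solvent)"
        )


class ChemistryTable:
    """Validated species + reaction set with lookup indexes.

    Attributes
    ----------
    species : list[SpeciesDef]
    reactions : list[ReactionDef]
    species_index : dict[str, int]
        Name -> dense integer code used by both engines.
    """

    def __init__(self, species: list[SpeciesDef], reactions: list[ReactionDef]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ChemistryError(f"duplicate species names in {names}")
        self.species = list(species)
        self.reactions = list(reactions)
        self.species_index: dict[str, int] = {n: i for i, n in enumerate(names)}
        self._validate()
        # (i, j) with i <= j  ->  list of reaction indices
        self.pair_reactions: dict[tuple[int, int], list[int]] = {}
        for r_idx, rxn in enumerate(self.reactions):
            i, j = sorted(self.species_index[n] for n in rxn.reactants)
            self.pair_reactions.setdefault((i, j), []).append(r_idx)
        if len(self.pair_reactions) != len(self.reactions):
            raise ChemistryError("duplicate reactant-pair entries in reaction list")
        self._radius_cache: dict[int, float] = {}

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        for rxn in self.reactions:
            for name in (*rxn.reactants, *rxn.products):
                if name not in self.species_index:
                    raise ChemistryError(
                        f"reaction {rxn.label()!r} references undeclared "
                        f"species {name!r}"
                    )

    # -- basic queries -------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def diffusion_coefficient(self, name: str) -> float:
        return self.species[self.species_index[name]].diffusion_coefficient

    def min_diffusion_coefficient(self) -> float:
        """Lowest D over *all* species in the table (schedule computable up
        front, independent of which species are currently alive)."""
        return min(s.diffusion_coefficient for s in self.species)

    def reaction_radius(self, r_idx: int) -> float:
        """Encounter radius sigma (m) of reaction ``r_idx``; configured value
        if present, else Smoluchowski inversion of the rate."""
        if r_idx not in self._radius_cache:
            rxn = self.reactions[r_idx]
            if rxn.reaction_radius is not None:
                self._radius_cache[r_idx] = rxn.reaction_radius
            else:
                self._radius_cache[r_idx] = reaction_radius_from_rate(rxn, self)
        return self._radius_cache[r_idx]

    def max_reaction_radius(self) -> float:
        """Largest sigma over reactions (0.0 for a pure-diffusion table)."""
        if not self.reactions:
            return 0.0
        return max(self.reaction_radius(i) for i in range(len(self.reactions)))

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": [
                {"name": s.name, "D": s.diffusion_coefficient, "charge": s.charge}
                for s in self.species
            ],
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "rate": r.rate,
                    **(
                        {"radius": r.reaction_radius}
                        if r.reaction_radius is not None
                        else {}
                    ),
                }
                for r in self.reactions
            ],
        }

    def subset(self, reaction_indices: list[int]) -> "ChemistryTable":
        """New table keeping all species but only the given reactions."""
        return ChemistryTable(
            self.species, [self.reactions[i] for i in reaction_indices]
        )


# ---------------------------------------------------------------------------


def _strip_water(names: list[str]) -> list[str]:
    return [n for n in names if n != WATER]


def load_chemistry(source: str | Path | dict | None = None) -> ChemistryTable:
    """Build a validated :class:`ChemistryTable`.

    Parameters
    ----------
    source
        ``None`` (the bundled pure-water 25 degC table of nine
        diffusion-controlled reactions), a mapping with ``species`` /
        ``reactions`` keys, or a path to a YAML/JSON file with the same
        layout::

            species:   [{name, D, charge?}]
            reactions: [{reactants, products, rate, radius?}]
    """
    if source is None or source == "pure_water_25C":
        text = (
            resources.files("radiolysim.data")
            .joinpath("pure_water_25C.yaml")
            .read_text()
        )
        cfg = yaml.safe_load(text)
    elif isinstance(source, dict):
        cfg = copy.deepcopy(source)
    else:
        cfg = yaml.safe_load(Path(source).read_text())

    species = [
        SpeciesDef(
            name=str(s["name"]),
            diffusion_coefficient=float(s["D"]),
            charge=int(s.get("charge", 0)),
        )
        for s in cfg.get("species", [])
    ]
    reactions = []
    for r in cfg.get("reactions", []):
        reactants = _strip_water([str(n) for n in r["reactants"]])
        products = _strip_water([str(n) for n in r.get("products", [])])
        reactions.append(
            ReactionDef(
                reactants=tuple(reactants),
                products=tuple(products),
                rate=float(r["rate"]),
                reaction_radius=(
                    float(r["radius"]) if r.get("radius") is not None else None
                ),
            )
        )
    return ChemistryTable(species, reactions)


def rate_to_per_molecule(rate: float, volume: float) -> float:
    """Convert a macroscopic rate (M^-1 s^-1) to a per-distinct-pair event
    rate (s^-1) in a well-mixed volume.

    ``k' = k / (N_A * V_litres)``: with S_m, S_l molecules of each reactant
    in the volume, S_m*S_l*k' (or S(S-1)/2*k' for identical reactants) is
    the total event propensity.

    Parameters
    ----------
    rate : float
        Rate constant in M^-1 s^-1.
    volume : float
        Compartment volume in m^3; must be positive.
    """
    if not volume > 0:
        raise ValueError(f"volume must be > 0, got {volume!r}")
    return rate / (AVOGADRO * volume * 1000.0)


def rate_to_volume_per_time(rate: float) -> float:
    """Rate constant in molecular units, m^3 s^-1 (``k / (1000 N_A)``)."""
    return rate / (AVOGADRO * 1000.0)


def reaction_radius_from_rate(
    reaction: ReactionDef, species: ChemistryTable
) -> float:
    """Encounter radius sigma implied by a diffusion-controlled rate.

    Smoluchowski: ``k_vol = 4 pi (D1 + D2) sigma`` with k_vol the rate in
    m^3 s^-1 per distinct molecule pair.  This is the convention under
    which the compartment propensities S_m*S_l*k'/V (distinct) and
    (1/2)S(S-1)*k'/V (identical) and the particle engine's
    encounter-at-sigma kinetics describe the same macroscopic rate — each
    distinct pair encounters at rate 4 pi D' sigma / V, so no extra
    symmetry factor enters for identical reactants.
    """
    a, b = reaction.reactants
    d_sum = species.diffusion_coefficient(a) + species.diffusion_coefficient(b)
    k_vol = rate_to_volume_per_time(reaction.rate)
    return k_vol / (4.0 * math.pi * d_sum)
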