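"""Physical constants, unit conversions, and the species/geometry catalogue.

Unit conventions used throughout the package:

* momenta        — atomic units (a.u.)
* energies       — eV (reported), hartree only as an intermediate
* distances      — ångström
* times          — femtoseconds
* masses         — amu (integer nominal masses for fragment ions)

The explosion simulator works internally in (amu, Å, fs); conversion factors
between that system and atomic units are derived here from scipy's CODATA
constants, never typed in by hand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const

# ---------------------------------------------------------------------------
# constants
# ---------------------------------------------------------------------------

#: hartree → eV
HARTREE_TO_EV: float = _const.physical_constants["Hartree energy in eV"][0]

#: bohr → Å
BOHR_TO_ANGSTROM: float = _const.physical_constants["Bohr radius"][0] * 1e10

#: amu → electron masses (atomic unit of mass)
AMU_TO_AU_MASS: float = _const.atomic_mass / _const.m_e

#: e²/4πε₀ in eV·Å — Coulomb energy of two unit charges 1 Å apart
COULOMB_EV_ANG: float = _const.e / (4.0 * math.pi * _const.epsilon_0) * 1e10

#: atomic unit of time in fs
AU_TIME_FS: float = _const.physical_constants["atomic unit of time"][0] * 1e15

#: acceleration in Å/fs² of a 1 amu body under a 1 eV/Å force
ACC_ANG_FS2: float = _const.e / _const.atomic_mass * 1e-10

#: kinetic energy in eV of a 1 amu body moving at 1 Å/fs is 0.5 * this
EV_PER_AMU_ANGFS2: float = 1.0 / ACC_ANG_FS2

#: momentum in a.u. of a 1 amu body moving at 1 Å/fs
P_AU_PER_AMU_ANGFS: float = AMU_TO_AU_MASS * AU_TIME_FS / BOHR_TO_ANGSTROM


@dataclass(frozen=True)
class UnitSystem:
    """Bundle of the conversion factors shared by all stages."""

    hartree_to_eV: float = HARTREE_TO_EV
    bohr_to_angstrom: float = BOHR_TO_ANGSTROM
    amu_to_au_mass: float = AMU_TO_AU_MASS
    coulomb_constant_eV_angstrom: float = COULOMB_EV_ANG


UNITS = UnitSystem()


def angstrom_to_bohr(x):
    return np.asarray(x, dtype=float) / BOHR_TO_ANGSTROM


def bohr_to_angstrom(x):
    return np.asarray(x, dtype=float) * BOHR_TO_ANGSTROM


def velocity_to_momentum_au(velocity_ang_fs, mass_amu):
    """Momentum in a.u. from velocity in Å/fs and mass in amu."""
    return np.asarray(velocity_ang_fs, dtype=float) * (
        mass_amu * P_AU_PER_AMU_ANGFS
    )


def momentum_au_to_velocity(p_au, mass_amu):
    """Velocity in Å/fs from momentum in a.u. and mass in amu."""
    return np.asarray(p_au, dtype=float) / (mass_amu * P_AU_PER_AMU_ANGFS)


# ---------------------------------------------------------------------------
# fragment species
# ---------------------------------------------------------------------------

#: nominal integer atomic masses, amu
ATOMIC_MASS = {"H": 1, "C": 12, "O": 16}

#: covalent radii (Å) for bond detection
COVALENT_RADIUS = {"H": 0.31, "C": 0.76, "O": 0.66}


@dataclass(frozen=True)
class FragmentSpecies:
    """An ionic fragment identified by nominal mass and charge.

    Masses are integer amu: the experiment separates species by nominal
    mass-to-charge only, so isotope-resolved masses would add nothing.
    """

    name: str
    charge: int
    composition: dict = field(hash=False)

    @property
    def mass(self) -> int:
        """Nominal mass in amu (sum of constituent nominal atomic masses)."""
        return sum(ATOMIC_MASS[el] * n for el, n in self.composition.items())

    def __post_init__(self):
        if not self.composition:
            raise ValueError("composition must be non-empty")
        if self.charge < 0:
            raise ValueError("charge must be >= 0")


def _sp(name: str, charge: int, **composition: int) -> FragmentSpecies:
    return FragmentSpecies(name=name, charge=charge, composition=composition)


#: every ion the coincidence channels use, plus the sequential intermediates
SPECIES_CATALOG: dict[str, FragmentSpecies] = {
    s.name: s
    for s in [
        _sp("H+", 1, H=1),
        _sp("OH+", 1, O=1, H=1),
        _sp("H2O+", 1, O=1, H=2),
        _sp("H3O+", 1, O=1, H=3),
        _sp("C2H3+", 1, C=2, H=3),
        _sp("C2H4+", 1, C=2, H=4),
        _sp("C2H5+", 1, C=2, H=5),
        _sp("C2H5O+", 1, C=2, H=5, O=1),
    ]
}


def species_catalog() -> dict[str, FragmentSpecies]:
    """The fragment-ion catalogue keyed by species label."""
    return dict(SPECIES_CATALOG)


def get_species(name: str) -> FragmentSpecies:
    try:
        return SPECIES_CATALOG[name]
    except KeyError:
        raise KeyError(
            f"unknown species {name!r}; known: {sorted(SPECIES_CATALOG)}"
        ) from None


# ---------------------------------------------------------------------------
# ethanol geometry
# ---------------------------------------------------------------------------


@dataclass
class MolecularGeometry:
    """Element labels, Cartesian coordinates (Å) and per-atom role labels."""

    elements: list
    coordinates: np.ndarray  # (n, 3), Å
    roles: list

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.elements), 3):
            raise ValueError("coordinates must be (n_atoms, 3)")

    def atoms_with_role(self, role: str) -> list:
        return [i for i, r in enumerate(self.roles) if r == role]

    def to_xyz(self, comment: str = "ethanol (anti conformer)") -> str:
        lines = [str(len(self.elements)), comment]
        for el, (x, y, z) in zip(self.elements, self.coordinates):
            lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
        return "\n".join(lines) + "\n"


# anti (trans) conformer, constructed from standard bond lengths/angles:
# r(C-O)=1.43 Å, r(C-C)=1.52 Å, r(O-H)=0.97 Å, r(C-H)=1.09 Å, tetrahedral
# angles, hydroxyl H anti to C_beta, methyl staggered.
_ETHANOL_COORDS = np.array(
    [
        [0.0000, 0.0000, 0.0000],  # O
        [1.4300, 0.0000, 0.0000],  # C_alpha
        [1.8997, 1.4457, 0.0000],  # C_beta
        [-0.2998, -0.9226, 0.0000],  # H (hydroxyl)
        [1.7999, -0.5092, 0.8900],  # H on C_alpha
        [1.7999, -0.5092, -0.8900],  # H on C_alpha
        [2.9893, 1.4737, 0.0000],  # H on C_beta (anti)
        [1.5233, 1.9500, 0.8900],  # H on C_beta
        [1.5233, 1.9500, -0.8900],  # H on C_beta
    ]
)

_ETHANOL_ELEMENTS = ["O", "C", "C", "H", "H", "H", "H", "H", "H"]
_ETHANOL_ROLES = [
    "O",
    "C_alpha",
    "C_beta",
    "hydroxyl-H",
    "alpha-H",
    "alpha-H",
    "beta-H",
    "beta-H",
    "beta-H",
]


def ethanol_geometry(conformer: str = "anti") -> MolecularGeometry:
    """Equilibrium ethanol geometry with per-atom role labels.

    Only the anti conformer is provided; ``conformer`` is accepted so callers
    can record which conformer a run assumed.
    """
    if conformer != "anti":
        raise NotImplementedError("only the anti conformer is implemented")
    return MolecularGeometry(
        elements=list(_ETHANOL_ELEMENTS),
        coordinates=_ETHANOL_COORDS.copy(),
        roles=list(_ETHANOL_ROLES),
    )


# atom-index partitions of the intact geometry into channel fragments;
# migrated hydrogens are assigned to the O-side fragment so that charge
# sites sit at the centers of mass of the nascent fragments.
FRAGMENT_ATOMS = {
    "NHM": {"OH+": [0, 3], "C2H5+": [1, 2, 4, 5, 6, 7, 8]},
    "SHM": {"H2O+": [0, 3, 4], "C2H4+": [1, 2, 5, 6, 7, 8]},
    "DHM": {"H3O+": [0, 3, 4, 6], "C2H3+": [1, 2, 5, 7, 8]},
    "TRIPLE": {"H+": [5], "H2O+": [0, 3, 4], "C2H3+": [1, 2, 6, 7, 8]},
    # step-1 partitions of the sequential breakup processes
    "seq_i": {"C2H3+": [1, 2, 5, 7, 8], "H3O+": [0, 3, 4, 6]},
    "seq_ii": {"H2O+": [0, 3, 4], "C2H4+": [1, 2, 5, 6, 7, 8]},
    "seq_iii": {"H+": [5], "C2H5O+": [0, 1, 2, 3, 4, 6, 7, 8]},
}


def fragment_sites(
    geometry: MolecularGeometry, partition: dict
) -> dict[str, np.ndarray]:
    """Center-of-mass charge sites (Å) for an atom-index partition."""
    sites = {}
    for species, idx in partition.items():
        m = np.array([ATOMIC_MASS[geometry.elements[i]] for i in idx], float)
        sites[species] = (
            m[:, None] * geometry.coordinates[idx]
        ).sum(0) / m.sum()
    return sites


def geometry_to_config(geometry: MolecularGeometry) -> dict:
    """Geometry as a plain mapping, ready for YAML serialization."""
    return {
        "elements": list(geometry.elements),
        "roles": list(geometry.roles),
        "coordinates_angstrom": geometry.coordinates.tolist(),
    }


def catalog_to_config() -> dict:
    return {
        name: {
            "mass_amu": sp.mass,
            "charge": sp.charge,
            "composition": dict(sp.composition),
        }
        for name, sp in SPECIES_CATALOG.items()
    }
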