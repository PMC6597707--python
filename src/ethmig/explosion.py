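"""Classical point-charge Coulomb-explosion simulator.

Fragments are reduced to point charges at fragment centers of mass; the
break-up is propagated with velocity Verlet under pairwise Coulomb forces
until the residual potential energy is a negligible fraction of the released
kinetic energy.  Concerted break-ups start all charges at once; sequential
break-ups explode a dication two-body first and, after an ionization delay
``t_ionize``, add a charge to the intermediate fragment and split it into two
daughters that then propagate as a three-body system.

Internal dynamical units are (amu, Å, fs); asymptotic momenta are returned in
atomic units and energies in eV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import (
    ACC_ANG_FS2,
    COULOMB_EV_ANG,
    EV_PER_AMU_ANGFS2,
    FRAGMENT_ATOMS,
    MolecularGeometry,
    ethanol_geometry,
    fragment_sites,
    get_species,
    velocity_to_momentum_au,
)

__all__ = [
    "ChargedBody",
    "BreakupProcess",
    "SimulatedEvent",
    "PROCESSES",
    "DegenerateConfigurationError",
    "NumericalFailureError",
    "coulomb_propagate",
    "propagate_to_asymptote",
    "simulate_concerted",
    "simulate_sequential",
    "simulate_process_ensemble",
    "two_body_ker",
    "random_rotation",
]

#: default base timestep, fs
DEFAULT_DT = 0.05
#: hard cap on simulated time, fs (50 ps)
MAX_TIME = 50_000.0
#: asymptote criterion: |V| < this fraction of the kinetic energy
ASYMPTOTE_TOL = 1e-3
#: minimum allowed pair distance in an initial configuration, Å
MIN_PAIR_DISTANCE = 0.05


class DegenerateConfigurationError(ValueError):
    """Two bodies closer than the minimum allowed pair distance."""


class NumericalFailureError(RuntimeError):
    """Propagation produced a non-finite state."""


@dataclass
class ChargedBody:
    """A point-charge fragment: mass (amu), charge (e), position (Å),
    velocity (Å/fs) and the species label it stands for."""

    mass: float
    charge: float
    position: np.ndarray
    velocity: np.ndarray
    species: str = ""

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not (
            np.all(np.isfinite(self.position))
            and np.all(np.isfinite(self.velocity))
        ):
            raise ValueError("non-finite initial state")

    @property
    def momentum_au(self) -> np.ndarray:
        return velocity_to_momentum_au(self.velocity, self.mass)


@dataclass(frozen=True)
class BreakupProcess:
    """A two-step sequential break-up of the ethanol dication.

    Step 1 ejects ``first`` against ``intermediate`` (one unit charge each,
    from rest at the geometry-derived charge sites).  At ``t_ionize`` the
    intermediate gains one more charge and splits into the two ``daughters``,
    placed at ``daughter_separation`` (Å, center of mass and momentum
    preserved, zero internal velocity), and the three bodies propagate to the
    asymptote.
    """

    process_id: str
    first: str
    intermediate: str
    daughters: tuple
    daughter_separation: float
    #: mass split of the daughter pair must reproduce the intermediate mass
    def __post_init__(self):
        m = sum(get_species(d).mass for d in self.daughters)
        if m != get_species(self.intermediate).mass:
            raise ValueError("daughter masses must sum to intermediate mass")


#: the three sequential processes of the triple-coincidence channel;
#: daughter separations are effective charge-site distances calibrated so
#: the simulated KER falls in the observed 0-5 / 5-13 eV bands.
PROCESSES: dict[str, BreakupProcess] = {
    "seq_i": BreakupProcess(
        "seq_i", "C2H3+", "H3O+", ("H+", "H2O+"), daughter_separation=3.0
    ),
    "seq_ii": BreakupProcess(
        "seq_ii", "H2O+", "C2H4+", ("H+", "C2H3+"), daughter_separation=3.0
    ),
    "seq_iii": BreakupProcess(
        "seq_iii", "H+", "C2H5O+", ("H2O+", "C2H3+"), daughter_separation=2.5
    ),
}


@dataclass
class SimulatedEvent:
    """Asymptotic outcome of one simulated break-up."""

    species: list
    momenta_au: np.ndarray  # (n_fragments, 3)
    ker_eV: float
    process_id: str
    t_ionize_fs: float | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# propagation core
# ---------------------------------------------------------------------------


def _pair_indices(n: int):
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _forces_and_potential(pos, charges, qq, ii, jj):
    """Pairwise Coulomb forces (eV/Å) and potential energy (eV)."""
    d = pos[ii] - pos[jj]
    r2 = (d * d).sum(axis=1)
    r = np.sqrt(r2)
    v = COULOMB_EV_ANG * qq / r
    fmag = v / r2  # k qq / r^2, per unit separation vector component / r
    fvec = fmag[:, None] * d
    forces = np.zeros_like(pos)
    np.add.at(forces, ii, fvec)
    np.add.at(forces, jj, -fvec)
    return forces, v.sum(), r.min()


def _kinetic(masses, vel):
    return 0.5 * EV_PER_AMU_ANGFS2 * (masses * (vel * vel).sum(axis=1)).sum()


def _propagate(
    masses,
    charges,
    pos,
    vel,
    *,
    dt0=DEFAULT_DT,
    t_end=None,
    to_asymptote=False,
    max_time=MAX_TIME,
    r_ref=3.0,
    dt_max=25.0,
    check_every=20,
):
    """Velocity-Verlet propagation with a separation-scaled timestep.

    Returns (pos, vel, t, info).  The timestep grows as
    dt0 * (r_min/r_ref)^1.5 (capped at dt_max) once the closest pair has
    separated beyond r_ref, which keeps the local error small where forces
    are strong and makes propagation to the Coulomb asymptote affordable.
    """
    masses = np.asarray(masses, float)
    charges = np.asarray(charges, float)
    pos = np.array(pos, float)
    vel = np.array(vel, float)
    n = len(masses)
    ii, jj = _pair_indices(n)
    qq = charges[ii] * charges[jj]

    forces, pot, rmin = _forces_and_potential(pos, charges, qq, ii, jj)
    if rmin < MIN_PAIR_DISTANCE:
        raise DegenerateConfigurationError(
            f"bodies closer than {MIN_PAIR_DISTANCE} Å (min pair "
            f"distance {rmin:.4f} Å)"
        )
    e0 = _kinetic(masses, vel) + pot
    acc = ACC_ANG_FS2 * forces / masses[:, None]

    t = 0.0
    step = 0
    limit = max_time if t_end is None else min(t_end, max_time)
    while t < limit:
        dt = dt0 * min(dt_max / dt0, max(1.0, (rmin / r_ref) ** 1.5))
        if t + dt > limit:
            dt = limit - t
        pos += vel * dt + 0.5 * acc * dt * dt
        forces, pot, rmin = _forces_and_potential(pos, charges, qq, ii, jj)
        new_acc = ACC_ANG_FS2 * forces / masses[:, None]
        vel += 0.5 * (acc + new_acc) * dt
        acc = new_acc
        t += dt
        step += 1
        if not np.isfinite(pos).all():
            raise NumericalFailureError(
                f"non-finite coordinates at step {step} (t = {t:.3f} fs)"
            )
        if to_asymptote and step % check_every == 0:
            ke = _kinetic(masses, vel)
            if ke > 0 and abs(pot) < ASYMPTOTE_TOL * ke:
                break

    ke = _kinetic(masses, vel)
    info = {
        "t_fs": t,
        "steps": step,
        "kinetic_eV": ke,
        "potential_eV": pot,
        "energy_drift_eV": (ke + pot) - e0,
        "initial_energy_eV": e0,
    }
    return pos, vel, t, info


def coulomb_propagate(
    bodies: list[ChargedBody],
    t_end: float,
    dt: float = DEFAULT_DT,
) -> list[ChargedBody]:
    """Propagate charged bodies under pairwise Coulomb forces for ``t_end`` fs.

    Total momentum is conserved exactly (pairwise forces); total energy to
    within the integrator drift tolerance.
    """
    if len(bodies) < 2:
        raise ValueError("need at least two bodies")
    if dt <= 0:
        raise ValueError("dt must be positive")
    masses = [b.mass for b in bodies]
    charges = [b.charge for b in bodies]
    pos = np.array([b.position for b in bodies], float)
    vel = np.array([b.velocity for b in bodies], float)
    pos, vel, _, _ = _propagate(masses, charges, pos, vel, dt0=dt, t_end=t_end)
    return [
        replace(b, position=pos[k].copy(), velocity=vel[k].copy())
        for k, b in enumerate(bodies)
    ]


def propagate_to_asymptote(
    bodies: list[ChargedBody], dt: float = DEFAULT_DT
) -> tuple[list[ChargedBody], dict]:
    """Propagate until the residual Coulomb potential is < 0.1% of the
    accumulated kinetic energy (50 ps cap). Returns (bodies, diagnostics)."""
    if len(bodies) < 2:
        raise ValueError("need at least two bodies")
    masses = [b.mass for b in bodies]
    charges = [b.charge for b in bodies]
    pos = np.array([b.position for b in bodies], float)
    vel = np.array([b.velocity for b in bodies], float)
    pos, vel, _, info = _propagate(
        masses, charges, pos, vel, dt0=dt, to_asymptote=True
    )
    out = [
        replace(b, position=pos[k].copy(), velocity=vel[k].copy())
        for k, b in enumerate(bodies)
    ]
    return out, info


def two_body_ker(r_angstrom: float, q1: float = 1.0, q2: float = 1.0) -> float:
    """Analytic KER (eV) of two point charges exploding from rest at r (Å)."""
    return COULOMB_EV_ANG * q1 * q2 / r_angstrom


# ---------------------------------------------------------------------------
# orientation sampling
# ---------------------------------------------------------------------------


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _event_from_bodies(bodies, process_id, t_ionize=None, diagnostics=None):
    momenta = np.array([b.momentum_au for b in bodies])
    ker = sum(
        0.5 * EV_PER_AMU_ANGFS2 * b.mass * float(b.velocity @ b.velocity)
        for b in bodies
    )
    return SimulatedEvent(
        species=[b.species for b in bodies],
        momenta_au=momenta,
        ker_eV=ker,
        process_id=process_id,
        t_ionize_fs=t_ionize,
        diagnostics=diagnostics or {},
    )


def _centered_sites(sites: dict[str, np.ndarray], masses) -> np.ndarray:
    pos = np.array(list(sites.values()), float)
    m = np.asarray(masses, float)
    com = (m[:, None] * pos).sum(0) / m.sum()
    return pos - com


# ---------------------------------------------------------------------------
# concerted break-up
# ---------------------------------------------------------------------------


def simulate_concerted(
    channel,
    geometry: MolecularGeometry | None = None,
    seed: int = 0,
    charge_sites: dict | None = None,
    dt: float = DEFAULT_DT,
) -> SimulatedEvent:
    """Concerted Coulomb explosion of a channel's fragments from rest.

    ``channel`` is a channel name with an atom partition in the catalogue
    (NHM, SHM, DHM, TRIPLE). Unit point charges start at the fragment centers
    of mass of the intact ethanol geometry, uniformly randomly oriented.
    """
    name = getattr(channel, "name", channel)
    if charge_sites is None:
        if name not in FRAGMENT_ATOMS:
            raise ValueError(
                f"unknown channel {name!r}; known: {sorted(FRAGMENT_ATOMS)}"
            )
        geometry = geometry or ethanol_geometry()
        charge_sites = fragment_sites(geometry, FRAGMENT_ATOMS[name])

    rng = np.random.default_rng(seed)
    rot = random_rotation(rng)
    species = list(charge_sites)
    masses = [get_species(s).mass for s in species]
    pos = _centered_sites(charge_sites, masses) @ rot.T
    bodies = [
        ChargedBody(
            mass=get_species(s).mass,
            charge=get_species(s).charge,
            position=pos[k],
            velocity=np.zeros(3),
            species=s,
        )
        for k, s in enumerate(species)
    ]
    bodies, info = propagate_to_asymptote(bodies, dt=dt)
    return _event_from_bodies(bodies, f"concerted_{name}", diagnostics=info)


# ---------------------------------------------------------------------------
# sequential break-up
# ---------------------------------------------------------------------------


def simulate_sequential(
    process: BreakupProcess | str,
    t_ionize: float,
    seed: int = 0,
    geometry: MolecularGeometry | None = None,
    daughter_sites: dict | None = None,
    dt: float = DEFAULT_DT,
) -> SimulatedEvent:
    """Two-step sequential Coulomb explosion (see :class:`BreakupProcess`).

    ``daughter_sites`` optionally overrides the isotropic daughter placement
    with explicit positions relative to the intermediate's center of mass
    (used e.g. to realize the degenerate t_ionize = 0 concerted limit).
    """
    if isinstance(process, str):
        process = PROCESSES[process]
    if t_ionize < 0:
        raise ValueError("t_ionize must be >= 0")
    rng = np.random.default_rng(seed)
    geometry = geometry or ethanol_geometry()

    # --- step 1: two-body explosion of the dication from rest
    sites = fragment_sites(geometry, FRAGMENT_ATOMS[process.process_id])
    species1 = [process.first, process.intermediate]
    masses1 = np.array([get_species(s).mass for s in species1], float)
    rot = random_rotation(rng)
    pos1 = (
        _centered_sites({s: sites[s] for s in species1}, masses1) @ rot.T
    )
    vel1 = np.zeros((2, 3))
    if t_ionize > 0:
        pos1, vel1, _, _ = _propagate(
            masses1, np.ones(2), pos1, vel1, dt0=dt, t_end=t_ionize
        )

    # --- step 2: charge up the intermediate and split it into daughters
    d1, d2 = process.daughters
    m1, m2 = get_species(d1).mass, get_species(d2).mass
    com = pos1[1]
    vcom = vel1[1]
    for attempt in range(10):
        if daughter_sites is not None:
            off1 = np.asarray(daughter_sites[d1], float)
            off2 = np.asarray(daughter_sites[d2], float)
        else:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            off1 = u * process.daughter_separation * m2 / (m1 + m2)
            off2 = -u * process.daughter_separation * m1 / (m1 + m2)
        pos3 = np.array([pos1[0], com + off1, com + off2])
        d = pos3[:, None, :] - pos3[None, :, :]
        rmin = np.sqrt(
            (d * d).sum(-1)[np.triu_indices(3, k=1)]
        ).min()
        if rmin >= MIN_PAIR_DISTANCE:
            break
        if daughter_sites is not None:
            raise DegenerateConfigurationError(
                "explicit daughter sites overlap another fragment"
            )
    else:
        raise DegenerateConfigurationError(
            "could not place daughters clear of the first fragment "
            "after 10 retries"
        )

    species3 = [process.first, d1, d2]
    masses3 = np.array([get_species(s).mass for s in species3], float)
    vel3 = np.array([vel1[0], vcom, vcom])
    charges3 = np.ones(3)

    pos3, vel3, _, info = _propagate(
        masses3, charges3, pos3, vel3, dt0=dt, to_asymptote=True
    )
    bodies = [
        ChargedBody(
            mass=masses3[k],
            charge=1.0,
            position=pos3[k],
            velocity=vel3[k],
            species=species3[k],
        )
        for k in range(3)
    ]
    return _event_from_bodies(
        bodies, process.process_id, t_ionize=t_ionize, diagnostics=info
    )


def simulate_process_ensemble(
    process: BreakupProcess | str,
    n: int,
    seed: int = 0,
    t_mean: float = 200.0,
    geometry: MolecularGeometry | None = None,
    dt: float = DEFAULT_DT,
) -> list[SimulatedEvent]:
    """``n`` sequential events with randomized orientation and exponential
    ionization delays of mean ``t_mean`` fs; reproducible given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(process, str):
        process = PROCESSES[process]
    rng = np.random.default_rng(seed)
    delays = rng.exponential(t_mean, size=n)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        simulate_sequential(
            process, float(t), seed=int(s), geometry=geometry, dt=dt
        )
        for t, s in zip(delays, child_seeds)
    ]
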