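"""Per-event derived observables: kinetic energies, KER, Newton-frame
momenta, and Dalitz energy-sharing coordinates.

Momenta are in atomic units, energies in eV.  The Newton frame follows the
convention used for the triple-coincidence channel: the reference fragment
(C2H3+) defines the +x axis, the "upper" fragment (H2O+) has non-negative
transverse momentum and the "lower" fragment (H+) non-positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .units import AMU_TO_AU_MASS, HARTREE_TO_EV, get_species

logger = logging.getLogger(__name__)

__all__ = [
    "CoincidenceEvent",
    "NewtonCoordinates",
    "DalitzPoint",
    "kinetic_energy",
    "ker",
    "newton_transform",
    "dalitz_coordinates",
    "dalitz_from_event",
    "split_by_proton_momentum",
]


@dataclass
class CoincidenceEvent:
    """One detected fragmentation event.

    ``fragments`` is an ordered list of (species label, momentum 3-vector in
    a.u.); ``delay_fs`` is signed (negative = the stronger pulse came first);
    ``source`` distinguishes pump-probe events from single-pulse background.
    """

    delay_fs: float
    fragments: list
    shot_id: int = -1
    source: str = "pump_probe"

    def __post_init__(self):
        if len(self.fragments) < 2:
            raise ValueError("an event needs at least two fragments")
        self.fragments = [
            (s, np.asarray(p, dtype=float)) for s, p in self.fragments
        ]
        for s, p in self.fragments:
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"bad momentum for fragment {s!r}")

    def momentum(self, species: str) -> np.ndarray:
        for s, p in self.fragments:
            if s == species:
                return p
        raise KeyError(f"event has no {species!r} fragment")

    @property
    def total_momentum(self) -> np.ndarray:
        return np.sum([p for _, p in self.fragments], axis=0)


@dataclass
class NewtonCoordinates:
    """Molecular-frame momenta: per fragment (p_parallel, p_perp, p) in a.u.,
    with p = sqrt(p_parallel² + p_perp²)."""

    species: list
    p_parallel: np.ndarray
    p_perp: np.ndarray

    @property
    def p(self) -> np.ndarray:
        return np.hypot(self.p_parallel, self.p_perp)

    def of(self, species: str) -> tuple:
        k = self.species.index(species)
        return float(self.p_parallel[k]), float(self.p_perp[k])


@dataclass(frozen=True)
class DalitzPoint:
    """Energy-sharing coordinates; the kinematically allowed region is
    y_d ∈ [-1/3, 2/3], |x_d| ≤ 1/√3."""

    x_d: float
    y_d: float


def kinetic_energy(momentum_au, mass_amu: float) -> float:
    """Nonrelativistic kinetic energy in eV: |p|²/2m (p in a.u., m in amu)."""
    if mass_amu <= 0:
        raise ValueError("mass must be positive")
    p = np.asarray(momentum_au, dtype=float)
    p2 = float(p @ p)
    return p2 / (2.0 * mass_amu * AMU_TO_AU_MASS) * HARTREE_TO_EV


def ker(event: CoincidenceEvent) -> float:
    """Kinetic energy release: summed fragment kinetic energies, eV."""
    return sum(
        kinetic_energy(p, get_species(s).mass) for s, p in event.fragments
    )


def newton_transform(
    event: CoincidenceEvent,
    reference: str = "C2H3+",
    upper: str = "H2O+",
    lower: str = "H+",
) -> NewtonCoordinates:
    """Rotate/reflect a 3-fragment event into the Newton frame.

    The reference fragment lies on +x with zero transverse component; the
    event plane is spanned by the reference and upper-fragment momenta, and
    the lower fragment's out-of-plane component is folded into its signed
    in-plane transverse component by projection.  Magnitudes of in-plane
    components are preserved; reflections are allowed so the upper/lower
    convention always holds.
    """
    if len(event.fragments) != 3:
        raise ValueError("Newton transform requires exactly 3 fragments")
    p_ref = event.momentum(reference)
    p_up = event.momentum(upper)
    p_lo = event.momentum(lower)
    norm_ref = np.linalg.norm(p_ref)
    if norm_ref < 1e-9:
        raise ValueError("reference momentum ~0: Newton frame undefined")
    x_hat = p_ref / norm_ref
    y_vec = p_up - (p_up @ x_hat) * x_hat
    ny = np.linalg.norm(y_vec)
    if ny < 1e-12:
        # upper fragment collinear with reference: any transverse axis works;
        # pick one orthogonal to x and orient it so the lower fragment is down
        trial = np.array([1.0, 0.0, 0.0])
        if abs(trial @ x_hat) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        y_hat = trial - (trial @ x_hat) * x_hat
        y_hat /= np.linalg.norm(y_hat)
        if p_lo @ y_hat > 0:
            y_hat = -y_hat
    else:
        y_hat = y_vec / ny

    species = [reference, upper, lower]
    moms = [p_ref, p_up, p_lo]
    p_par = np.array([p @ x_hat for p in moms])
    p_perp = np.array([p @ y_hat for p in moms])
    return NewtonCoordinates(
        species=species, p_parallel=p_par, p_perp=p_perp
    )


def dalitz_coordinates(
    e_c2h3: float, e_h2o: float, e_h: float
) -> DalitzPoint:
    """Dalitz coordinates of the triple channel:
    x_d = (E(C2H3+) - E(H2O+)) / (√3·KER),  y_d = E(H+)/KER - 1/3."""
    if min(e_c2h3, e_h2o, e_h) < 0:
        raise ValueError("fragment energies must be non-negative")
    total = e_c2h3 + e_h2o + e_h
    if total <= 0:
        raise ValueError("KER must be positive")
    return DalitzPoint(
        x_d=(e_c2h3 - e_h2o) / (np.sqrt(3.0) * total),
        y_d=e_h / total - 1.0 / 3.0,
    )


def dalitz_from_event(event: CoincidenceEvent) -> DalitzPoint:
    """Dalitz point of a triple-coincidence event (H+ + H2O+ + C2H3+)."""
    energies = {
        s: kinetic_energy(p, get_species(s).mass) for s, p in event.fragments
    }
    return dalitz_coordinates(
        energies["C2H3+"], energies["H2O+"], energies["H+"]
    )


def split_by_proton_momentum(
    events: list[CoincidenceEvent], p_split: float = 20.0
) -> tuple[list[CoincidenceEvent], list[CoincidenceEvent]]:
    """Partition events by proton momentum magnitude: |p(H+)| < p_split goes
    low, >= p_split goes high.  Events without an H+ fragment are skipped
    with a counted warning."""
    low, high = [], []
    skipped = 0
    for ev in events:
        try:
            p = ev.momentum("H+")
        except KeyError:
            skipped += 1
            continue
        (high if np.linalg.norm(p) >= p_split else low).append(ev)
    if skipped:
        logger.warning(
            "split_by_proton_momentum: skipped %d events without H+", skipped
        )
    return low, high
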