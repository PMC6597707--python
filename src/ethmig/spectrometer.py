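"""Idealized single-region ion-momentum spectrometer (COLTRIMS-style).

A uniform extraction field E over an acceleration length L maps an ion of
mass m, charge q and initial momentum p onto a time of flight and a detector
position:

    L = (p_z/m) t + (q E / 2m) t²,   x = (p_x/m) t,   y = (p_y/m) t

with the spectrometer axis (+z) pointing at the detector.  The inverse map
recovers the momentum from (tof, x, y) given a species hypothesis.  No drift
tube, lens aberrations, electron arm or magnetic field are modelled: one
region is enough to make the TOF ↔ momentum chain testable end to end.

Interface units: momenta a.u., tof ns, positions mm; config in SI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants as _const

from .units import FragmentSpecies, get_species

__all__ = [
    "SpectrometerConfig",
    "DetectorHit",
    "forward_model",
    "reconstruct_momentum",
    "tof_at_rest",
    "tof_window",
]

#: a.u. of momentum in SI (kg m/s)
P_AU_SI = _const.physical_constants["atomic unit of momentum"][0]

#: hard sanity cap on time of flight, s
MAX_TOF = 100e-6


@dataclass(frozen=True)
class SpectrometerConfig:
    """Uniform-field spectrometer parameters (SI units, t0 in ns)."""

    extraction_field_V_m: float = 2000.0  # 20 V/cm
    acceleration_length_m: float = 0.10
    detector_radius_m: float = 0.060
    t0_ns: float = 0.0

    def __post_init__(self):
        if min(
            self.extraction_field_V_m,
            self.acceleration_length_m,
            self.detector_radius_m,
        ) <= 0:
            raise ValueError("field, length and radius must be positive")


DEFAULT_SPECTROMETER = SpectrometerConfig()


@dataclass
class DetectorHit:
    """One ion hit: time of flight (ns) and detector position (mm)."""

    tof_ns: float
    x_mm: float
    y_mm: float
    species_hypothesis: str | None = None
    out_of_acceptance: bool = False
    shot_id: int = -1
    delay_fs: float = 0.0


def _mass_charge_si(species: FragmentSpecies):
    m = species.mass * _const.atomic_mass
    q = species.charge * _const.e
    if q <= 0:
        raise ValueError(f"species {species.name} has no positive charge")
    return m, q


def forward_model(
    momentum_au,
    species: FragmentSpecies | str,
    config: SpectrometerConfig = DEFAULT_SPECTROMETER,
) -> DetectorHit:
    """Map an initial momentum (a.u.) onto a detector hit.

    With the field pushing every positive ion toward the detector the TOF
    quadratic always has one positive root; ions landing beyond the detector
    radius are flagged but retained.
    """
    if isinstance(species, str):
        species = get_species(species)
    m, q = _mass_charge_si(species)
    p = np.asarray(momentum_au, dtype=float) * P_AU_SI
    vz = p[2] / m
    a = q * config.extraction_field_V_m / m
    L = config.acceleration_length_m
    # L = vz t + a t²/2  →  positive root
    t = (-vz + np.sqrt(vz * vz + 2.0 * a * L)) / a
    if not (0.0 < t < MAX_TOF):
        raise ValueError(f"unphysical time of flight {t:.3e} s")
    x = p[0] / m * t
    y = p[1] / m * t
    r = np.hypot(x, y)
    return DetectorHit(
        tof_ns=t * 1e9 + config.t0_ns,
        x_mm=x * 1e3,
        y_mm=y * 1e3,
        species_hypothesis=species.name,
        out_of_acceptance=bool(r > config.detector_radius_m),
    )


def reconstruct_momentum(
    hit: DetectorHit,
    species: FragmentSpecies | str,
    config: SpectrometerConfig = DEFAULT_SPECTROMETER,
) -> np.ndarray:
    """Invert the forward model: momentum (a.u.) from (tof, x, y) under a
    species hypothesis.  Exact algebraic inverse of :func:`forward_model`."""
    if isinstance(species, str):
        species = get_species(species)
    m, q = _mass_charge_si(species)
    t = (hit.tof_ns - config.t0_ns) * 1e-9
    if t <= 0:
        raise ValueError("tof must exceed t0")
    E = config.extraction_field_V_m
    L = config.acceleration_length_m
    pz = m * L / t - q * E * t / 2.0
    px = m * (hit.x_mm * 1e-3) / t
    py = m * (hit.y_mm * 1e-3) / t
    return np.array([px, py, pz]) / P_AU_SI


def tof_at_rest(
    species: FragmentSpecies | str,
    config: SpectrometerConfig = DEFAULT_SPECTROMETER,
) -> float:
    """Time of flight (ns) of an ion created at rest: t0 + sqrt(2Lm/qE)."""
    if isinstance(species, str):
        species = get_species(species)
    m, q = _mass_charge_si(species)
    t = np.sqrt(
        2.0 * config.acceleration_length_m * m
        / (q * config.extraction_field_V_m)
    )
    return t * 1e9 + config.t0_ns


def tof_window(
    species: FragmentSpecies | str,
    p_max_au: float = 150.0,
    config: SpectrometerConfig = DEFAULT_SPECTROMETER,
) -> tuple[float, float]:
    """TOF window (ns) covering initial |p_z| ≤ p_max_au for a species.

    Bounds are the exact TOF roots at p_z = ±p_max (ions launched toward the
    detector arrive early, ions launched away turn around and arrive late; the
    two shifts are not symmetric).
    """
    if isinstance(species, str):
        species = get_species(species)
    early = forward_model([0.0, 0.0, +p_max_au], species, config).tof_ns
    late = forward_model([0.0, 0.0, -p_max_au], species, config).tof_ns
    # small slack so boundary momenta stay inside the half-open window
    width = late - early
    return (early - 1e-6 * width, late + 1e-6 * width)


# --- vectorized forward model used by the synthetic event generator --------


def forward_model_arrays(
    momenta_au: np.ndarray,
    species: FragmentSpecies | str,
    config: SpectrometerConfig = DEFAULT_SPECTROMETER,
):
    """Vectorized forward model: (n, 3) momenta → (tof_ns, x_mm, y_mm)."""
    if isinstance(species, str):
        species = get_species(species)
    m, q = _mass_charge_si(species)
    p = np.asarray(momenta_au, dtype=float) * P_AU_SI
    vz = p[:, 2] / m
    a = q * config.extraction_field_V_m / m
    L = config.acceleration_length_m
    t = (-vz + np.sqrt(vz * vz + 2.0 * a * L)) / a
    x = p[:, 0] / m * t
    y = p[:, 1] / m * t
    return t * 1e9 + config.t0_ns, x * 1e3, y * 1e3
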