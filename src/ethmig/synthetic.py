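"""Ground-truth synthetic data: pump-probe coincidence event streams and
AIMD-like trajectory ensembles.

The generator stands in for the two undeposited data families and encodes the
statistical structure the analysis is designed to extract:

* **Event streams** — per pulse pair a fragmentation channel is drawn with
  delay-independent branching and a migration completion time T is drawn from
  an exponential clock.  If the probe arrives before T the event appears in
  the precursor (no-migration) channel; afterwards in the migration channel,
  Coulomb-exploding from a separation that grows linearly with (delay − T),
  which produces the delay-dependent, decreasing KER features.  Single-pulse
  background events populate delay-independent KER bands.  Two-body break-ups
  use the closed-form Coulomb solution (exact for two point charges from
  rest; cross-checked against the numerical propagator in the tests).

* **Trajectory ensembles** — scripted 9-atom geometry time series with
  hydrogen-transfer paths at sampled times: the first and second migration
  times are drawn independently (the first from a truncated exponential below
  the second's support floor, so the ordered pair stays exactly independent),
  the C–O break follows the second migration by a fixed offset plus Gaussian
  noise (the concerted mechanism), and migration origins are sampled 50/50
  between the alpha and beta carbons.

Every artifact is reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .explosion import random_rotation, two_body_ker
from .spectrometer import (
    DEFAULT_SPECTROMETER,
    SpectrometerConfig,
    forward_model_arrays,
)
from .trajectory import Trajectory
from .units import (
    AMU_TO_AU_MASS,
    HARTREE_TO_EV,
    ethanol_geometry,
    get_species,
)

__all__ = [
    "GeneratorConfig",
    "generate_event_stream",
    "generate_trajectory_ensemble",
    "generate_gating_benchmark",
    "two_body_momenta",
    "write_manifest",
]

#: channel → (fragment 1, fragment 2) for the double-coincidence stream
CHANNEL_SPECIES = {
    "NHM": ("OH+", "C2H5+"),
    "SHM": ("H2O+", "C2H4+"),
    "DHM": ("H3O+", "C2H3+"),
}

#: precursor channel observed when the probe arrives before migration
PRECURSOR_CHANNEL = "NHM"


@dataclass
class GeneratorConfig:
    """Study conditions for both synthetic data families.

    Event stream: ``delay_edges_fs`` with ``pulse_pairs_per_bin`` pulse pairs
    per bin; each pair yields an event with ``event_probability``; a
    ``background_fraction`` of events come from a single pulse (delay
    independent).  Channel branching is delay independent; migration
    completion times are exponential with per-channel means ``tau_fs`` scaled
    by ``internal_energy_reference_eV / internal_energy_eV`` (hydrogens
    migrate faster at higher internal energy).  Migration channels explode
    from ``explosion_r0_angstrom``, calibrated so the KER at the moment of
    migration sits at the top of the channel's KER gate, then separate at
    ``separation_speed_angstrom_fs``.

    Trajectories: ``n_trajectories`` scripted geometries on a ``dt_fs`` grid
    up to ``max_time_fs``; first migration ~ Exp(``tau1_fs``) truncated below
    ``t2_floor_fs``; second ~ ``t2_floor_fs`` + Exp(``tau2_fs``); C–O break =
    second migration + ``co_break_offset_fs`` + N(0, ``co_break_sigma_fs``).

    Pulse metadata (wavelength, duration, intensities) is provenance only.
    """

    # --- event stream
    delay_min_fs: float = -1000.0
    delay_max_fs: float = 1000.0
    delay_bin_fs: float = 50.0
    pulse_pairs_per_bin: int = 3000
    event_probability: float = 0.45
    branching: dict = field(
        default_factory=lambda: {"NHM": 0.30, "SHM": 0.30, "DHM": 0.35}
    )
    background_fraction: float = 0.05
    tau_fs: dict = field(
        default_factory=lambda: {"NHM": 250.0, "SHM": 300.0, "DHM": 300.0}
    )
    internal_energy_eV: float = 10.0
    internal_energy_reference_eV: float = 10.0
    explosion_r0_angstrom: dict = field(
        default_factory=lambda: {"NHM": 4.1, "SHM": 4.1, "DHM": 4.1}
    )
    separation_speed_angstrom_fs: float = 0.015
    background_ker_eV: float = 5.0
    background_ker_sigma_eV: float = 0.4

    # --- trajectory ensemble
    n_trajectories: int = 200
    trajectory_dt_fs: float = 2.0
    trajectory_max_time_fs: float = 3000.0
    trajectory_branching: dict = field(
        default_factory=lambda: {"DHM": 0.5, "SHM": 0.25, "NHM": 0.25}
    )
    trajectory_charge: int = 2
    trajectory_internal_energy_eV: float = 5.0
    tau1_fs: float = 150.0
    t2_floor_fs: float = 400.0
    tau2_fs: float = 600.0
    co_break_offset_fs: float = 40.0
    co_break_sigma_fs: float = 5.0
    migration_speed_angstrom_fs: float = 0.02
    co_speed_angstrom_fs: float = 0.02
    jitter_angstrom: float = 0.01

    # --- provenance only
    pulse_wavelength_nm: float = 730.0
    pulse_duration_fs: float = 9.0
    pump_intensity_W_cm2: float = 4.2e14
    probe_intensity_W_cm2: float = 6.7e14

    def __post_init__(self):
        total = sum(self.branching.values())
        if not (0 < total <= 1.0 + 1e-9):
            raise ValueError("branching fractions must sum to (0, 1]")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must be in [0, 1]")
        for name, value in [
            ("pulse_pairs_per_bin", self.pulse_pairs_per_bin),
            ("delay_bin_fs", self.delay_bin_fs),
            ("trajectory_dt_fs", self.trajectory_dt_fs),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def delay_edges_fs(self) -> np.ndarray:
        return np.arange(
            self.delay_min_fs,
            self.delay_max_fs + self.delay_bin_fs / 2,
            self.delay_bin_fs,
        )

    def effective_tau(self, channel: str) -> float:
        scale = self.internal_energy_reference_eV / self.internal_energy_eV
        return self.tau_fs[channel] * scale


# ---------------------------------------------------------------------------
# two-body kinematics helpers
# ---------------------------------------------------------------------------


def two_body_momenta(
    ker_eV: np.ndarray, m1_amu: float, m2_amu: float, directions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Back-to-back momenta (a.u.) for two-body events of given KER (eV).

    |p| = sqrt(2 μ KER) with μ the reduced mass; momentum is conserved
    exactly.  ``directions`` is an (n, 3) array of unit vectors.
    """
    mu_au = (m1_amu * m2_amu) / (m1_amu + m2_amu) * AMU_TO_AU_MASS
    p_mag = np.sqrt(2.0 * mu_au * np.asarray(ker_eV, float) / HARTREE_TO_EV)
    p1 = p_mag[:, None] * directions
    return p1, -p1


def _random_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# event stream
# ---------------------------------------------------------------------------


def generate_event_stream(
    config: GeneratorConfig,
    seed: int = 0,
    spectrometer: SpectrometerConfig = DEFAULT_SPECTROMETER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic pump-probe double-coincidence stream.

    Returns ``(hits, truth)``: ``hits`` has one row per ion hit
    (shot_id, delay_fs, tof_ns, x_mm, y_mm); ``truth`` one row per event with
    the destined channel, the observed channel, the sampled migration time
    and the true KER.
    """
    rng = np.random.default_rng(seed)
    edges = config.delay_edges_fs
    names = sorted(config.branching)
    probs = np.array([config.branching[c] for c in names], float)
    probs = probs / probs.sum()

    rows_truth = []
    shot = 0
    hit_frames = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_events = int(
            rng.binomial(config.pulse_pairs_per_bin, config.event_probability)
        )
        if n_events == 0:
            continue
        delays = rng.uniform(lo, hi, size=n_events)
        destined = rng.choice(names, size=n_events, p=probs)
        is_bg = rng.random(n_events) < config.background_fraction
        taus = np.array([config.effective_tau(c) for c in destined])
        T = rng.exponential(taus)
        migrated = np.abs(delays) >= T

        observed = np.where(migrated, destined, PRECURSOR_CHANNEL)
        observed = np.where(is_bg, destined, observed)

        r0 = np.array(
            [config.explosion_r0_angstrom[c] for c in observed], float
        )
        sep = np.where(
            migrated & ~is_bg,
            r0 + config.separation_speed_angstrom_fs * (np.abs(delays) - T),
            r0,
        )
        ker = two_body_ker(sep)
        ker = np.where(
            is_bg,
            rng.normal(config.background_ker_eV,
                       config.background_ker_sigma_eV, n_events),
            ker,
        )
        ker = np.maximum(ker, 1e-6)
        dirs = _random_directions(rng, n_events)

        shot_ids = np.arange(shot, shot + n_events)
        shot += n_events
        for ch in set(observed):
            m = observed == ch
            sp1, sp2 = CHANNEL_SPECIES[ch]
            p1, p2 = two_body_momenta(
                ker[m],
                get_species(sp1).mass,
                get_species(sp2).mass,
                dirs[m],
            )
            for sp, p in ((sp1, p1), (sp2, p2)):
                tof, x, y = forward_model_arrays(p, sp, spectrometer)
                hit_frames.append(
                    pd.DataFrame(
                        {
                            "shot_id": shot_ids[m],
                            "delay_fs": delays[m],
                            "tof_ns": tof,
                            "x_mm": x,
                            "y_mm": y,
                        }
                    )
                )
        rows_truth.append(
            pd.DataFrame(
                {
                    "shot_id": shot_ids,
                    "delay_fs": delays,
                    "destined_channel": destined,
                    "observed_channel": observed,
                    "migration_time_fs": T,
                    "ker_eV": ker,
                    "source": np.where(is_bg, "single_pulse", "pump_probe"),
                }
            )
        )

    hits = (
        pd.concat(hit_frames, ignore_index=True)
        .sort_values(["shot_id", "tof_ns"], kind="stable")
        .reset_index(drop=True)
    )
    truth = (
        pd.concat(rows_truth, ignore_index=True)
        .sort_values("shot_id", kind="stable")
        .reset_index(drop=True)
    )
    return hits, truth


# ---------------------------------------------------------------------------
# gating benchmark stream
# ---------------------------------------------------------------------------


def generate_gating_benchmark(
    n_per_channel: int = 500,
    n_false: int = 500,
    seed: int = 0,
    ker_eV: float = 3.0,
    triple_template=None,
    spectrometer: SpectrometerConfig = DEFAULT_SPECTROMETER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mixed stream for gating validation: momentum-conserving events in each
    double-coincidence channel plus optional triple events and false pairs
    built from unrelated momenta.

    ``triple_template`` is an (3, 3) array of momenta (a.u.) for the species
    (H+, H2O+, C2H3+), e.g. from a concerted simulation; each triple event is
    a random rotation of it.  Returns (hits, truth) with the true channel per
    shot ('FALSE' for false pairs).
    """
    rng = np.random.default_rng(seed)
    shot = 0
    hit_rows = []
    truth_rows = []

    def emit(shot_id, species, momenta):
        for sp, p in zip(species, momenta):
            tof, x, y = forward_model_arrays(p[None, :], sp, spectrometer)
            hit_rows.append(
                {
                    "shot_id": shot_id,
                    "delay_fs": 0.0,
                    "tof_ns": float(tof[0]),
                    "x_mm": float(x[0]),
                    "y_mm": float(y[0]),
                }
            )

    for ch, (sp1, sp2) in CHANNEL_SPECIES.items():
        dirs = _random_directions(rng, n_per_channel)
        kers = np.full(n_per_channel, ker_eV)
        p1, p2 = two_body_momenta(
            kers, get_species(sp1).mass, get_species(sp2).mass, dirs
        )
        for k in range(n_per_channel):
            emit(shot, (sp1, sp2), (p1[k], p2[k]))
            truth_rows.append({"shot_id": shot, "channel": ch})
            shot += 1

    if triple_template is not None:
        template = np.asarray(triple_template, float)
        for _ in range(n_per_channel):
            rot = random_rotation(rng)
            emit(shot, ("H+", "H2O+", "C2H3+"), template @ rot.T)
            truth_rows.append({"shot_id": shot, "channel": "TRIPLE"})
            shot += 1

    # false pairs: two heavy ions with unrelated momenta
    heavy = ["OH+", "H2O+", "H3O+", "C2H3+", "C2H4+", "C2H5+"]
    for _ in range(n_false):
        sp1, sp2 = rng.choice(heavy, size=2, replace=False)
        mags = rng.uniform(30.0, 100.0, size=2)
        dirs = _random_directions(rng, 2)
        emit(shot, (sp1, sp2), (mags[0] * dirs[0], mags[1] * dirs[1]))
        truth_rows.append({"shot_id": shot, "channel": "FALSE"})
        shot += 1

    hits = pd.DataFrame(hit_rows).sort_values(
        ["shot_id", "tof_ns"], kind="stable"
    ).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return hits, truth


# ---------------------------------------------------------------------------
# trajectory ensemble
# ---------------------------------------------------------------------------

# atom indices in the ethanol geometry
_O, _CA, _CB, _HO = 0, 1, 2, 3
_ALPHA_H = [4, 5]
_BETA_H = [6, 7, 8]
#: final H–O distance of a migrated hydrogen, Å
_H_FINAL = 0.95


def _truncated_exponential(
    rng: np.random.Generator, tau: float, upper: float
) -> float:
    u = rng.random()
    return float(-tau * np.log1p(-u * (1.0 - np.exp(-upper / tau))))


def _sample_origins(rng: np.random.Generator, n_migrations: int):
    """Independent 50/50 alpha/beta carbon choice per migration, then a free
    hydrogen on that carbon (falling back to the other carbon if exhausted)."""
    free = {"alpha": list(_ALPHA_H), "beta": list(_BETA_H)}
    out = []
    for _ in range(n_migrations):
        carbon = "alpha" if rng.random() < 0.5 else "beta"
        if not free[carbon]:
            carbon = "alpha" if carbon == "beta" else "beta"
        h = free[carbon].pop(0)
        out.append((carbon, h))
    return out


def _script_trajectory(
    config: GeneratorConfig,
    channel: str,
    migrations: list,  # [(t_fs, h_index)], sorted by time
    t_co_fs: float | None,
    rng: np.random.Generator,
    trajectory_id: str,
) -> tuple[Trajectory, float | None]:
    """Build the scripted geometry time series.

    The O-bearing group (O, hydroxyl H, captured hydrogens) separates from
    C_alpha along the initial C→O direction so that d(C_alpha, O) crosses the
    3 Å break threshold at ``t_co_fs``; each migrating H approaches O
    radially so that d(H, O) crosses 1 Å exactly at its migration time.
    Returns the trajectory and the actual scripted break time (shifted if the
    separation ramp would have to start before t = 0).
    """
    geo = ethanol_geometry()
    base = geo.coordinates + rng.normal(
        0.0, config.jitter_angstrom, size=geo.coordinates.shape
    )
    n_frames = int(round(config.trajectory_max_time_fs
                         / config.trajectory_dt_fs)) + 1
    t = np.arange(n_frames) * config.trajectory_dt_fs

    frames = np.broadcast_to(base, (n_frames, 9, 3)).copy()

    # C–O separation schedule
    t_co_actual = None
    d_co0 = float(np.linalg.norm(base[_O] - base[_CA]))
    if t_co_fs is not None:
        v = config.co_speed_angstrom_fs
        ramp = (3.0 - d_co0) / v
        t_start = max(t_co_fs - ramp, 0.0)
        t_co_actual = t_start + ramp
        u_sep = (base[_O] - base[_CA])
        u_sep = u_sep / np.linalg.norm(u_sep)
        extra = v * np.maximum(t - t_start, 0.0)
        o_shift = extra[:, None] * u_sep[None, :]
    else:
        o_shift = np.zeros((n_frames, 3))

    o_pos = base[_O][None, :] + o_shift
    frames[:, _O] = o_pos
    frames[:, _HO] = base[_HO][None, :] + o_shift  # hydroxyl H rides with O

    for t_mig, h in migrations:
        u = base[h] - base[_O]
        d0 = float(np.linalg.norm(u))
        u = u / d0
        # approach speed fast enough that the ramp starts at t >= 0, so the
        # H still sits at its origin carbon in the first frame
        v_mig = max(
            config.migration_speed_angstrom_fs,
            (d0 - 1.0) / max(t_mig, config.trajectory_dt_fs),
        )
        d = np.clip(1.0 - v_mig * (t - t_mig), _H_FINAL, d0)
        frames[:, h] = o_pos + d[:, None] * u[None, :]

    rot = random_rotation(rng)
    frames = frames @ rot.T

    traj = Trajectory(
        elements=list(geo.elements),
        frames=frames,
        dt_fs=config.trajectory_dt_fs,
        charge=config.trajectory_charge,
        internal_energy_eV=config.trajectory_internal_energy_eV,
        trajectory_id=trajectory_id,
    )
    return traj, t_co_actual


def generate_trajectory_ensemble(
    config: GeneratorConfig, seed: int = 0
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Scripted AIMD-like ensemble with recorded per-trajectory ground truth.

    DHM trajectories carry two independent migration times (t1 truncated
    below the floor of t2's support, so the ordered pair is independent by
    construction) and a C–O break concerted with the second migration;
    SHM trajectories one migration with a concerted break; NHM trajectories
    separate OH without migration.
    """
    rng = np.random.default_rng(seed)
    names = sorted(config.trajectory_branching)
    probs = np.array(
        [config.trajectory_branching[c] for c in names], float
    )
    probs = probs / probs.sum()

    trajectories = []
    rows = []
    for k in range(config.n_trajectories):
        channel = str(rng.choice(names, p=probs))
        tid = f"traj_{k:04d}_{channel}"
        t1 = t2 = t_co = None
        origins = []
        if channel == "DHM":
            t1 = _truncated_exponential(rng, config.tau1_fs,
                                        config.t2_floor_fs)
            t2 = config.t2_floor_fs + float(
                rng.exponential(config.tau2_fs)
            )
            t_co = t2 + config.co_break_offset_fs + float(
                rng.normal(0.0, config.co_break_sigma_fs)
            )
            origins = _sample_origins(rng, 2)
            migrations = [(t1, origins[0][1]), (t2, origins[1][1])]
        elif channel == "SHM":
            t1 = float(rng.exponential(config.tau1_fs * 2.0))
            t_co = t1 + config.co_break_offset_fs + float(
                rng.normal(0.0, config.co_break_sigma_fs)
            )
            origins = _sample_origins(rng, 1)
            migrations = [(t1, origins[0][1])]
        elif channel == "NHM":
            t_co = 100.0 + float(rng.exponential(500.0))
            migrations = []
        else:  # unfragmented
            migrations = []

        traj, t_co_actual = _script_trajectory(
            config, channel, migrations, t_co, rng, tid
        )
        trajectories.append(traj)
        rows.append(
            {
                "trajectory_id": tid,
                "channel": channel,
                "t1_fs": np.nan if t1 is None else t1,
                "t2_fs": np.nan if t2 is None else t2,
                "t_co_fs": np.nan if t_co_actual is None else t_co_actual,
                "first_origin": origins[0][0] if origins else "",
                "second_origin": origins[1][0] if len(origins) > 1 else "",
            }
        )
    return trajectories, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def write_manifest(
    outdir, config: GeneratorConfig, seed: int, files: list
) -> Path:
    """Record config, seed and output file hashes for provenance."""
    outdir = Path(outdir)
    manifest = {
        "seed": int(seed),
        "config": asdict(config),
        "files": {},
    }
    for f in files:
        f = Path(f)
        manifest["files"][f.name] = hashlib.sha256(
            f.read_bytes()
        ).hexdigest()
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
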