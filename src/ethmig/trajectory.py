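"""AIMD-style trajectory post-processing.

Implements the migration-time and bond-break criteria used to classify
hydrogen migration in ethanol ions:

* a hydrogen counts as migrated the first time its distance to the O atom
  drops below 1 Å (the original hydroxyl hydrogen, identified at frame 0,
  is excluded);
* the C–O bond counts as broken the first time the distance between O and
  the carbon it departs from (the nearest carbon at frame 0, C_alpha)
  exceeds 3 Å;

plus fragment identification from the final frame's bond graph, cumulative
yield curves, theory-to-experiment scaling, and the migration-time
correlation analyses (second vs first migration, C–O break vs second
migration, alpha/beta origin split).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .units import ATOMIC_MASS, COVALENT_RADIUS

__all__ = [
    "Trajectory",
    "MigrationRecord",
    "YieldCurve",
    "XYZFormatError",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "migration_times",
    "co_break_time",
    "final_fragments",
    "analyze_trajectory",
    "cumulative_yield",
    "scale_to_experiment",
    "migration_correlations",
    "records_to_frame",
]

#: H–O capture distance, Å
MIGRATION_THRESHOLD = 1.0
#: C–O break distance, Å
CO_BREAK_THRESHOLD = 3.0
#: bond iff distance < BOND_SCALE * (r_cov_i + r_cov_j)
BOND_SCALE = 1.2


class XYZFormatError(ValueError):
    """Malformed multi-frame XYZ input."""


@dataclass
class Trajectory:
    """Element labels plus per-frame Cartesian coordinates at fixed timestep.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``dt_fs`` is the frame
    spacing.  ``charge`` and ``internal_energy_eV`` are precursor metadata.
    """

    elements: list
    frames: np.ndarray
    dt_fs: float
    charge: int = 1
    internal_energy_eV: float = 0.0
    trajectory_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.elements):
            raise ValueError("frames and elements disagree on atom count")
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_fs(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_fs

    def atom_indices(self, element: str) -> np.ndarray:
        return np.array(
            [i for i, el in enumerate(self.elements) if el == element], int
        )


@dataclass
class MigrationRecord:
    """Per-trajectory migration/break times (fs; None = not observed)."""

    trajectory_id: str = ""
    first_migration_fs: float | None = None
    second_migration_fs: float | None = None
    first_origin: str | None = None  # alpha / beta
    second_origin: str | None = None
    co_break_fs: float | None = None
    oh_formation_fs: float | None = None
    final_channel: str = "unfragmented"
    internal_energy_eV: float = 0.0
    charge: int = 1

    def event_time(self) -> float | None:
        """The time that 'completes' the record's channel: C–O break for NHM,
        first migration for SHM, second migration for DHM."""
        if self.final_channel == "NHM":
            return self.co_break_fs
        if self.final_channel == "SHM":
            return self.first_migration_fs
        if self.final_channel == "DHM":
            return self.second_migration_fs
        return None


@dataclass
class YieldCurve:
    """Yield sampled on a time grid; cumulative counts are non-decreasing."""

    times_fs: np.ndarray
    values: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self):
        self.times_fs = np.asarray(self.times_fs, float)
        self.values = np.asarray(self.values, float)
        if self.times_fs.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")

    def value_at(self, t_fs: float) -> float:
        """Nearest-grid-point lookup."""
        return float(self.values[np.argmin(np.abs(self.times_fs - t_fs))])


# ---------------------------------------------------------------------------
# XYZ I/O (through MDAnalysis; imported lazily, its import is expensive)
# ---------------------------------------------------------------------------

_KNOWN_ELEMENTS = {"H", "C", "O"}


def _validate_xyz_frames(path) -> int:
    """Check that every XYZ frame declares the same atom count; returns the
    frame count.  MDAnalysis reads the topology from the first frame only, so
    a malformed file would otherwise be mis-parsed silently."""
    n_atoms = None
    n_frames = 0
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                if header == "" :
                    break
                continue
            try:
                count = int(header)
            except ValueError:
                raise XYZFormatError(
                    f"{path}: frame {n_frames}: bad atom-count line "
                    f"{header.strip()!r}"
                ) from None
            if n_atoms is None:
                n_atoms = count
            elif count != n_atoms:
                raise XYZFormatError(
                    f"{path}: frame {n_frames} declares {count} atoms, "
                    f"expected {n_atoms}"
                )
            fh.readline()  # comment line
            for k in range(count):
                line = fh.readline()
                if len(line.split()) < 4:
                    raise XYZFormatError(
                        f"{path}: frame {n_frames}: truncated atom line {k}"
                    )
            n_frames += 1
    if not n_frames:
        raise XYZFormatError(f"{path}: no frames found")
    return n_frames


def read_xyz_trajectory(
    path,
    dt_fs: float,
    charge: int = 1,
    internal_energy_eV: float = 0.0,
    trajectory_id: str = "",
) -> Trajectory:
    """Read a multi-frame XYZ file (count line, comment line, ``el x y z``)."""
    import MDAnalysis as mda

    n_frames = _validate_xyz_frames(path)
    try:
        u = mda.Universe(str(path))
        elements = [str(n) for n in u.atoms.names]
        frames = np.array(
            [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
        )
    except Exception as exc:  # MDAnalysis raises several error types here
        raise XYZFormatError(f"cannot parse {path}: {exc}") from exc
    if len(frames) != n_frames:
        raise XYZFormatError(
            f"{path}: read {len(frames)} frames, header scan found {n_frames}"
        )
    unknown = set(elements) - _KNOWN_ELEMENTS
    if unknown:
        raise XYZFormatError(
            f"unknown element symbols {sorted(unknown)} in {path}"
        )
    return Trajectory(
        elements=elements,
        frames=frames,
        dt_fs=dt_fs,
        charge=charge,
        internal_energy_eV=internal_energy_eV,
        trajectory_id=trajectory_id or str(path),
    )


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as concatenated XYZ frames."""
    import MDAnalysis as mda

    n = len(traj.elements)
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", traj.elements)
    with mda.Writer(str(path), n_atoms=n) as w:
        for frame in traj.frames:
            u.atoms.positions = frame
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# migration / break criteria
# ---------------------------------------------------------------------------


def _single_atom_index(traj: Trajectory, element: str) -> int:
    idx = traj.atom_indices(element)
    if len(idx) == 0:
        raise ValueError(f"trajectory has no {element} atom")
    return int(idx[0])


def _first_crossing_below(d: np.ndarray, threshold: float) -> int | None:
    """Index of the first frame where d < threshold, else None."""
    below = np.nonzero(d < threshold)[0]
    return int(below[0]) if len(below) else None


def migration_times(
    traj: Trajectory, threshold: float = MIGRATION_THRESHOLD
) -> MigrationRecord:
    """First/second H-migration times by the first-crossing rule.

    For every hydrogen except the original hydroxyl H (d(H,O) < threshold at
    frame 0) the first frame with d(H,O) < threshold is found; the two
    earliest crossing times become the first and second migration times, with
    origins (alpha/beta) taken from the nearest carbon at frame 0.  Ties in
    the same frame break by atom index.
    """
    o_idx = _single_atom_index(traj, "O")
    c_idx = traj.atom_indices("C")
    if len(c_idx) != 2:
        raise ValueError("expected exactly two carbon atoms")
    h_idx = traj.atom_indices("H")

    frame0 = traj.frames[0]
    d_co0 = np.linalg.norm(frame0[c_idx] - frame0[o_idx], axis=1)
    c_alpha = c_idx[np.argmin(d_co0)]

    crossings = []  # (frame, atom index, origin)
    for h in h_idx:
        d = np.linalg.norm(traj.frames[:, h] - traj.frames[:, o_idx], axis=1)
        if d[0] < threshold:
            continue  # the original hydroxyl hydrogen
        k = _first_crossing_below(d, threshold)
        if k is None:
            continue
        d_hc0 = np.linalg.norm(frame0[c_idx] - frame0[h], axis=1)
        origin = "alpha" if c_idx[np.argmin(d_hc0)] == c_alpha else "beta"
        crossings.append((k, int(h), origin))

    crossings.sort()
    rec = MigrationRecord(
        trajectory_id=traj.trajectory_id,
        internal_energy_eV=traj.internal_energy_eV,
        charge=traj.charge,
    )
    if crossings:
        rec.first_migration_fs = crossings[0][0] * traj.dt_fs
        rec.first_origin = crossings[0][2]
    if len(crossings) > 1:
        rec.second_migration_fs = crossings[1][0] * traj.dt_fs
        rec.second_origin = crossings[1][2]
    return rec


def co_break_time(
    traj: Trajectory, threshold: float = CO_BREAK_THRESHOLD
) -> float | None:
    """Time (fs) of the first frame where d(O, C_alpha) > threshold, where
    C_alpha is the carbon nearest O at frame 0; None if never."""
    o_idx = _single_atom_index(traj, "O")
    c_idx = traj.atom_indices("C")
    frame0 = traj.frames[0]
    d0 = np.linalg.norm(frame0[c_idx] - frame0[o_idx], axis=1)
    c_alpha = c_idx[np.argmin(d0)]
    d = np.linalg.norm(traj.frames[:, c_alpha] - traj.frames[:, o_idx], axis=1)
    above = np.nonzero(d > threshold)[0]
    return float(above[0] * traj.dt_fs) if len(above) else None


# ---------------------------------------------------------------------------
# final-frame fragment identification
# ---------------------------------------------------------------------------

#: composition (element→count) → fragment formula label
_FRAGMENT_FORMULAS = {
    (("H", 1),): "H",
    (("H", 1), ("O", 1)): "OH",
    (("H", 2), ("O", 1)): "H2O",
    (("H", 3), ("O", 1)): "H3O",
    (("C", 2), ("H", 3)): "C2H3",
    (("C", 2), ("H", 4)): "C2H4",
    (("C", 2), ("H", 5)): "C2H5",
    (("C", 2), ("H", 6), ("O", 1)): "C2H6O",
}

_CHANNEL_FRAGMENTS = {
    frozenset({"OH", "C2H5"}): "NHM",
    frozenset({"H2O", "C2H4"}): "SHM",
    frozenset({"H3O", "C2H3"}): "DHM",
    frozenset({"H", "H2O", "C2H3"}): "TRIPLE",
}


def _bond_components(elements, coords, bond_scale):
    n = len(elements)
    radii = np.array([COVALENT_RADIUS[el] for el in elements])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cutoff = bond_scale * (radii[:, None] + radii[None, :])
    adj = (d < cutoff) & ~np.eye(n, dtype=bool)
    # connected components by BFS
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(adj[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(sorted(comp))
    return comps


def final_fragments(
    traj: Trajectory, bond_scale: float = BOND_SCALE
) -> str:
    """Channel label from the last frame's bond-graph connected components.

    Returns NHM/SHM/DHM/TRIPLE when the component compositions match a known
    channel, 'unfragmented' for a single component, 'other' otherwise.
    """
    coords = traj.frames[-1]
    comps = _bond_components(traj.elements, coords, bond_scale)
    if len(comps) == 1:
        return "unfragmented"
    formulas = set()
    for comp in comps:
        counts: dict = {}
        for i in comp:
            counts[traj.elements[i]] = counts.get(traj.elements[i], 0) + 1
        key = tuple(sorted(counts.items()))
        formulas.add(_FRAGMENT_FORMULAS.get(key, "?"))
    return _CHANNEL_FRAGMENTS.get(frozenset(formulas), "other")


def analyze_trajectory(traj: Trajectory) -> MigrationRecord:
    """Full per-trajectory record: migration times, C–O break, final channel."""
    rec = migration_times(traj)
    rec.co_break_fs = co_break_time(traj)
    rec.final_channel = final_fragments(traj)
    if rec.final_channel == "NHM":
        rec.oh_formation_fs = rec.co_break_fs
    return rec


# ---------------------------------------------------------------------------
# yield curves and correlations
# ---------------------------------------------------------------------------


def cumulative_yield(
    records: list[MigrationRecord],
    channel: str,
    times_fs: np.ndarray,
) -> YieldCurve:
    """Cumulative count of ``channel`` trajectories whose defining event time
    is ≤ t, on the given time grid."""
    times_fs = np.asarray(times_fs, float)
    events = np.array(
        [
            r.event_time()
            for r in records
            if r.final_channel == channel and r.event_time() is not None
        ],
        float,
    )
    values = (
        (events[None, :] <= times_fs[:, None]).sum(axis=1).astype(float)
        if len(events)
        else np.zeros_like(times_fs)
    )
    return YieldCurve(times_fs=times_fs, values=values)


def scale_to_experiment(
    theory: YieldCurve, experiment: YieldCurve, t_ref_fs: float = 1000.0
) -> YieldCurve:
    """Scale the theory curve to match the experimental normalized yield at
    ``t_ref_fs`` (nearest grid point), where the yield has saturated."""
    denom = theory.value_at(t_ref_fs)
    if denom == 0:
        raise ValueError(f"theory curve is zero at t_ref = {t_ref_fs} fs")
    factor = experiment.value_at(t_ref_fs) / denom
    return YieldCurve(
        times_fs=theory.times_fs.copy(),
        values=theory.values * factor,
        scale_factor=theory.scale_factor * factor,
    )


def _pair_correlation(x: np.ndarray, y: np.ndarray) -> dict | None:
    if len(x) < 3:
        return None
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    lr = _stats.linregress(x, y)
    return {
        "n": int(len(x)),
        "r": float(lr.rvalue),
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
    }


def migration_correlations(records: list[MigrationRecord]) -> dict:
    """Correlation summary over migration records.

    Returns Pearson r plus least-squares slope/intercept for (t2 vs t1) and
    (t_CO vs t2), and the alpha/beta counts of the second-migration origin.
    A correlation with fewer than 3 complete pairs or zero variance is
    reported as None.
    """
    t1t2 = np.array(
        [
            (r.first_migration_fs, r.second_migration_fs)
            for r in records
            if r.first_migration_fs is not None
            and r.second_migration_fs is not None
        ],
        float,
    ).reshape(-1, 2)
    t2co = np.array(
        [
            (r.second_migration_fs, r.co_break_fs)
            for r in records
            if r.second_migration_fs is not None
            and r.co_break_fs is not None
        ],
        float,
    ).reshape(-1, 2)
    origins = [r.second_origin for r in records if r.second_origin]
    return {
        "t2_vs_t1": _pair_correlation(t1t2[:, 0], t1t2[:, 1]),
        "t_co_vs_t2": _pair_correlation(t2co[:, 0], t2co[:, 1]),
        "origin_counts": {
            "alpha": origins.count("alpha"),
            "beta": origins.count("beta"),
        },
        "pairs_t2_t1": t1t2,
        "pairs_tco_t2": t2co,
    }


def records_to_frame(records: list[MigrationRecord]) -> pd.DataFrame:
    """One-row-per-trajectory record table."""
    return pd.DataFrame(
        {
            "trajectory_id": [r.trajectory_id for r in records],
            "charge": [r.charge for r in records],
            "internal_energy_eV": [r.internal_energy_eV for r in records],
            "first_migration_fs": [
                math.nan if r.first_migration_fs is None
                else r.first_migration_fs
                for r in records
            ],
            "second_migration_fs": [
                math.nan if r.second_migration_fs is None
                else r.second_migration_fs
                for r in records
            ],
            "first_origin": [r.first_origin or "" for r in records],
            "second_origin": [r.second_origin or "" for r in records],
            "co_break_fs": [
                math.nan if r.co_break_fs is None else r.co_break_fs
                for r in records
            ],
            "final_channel": [r.final_channel for r in records],
        }
    )
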