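"""Channel identification: PIPICO maps, TOF-window species assignment and
momentum-conservation gating.

Hits are exchanged as pandas DataFrames with columns
``shot_id, delay_fs, tof_ns, x_mm, y_mm`` (one row per ion hit).  For every
laser-shot pair the hits are matched against the channel definitions: each
candidate channel needs one hit inside every member species' TOF window, the
momenta are reconstructed under those species hypotheses, and the event is
accepted only if the reconstructed momenta conserve momentum.

Neighbouring-mass ions (OH+/H2O+/H3O+) have overlapping TOF windows, so a
shot can be window-compatible with several channels; the gate-passing
channel with the smallest |Σp| wins, with the fixed priority
TRIPLE > DHM > SHM > NHM breaking exact ties.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import CoincidenceEvent
from .spectrometer import (
    DEFAULT_SPECTROMETER,
    DetectorHit,
    SpectrometerConfig,
    reconstruct_momentum,
    tof_window,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelDef",
    "CHANNELS",
    "PipicoMap",
    "build_pipico_map",
    "assign_channel",
    "assign_channels",
]

#: default maximum expected |p| (a.u.) used to derive TOF window half-widths
DEFAULT_P_MAX = 150.0


@dataclass(frozen=True)
class ChannelDef:
    """A coincidence channel: member species, KER gate [low, high) in eV and
    the momentum-conservation threshold in a.u."""

    name: str
    species: tuple
    ker_gate: tuple = (0.0, np.inf)
    momentum_sum_threshold: float = 10.0
    #: additional KER sub-gates (eV), e.g. the triple channel's low/high split
    sub_gates: tuple = ()

    def ker_in_gate(self, ker_eV: float) -> bool:
        return self.ker_gate[0] <= ker_eV < self.ker_gate[1]


#: priority order: the triple coincidence is strictly more constrained
CHANNELS: list[ChannelDef] = [
    ChannelDef(
        "TRIPLE",
        ("H+", "H2O+", "C2H3+"),
        ker_gate=(0.0, 13.0),
        sub_gates=((0.0, 5.0), (5.0, 13.0)),
    ),
    ChannelDef("DHM", ("H3O+", "C2H3+"), ker_gate=(0.5, 3.6)),
    ChannelDef("SHM", ("H2O+", "C2H4+"), ker_gate=(0.5, 3.6)),
    ChannelDef("NHM", ("OH+", "C2H5+"), ker_gate=(0.0, 4.0)),
]

CHANNEL_BY_NAME = {c.name: c for c in CHANNELS}


@dataclass
class PipicoMap:
    """2D histogram of (first-ion, second-ion) time of flight."""

    tof1_edges: np.ndarray
    tof2_edges: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        t1 = 0.5 * (self.tof1_edges[:-1] + self.tof1_edges[1:])
        t2 = 0.5 * (self.tof2_edges[:-1] + self.tof2_edges[1:])
        g1, g2 = np.meshgrid(t1, t2, indexing="ij")
        return pd.DataFrame(
            {
                "tof1_ns": g1.ravel(),
                "tof2_ns": g2.ravel(),
                "counts": self.counts.ravel().astype(int),
            }
        )


def build_pipico_map(
    hits: pd.DataFrame,
    tof1_edges: np.ndarray,
    tof2_edges: np.ndarray | None = None,
) -> PipicoMap:
    """PIPICO map: for every shot, every ordered hit pair (earlier, later)
    increments the histogram."""
    tof1_edges = np.asarray(tof1_edges, float)
    tof2_edges = (
        tof1_edges if tof2_edges is None else np.asarray(tof2_edges, float)
    )
    first, second = [], []
    for _, grp in hits.groupby("shot_id"):
        tofs = np.sort(grp["tof_ns"].to_numpy())
        if len(tofs) < 2:
            continue
        for i, j in itertools.combinations(range(len(tofs)), 2):
            first.append(tofs[i])
            second.append(tofs[j])
    counts, _, _ = np.histogram2d(
        first, second, bins=[tof1_edges, tof2_edges]
    )
    return PipicoMap(tof1_edges, tof2_edges, counts.astype(int))


def _hit_arrays(hits) -> tuple:
    if isinstance(hits, pd.DataFrame):
        return (
            hits["tof_ns"].to_numpy(float),
            hits["x_mm"].to_numpy(float),
            hits["y_mm"].to_numpy(float),
            float(hits["delay_fs"].iloc[0]) if len(hits) else 0.0,
            int(hits["shot_id"].iloc[0]) if len(hits) else -1,
        )
    # list of DetectorHit
    return (
        np.array([h.tof_ns for h in hits], float),
        np.array([h.x_mm for h in hits], float),
        np.array([h.y_mm for h in hits], float),
        hits[0].delay_fs if hits else 0.0,
        hits[0].shot_id if hits else -1,
    )


def assign_channel(
    hits,
    channels: list[ChannelDef] | None = None,
    config: SpectrometerConfig = DEFAULT_SPECTROMETER,
    p_max_au: float = DEFAULT_P_MAX,
) -> tuple[str | None, CoincidenceEvent | None]:
    """Assign the hits of one shot to a coincidence channel.

    Returns (channel name, reconstructed event) or (None, None).  Among the
    channels whose species TOF windows can each be matched to a distinct hit
    and whose reconstructed momenta satisfy |Σp| < threshold, the one with
    the smallest |Σp| is returned (list order breaks ties).
    """
    channels = channels if channels is not None else CHANNELS
    tofs, xs, ys, delay, shot = _hit_arrays(hits)
    n = len(tofs)
    if n < 2:
        return None, None

    windows = {}
    recon_cache: dict = {}

    def recon(i, sp):
        key = (i, sp)
        if key not in recon_cache:
            recon_cache[key] = reconstruct_momentum(
                DetectorHit(tof_ns=tofs[i], x_mm=xs[i], y_mm=ys[i]),
                sp,
                config,
            )
        return recon_cache[key]

    best = None  # (|Σp|, rank, channel, assignment)
    for rank, ch in enumerate(channels):
        k = len(ch.species)
        if n < k:
            continue
        cands = []
        for sp in ch.species:
            if sp not in windows:
                windows[sp] = tof_window(sp, p_max_au, config)
            lo, hi = windows[sp]
            idx = np.nonzero((tofs >= lo) & (tofs < hi))[0]
            cands.append(idx)
        if any(len(c) == 0 for c in cands):
            continue
        for combo in itertools.product(*cands):
            if len(set(combo)) != k:
                continue
            psum = np.sum([recon(i, sp) for i, sp in zip(combo, ch.species)],
                          axis=0)
            cost = float(np.linalg.norm(psum))
            if cost < ch.momentum_sum_threshold:
                if best is None or (cost, rank) < (best[0], best[1]):
                    best = (cost, rank, ch, combo)

    if best is None:
        return None, None
    _, _, ch, combo = best
    event = CoincidenceEvent(
        delay_fs=delay,
        fragments=[
            (sp, recon(i, sp)) for i, sp in zip(combo, ch.species)
        ],
        shot_id=shot,
    )
    return ch.name, event


def assign_channels(
    hits: pd.DataFrame,
    channels: list[ChannelDef] | None = None,
    config: SpectrometerConfig = DEFAULT_SPECTROMETER,
    p_max_au: float = DEFAULT_P_MAX,
) -> tuple[dict, dict]:
    """Assign every shot in a hit table.

    Returns ``(events, stats)`` where ``events`` maps channel name → list of
    :class:`CoincidenceEvent` and ``stats`` counts shots, assignments and
    rejections.
    """
    channels = channels if channels is not None else CHANNELS
    events: dict = {c.name: [] for c in channels}
    stats = {"shots": 0, "assigned": 0, "rejected": 0}
    for _, grp in hits.groupby("shot_id"):
        stats["shots"] += 1
        name, ev = assign_channel(grp, channels, config, p_max_au)
        if name is None:
            stats["rejected"] += 1
        else:
            stats["assigned"] += 1
            events[name].append(ev)
    logger.info("channel assignment: %s", stats)
    return events, stats
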