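"""Pump-probe delay analysis: KER-vs-delay maps, pulse-pair-normalized yield
curves, saturation-time fits and channel-ratio flatness tests.

Delays are signed (negative = the stronger pulse arrives first) and the
positive and negative branches are analyzed independently.  Delay bins inside
the pulse-overlap window (default |t| < 30 fs) are flagged because pump and
probe interfere there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize as _optimize

from .coincidence import ChannelDef
from .kinematics import CoincidenceEvent, ker

__all__ = [
    "DelayScan",
    "KerDelayMap",
    "default_delay_edges",
    "ker_delay_map",
    "yield_vs_delay",
    "channel_ratio",
    "ratio_slope",
    "fit_saturation_time",
]

#: pulse-overlap exclusion half-window, fs
OVERLAP_WINDOW_FS = 30.0


def default_delay_edges(
    t_min: float = -1000.0, t_max: float = 1000.0, width: float = 50.0
) -> np.ndarray:
    """Default delay binning: 50 fs bins from -1 ps to +1 ps."""
    return np.arange(t_min, t_max + width / 2, width)


@dataclass
class DelayScan:
    """Per-delay-bin gated counts and pulse-pair-normalized yields."""

    delay_edges_fs: np.ndarray
    pulse_pairs: np.ndarray
    counts: np.ndarray
    channel: str = ""
    ker_gate: tuple = (0.0, np.inf)
    overlap_window_fs: float = OVERLAP_WINDOW_FS

    def __post_init__(self):
        self.delay_edges_fs = np.asarray(self.delay_edges_fs, float)
        self.pulse_pairs = np.asarray(self.pulse_pairs, float)
        self.counts = np.asarray(self.counts, float)
        nbins = len(self.delay_edges_fs) - 1
        if len(self.pulse_pairs) != nbins or len(self.counts) != nbins:
            raise ValueError("pulse_pairs/counts must match the binning")

    @property
    def centers_fs(self) -> np.ndarray:
        return 0.5 * (self.delay_edges_fs[:-1] + self.delay_edges_fs[1:])

    @property
    def valid(self) -> np.ndarray:
        """Bins with pulse pairs recorded (reported bins)."""
        return self.pulse_pairs > 0

    @property
    def overlap_flag(self) -> np.ndarray:
        """Bins inside the pulse-overlap exclusion window."""
        return np.abs(self.centers_fs) < self.overlap_window_fs

    @property
    def yields(self) -> np.ndarray:
        out = np.full_like(self.counts, np.nan, dtype=float)
        ok = self.valid
        out[ok] = self.counts[ok] / self.pulse_pairs[ok]
        return out

    @property
    def yield_errors(self) -> np.ndarray:
        """Poisson (counting) uncertainty of the normalized yield."""
        out = np.full_like(self.counts, np.nan, dtype=float)
        ok = self.valid
        out[ok] = np.sqrt(np.maximum(self.counts[ok], 1.0)) / self.pulse_pairs[ok]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delay_fs": self.centers_fs,
                "pulse_pairs": self.pulse_pairs,
                "counts": self.counts,
                "yield": self.yields,
                "yield_err": self.yield_errors,
                "overlap_flagged": self.overlap_flag,
            }
        )


@dataclass
class KerDelayMap:
    """2D histogram of (delay, KER) for one channel."""

    delay_edges_fs: np.ndarray
    ker_edges_eV: np.ndarray
    counts: np.ndarray
    channel: str = ""

    def to_frame(self) -> pd.DataFrame:
        d = 0.5 * (self.delay_edges_fs[:-1] + self.delay_edges_fs[1:])
        k = 0.5 * (self.ker_edges_eV[:-1] + self.ker_edges_eV[1:])
        gd, gk = np.meshgrid(d, k, indexing="ij")
        return pd.DataFrame(
            {
                "delay_fs": gd.ravel(),
                "ker_eV": gk.ravel(),
                "counts": self.counts.ravel().astype(int),
            }
        )

    def mean_ker_per_delay(self) -> np.ndarray:
        """Mean KER per delay column (NaN where a column is empty)."""
        k = 0.5 * (self.ker_edges_eV[:-1] + self.ker_edges_eV[1:])
        tot = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, (self.counts @ k) / tot, np.nan)


def ker_delay_map(
    events: list[CoincidenceEvent],
    channel: ChannelDef,
    delay_edges_fs: np.ndarray | None = None,
    ker_edges_eV: np.ndarray | None = None,
) -> KerDelayMap:
    """Histogram channel events in the (delay, KER) plane."""
    delay_edges_fs = (
        default_delay_edges() if delay_edges_fs is None else
        np.asarray(delay_edges_fs, float)
    )
    ker_edges_eV = (
        np.arange(0.0, 15.0 + 0.125, 0.25) if ker_edges_eV is None else
        np.asarray(ker_edges_eV, float)
    )
    delays = np.array([ev.delay_fs for ev in events], float)
    kers = np.array([ker(ev) for ev in events], float)
    counts, _, _ = np.histogram2d(
        delays, kers, bins=[delay_edges_fs, ker_edges_eV]
    )
    return KerDelayMap(
        delay_edges_fs, ker_edges_eV, counts.astype(int), channel.name
    )


def yield_vs_delay(
    events: list[CoincidenceEvent],
    channel: ChannelDef,
    ker_gate: tuple | None = None,
    pulse_pairs: np.ndarray | float = 1.0,
    delay_edges_fs: np.ndarray | None = None,
    overlap_window_fs: float = OVERLAP_WINDOW_FS,
) -> DelayScan:
    """Gated, pulse-pair-normalized yield per delay bin.

    ``ker_gate`` defaults to the channel's own gate ([low, high), half-open);
    ``pulse_pairs`` is either a per-bin array or a scalar count.
    """
    delay_edges_fs = (
        default_delay_edges() if delay_edges_fs is None else
        np.asarray(delay_edges_fs, float)
    )
    gate = tuple(ker_gate) if ker_gate is not None else tuple(channel.ker_gate)
    nbins = len(delay_edges_fs) - 1
    pp = (
        np.full(nbins, float(pulse_pairs))
        if np.isscalar(pulse_pairs)
        else np.asarray(pulse_pairs, float)
    )
    delays = np.array([ev.delay_fs for ev in events], float)
    kers = np.array([ker(ev) for ev in events], float)
    sel = (kers >= gate[0]) & (kers < gate[1]) if len(events) else slice(0)
    counts, _ = np.histogram(delays[sel] if len(events) else [], bins=delay_edges_fs)
    return DelayScan(
        delay_edges_fs=delay_edges_fs,
        pulse_pairs=pp,
        counts=counts.astype(float),
        channel=channel.name,
        ker_gate=gate,
        overlap_window_fs=overlap_window_fs,
    )


def channel_ratio(a: DelayScan, b: DelayScan) -> pd.DataFrame:
    """Per-bin yield ratio a/b with a counting-statistics uncertainty.

    Bins where either scan has no pulse pairs or b has zero counts are
    dropped.  The relative uncertainty adds the two Poisson terms in
    quadrature: σ_ratio/ratio = sqrt(1/Na + 1/Nb).
    """
    if not np.array_equal(a.delay_edges_fs, b.delay_edges_fs):
        raise ValueError("delay binnings differ")
    ok = a.valid & b.valid & (b.counts > 0) & (a.counts > 0)
    ratio = (a.counts[ok] / a.pulse_pairs[ok]) / (
        b.counts[ok] / b.pulse_pairs[ok]
    )
    sigma = ratio * np.sqrt(1.0 / a.counts[ok] + 1.0 / b.counts[ok])
    return pd.DataFrame(
        {
            "delay_fs": a.centers_fs[ok],
            "ratio": ratio,
            "sigma": sigma,
            "overlap_flagged": a.overlap_flag[ok],
        }
    )


def ratio_slope(ratio: pd.DataFrame, exclude_overlap: bool = True) -> dict:
    """Weighted least-squares slope of ratio vs delay and its z-score.

    Used for the competing-reaction test: with delay-independent branching
    the slope should be consistent with zero.
    """
    df = ratio[~ratio["overlap_flagged"]] if exclude_overlap else ratio
    t = df["delay_fs"].to_numpy()
    y = df["ratio"].to_numpy()
    w = 1.0 / df["sigma"].to_numpy() ** 2
    if len(t) < 3:
        raise ValueError("need at least 3 ratio points")
    # weighted linear fit y = c0 + c1 t
    W = np.sum(w)
    tw = np.sum(w * t) / W
    yw = np.sum(w * y) / W
    s_tt = np.sum(w * (t - tw) ** 2)
    slope = np.sum(w * (t - tw) * (y - yw)) / s_tt
    slope_err = np.sqrt(1.0 / s_tt)
    return {
        "slope_per_fs": float(slope),
        "slope_err": float(slope_err),
        "z": float(slope / slope_err),
        "n": int(len(t)),
    }


def fit_saturation_time(
    scan: DelayScan, branch: str = "positive"
) -> dict:
    """Fit A·(1 − exp(−t/τ)) to a delay branch of a yield scan.

    A convenience estimator of the migration time constant from the gated
    yield curve; overlap-flagged and empty bins are excluded.  ``branch`` is
    'positive', 'negative', or 'both' (fit against |t|, appropriate when the
    migration clock is the same for either pulse ordering).  Returns the
    fitted amplitude, τ (fs) and 1σ uncertainties.
    """
    t = scan.centers_fs
    ok = scan.valid & ~scan.overlap_flag
    if branch == "positive":
        ok &= t > 0
        tt = t[ok]
    elif branch == "negative":
        ok &= t < 0
        tt = -t[ok]
    elif branch == "both":
        tt = np.abs(t[ok])
    else:
        raise ValueError("branch must be 'positive', 'negative' or 'both'")
    yy = scan.yields[ok]
    ee = scan.yield_errors[ok]
    if ok.sum() < 3:
        raise ValueError("not enough bins to fit")

    def model(t, amp, tau):
        return amp * (1.0 - np.exp(-t / tau))

    p0 = (float(np.nanmax(yy)), float(np.median(tt)))
    popt, pcov = _optimize.curve_fit(
        model, tt, yy, p0=p0, sigma=ee, absolute_sigma=True, maxfev=10000
    )
    perr = np.sqrt(np.diag(pcov))
    return {
        "amplitude": float(popt[0]),
        "tau_fs": float(popt[1]),
        "amplitude_err": float(perr[0]),
        "tau_err_fs": float(perr[1]),
        "n_bins": int(ok.sum()),
    }
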