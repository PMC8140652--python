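"""Kinematic error metrics for continuous joystick target tracking.

Eight metrics quantify how a cursor trajectory ``C(t)`` deviates from a
smoothly moving target ``T(t)`` on a 2-D display:

====  ==========================  =====================================
TM    tremor magnitude            norm of the per-axis analytic-signal
                                  envelopes of the 3-10 Hz cursor band
AD    absolute distance           ``||C(t) - T(t)||``
VE    vector error                ``||T_seg - C_seg||`` over one sample
SL    slowness                    ``exp(-0.042 * S_c)``, cursor speed
                                  ``S_c`` in screen units per ms
SD    speed difference            ``S_c - S_T``
ED    excursion difference        ``||T|| - ||C||`` from display center
VA    vector angle                angle between cursor and target
                                  displacement segments
CA    correction angle            angle between the target segment and
                                  the optimal path from cursor to target
====  ==========================  =====================================

Tremor is read from the 3-10 Hz band of the raw cursor; all other metrics
use the < 3 Hz low-passed traces.  Instantaneous series are averaged over
contiguous, non-overlapping epochs (100 ms for timescale analysis, 1-10 s
for alignment with neural features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from stnmes._dsp import check_uniform, envelope, fir_taps, odd, zero_phase_filter

#: Canonical metric order used everywhere downstream (8-D metric space).
METRICS = ("TM", "AD", "VE", "SL", "SD", "ED", "VA", "CA")

#: Decay constant of the slowness metric, per (screen unit / ms) of speed.
SLOWNESS_DECAY = 0.042

#: Segment/offset norms below this are treated as degenerate for angles.
DEGENERATE_NORM = 1e-12


@dataclass
class Trace:
    """A uniformly sampled 2-D position series (cursor or target).

    Parameters
    ----------
    t : array of sample times in seconds (uniform, strictly increasing).
    x, y : screen-unit coordinates, same length as ``t``.
    fs : sample rate in Hz; must exceed 20 Hz to resolve 3-10 Hz tremor.
    role : ``"cursor"`` or ``"target"``.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float
    role: str = "cursor"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shapes")
        if self.fs <= 20.0:
            raise ValueError("sample rate must exceed 20 Hz to resolve tremor")
        step = check_uniform(self.t)
        if abs(step - 1.0 / self.fs) > 1e-6 * step:
            raise ValueError("time grid spacing inconsistent with fs")

    def __len__(self) -> int:
        return self.t.size

    @property
    def xy(self) -> np.ndarray:
        """Positions as an (n, 2) array."""
        return np.column_stack([self.x, self.y])

    @property
    def duration(self) -> float:
        """Nominal covered duration, n / fs, in seconds."""
        return len(self) / self.fs


def _same_grid(a: Trace, b: Trace) -> None:
    if len(a) != len(b) or abs(a.fs - b.fs) > 1e-9 or abs(a.t[0] - b.t[0]) > 1e-9:
        raise ValueError("traces must share one time grid")


def split_bands(
    trace: Trace,
    lp_cutoff: float = 3.0,
    tremor_band: tuple[float, float] = (3.0, 10.0),
    taps_seconds: float = 2.0,
) -> tuple[Trace, Trace]:
    """Split a trace into its slow (< 3 Hz) and tremor (3-10 Hz) components.

    Both filters are zero-phase linear-phase FIR designs so the components
    stay time-aligned with the original grid.  Traces shorter than one
    second raise; traces shorter than the nominal filter length get a
    proportionally shorter (coarser) filter with a warning.

    Returns
    -------
    (slow, tremor) : traces on the input grid.
    """
    n = len(trace)
    if n < trace.fs:
        raise ValueError("trace shorter than 1 s; band filters are undefined")
    numtaps = odd(int(taps_seconds * trace.fs))
    if numtaps > n:
        numtaps = odd(n - 2)
        warnings.warn(
            "trace shorter than the nominal filter; using a coarser design",
            stacklevel=2,
        )
    lp = fir_taps(trace.fs, lp_cutoff, pass_zero=True, numtaps=numtaps)
    bp = fir_taps(trace.fs, list(tremor_band), pass_zero=False, numtaps=numtaps)
    xy = np.vstack([trace.x, trace.y])
    # exact unit gain at DC for the low-pass, exact null for the band-pass
    lp = lp / lp.sum()
    bp = bp - bp.sum() / bp.size
    slow_xy = zero_phase_filter(xy, lp)
    trem_xy = zero_phase_filter(xy, bp)
    slow = replace(trace, x=slow_xy[0], y=slow_xy[1])
    tremor = replace(trace, x=trem_xy[0], y=trem_xy[1])
    return slow, tremor


def tremor_magnitude(tremor: Trace) -> np.ndarray:
    """Per-sample tremor magnitude: Euclidean norm of the two per-axis
    analytic-signal envelopes of the tremor-band trace."""
    env_x = envelope(tremor.x)
    env_y = envelope(tremor.y)
    return np.hypot(env_x, env_y)


def _segments(cursor: Trace, target: Trace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sample displacement segments and the cursor-to-target offset.

    Returns ``(cbar, tbar, obar)``, each of shape (n-1, 2); ``obar`` is the
    optimal-path vector ``T(t) - C(t)`` evaluated at the segment start.
    """
    _same_grid(cursor, target)
    c = cursor.xy
    tg = target.xy
    cbar = np.diff(c, axis=0)
    tbar = np.diff(tg, axis=0)
    obar = (tg - c)[:-1]
    return cbar, tbar, obar


def tracking_errors(
    cursor_slow: Trace, target: Trace
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Instantaneous AD (n,), VE (n-1,) and ED (n,) series.

    VE is the magnitude of the vector difference between the target and
    cursor one-sample displacement segments; ED references the display
    center as origin.
    """
    _same_grid(cursor_slow, target)
    ad = np.linalg.norm(cursor_slow.xy - target.xy, axis=1)
    cbar, tbar, _ = _segments(cursor_slow, target)
    ve = np.linalg.norm(tbar - cbar, axis=1)
    ed = np.linalg.norm(target.xy, axis=1) - np.linalg.norm(cursor_slow.xy, axis=1)
    return ad, ve, ed


def kinematic_metrics(
    cursor_slow: Trace, target: Trace
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Speeds and derived metrics: ``(S_c, S_T, SL, SD)``, each (n-1,).

    Speeds are expressed in screen units per millisecond — the unit in
    which the slowness decay constant 0.042 is calibrated — using one
    sample period as the finite-difference step.
    """
    cbar, tbar, _ = _segments(cursor_slow, target)
    dt_ms = 1000.0 / cursor_slow.fs
    s_c = np.linalg.norm(cbar, axis=1) / dt_ms
    s_t = np.linalg.norm(tbar, axis=1) / dt_ms
    sl = np.exp(-SLOWNESS_DECAY * s_c)
    sd = s_c - s_t
    return s_c, s_t, sl, sd


def _angle_between(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Angle between row vectors with a validity mask for degenerate rows."""
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    valid = (nu > DEGENERATE_NORM) & (nv > DEGENERATE_NORM)
    denom = np.where(valid, nu * nv, 1.0)
    cosang = np.clip(np.sum(u * v, axis=1) / denom, -1.0, 1.0)
    ang = np.where(valid, np.arccos(cosang), np.nan)
    return ang, valid


def angular_metrics(
    cursor_slow: Trace, target: Trace
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vector angle VA and correction angle CA, with a shared validity mask.

    Samples where any participating segment norm is below ``DEGENERATE_NORM``
    are flagged invalid (NaN) rather than imputed: arccos is undefined there
    and imputing zero would bias toward good performance.
    """
    cbar, tbar, obar = _segments(cursor_slow, target)
    va, va_valid = _angle_between(cbar, tbar)
    ca, ca_valid = _angle_between(obar, tbar)
    return va, ca, va_valid & ca_valid


@dataclass
class InstantaneousMetrics:
    """Per-sample metric series on (subsets of) one time grid.

    ``series[m]`` is a ``(times, values, valid)`` triple; segment-based
    metrics live on the n-1 segment-start times.
    """

    series: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    fs: float

    def __getitem__(self, m: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.series[m]


def instantaneous_metrics(cursor: Trace, target: Trace) -> InstantaneousMetrics:
    """Compute all eight instantaneous metric series from raw traces.

    The cursor is band-split internally: tremor magnitude comes from the
    3-10 Hz band, everything else from the < 3 Hz band.  The target is
    low-passed with the same filter.
    """
    _same_grid(cursor, target)
    cursor_slow, cursor_tremor = split_bands(cursor)
    target_slow, _ = split_bands(target)

    tm = tremor_magnitude(cursor_tremor)
    ad, ve, ed = tracking_errors(cursor_slow, target_slow)
    _, _, sl, sd = kinematic_metrics(cursor_slow, target_slow)
    va, ca, ang_valid = angular_metrics(cursor_slow, target_slow)

    t = cursor.t
    t_seg = t[:-1]
    all_valid = np.ones_like(tm, dtype=bool)
    seg_valid = np.ones_like(ve, dtype=bool)
    series = {
        "TM": (t, tm, all_valid),
        "AD": (t, ad, all_valid),
        "VE": (t_seg, ve, seg_valid),
        "SL": (t_seg, sl, seg_valid),
        "SD": (t_seg, sd, seg_valid),
        "ED": (t, ed, all_valid),
        "VA": (t_seg, va, ang_valid),
        "CA": (t_seg, ca, ang_valid),
    }
    return InstantaneousMetrics(series=series, fs=cursor.fs)


@dataclass
class MetricMatrix:
    """Epoch-aggregated metric values: one row per complete epoch.

    ``values`` is an (epochs x 8) DataFrame in METRICS order; cells with no
    valid samples are NaN and such epochs are excluded from model fitting.
    """

    epochs: np.ndarray  # (n, 2) start/end times, contiguous half-open
    values: pd.DataFrame
    epoch_len: float
    subject_id: str = ""
    group: str = ""
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def complete(self) -> np.ndarray:
        """Boolean mask of rows with all eight metrics present."""
        return ~self.values.isna().any(axis=1).to_numpy()

    def complete_values(self) -> np.ndarray:
        """(m, 8) array of rows with no missing cells."""
        return self.values.to_numpy()[self.complete]

    def to_csv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "epoch_start", self.epochs[:, 0])
        df.insert(1, "epoch_end", self.epochs[:, 1])
        df.to_csv(path, index=False)


def epoch_edges(t0: float, duration: float, epoch_len: float) -> np.ndarray:
    """Contiguous half-open epoch boundaries covering ``duration`` seconds;
    the trailing partial epoch is dropped."""
    n_epochs = int(np.floor(duration / epoch_len + 1e-9))
    starts = t0 + epoch_len * np.arange(n_epochs)
    return np.column_stack([starts, starts + epoch_len])


def _epoch_mean(
    t: np.ndarray,
    v: np.ndarray,
    valid: np.ndarray,
    t0: float,
    epoch_len: float,
    n_epochs: int,
) -> np.ndarray:
    """Mean of valid samples per half-open epoch [start, end); NaN if none."""
    idx = np.floor((t - t0) / epoch_len + 1e-9).astype(int)
    ok = valid & (idx >= 0) & (idx < n_epochs)
    sums = np.bincount(idx[ok], weights=v[ok], minlength=n_epochs)
    counts = np.bincount(idx[ok], minlength=n_epochs)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def epoch_metrics(
    inst: InstantaneousMetrics,
    epoch_len: float,
    t0: float | None = None,
    subject_id: str = "",
    group: str = "",
    agg: str = "mean",
) -> MetricMatrix:
    """Aggregate instantaneous metric series over contiguous epochs.

    Each epoch's value is the arithmetic mean (or median, via ``agg``) of
    the metric's valid samples in the half-open window; degenerate-flagged
    angle samples are excluded.  Epoch count derives from the nominal grid
    duration n / fs so segment series one sample short still fill the last
    epoch.
    """
    if epoch_len < 2.0 / inst.fs:
        raise ValueError("epoch_len must cover at least 2 sample periods")
    t_ref = inst["TM"][0]
    if t0 is None:
        t0 = float(t_ref[0])
    duration = t_ref.size / inst.fs
    edges = epoch_edges(t0, duration, epoch_len)
    n_epochs = len(edges)
    cols = {}
    for m in METRICS:
        t, v, valid = inst[m]
        valid = valid & np.isfinite(v)
        if agg == "mean":
            cols[m] = _epoch_mean(t, v, valid, t0, epoch_len, n_epochs)
        elif agg == "median":
            idx = np.floor((t - t0) / epoch_len + 1e-9).astype(int)
            col = np.full(n_epochs, np.nan)
            ok = valid & (idx >= 0) & (idx < n_epochs)
            for e in range(n_epochs):
                sel = v[ok & (idx == e)]
                if sel.size:
                    col[e] = np.median(sel)
            cols[m] = col
        else:
            raise ValueError(f"unknown aggregator {agg!r}")
    values = pd.DataFrame(cols, columns=list(METRICS))
    return MetricMatrix(
        epochs=edges,
        values=values,
        epoch_len=epoch_len,
        subject_id=subject_id,
        group=group,
    )


def metrics_from_traces(
    cursor: Trace,
    target: Trace,
    epoch_len: float,
    subject_id: str = "",
    group: str = "",
) -> MetricMatrix:
    """Convenience wrapper: raw traces straight to an epoch MetricMatrix."""
    inst = instantaneous_metrics(cursor, target)
    return epoch_metrics(inst, epoch_len, subject_id=subject_id, group=group)
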