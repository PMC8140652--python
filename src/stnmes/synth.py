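"""Ground-truth-known synthetic sessions: task, behavior and coupled LFP.

A slow latent impairment process ``s(t)`` (stationary Ornstein-Uhlenbeck,
correlation time ~7 s to match the observed timescale of Parkinsonian
motor fluctuations) drives both halves of a session through separate
noise streams:

* behavior — a smooth Lissajous-mixture target is pursued by a cursor
  whose lag, speed (bradykinesia), heading noise and 4-8 Hz tremor
  amplitude all scale with the rectified latent; control subjects run the
  identical pursuit dynamics with the impairment drive clamped to zero;
* LFP — six canonical-band noise carriers whose instantaneous amplitudes
  are linearly coupled (positively or negatively, per the coupling vector
  ``w_true``) to the standardized latent, on a 1/f background with 60 Hz
  line contamination.

Because behavior and LFP share only the latent, any behavior-from-LFP
decoding measured downstream reflects recovery of that latent state, not
leakage of the cursor signal itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from stnmes.behavior import Trace
from stnmes.spectral import CANONICAL_BANDS, LFPRecording

def _ou_process(
    rng: np.random.Generator, n: int, fs: float, tau: float, sd: float = 1.0
) -> np.ndarray:
    """Stationary AR(1) (discretized Ornstein-Uhlenbeck) sample path."""
    a = np.exp(-1.0 / (fs * tau))
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), n)
    x0 = rng.normal(0.0, sd)
    return signal.lfilter([1.0], [1.0, -a], innov, zi=[a * x0])[0]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic session.

    Screen units live on a +/-10 unit display.  Couplings: ``w_true[b]``
    is the fractional amplitude modulation of canonical band ``b`` per
    standard deviation of the latent; the default signs (+ theta/alpha,
    + beta, - vhf) mirror the empirically observed direction of
    band-power/impairment correlations.
    """

    duration: float = 600.0  # s
    behavior_fs: float = 1000.0  # Hz
    lfp_fs: float = 4000.0  # Hz, pre-decimation
    display_halfwidth: float = 10.0  # screen units

    # latent impairment process
    tau: float = 7.0  # s, correlation time
    latent_sd: float = 0.4

    # behavioral couplings (all scale the softplus-rectified latent)
    base_lag: float = 0.12  # s, visuomotor delay
    lag_gain: float = 1.8  # extra lag per unit drive
    brady_gain: float = 1.4  # speed scale exp(-brady_gain * drive)
    tremor_gain: float = 1.1  # screen units of tremor per unit drive
    tremor_freq_range: tuple[float, float] = (4.0, 8.0)
    heading_noise_gain: float = 1.1  # rad sd per unit drive
    pursuit_gain: float = 8.0  # 1/s, visuomotor feedback gain
    control_rate: float = 100.0  # Hz of the pursuit update loop
    cursor_noise_sd: float = 0.12  # screen units, both groups

    # LFP couplings
    w_true: tuple[float, ...] = (0.5, 0.5, 0.0, 0.0, 0.0, -0.5)
    one_over_f_exponent: float = 1.5
    line_amp: float = 2.0  # 60 Hz amplitude relative to background sd
    band_snr: float = 2.0  # band-carrier RMS over in-band background RMS
    band_noise_gain: float = 0.35  # log-amplitude sd of per-band fluctuations
    band_noise_tau: float = 5.0  # s, correlation time of per-band fluctuations
    global_noise_gain: float = 0.6  # log-amplitude sd of the common gain drift
    global_noise_tau: float = 7.0  # s, correlation time of the gain drift

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("latent correlation time must be positive")
        if len(self.w_true) != len(CANONICAL_BANDS):
            raise ValueError("w_true must have one gain per canonical band")


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def impairment_drive(s: np.ndarray) -> np.ndarray:
    """Rectified latent driving all behavioral impairment channels.

    Softplus keeps the drive strictly positive (impairment severity cannot
    be negative) while remaining smooth and monotone in the latent — a
    kink-free rectifier matters because the Motor Error Score inherits any
    nonlinearity of the latent-to-behavior map, and downstream
    coefficient-recovery analyses assume that map is close to linear over
    the latent's typical range.
    """
    return softplus(s)


def latent_impairment(
    config: GeneratorConfig, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the latent impairment process on the behavior grid.

    Stationary AR(1) (discretized Ornstein-Uhlenbeck) with correlation
    time ``tau`` and the configured stationary standard deviation.
    """
    if config.duration < 10 * config.tau:
        warnings.warn("duration < 10 tau; latent statistics will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = int(round(config.duration * config.behavior_fs))
    s = _ou_process(rng, n, config.behavior_fs, config.tau, sd=config.latent_sd)
    t = np.arange(n) / config.behavior_fs
    return t, s


def _target_path(config: GeneratorConfig, t: np.ndarray, rng: np.random.Generator):
    """Smooth closed Lissajous mixture covering most of the display."""
    a = 0.62 * config.display_halfwidth
    b = 0.15 * config.display_halfwidth
    f1, f2 = 0.10, 0.17
    f3, f4 = 0.31, 0.23
    p = rng.uniform(0, 2 * np.pi, 4)
    x = a * np.sin(2 * np.pi * f1 * t + p[0]) + b * np.sin(2 * np.pi * f3 * t + p[1])
    y = a * np.sin(2 * np.pi * f2 * t + p[2]) + b * np.sin(2 * np.pi * f4 * t + p[3])
    return x, y


def _lowpass_noise(rng, n, fs, sd, cutoff=15.0):
    sos = signal.butter(4, cutoff, fs=fs, output="sos")
    w = signal.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
    return sd * w / w.std(ddof=0)


def simulate_behavior(
    config: GeneratorConfig,
    s: np.ndarray,
    group: str = "PD",
    seed: int = 0,
) -> tuple[Trace, Trace]:
    """Simulate one session's (target, cursor) traces.

    The cursor pursues the lagged target through a first-order visuomotor
    feedback loop updated at ``control_rate``.  For the PD group the lag
    grows, the pursuit speed shrinks (``exp(-brady_gain * drive)``), the
    heading acquires directional noise, and 4-8 Hz tremor rides on top —
    every channel scaled smoothly by the softplus-rectified latent, so a
    patient carries a positive baseline impairment that waxes and wanes
    with the latent state.  Controls run the same loop with the drive
    clamped at zero, which reduces to a smoothed, delayed copy of the
    target plus low-amplitude positional noise.
    """
    if group not in ("PD", "control"):
        raise ValueError("group must be 'PD' or 'control'")
    rng = np.random.default_rng(seed)
    fs = config.behavior_fs
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    if s.size != n:
        raise ValueError("latent series must live on the behavior grid")

    tx, ty = _target_path(config, t, rng)

    # pursuit loop on the coarser control grid
    dtc = 1.0 / config.control_rate
    nc = int(round(config.duration * config.control_rate))
    tc = np.arange(nc) * dtc
    p = impairment_drive(np.interp(tc, t, s)) if group == "PD" else np.zeros(nc)

    lag = np.clip(config.base_lag * (1.0 + config.lag_gain * p), 0.02, 1.0)
    dx = np.interp(np.clip(tc - lag, 0.0, t[-1]), t, tx)
    dy = np.interp(np.clip(tc - lag, 0.0, t[-1]), t, ty)
    alpha = np.clip(config.pursuit_gain * np.exp(-config.brady_gain * p) * dtc, 0.0, 1.0)
    theta = rng.normal(0.0, 1.0, nc) * config.heading_noise_gain * p
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    cx = np.empty(nc)
    cy = np.empty(nc)
    cx[0], cy[0] = dx[0], dy[0]
    for i in range(1, nc):
        ex = dx[i] - cx[i - 1]
        ey = dy[i] - cy[i - 1]
        ex, ey = cos_t[i] * ex - sin_t[i] * ey, sin_t[i] * ex + cos_t[i] * ey
        cx[i] = cx[i - 1] + alpha[i] * ex
        cy[i] = cy[i - 1] + alpha[i] * ey

    ux = np.interp(t, tc, cx)
    uy = np.interp(t, tc, cy)

    if group == "PD":
        amp = config.tremor_gain * impairment_drive(s)
        f_tr = rng.uniform(*config.tremor_freq_range)
        ph = rng.uniform(0, 2 * np.pi, 2)
        ux = ux + amp * np.sin(2 * np.pi * f_tr * t + ph[0])
        uy = uy + amp * np.sin(2 * np.pi * f_tr * t + ph[1])

    ux = ux + _lowpass_noise(rng, n, fs, config.cursor_noise_sd)
    uy = uy + _lowpass_noise(rng, n, fs, config.cursor_noise_sd)

    target = Trace(t=t, x=tx, y=ty, fs=fs, role="target")
    cursor = Trace(t=t, x=ux, y=uy, fs=fs, role="cursor")
    return target, cursor


def simulate_lfp(
    config: GeneratorConfig,
    s: np.ndarray,
    seed: int = 0,
    subject_id: str = "",
) -> LFPRecording:
    """Simulate a raw LFP whose band powers track the latent state.

    Signal = sum over canonical bands of band-limited Gaussian noise with
    instantaneous amplitude ``a_b * max(1 + w_true[b] * s_hat, 0)`` (s_hat
    the standardized latent), plus a 1/f^chi background and 60 Hz line
    contamination with harmonics.  Carrier amplitudes ``a_b`` are set to
    ``band_snr`` times the background's in-band RMS, so the coupled
    component dominates its own band without erasing the 1/f backdrop.

    Two lognormal amplitude fluctuations ride on top of the coupling, as
    in real recordings: a slow per-band fluctuation (independent across
    bands — endogenous power bursts unrelated to behavior) and a slower
    gain drift common to the whole spectrum (electrode impedance /
    arousal).  The first caps how well any single band can track the
    latent; the second can only be removed by contrasting bands, which is
    what gives multi-spectral decoding its edge over single-band decoding.
    """
    rng = np.random.default_rng(seed)
    fs = config.lfp_fs
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    t_beh = np.arange(s.size) / config.behavior_fs
    s_hat = (s - s.mean()) / s.std(ddof=0)
    s_lfp = np.interp(t, t_beh, s_hat)

    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    chi = config.one_over_f_exponent
    shape = np.zeros_like(freqs)
    nz = freqs >= 1.0
    shape[nz] = freqs[nz] ** (-chi / 2.0)
    coef = shape * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    background = np.fft.irfft(coef, n)
    bg_fft = np.fft.rfft(background)
    bg_std = background.std(ddof=0)
    background = background / bg_std

    def in_band_rms(lo: float, hi: float) -> float:
        """RMS of the (unit-variance) background within [lo, hi), by Parseval."""
        sel = (freqs >= lo) & (freqs < hi)
        return float(np.sqrt(2.0 * np.sum(np.abs(bg_fft[sel]) ** 2) / n**2) / bg_std)

    nu_b = config.band_noise_gain
    nu_g = config.global_noise_gain
    v = background.copy()
    for (name, lo, hi), w_b in zip(CANONICAL_BANDS, config.w_true):
        white = np.fft.rfft(rng.normal(size=n))
        sel = (freqs >= lo) & (freqs < hi)
        carrier = np.fft.irfft(np.where(sel, white, 0.0), n)
        carrier = carrier / carrier.std(ddof=0)
        mod = 1.0 + w_b * s_lfp
        clip_frac = float(np.mean(mod < 0.0))
        if clip_frac > 0.05:
            warnings.warn(
                f"band {name}: {clip_frac:.0%} of samples amplitude-clipped; "
                "the coupling is distorted",
                stacklevel=2,
            )
        # endogenous slow power fluctuation of this band, independent of
        # the latent (lognormal so it never clips)
        eta_b = _ou_process(rng, n, fs, config.band_noise_tau)
        endo = np.exp(nu_b * eta_b - 0.5 * nu_b**2)
        amp = config.band_snr * in_band_rms(lo, hi)
        v = v + amp * np.maximum(mod, 0.0) * endo * carrier

    # common multiplicative gain drift (electrode/arousal), shared by the
    # background and every band but not by line interference
    eta_g = _ou_process(rng, n, fs, config.global_noise_tau)
    v = v * np.exp(nu_g * eta_g - 0.5 * nu_g**2)

    ph = rng.uniform(0, 2 * np.pi, 5)
    v = v + config.line_amp * np.sin(2 * np.pi * 60.0 * t + ph[0])
    for h in range(2, 6):
        f0 = 60.0 * h
        if f0 < fs / 2:
            v = v + 0.3 * config.line_amp * np.sin(2 * np.pi * f0 * t + ph[h - 1])

    return LFPRecording(v=v, fs=fs, subject_id=subject_id)


@dataclass
class Session:
    """One synthetic subject-session with its ground truth."""

    subject_id: str
    group: str
    config: GeneratorConfig
    t: np.ndarray
    s: np.ndarray  # latent impairment on the behavior grid
    target: Trace
    cursor: Trace
    lfp: LFPRecording | None
    w_true: np.ndarray
    seed: int
    extra: dict = field(default_factory=dict)

    def epoch_latent(self, epoch_len: float) -> np.ndarray:
        """Per-epoch mean latent state on the shared epoch grid."""
        per = int(round(epoch_len * self.config.behavior_fs))
        n_epochs = self.s.size // per
        return self.s[: n_epochs * per].reshape(n_epochs, per).mean(axis=1)


def simulate_session(
    config: GeneratorConfig,
    group: str = "PD",
    seed: int = 0,
    subject_id: str = "",
    with_lfp: bool = True,
) -> Session:
    """Generate one full session (latent + behavior + optionally LFP)."""
    child = np.random.SeedSequence(seed).generate_state(3)
    _, s = latent_impairment(config, seed=int(child[0]))
    target, cursor = simulate_behavior(config, s, group=group, seed=int(child[1]))
    lfp = None
    if with_lfp:
        lfp = simulate_lfp(config, s, seed=int(child[2]), subject_id=subject_id)
    return Session(
        subject_id=subject_id,
        group=group,
        config=config,
        t=target.t,
        s=s,
        target=target,
        cursor=cursor,
        lfp=lfp,
        w_true=np.asarray(config.w_true, dtype=float),
        seed=seed,
    )


def simulate_cohort(
    n_subjects: int,
    heterogeneity: str = "mixed",
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> tuple[list[Session], Session]:
    """Generate a PD cohort plus one shared control session.

    ``heterogeneity``: ``"shared"`` gives every subject the configured
    ``w_true``; ``"orthogonal"`` gives each subject a single-band coupling
    on a distinct canonical band (pairwise-orthogonal vectors, n <= 6);
    ``"mixed"`` draws per-subject vectors around the configured mean.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    config = config or GeneratorConfig()
    n_bands = len(CANONICAL_BANDS)
    if heterogeneity == "orthogonal" and n_subjects > n_bands:
        raise ValueError(f"orthogonal couplings support at most {n_bands} subjects")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_subjects + 1)
    rng = np.random.default_rng(seeds[-1])

    sessions = []
    for i in range(n_subjects):
        if heterogeneity == "shared":
            w = tuple(config.w_true)
        elif heterogeneity == "orthogonal":
            w = tuple(0.7 if b == i else 0.0 for b in range(n_bands))
        elif heterogeneity == "mixed":
            w = tuple(np.asarray(config.w_true) + rng.normal(0.0, 0.15, n_bands))
        else:
            raise ValueError(f"unknown heterogeneity {heterogeneity!r}")
        cfg_i = replace(config, w_true=w)
        sessions.append(
            simulate_session(cfg_i, group="PD", seed=int(seeds[i]), subject_id=f"S{i:02d}")
        )
    control = simulate_session(
        config, group="control", seed=int(seeds[-1]), subject_id="CTRL", with_lfp=False
    )
    return sessions, control
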