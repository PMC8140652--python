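"""STN LFP preprocessing and Hilbert filter-bank band-power features.

Raw microelectrode voltage is notch-filtered at 60 Hz and its first four
harmonics, z-scored, artifact-masked above four standard deviations,
band-passed 3-400 Hz and decimated to 1 kHz.  Spectral power is then
estimated by FFT convolution with a bank of 2 Hz-wide linear-phase FIR
filters centered at every integer frequency from 4 to 400 Hz; per-sample
power is the squared magnitude of each band's analytic signal.  Powers are
averaged within epochs and within 42 sub-bands — six canonical bands
(theta/alpha 4-12, beta 12-30, low/mid/high gamma 30-60/60-100/100-200,
vhf 200-400 Hz), each tiled by seven geometrically spaced sub-bands —
log-transformed and z-scored per column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import signal

from stnmes._dsp import odd

#: Canonical frequency bands (name, lo, hi) in Hz.
CANONICAL_BANDS = (
    ("theta_alpha", 4.0, 12.0),
    ("beta", 12.0, 30.0),
    ("gamma_low", 30.0, 60.0),
    ("gamma_mid", 60.0, 100.0),
    ("gamma_high", 100.0, 200.0),
    ("vhf", 200.0, 400.0),
)

DEFAULT_CENTERS = np.arange(4, 401)  # 1 Hz-spaced filter centers, inclusive


@dataclass
class LFPRecording:
    """A single-channel LFP voltage series with artifact bookkeeping."""

    v: np.ndarray
    fs: float
    mask: np.ndarray | None = None  # True where the sample is an artifact
    subject_id: str = ""
    session_id: str = ""
    electrode_id: str = ""
    flagged: bool = False

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.v.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.size != self.v.size:
                raise ValueError("artifact mask length must match the signal")

    def __len__(self) -> int:
        return self.v.size

    @property
    def duration(self) -> float:
        return self.v.size / self.fs


@dataclass(frozen=True)
class BandScheme:
    """Sub-band tiling of the canonical bands.

    ``sub_edges[name]`` holds the ``n_sub + 1`` edges exactly tiling
    ``[lo, hi)`` of that canonical band; sub-band widths grow with
    frequency under the default geometric spacing.
    """

    bands: tuple[tuple[str, float, float], ...]
    n_sub: int
    spacing: str
    sub_edges: dict[str, np.ndarray]

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    @property
    def n_features(self) -> int:
        return len(self.bands) * self.n_sub

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(
            f"{name}_{k}" for name, _, _ in self.bands for k in range(self.n_sub)
        )

    def feature_bounds(self) -> list[tuple[str, int, float, float]]:
        """(band, sub index, lo, hi) per feature, in column order."""
        out = []
        for name, _, _ in self.bands:
            e = self.sub_edges[name]
            for k in range(self.n_sub):
                out.append((name, k, float(e[k]), float(e[k + 1])))
        return out

    def assign_centers(self, centers: np.ndarray) -> list[np.ndarray]:
        """Boolean center mask per feature; half-open [lo, hi), with the
        overall upper edge made inclusive so the top center is not orphaned."""
        top = max(hi for _, _, hi in self.bands)
        masks = []
        for _, _, lo, hi in self.feature_bounds():
            m = (centers >= lo) & (centers < hi)
            if hi == top:
                m |= centers == top
            masks.append(m)
        return masks

    def band_columns(self, name: str) -> list[str]:
        if name not in self.band_names:
            raise ValueError(f"unknown canonical band {name!r}")
        return [f"{name}_{k}" for k in range(self.n_sub)]


def build_band_scheme(
    n_sub: int = 7,
    spacing: str = "geometric",
    bands: tuple[tuple[str, float, float], ...] = CANONICAL_BANDS,
) -> BandScheme:
    """Construct the canonical 6-band x 7-sub-band (42 feature) scheme.

    Geometric spacing puts edge ``k`` of band ``[a, b)`` at
    ``a * (b/a)**(k / n_sub)`` so sub-band width scales with frequency;
    ``spacing="linear"`` tiles each band uniformly instead.
    """
    sub_edges = {}
    for name, lo, hi in bands:
        if spacing == "geometric":
            edges = lo * (hi / lo) ** (np.arange(n_sub + 1) / n_sub)
        elif spacing == "linear":
            edges = np.linspace(lo, hi, n_sub + 1)
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        edges[0], edges[-1] = lo, hi  # exact tiling at band edges
        sub_edges[name] = edges
    return BandScheme(bands=tuple(bands), n_sub=n_sub, spacing=spacing, sub_edges=sub_edges)


def preprocess_lfp(
    raw: LFPRecording,
    target_fs: float = 1000.0,
    line_freq: float = 60.0,
    n_line_harmonics: int = 5,
    artifact_sd: float = 4.0,
    band: tuple[float, float] = (3.0, 400.0),
    notch_q: float = 30.0,
    mask_warn_frac: float = 0.2,
) -> LFPRecording:
    """Clean and decimate a raw recording to the 1 kHz analysis rate.

    Processing order: (1) notch at the line frequency and its first four
    harmonics; (2) global z-score; (3) samples beyond ``artifact_sd``
    standard deviations masked and linearly interpolated (the mask is
    kept); (4) zero-phase 3-400 Hz band-pass; (5) decimation to
    ``target_fs`` with logical-OR pooling of the artifact mask.
    """
    if raw.fs < 2 * band[1]:
        raise ValueError("sample rate too low to realize the 3-400 Hz band-pass")
    q = raw.fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError("fs must be an integer multiple of the target rate")
    q = int(round(q))

    v = raw.v.astype(float)
    for k in range(1, n_line_harmonics + 1):
        f0 = line_freq * k
        if f0 >= raw.fs / 2:
            break
        b, a = signal.iirnotch(f0, Q=notch_q, fs=raw.fs)
        v = signal.filtfilt(b, a, v)

    v = (v - v.mean()) / v.std(ddof=0)
    mask = raw.mask | (np.abs(v) > artifact_sd)
    flagged = raw.flagged
    if mask.mean() > mask_warn_frac:
        warnings.warn(
            f"{mask.mean():.0%} of samples masked as artifact; recording flagged",
            stacklevel=2,
        )
        flagged = True
    if mask.any() and not mask.all():
        idx = np.arange(v.size)
        v = v.copy()
        v[mask] = np.interp(idx[mask], idx[~mask], v[~mask])

    sos = signal.butter(4, band, btype="bandpass", fs=raw.fs, output="sos")
    v = signal.sosfiltfilt(sos, v)

    if q > 1:
        v = signal.resample_poly(v, up=1, down=q)
        n_full = (mask.size // q) * q
        mask_ds = mask[:n_full].reshape(-1, q).any(axis=1)
        if mask.size % q:  # trailing partial block
            mask_ds = np.r_[mask_ds, mask[n_full:].any()]
        mask_ds = mask_ds[: v.size]
        if mask_ds.size < v.size:
            mask_ds = np.r_[mask_ds, np.zeros(v.size - mask_ds.size, bool)]
    else:
        mask_ds = mask
    return replace(raw, v=v, fs=target_fs, mask=mask_ds, flagged=flagged)


class _FilterBank:
    """FFT-convolution machinery shared by all integer-Hz centers.

    All centers use the same 2 Hz-wide prototype: a Hamming-windowed-sinc
    low-pass of half the bandwidth, modulated to each center frequency.
    The zero-phase frequency response of the modulated FIR is therefore the
    low-pass response shifted to +/- f, which lets one low-pass response
    (computed once on the padded FFT grid) serve every center by integer
    bin shifts.  The per-center analytic signal comes from zeroing negative
    frequencies before the inverse FFT.
    """

    def __init__(
        self,
        n: int,
        fs: float,
        bandwidth: float = 2.0,
        taps_seconds: float = 3.0,
    ) -> None:
        if fs != int(fs):
            raise ValueError("filter bank requires an integer sample rate")
        fs = int(fs)
        numtaps = odd(int(taps_seconds * fs))
        if numtaps > n:
            raise ValueError(
                f"recording of {n} samples is shorter than the "
                f"{numtaps}-tap analysis filter"
            )
        m = sfft.next_fast_len(int(np.ceil((n + numtaps) / fs)))
        self.n, self.fs, self.L = n, fs, m * fs
        self.bins_per_hz = m
        taps = signal.firwin(numtaps, bandwidth / 2.0, fs=fs)
        taps = taps / taps.sum()
        h = np.zeros(self.L)
        h[:numtaps] = taps
        h = np.roll(h, -(numtaps // 2))  # center at index 0 -> zero phase
        self.h_lp = sfft.fft(h).real
        self._x_fft: np.ndarray | None = None

    def load(self, x: np.ndarray) -> None:
        xp = np.zeros(self.L)
        xp[: self.n] = x
        self._x_fft = sfft.fft(xp)

    def analytic(self, center: float) -> np.ndarray:
        """Analytic signal of the 2 Hz band at ``center`` (integer Hz)."""
        if self._x_fft is None:
            raise RuntimeError("call load() first")
        shift = int(round(center * self.bins_per_hz))
        if shift != center * self.bins_per_hz:
            raise ValueError("centers must be integer Hz")
        h_bp = np.roll(self.h_lp, shift) + np.roll(self.h_lp, -shift)
        half = self.L // 2
        spec = np.zeros(self.L, dtype=complex)
        spec[1:half] = 2.0 * self._x_fft[1:half] * h_bp[1:half]
        spec[0] = self._x_fft[0] * h_bp[0]
        spec[half] = self._x_fft[half] * h_bp[half]
        return sfft.ifft(spec)[: self.n]

    def power(self, center: float) -> np.ndarray:
        """Per-sample band power: squared analytic-signal magnitude."""
        a = self.analytic(center)
        return a.real**2 + a.imag**2


def spectral_power(
    clean: LFPRecording,
    centers: np.ndarray = DEFAULT_CENTERS,
    bandwidth: float = 2.0,
    taps_seconds: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample power at 1 Hz-spaced centers; (centers, power matrix).

    The returned matrix is centers x samples and non-negative.  Memory
    grows with both axes; for long recordings use
    :func:`epoch_spectral_features`, which streams over centers.
    """
    centers = np.asarray(centers, dtype=float)
    bank = _FilterBank(len(clean), clean.fs, bandwidth, taps_seconds)
    bank.load(clean.v)
    out = np.empty((centers.size, len(clean)))
    for i, f in enumerate(centers):
        out[i] = bank.power(f)
    return centers, out


@dataclass
class SpectralFeatures:
    """Epoch x sub-band normalized log-power features."""

    times: np.ndarray  # (n_epochs, 2) start/end seconds
    values: pd.DataFrame  # columns = scheme.feature_names
    scheme: BandScheme
    epoch_len: float
    norm_mean: np.ndarray = field(default=None)
    norm_sd: np.ndarray = field(default=None)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def valid(self) -> np.ndarray:
        return ~self.values.isna().any(axis=1).to_numpy()

    def band_power(self, name: str) -> np.ndarray:
        """Canonical-band series: mean of the band's sub-band features."""
        return self.values[self.scheme.band_columns(name)].mean(axis=1).to_numpy()


def _center_epoch_means(
    clean: LFPRecording,
    centers: np.ndarray,
    epoch_lens: list[float],
    bandwidth: float,
    taps_seconds: float,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Epoch-mean power per center for several epoch grids in one pass.

    Returns per epoch length: the epoch edge array, a centers x epochs
    matrix of mean power over valid (unmasked) samples, and the per-epoch
    valid-sample count.
    """
    n = len(clean)
    valid = ~clean.mask
    t_idx = np.arange(n)
    edges_list, mats, counts_list = [], [], []
    idx_per_len, nep_per_len = [], []
    for el in epoch_lens:
        samples_per = el * clean.fs
        n_epochs = int(np.floor(n / samples_per + 1e-9))
        if n_epochs < 1:
            raise ValueError(f"recording too short for {el} s epochs")
        starts = el * np.arange(n_epochs)
        edges_list.append(np.column_stack([starts, starts + el]))
        idx = np.floor(t_idx / samples_per + 1e-9).astype(int)
        ok = valid & (idx < n_epochs)
        counts = np.bincount(idx[ok], minlength=n_epochs)
        idx_per_len.append((idx, ok))
        nep_per_len.append(n_epochs)
        counts_list.append(counts)
        mats.append(np.empty((centers.size, n_epochs)))

    bank = _FilterBank(n, clean.fs, bandwidth, taps_seconds)
    bank.load(clean.v)
    for i, f in enumerate(centers):
        p = bank.power(f)
        for j, (idx, ok) in enumerate(idx_per_len):
            sums = np.bincount(idx[ok], weights=p[ok], minlength=nep_per_len[j])
            with np.errstate(invalid="ignore", divide="ignore"):
                mats[j][i] = sums / counts_list[j]
    return edges_list, mats, counts_list


def _features_from_center_means(
    edges: np.ndarray,
    center_means: np.ndarray,
    counts: np.ndarray,
    centers: np.ndarray,
    scheme: BandScheme,
    epoch_len: float,
    normalize: bool,
) -> SpectralFeatures:
    masks = scheme.assign_centers(centers)
    n_epochs = center_means.shape[1]
    vals = np.empty((n_epochs, scheme.n_features))
    for j, m in enumerate(masks):
        if not m.any():
            raise ValueError("a sub-band contains no filter centers")
        vals[:, j] = center_means[m].mean(axis=0)
    vals = np.log(np.maximum(vals, 1e-300))
    vals[counts == 0, :] = np.nan  # fully masked epochs drop downstream
    ok = counts > 0
    if normalize:
        mean = np.nanmean(vals[ok], axis=0)
        sd = np.nanstd(vals[ok], axis=0, ddof=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        vals = (vals - mean) / sd
    else:
        mean = np.zeros(scheme.n_features)
        sd = np.ones(scheme.n_features)
    df = pd.DataFrame(vals, columns=list(scheme.feature_names))
    return SpectralFeatures(
        times=edges,
        values=df,
        scheme=scheme,
        epoch_len=epoch_len,
        norm_mean=mean,
        norm_sd=sd,
    )


def epoch_spectral_features(
    clean: LFPRecording,
    epoch_len: float,
    scheme: BandScheme | None = None,
    centers: np.ndarray = DEFAULT_CENTERS,
    bandwidth: float = 2.0,
    taps_seconds: float = 3.0,
    normalize: bool = True,
) -> SpectralFeatures:
    """Epoch-averaged, log-transformed, per-column z-scored band features.

    Per epoch and sub-band the power is averaged over unmasked samples and
    over the integer-Hz centers falling in the sub-band, then logged; each
    column is z-scored over epochs with the normalization parameters
    stored.  Fully artifact-masked epochs are NaN rows.
    """
    scheme = scheme or build_band_scheme()
    centers = np.asarray(centers, dtype=float)
    edges_list, mats, counts_list = _center_epoch_means(
        clean, centers, [epoch_len], bandwidth, taps_seconds
    )
    return _features_from_center_means(
        edges_list[0], mats[0], counts_list[0], centers, scheme, epoch_len, normalize
    )


def multi_epoch_spectral_features(
    clean: LFPRecording,
    epoch_lens: list[float],
    scheme: BandScheme | None = None,
    centers: np.ndarray = DEFAULT_CENTERS,
    bandwidth: float = 2.0,
    taps_seconds: float = 3.0,
    normalize: bool = True,
) -> dict[float, SpectralFeatures]:
    """Features for several epoch lengths sharing one filter-bank pass."""
    scheme = scheme or build_band_scheme()
    centers = np.asarray(centers, dtype=float)
    edges_list, mats, counts_list = _center_epoch_means(
        clean, centers, list(epoch_lens), bandwidth, taps_seconds
    )
    return {
        el: _features_from_center_means(
            edges_list[j], mats[j], counts_list[j], centers, scheme, el, normalize
        )
        for j, el in enumerate(epoch_lens)
    }


def minmax_log_scale(power: np.ndarray) -> np.ndarray:
    """Visualization scaling: log power min-max mapped to [0, 1] exactly."""
    lp = np.log(np.maximum(np.asarray(power, dtype=float), 1e-300))
    lo, hi = lp.min(), lp.max()
    if hi == lo:
        return np.zeros_like(lp)
    return (lp - lo) / (hi - lo)
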