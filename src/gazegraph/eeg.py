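"""Multichannel EEG segmentation and per-segment feature extraction.

Seven node features are computed per 4 s segment: channel-averaged mean
amplitude, STFT spectral entropy, mean pairwise Pearson correlation
(functional-connectivity synchronization), approximate entropy, sample
entropy, normalized permutation entropy and wavelet entropy.  Per-channel
quantities are reduced to one scalar per segment by averaging (median
selectable) because a feature-graph node carries a single attribute.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import pywt
from scipy.signal import butter, get_window, sosfiltfilt

__all__ = [
    "EEGRecording",
    "EEGSegment",
    "EEGFeatureSet",
    "EEGFeatureConfig",
    "EEG_FEATURE_NAMES",
    "segment_recording",
    "approximate_entropy",
    "sample_entropy",
    "permutation_entropy",
    "wavelet_entropy",
    "spectral_entropy_from_power",
    "stft_spectral_entropy",
    "pcc_synchronization",
    "extract_eeg_features",
    "bandpass_filter",
]

#: Fixed node ordering of the EEG block of the feature graph.
EEG_FEATURE_NAMES = (
    "mean_value",
    "stft_entropy",
    "pcc_sync",
    "appr_en",
    "samp_en",
    "perm_en",
    "wavelet_en",
)

DEFAULT_CHANNELS = ("F3", "F4", "T3", "C3", "C4", "T4", "O1", "O2")


@dataclass
class EEGRecording:
    """A channels x samples recording in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
    rate_hz : float
        Sampling frequency.
    channel_names : tuple of str
    """

    data: np.ndarray
    rate_hz: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be a 2-D channels x samples matrix")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.rate_hz


@dataclass
class EEGSegment:
    """One fixed-length window cut from a recording."""

    data: np.ndarray
    index: int
    rate_hz: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.index < 0:
            raise ValueError("segment index must be >= 0")


@dataclass
class EEGFeatureSet:
    """The seven EEG node attributes of one segment, in fixed order."""

    mean_value: float
    stft_entropy: float
    pcc_sync: float
    appr_en: float
    samp_en: float
    perm_en: float
    wavelet_en: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in EEG_FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in EEG_FEATURE_NAMES}


@dataclass
class EEGFeatureConfig:
    """Tunable parameters of the EEG feature extractors.

    Defaults follow common practice for short biosignal windows: embedding
    dimension m=2 with tolerance r = 0.2 x SD for ApEn/SampEn, ordinal
    patterns of order 3 at lag 1, a 5-level db4 wavelet decomposition, and
    1 s Hann windows hopped by 0.5 s for the STFT.
    """

    m: int = 2
    r_factor: float = 0.2
    perm_order: int = 3
    perm_delay: int = 1
    wavelet: str = "db4"
    wavelet_levels: int = 5
    stft_win_s: float = 1.0
    stft_hop_s: float = 0.5
    reduction: Literal["mean", "median"] = "mean"
    #: Cap used when SampEn template counts degenerate (A=0 or B=0); see
    #: :func:`sample_entropy`.
    sampen_cap: float | None = None


# ---------------------------------------------------------------------------
# segmentation


def segment_recording(
    rec: EEGRecording, window_s: float = 4.0, overlap_s: float = 0.0
) -> list[EEGSegment]:
    """Cut a recording into fixed-length windows starting at time 0.

    The trailing partial window is discarded.  A recording shorter than one
    window yields an empty list with a warning rather than an error, so
    batch jobs over heterogeneous recordings do not abort.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0 <= overlap_s < window_s:
        raise ValueError("overlap_s must satisfy 0 <= overlap_s < window_s")
    win = int(round(window_s * rec.rate_hz))
    hop = int(round((window_s - overlap_s) * rec.rate_hz))
    n = rec.data.shape[1]
    if n < win:
        warnings.warn(
            f"recording of {rec.duration_s:.2f}s shorter than one "
            f"{window_s}s window; no segments produced",
            stacklevel=2,
        )
        return []
    starts = range(0, n - win + 1, hop)
    return [
        EEGSegment(data=rec.data[:, s : s + win], index=i, rate_hz=rec.rate_hz)
        for i, s in enumerate(starts)
    ]


# ---------------------------------------------------------------------------
# entropy estimators

try:  # jitted O(n^2) template-count kernels; numpy fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _apen_phi_numpy(x: np.ndarray, m: int, r: float) -> float:
    n = x.shape[0]
    nt = n - m + 1
    templ = np.lib.stride_tricks.sliding_window_view(x, m)
    # Chebyshev distances between all template pairs
    d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
    c = (d <= r).sum(axis=1) / nt
    return float(np.mean(np.log(c)))


def _sampen_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    n = x.shape[0]
    nt = n - m  # templates compared for both m and m+1 (Richman-Moorman)
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
    dm = np.abs(tm[:, None, :] - tm[None, :, :]).max(axis=2)
    dm1 = np.abs(tm1[:, None, :] - tm1[None, :, :]).max(axis=2)
    iu = np.triu_indices(nt, k=1)
    b = int((dm[iu] <= r).sum())
    a = int((dm1[iu] <= r).sum())
    return b, a


if _HAVE_NUMBA:

    @njit(cache=True)
    def _entropy_profile_kernel(x, m, r):  # pragma: no cover
        """One O(n^2) pass -> (phi_m, phi_m1, B, A).

        phi_m / phi_m1 are the ApEn log-count averages over n-m+1 / n-m
        templates (self-matches included); B / A are the SampEn m / m+1
        pair counts over the first n-m templates (self-matches excluded).
        The (m+1)-template pair set of ApEn and SampEn coincide, so all
        four quantities share one pairwise Chebyshev sweep.
        """
        n = x.shape[0]
        nt = n - m + 1
        nt1 = n - m
        cntm = np.zeros(nt, dtype=np.int64)
        cntm1 = np.zeros(nt1, dtype=np.int64)
        b = 0
        a = 0
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                d = 0.0
                for k in range(m):
                    dd = abs(x[i + k] - x[j + k])
                    if dd > d:
                        d = dd
                if d <= r:
                    cntm[i] += 1
                    cntm[j] += 1
                    if j < nt1:
                        b += 1
                    if j < nt1:
                        dd = abs(x[i + m] - x[j + m])
                        if dd > d:
                            d = dd
                        if d <= r:
                            cntm1[i] += 1
                            cntm1[j] += 1
                            a += 1
        phi_m = 0.0
        for i in range(nt):
            phi_m += np.log((cntm[i] + 1) / nt)  # +1: self-match
        phi_m /= nt
        phi_m1 = 0.0
        for i in range(nt1):
            phi_m1 += np.log((cntm1[i] + 1) / nt1)
        phi_m1 /= nt1
        return phi_m, phi_m1, b, a

    def _entropy_profile(x, m, r):
        phi_m, phi_m1, b, a = _entropy_profile_kernel(x, m, r)
        return float(phi_m), float(phi_m1), int(b), int(a)

else:  # pragma: no cover

    def _entropy_profile(x, m, r):
        phi_m = _apen_phi_numpy(x, m, r)
        phi_m1 = _apen_phi_numpy(x, m + 1, r)
        b, a = _sampen_counts_numpy(x, m, r)
        return phi_m, phi_m1, b, a




def _resolve_tolerance(x: np.ndarray, r: float | None, r_factor: float) -> float:
    if r is not None:
        if r <= 0:
            raise ValueError("tolerance r must be positive")
        return float(r)
    return float(r_factor) * float(np.std(x))


def approximate_entropy(
    x: Sequence[float], m: int = 2, r: float | None = None, r_factor: float = 0.2
) -> float:
    """Approximate entropy ApEn(m, r) of a scalar series.

    ApEn = Phi^m(r) - Phi^{m+1}(r) where Phi^m is the average log fraction
    of templates of length m within Chebyshev distance r, self-matches
    included.  When ``r`` is None it defaults to ``r_factor * sd(x)``; a
    zero-variance series then has r = 0 and, because every template still
    matches itself (and all others exactly), ApEn is 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if x.shape[0] <= m + 1:
        raise ValueError(f"series of length {x.shape[0]} too short for m={m}")
    rr = _resolve_tolerance(x, r, r_factor)
    phi_m, phi_m1, _, _ = _entropy_profile(x, m, rr)
    return phi_m - phi_m1


def sample_entropy(
    x: Sequence[float],
    m: int = 2,
    r: float | None = None,
    r_factor: float = 0.2,
    cap: float | None = None,
) -> float:
    """Sample entropy SampEn(m, r) = -ln(A / B), self-matches excluded.

    B and A count m- and (m+1)-template pairs within Chebyshev tolerance r
    among the first N-m templates.  Degenerate counts are never returned as
    NaN: if B = 0 or A = 0 the documented sentinel ``cap`` is returned,
    defaulting to ln of the maximum possible pair count
    ``(N-m)(N-m-1)/2`` — the largest value -ln(A/B) could attain with one
    (m+1)-match.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    n = x.shape[0]
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    rr = _resolve_tolerance(x, r, r_factor)
    if rr == 0.0 and np.ptp(x) == 0.0:
        return 0.0  # constant series: all templates match exactly, A/B = 1
    _, _, b, a = _entropy_profile(x, m, rr)
    if cap is None:
        cap = math.log((n - m) * (n - m - 1) / 2)
    if b == 0 or a == 0:
        return float(cap)
    return float(-math.log(a / b))


def permutation_entropy(
    x: Sequence[float], order: int = 3, delay: int = 1
) -> float:
    """Normalized permutation entropy in [0, 1].

    Shannon entropy of the ordinal-pattern distribution divided by
    log(order!).  Ties within a window are broken by order of appearance
    (stable argsort), so equal values keep their temporal order.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if order < 2:
        raise ValueError("order must be >= 2")
    if delay < 1:
        raise ValueError("delay must be >= 1")
    n = x.shape[0]
    n_windows = n - (order - 1) * delay
    if n_windows < 1:
        raise ValueError(
            f"series of length {n} too short for order={order}, delay={delay}"
        )
    # windows[i] = x[i], x[i+delay], ..., x[i+(order-1)delay]
    idx = np.arange(n_windows)[:, None] + delay * np.arange(order)[None, :]
    windows = x[idx]
    ranks = np.argsort(windows, axis=1, kind="stable")
    # encode each pattern as an integer in base `order`
    codes = (ranks * order ** np.arange(order)[None, :]).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(math.factorial(order))


def wavelet_entropy(
    x: Sequence[float], wavelet: str = "db4", levels: int = 5
) -> float:
    """Shannon entropy (nats) of the relative wavelet-band energies.

    The series is decomposed with a periodized discrete wavelet transform
    into ``levels`` detail bands plus the final approximation; the entropy
    of the normalized band-energy distribution measures how evenly signal
    energy spreads across scales (0 for one active band, ln(levels+1) for
    a uniform spread).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if x.shape[0] < 2**levels:
        raise ValueError(
            f"series of length {x.shape[0]} too short for {levels}-level decomposition"
        )
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="periodization")
    energies = np.array([float(np.sum(c**2)) for c in coeffs])
    total = energies.sum()
    if total == 0:
        return 0.0
    p = energies / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# time-frequency and synchronization features


def _stft_power(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Magnitude-squared STFT over complete Hann-windowed frames.

    Only frames that fit entirely inside the segment are used (no padding),
    which keeps the distribution free of boundary artifacts and makes the
    computation exactly reproducible by a direct windowed DFT.
    """
    w = get_window("hann", win, fftbins=True)
    n = x.shape[0]
    starts = range(0, n - win + 1, hop)
    frames = np.stack([x[s : s + win] * w for s in starts])
    return np.abs(np.fft.rfft(frames, axis=1)) ** 2


def spectral_entropy_from_power(power: np.ndarray) -> float:
    """Shannon entropy (nats) of a non-negative power array, normalized
    to a probability distribution over its bins; 0 for zero total power."""
    power = np.asarray(power, dtype=float)
    if (power < 0).any():
        raise ValueError("power must be non-negative")
    total = power.sum()
    if total == 0:
        return 0.0
    p = (power / total).ravel()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def stft_spectral_entropy(
    seg: EEGSegment, win_s: float = 1.0, hop_s: float = 0.5
) -> float:
    """Shannon entropy of the normalized STFT power distribution.

    The magnitude-squared short-time Fourier transform of each channel is
    normalized to a probability distribution over all (time, frequency)
    bins; the per-channel entropies (nats) are averaged.  A zero-energy
    channel contributes 0 by convention.
    """
    if not 0 < hop_s <= win_s:
        raise ValueError("need 0 < hop_s <= win_s")
    win = int(round(win_s * seg.rate_hz))
    hop = int(round(hop_s * seg.rate_hz))
    if win > seg.data.shape[1]:
        raise ValueError("STFT window longer than segment")
    return float(
        np.mean([spectral_entropy_from_power(_stft_power(ch, win, hop)) for ch in seg.data])
    )


def pcc_synchronization(seg: EEGSegment) -> tuple[np.ndarray, float]:
    """Pairwise Pearson correlation between channels.

    Returns the symmetric channel x channel correlation matrix and the mean
    of its strict upper triangle — the scalar synchronization attribute of
    the feature-graph node.
    """
    data = seg.data
    if data.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    sds = data.std(axis=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"zero-variance channel(s) at index {bad.tolist()}")
    mat = np.corrcoef(data)
    iu = np.triu_indices(data.shape[0], k=1)
    return mat, float(mat[iu].mean())


# ---------------------------------------------------------------------------
# band-pass plumbing for real recordings


def bandpass_filter(
    rec: EEGRecording, low_hz: float = 0.5, high_hz: float = 45.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, for real recordings.

    Synthetic data is generated already in-band and bypasses this step.
    """
    if not 0 < low_hz < high_hz < rec.rate_hz / 2:
        raise ValueError("need 0 < low_hz < high_hz < Nyquist")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.rate_hz, output="sos")
    return EEGRecording(
        data=sosfiltfilt(sos, rec.data, axis=1),
        rate_hz=rec.rate_hz,
        channel_names=rec.channel_names,
    )


# ---------------------------------------------------------------------------
# per-segment feature vector


def extract_eeg_features(
    seg: EEGSegment, config: EEGFeatureConfig | None = None
) -> EEGFeatureSet:
    """Compute the seven EEG node features of one segment.

    Per-channel quantities (mean amplitude and the four entropies) are
    reduced across channels by the configured reduction (mean by default);
    STFT entropy is already channel-averaged and the synchronization value
    is the mean upper-triangle pairwise correlation.
    """
    cfg = config or EEGFeatureConfig()
    reduce = np.mean if cfg.reduction == "mean" else np.median

    def per_channel(fn):
        return float(reduce([fn(ch) for ch in seg.data]))

    def apen_sampen(ch: np.ndarray) -> tuple[float, float]:
        # one pairwise sweep serves both regularity statistics
        rr = cfg.r_factor * float(np.std(ch))
        n = ch.shape[0]
        if rr == 0.0 and np.ptp(ch) == 0.0:
            return 0.0, 0.0
        phi_m, phi_m1, b, a = _entropy_profile(np.asarray(ch, float), cfg.m, rr)
        cap = cfg.sampen_cap
        if cap is None:
            cap = math.log((n - cfg.m) * (n - cfg.m - 1) / 2)
        se = float(cap) if (b == 0 or a == 0) else -math.log(a / b)
        return phi_m - phi_m1, se

    both_entropies = [apen_sampen(ch) for ch in seg.data]
    _, sync = pcc_synchronization(seg)
    return EEGFeatureSet(
        mean_value=per_channel(np.mean),
        stft_entropy=stft_spectral_entropy(seg, cfg.stft_win_s, cfg.stft_hop_s),
        pcc_sync=sync,
        appr_en=float(reduce([ae for ae, _ in both_entropies])),
        samp_en=float(reduce([se for _, se in both_entropies])),
        perm_en=per_channel(
            lambda ch: permutation_entropy(ch, cfg.perm_order, cfg.perm_delay)
        ),
        wavelet_en=per_channel(
            lambda ch: wavelet_entropy(ch, cfg.wavelet, cfg.wavelet_levels)
        ),
    )
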