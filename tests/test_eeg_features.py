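"""EEG feature extractors against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazegraph as gg
from gazegraph.eeg import EEG_FEATURE_NAMES, EEGRecording, EEGSegment, _stft_power


def make_segment(data, rate_hz=256.0, index=0):
    return EEGSegment(data=np.atleast_2d(np.asarray(data, float)), index=index, rate_hz=rate_hz)


# ---------------------------------------------------------------------------
# segmentation


@pytest.mark.parametrize(
    "duration_s,window_s,expected",
    [(360.0, 4.0, 90), (8.0, 4.0, 2), (3.9, 4.0, 0)],
)
def test_segment_count_and_shape(duration_s, window_s, expected):
    """Non-overlapping 4 s windows; the trailing partial window is dropped."""
    n = int(duration_s * 256)
    rec = EEGRecording(
        data=np.zeros((8, n)) + np.arange(n), rate_hz=256.0,
    )
    if expected == 0:
        with pytest.warns(UserWarning):
            segs = gg.segment_recording(rec, window_s)
    else:
        segs = gg.segment_recording(rec, window_s)
    assert len(segs) == expected
    for i, s in enumerate(segs):
        assert s.data.shape == (8, int(window_s * 256))
        assert s.index == i
    # contiguity from time zero
    if expected:
        assert np.array_equal(segs[0].data[0], np.arange(int(window_s * 256)))


def test_segment_overlap_validation():
    rec = EEGRecording(data=np.zeros((2, 1024)), rate_hz=256.0, channel_names=("a", "b"))
    with pytest.raises(ValueError):
        gg.segment_recording(rec, 4.0, overlap_s=4.0)


# ---------------------------------------------------------------------------
# approximate / sample entropy vs double-loop oracles


def apen_oracle(x, m, r):
    """Direct Phi^m(r) - Phi^{m+1}(r), self-matches included."""

    def phi(mm):
        n = len(x)
        nt = n - mm + 1
        templates = [x[i : i + mm] for i in range(nt)]
        total = 0.0
        for ti in templates:
            c = sum(
                1 for tj in templates if max(abs(a - b) for a, b in zip(ti, tj)) <= r
            )
            total += math.log(c / nt)
        return total / nt

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m, r):
    """-ln(A/B) over the first n-m templates, self-matches excluded."""
    n = len(x)
    nt = n - m

    def count(mm):
        templates = [x[i : i + mm] for i in range(nt)]
        return sum(
            1
            for i in range(nt - 1)
            for j in range(i + 1, nt)
            if max(abs(a - b) for a, b in zip(templates[i], templates[j])) <= r
        )

    b, a = count(m), count(m + 1)
    return -math.log(a / b)


@pytest.mark.parametrize("seed,n", [(0, 100), (7, 50), (21, 120)])
def test_apen_matches_bruteforce(seed, n):
    x = np.random.default_rng(seed).uniform(size=n)
    r = 0.2 * float(np.std(x))
    assert gg.approximate_entropy(x, m=2, r=r) == pytest.approx(
        apen_oracle(list(x), 2, r), abs=1e-10
    )


@pytest.mark.parametrize("seed,n", [(1, 50), (5, 80), (13, 200)])
def test_sampen_matches_bruteforce(seed, n):
    x = np.random.default_rng(seed).uniform(size=n)
    r = 0.2 * float(np.std(x))
    assert gg.sample_entropy(x, m=2, r=r) == pytest.approx(
        sampen_oracle(list(x), 2, r), abs=1e-10
    )


def test_entropy_constant_series_is_zero():
    x = np.full(64, 3.7)
    assert gg.approximate_entropy(x) == pytest.approx(0.0, abs=1e-12)
    assert gg.sample_entropy(x) == pytest.approx(0.0, abs=1e-12)


def test_sampen_periodic_series_is_zero():
    """Strict periodicity: every m-match extends to an (m+1)-match, A/B = 1."""
    x = np.array([1.0, 2.0, 3.0] * 20)
    assert gg.sample_entropy(x, m=2, r=0.1) == pytest.approx(0.0, abs=1e-12)


def test_apen_noise_exceeds_sine():
    rng = np.random.default_rng(42)
    noise = rng.standard_normal(512)
    t = np.arange(512)
    sine = np.sin(2 * np.pi * 10 * t / 256)
    assert gg.approximate_entropy(noise) > gg.approximate_entropy(sine)


def test_sampen_degenerate_counts_return_cap():
    """No (m+1)-template matches -> the documented finite sentinel, not NaN."""
    x = np.array([0.0, 100.0, -50.0, 200.0, -130.0, 60.0, -10.0, 140.0])
    val = gg.sample_entropy(x, m=2, r=1e-9)
    n, m = len(x), 2
    assert val == pytest.approx(math.log((n - m) * (n - m - 1) / 2))
    assert np.isfinite(val)
    assert gg.sample_entropy(x, m=2, r=1e-9, cap=7.5) == 7.5


def test_apen_sampen_affine_invariance():
    """With relative tolerance r = 0.2 sd, x -> a x + b leaves both unchanged."""
    x = np.random.default_rng(9).standard_normal(150)
    y = 3.5 * x - 42.0
    assert gg.approximate_entropy(x) == pytest.approx(gg.approximate_entropy(y), abs=1e-10)
    assert gg.sample_entropy(x) == pytest.approx(gg.sample_entropy(y), abs=1e-10)


# ---------------------------------------------------------------------------
# permutation entropy


def test_perm_entropy_hand_example():
    """Six consecutive pairs of [4,7,9,10,6,11,3]: 4 rising, 2 falling."""
    x = [4, 7, 9, 10, 6, 11, 3]
    expected = -(4 / 6 * math.log2(4 / 6) + 2 / 6 * math.log2(2 / 6)) / math.log2(2)
    assert gg.permutation_entropy(x, order=2, delay=1) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.9183, abs=1e-4)


def test_perm_entropy_monotone_series_is_zero():
    assert gg.permutation_entropy(np.arange(50.0), order=3) == 0.0


def test_perm_entropy_uniform_patterns_is_one():
    """A series realizing both order-2 patterns equally often."""
    x = [0, 1, 0, 1, 0, 1, 0, 1, 0]
    assert gg.permutation_entropy(x, order=2) == pytest.approx(1.0, abs=1e-12)


def test_perm_entropy_tie_breaking_by_appearance():
    # all-equal windows collapse to the single "rising" pattern
    assert gg.permutation_entropy(np.ones(20), order=3) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=10, max_size=60), st.integers(2, 4))
def test_perm_entropy_bounded(xs, order):
    val = gg.permutation_entropy(xs, order=order)
    assert 0.0 <= val <= 1.0 + 1e-12


def test_perm_entropy_too_short_raises():
    with pytest.raises(ValueError):
        gg.permutation_entropy([1.0, 2.0], order=3)


# ---------------------------------------------------------------------------
# wavelet entropy vs an independent periodized db4 filter-bank oracle

# Daubechies-4 scaling (low-pass) coefficients, hardcoded published values
_DB4_LO = np.array(
    [
        0.23037781330885523,
        0.7148465705525415,
        0.6308807679295904,
        -0.02798376941698385,
        -0.18703481171888114,
        0.030841381835986965,
        0.032883011666982945,
        -0.010597401784997278,
    ]
)
# quadrature-mirror high-pass analysis taps: hi[j] = (-1)^j lo[L-1-j]
_DB4_HI = np.array([(-1) ** k * _DB4_LO[len(_DB4_LO) - 1 - k] for k in range(len(_DB4_LO))])


def _circular_dwt_step(x):
    """One level of the periodized db4 analysis filter bank.

    a[k] = sum_j x[(2k + j - s) mod n] * lo[j] with phase s = L/2 - 1
    (circular correlation downsampled by two); n/2 coefficients per band.
    """
    n = len(x)
    L = len(_DB4_LO)
    s = L // 2 - 1
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(L)[None, :] - s) % n
    a = (x[idx] * _DB4_LO[None, :]).sum(axis=1)
    d = (x[idx] * _DB4_HI[None, :]).sum(axis=1)
    return a, d


def wavelet_entropy_oracle(x, levels):
    """Band energies from the explicit periodized db4 pyramid."""
    a = np.asarray(x, float)
    energies = []
    for _ in range(levels):
        a, d = _circular_dwt_step(a)
        energies.append(float(np.sum(d**2)))
    energies.append(float(np.sum(a**2)))
    p = np.array(energies)
    p = p / p.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def test_wavelet_entropy_matches_stepwise_oracle():
    x = np.random.default_rng(17).standard_normal(256)
    assert gg.wavelet_entropy(x, levels=5) == pytest.approx(
        wavelet_entropy_oracle(x, 5), abs=1e-8
    )


def test_wavelet_entropy_uniform_bands():
    """Equal energy in all L bands gives exactly ln L."""
    import pywt

    levels = 3
    n = 64
    # build a signal from unit-energy coefficients in every band
    shapes = pywt.wavedec(np.zeros(n), "db4", level=levels, mode="periodization")
    coeffs = []
    rng = np.random.default_rng(5)
    for c in shapes:
        v = rng.standard_normal(len(c))
        coeffs.append(v / np.linalg.norm(v))
    x = pywt.waverec(coeffs, "db4", mode="periodization")
    assert gg.wavelet_entropy(x, levels=levels) == pytest.approx(
        math.log(levels + 1), abs=1e-8
    )


def test_wavelet_entropy_single_band_is_zero():
    import pywt

    shapes = pywt.wavedec(np.zeros(64), "db4", level=3, mode="periodization")
    coeffs = [np.zeros(len(c)) for c in shapes]
    coeffs[0][:] = 1.0  # all energy in the approximation band
    x = pywt.waverec(coeffs, "db4", mode="periodization")
    assert gg.wavelet_entropy(x, levels=3) == pytest.approx(0.0, abs=1e-10)


def test_wavelet_entropy_too_short_raises():
    with pytest.raises(ValueError):
        gg.wavelet_entropy(np.zeros(16), levels=5)


# ---------------------------------------------------------------------------
# STFT spectral entropy


def stft_entropy_oracle(seg, win_s, hop_s):
    """Direct windowed-DFT recomputation (explicit complex exponentials)."""
    win = int(round(win_s * seg.rate_hz))
    hop = int(round(hop_s * seg.rate_hz))
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(win) / win)  # periodic Hann
    k = np.arange(win // 2 + 1)
    dft = np.exp(-2j * np.pi * np.outer(k, np.arange(win)) / win)
    ents = []
    for ch in seg.data:
        frames = [ch[s : s + win] * w for s in range(0, len(ch) - win + 1, hop)]
        power = np.abs(np.stack([dft @ f for f in frames])) ** 2
        p = (power / power.sum()).ravel()
        p = p[p > 0]
        ents.append(float(-(p * np.log(p)).sum()))
    return float(np.mean(ents))


def test_stft_entropy_matches_dft_oracle():
    rng = np.random.default_rng(23)
    seg = make_segment(rng.standard_normal((3, 512)), rate_hz=128.0)
    assert gg.stft_spectral_entropy(seg, 1.0, 0.5) == pytest.approx(
        stft_entropy_oracle(seg, 1.0, 0.5), abs=1e-8
    )


def test_spectral_entropy_distribution_extremes():
    """One active bin -> 0; perfectly flat power -> log(#bins); zero -> 0."""
    from gazegraph.eeg import spectral_entropy_from_power

    one_hot = np.zeros((4, 16))
    one_hot[2, 5] = 3.7
    assert spectral_entropy_from_power(one_hot) == 0.0
    assert spectral_entropy_from_power(np.full((4, 16), 2.0)) == pytest.approx(
        math.log(64), abs=1e-12
    )
    assert spectral_entropy_from_power(np.zeros((2, 8))) == 0.0


def test_stft_entropy_white_noise_near_log_bins():
    """White noise spreads power over all bins; the entropy sits just below
    log(#bins) by the expected log of the exponential bin-power spread."""
    rng = np.random.default_rng(11)
    seg = make_segment(rng.standard_normal((1, 256 * 8)), rate_hz=256.0)
    win, hop = 256, 128
    n_frames = (256 * 8 - win) // hop + 1
    n_bins = (win // 2 + 1) * n_frames
    val = gg.stft_spectral_entropy(seg, 1.0, 0.5)
    assert math.log(n_bins) - 0.6 < val < math.log(n_bins)


# ---------------------------------------------------------------------------
# PCC synchronization


def test_pcc_identical_channels():
    x = np.random.default_rng(2).standard_normal(100)
    mat, scalar = gg.pcc_synchronization(make_segment(np.stack([x, x, x])))
    assert np.allclose(mat, 1.0)
    assert scalar == pytest.approx(1.0)


def test_pcc_anticorrelated():
    x = np.random.default_rng(3).standard_normal(100)
    mat, _ = gg.pcc_synchronization(make_segment(np.stack([x, -x])))
    assert mat[0, 1] == pytest.approx(-1.0)


def test_pcc_three_channel_toy():
    """Closed-form: rows 1 and 2 proportional (r=1), row 3 reversed (r=-1)."""
    seg = make_segment([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]])
    mat, scalar = gg.pcc_synchronization(seg)
    assert mat[0, 1] == pytest.approx(1.0)
    assert mat[0, 2] == pytest.approx(-1.0)
    assert mat[1, 2] == pytest.approx(-1.0)
    assert scalar == pytest.approx(-1.0 / 3.0)


def test_pcc_matrix_properties_random():
    rng = np.random.default_rng(8)
    seg = make_segment(rng.standard_normal((6, 200)))
    mat, _ = gg.pcc_synchronization(seg)
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 1.0)
    assert (np.abs(mat) <= 1 + 1e-12).all()


def test_pcc_zero_variance_channel_errors():
    seg = make_segment([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
    with pytest.raises(ValueError, match="0"):
        gg.pcc_synchronization(seg)


# ---------------------------------------------------------------------------
# full per-segment extraction


def test_extract_features_names_and_determinism():
    rng = np.random.default_rng(4)
    seg = make_segment(rng.standard_normal((8, 1024)))
    fs1 = gg.extract_eeg_features(seg)
    fs2 = gg.extract_eeg_features(seg)
    assert tuple(fs1.as_dict()) == EEG_FEATURE_NAMES
    assert fs1.as_dict() == fs2.as_dict()
    assert np.isfinite(fs1.as_array()).all()


def test_extract_mean_value_offset():
    rng = np.random.default_rng(6)
    base = rng.standard_normal((4, 1024))
    base -= base.mean(axis=1, keepdims=True)
    fs = gg.extract_eeg_features(make_segment(base + 5.0))
    assert fs.mean_value == pytest.approx(5.0, abs=1e-10)
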