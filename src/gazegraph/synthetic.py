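"""Seeded two-group synthetic cohorts of EEG and eye-tracking recordings.

The generator stands in for a clinical cohort of young children (two
groups, 21 + 21 by default) whose resting EEG differs in signal
complexity, oscillatory content and channel coupling, and whose fixation
behavior differs in per-test total fixation duration.  Each generative
knob maps onto one extracted feature family:

* ``eeg_ar_coefficient`` (lag-1 autoregression) — regularity, hence the
  approximate / sample / permutation entropies;
* ``eeg_sine_amplitude`` of an in-band 10 Hz oscillation — the STFT and
  wavelet (time-frequency) entropies;
* ``eeg_coupling`` of a shared latent driver — pairwise channel
  correlation (synchronization);
* ``eeg_noise_sd`` — broadband complexity;
* ``eeg_offset_uv`` — the mean-amplitude feature;
* ``fixation_mean_ms`` / ``fixation_sd_ms`` — the seven per-test total
  fixation durations.

Per channel, the signal is x_t = phi * x_{t-1} + innovation_t plus the
oscillation and offset, where the innovation mixes a channel-private and a
shared standard-normal driver.  All signals are generated in-band; no
filtering stage is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .eeg import DEFAULT_CHANNELS, EEGRecording
from .eye import MIN_FIXATION_MS, TEST_NAMES, FixationRecord

__all__ = [
    "GroupSpec",
    "SyntheticSubject",
    "default_group_specs",
    "simulate_eeg",
    "simulate_fixations",
    "simulate_dataset",
]

#: Canonical AOI label recorded for each test's fixations.
TEST_AOI = {
    "ExoticFace": "face",
    "SocialInteraction": "actors",
    "JointAttention": "target",
    "ModJoint1": "gaze_target",
    "ModJoint2": "gaze_target",
    "NativeFace1": "face",
    "NativeFace2": "face",
}

#: Each test shows 6 photo presentations of 10 s.
TEST_DURATION_MS = 6 * 10_000.0


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters of one subject group.

    ``fixation_mean_ms``/``fixation_sd_ms`` map each of the seven test
    names to the mean / SD of that test's total valid fixation duration;
    ``subthreshold_rate`` is the expected number of sub-60 ms (invalid)
    fixation events per test.
    """

    label: str
    eeg_ar_coefficient: float
    eeg_sine_amplitude: float
    eeg_noise_sd: float
    fixation_mean_ms: Mapping[str, float]
    fixation_sd_ms: Mapping[str, float]
    subthreshold_rate: float = 3.0
    eeg_offset_uv: float = 0.0
    eeg_coupling: float = 0.5
    eeg_sine_hz: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.eeg_ar_coefficient < 1:
            raise ValueError("eeg_ar_coefficient must be in [0, 1)")
        if self.eeg_noise_sd <= 0:
            raise ValueError("eeg_noise_sd must be positive")
        if not 0 <= self.eeg_coupling <= 1:
            raise ValueError("eeg_coupling must be in [0, 1]")
        if self.subthreshold_rate < 0:
            raise ValueError("subthreshold_rate must be >= 0")
        for table, name in ((self.fixation_mean_ms, "fixation_mean_ms"),
                            (self.fixation_sd_ms, "fixation_sd_ms")):
            if set(table) != set(TEST_NAMES):
                raise ValueError(f"{name} must map exactly the 7 test names")
            if any(v < 0 for v in table.values()):
                raise ValueError(f"{name} values must be >= 0")


@dataclass
class SyntheticSubject:
    """One simulated child: group label, EEG recording, fixation log."""

    subject_id: str
    group: str
    eeg: EEGRecording
    fixations: list[FixationRecord]


def default_group_specs() -> tuple[GroupSpec, GroupSpec]:
    """The default well-separated two-group configuration.

    The contrasts are deliberately strong (every affected feature family is
    separated by well over two pooled SDs at the subject level): the "ASD"
    group has less regular, noisier, weaker-alpha, less synchronized EEG
    with a lower mean offset, and shorter fixation totals on the face and
    social tests — the direction of group differences this kind of study
    reports.  Fixation totals are on the order of tens of seconds out of
    60 s of stimulus per test.
    """
    td_fix = {
        "ExoticFace": 30_000.0,
        "SocialInteraction": 34_000.0,
        "JointAttention": 28_000.0,
        "ModJoint1": 31_000.0,
        "ModJoint2": 30_000.0,
        "NativeFace1": 36_000.0,
        "NativeFace2": 35_000.0,
    }
    asd_fix = {
        "ExoticFace": 21_000.0,
        "SocialInteraction": 22_000.0,
        "JointAttention": 25_000.0,
        "ModJoint1": 24_000.0,
        "ModJoint2": 25_000.0,
        "NativeFace1": 22_000.0,
        "NativeFace2": 20_000.0,
    }
    sd = {t: 2_500.0 for t in TEST_NAMES}
    asd = GroupSpec(
        label="ASD",
        eeg_ar_coefficient=0.55,
        eeg_sine_amplitude=0.8,
        eeg_noise_sd=1.2,
        eeg_offset_uv=-2.0,
        eeg_coupling=0.4,
        fixation_mean_ms=asd_fix,
        fixation_sd_ms=sd,
    )
    td = GroupSpec(
        label="TD",
        eeg_ar_coefficient=0.85,
        eeg_sine_amplitude=1.6,
        eeg_noise_sd=0.6,
        eeg_offset_uv=2.0,
        eeg_coupling=0.8,
        fixation_mean_ms=td_fix,
        fixation_sd_ms=sd,
    )
    return asd, td


def simulate_eeg(
    spec: GroupSpec,
    n_channels: int = 8,
    duration_s: float = 360.0,
    rate_hz: float = 256.0,
    seed: int = 0,
) -> EEGRecording:
    """One subject's multichannel EEG under a group spec.

    Channels share a latent standard-normal driver mixed into each
    channel's AR(1) innovations at weight ``eeg_coupling`` (so pairwise
    correlation is non-degenerate and tunable), plus a common in-band
    sinusoid and a DC offset.  Identical (spec, seed) give bit-identical
    output.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration_s and rate_hz must be positive")
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    n = int(round(duration_s * rate_hz))
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(n)
    c = spec.eeg_coupling
    t = np.arange(n) / rate_hz
    sine = spec.eeg_sine_amplitude * np.sin(2 * np.pi * spec.eeg_sine_hz * t)
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        private = rng.standard_normal(n)
        innov = spec.eeg_noise_sd * (c * shared + np.sqrt(1 - c**2) * private)
        ar = lfilter([1.0], [1.0, -spec.eeg_ar_coefficient], innov)
        data[ch] = spec.eeg_offset_uv + sine + ar
    names = (
        DEFAULT_CHANNELS
        if n_channels == len(DEFAULT_CHANNELS)
        else tuple(f"CH{i + 1}" for i in range(n_channels))
    )
    return EEGRecording(data=data, rate_hz=rate_hz, channel_names=names)


def simulate_fixations(spec: GroupSpec, seed: int = 0) -> list[FixationRecord]:
    """One subject's fixation log over all seven tests.

    Per test, the total valid fixation duration is drawn from
    Normal(mean, sd) (clipped at 0) and split across events of at least
    60 ms; an additional Poisson(``subthreshold_rate``) count of sub-60 ms
    events models unconscious gazing that downstream thresholding must
    discard.  Events are laid out sequentially with small gaps inside the
    test's 60 s presentation window.
    """
    rng = np.random.default_rng(seed)
    records: list[FixationRecord] = []
    for test in TEST_NAMES:
        total = max(0.0, rng.normal(spec.fixation_mean_ms[test], spec.fixation_sd_ms[test]))
        durations: list[float] = []
        if total >= MIN_FIXATION_MS:
            # mean valid fixation ~300 ms; floor of 60 ms per event
            k = max(1, int(total // 300.0))
            k = min(k, int(total // MIN_FIXATION_MS))
            extra = total - MIN_FIXATION_MS * k
            shares = rng.dirichlet(np.full(k, 5.0)) * extra
            durations.extend(MIN_FIXATION_MS + shares)
        n_sub = rng.poisson(spec.subthreshold_rate)
        durations.extend(rng.uniform(10.0, MIN_FIXATION_MS - 1e-6, size=n_sub))
        order = rng.permutation(len(durations))
        onset = 0.0
        for i in order:
            onset += rng.uniform(50.0, 300.0)
            records.append(
                FixationRecord(
                    test=test,
                    aoi=TEST_AOI[test],
                    onset_ms=onset,
                    duration_ms=float(durations[i]),
                )
            )
            onset += durations[i]
    return records


def subject_seeds(master_seed: int, index: int) -> tuple[int, int]:
    """Deterministic (eeg_seed, fixation_seed) for subject ``index``.

    Derived by hashing (master_seed, index) through numpy's SeedSequence,
    so extending a cohort never reshuffles existing subjects.
    """
    eeg = int(np.random.SeedSequence((master_seed, index, 0)).generate_state(1)[0] % 2**31)
    fix = int(np.random.SeedSequence((master_seed, index, 1)).generate_state(1)[0] % 2**31)
    return eeg, fix


def simulate_dataset(
    spec_a: GroupSpec,
    spec_b: GroupSpec,
    n_a: int = 21,
    n_b: int = 21,
    seed: int = 0,
    n_channels: int = 8,
    duration_s: float = 360.0,
    rate_hz: float = 256.0,
) -> list[SyntheticSubject]:
    """A full two-group cohort (21 + 21 subjects by default)."""
    if n_a < 1 or n_b < 1:
        raise ValueError("need at least one subject per group")
    subjects = []
    specs = [spec_a] * n_a + [spec_b] * n_b
    for idx, spec in enumerate(specs):
        eeg_seed, fix_seed = subject_seeds(seed, idx)
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{idx + 1:03d}",
                group=spec.label,
                eeg=simulate_eeg(spec, n_channels, duration_s, rate_hz, eeg_seed),
                fixations=simulate_fixations(spec, fix_seed),
            )
        )
    return subjects
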