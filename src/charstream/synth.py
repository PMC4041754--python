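"""Synthetic multichannel EEG aligned to a stimulus schedule, with ground truth.

The generator emulates the phenomenology of a fast auditory speller session:

* every stimulus evokes a small standard auditory response (N1–P2 complex),
  identical for all symbols;
* attended (target) stimuli additionally evoke condition-specific
  class-discriminative components — an N200/P300 complex for the oddball
  conditions A/B, and a slow central negativity spanning roughly −200 to
  +200 ms around stimulus onset for the sequential condition C (the user
  knows when the target will occur, so discriminative activity may precede
  it);
* in the sequential condition, the same-group neighbours of a target
  (pre-/post-target stimuli) may evoke an attenuated copy of the target
  response — the confusion structure that motivates the sequential
  meta-classifier;
* background activity is 1/f^beta (pink) noise;
* optional eye-movement artifacts are frontal/EOG-dominant slow deflections
  that can be partially time-locked to target onsets.

ERP components are sums of Gaussian-windowed bumps, not recorded templates:
simple, fully parameterized, and exactly reconstructable. Every additive
term (ERP, artifact, noise) is logged separately so tests can verify exact
ground-truth bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from charstream.paradigm import StimulusSchedule

# 16-channel test montage (10-20 subset) plus bipolar EOG derivations.
MONTAGE_16 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "C3", "Cz", "C4", "T8",
    "P3", "Pz", "P4", "O1", "O2",
)
EOG_CHANNELS = ("vEOG", "hEOG")

# 63-channel extended 10-20 montage for full-scale simulations.
MONTAGE_63 = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz", "F9",
)

# named scalp distributions (channel -> relative weight); channels absent
# from the montage are silently dropped, the result is max-abs normalized
TOPOGRAPHIES: dict[str, dict[str, float]] = {
    "frontocentral": {
        "Fz": 1.0, "FCz": 0.95, "Cz": 0.8, "F3": 0.7, "F4": 0.7,
        "FC1": 0.8, "FC2": 0.8, "C3": 0.55, "C4": 0.55,
        "Fp1": 0.3, "Fp2": 0.3, "F7": 0.2, "F8": 0.2,
    },
    "central": {
        "Cz": 1.0, "FCz": 0.85, "CPz": 0.85, "C1": 0.9, "C2": 0.9,
        "C3": 0.75, "C4": 0.75, "Fz": 0.55, "Pz": 0.55,
        "FC1": 0.7, "FC2": 0.7, "CP1": 0.7, "CP2": 0.7,
    },
    "centroparietal": {
        "Pz": 1.0, "CPz": 0.9, "Cz": 0.7, "P3": 0.8, "P4": 0.8,
        "CP1": 0.8, "CP2": 0.8, "P1": 0.9, "P2": 0.9,
        "PO3": 0.5, "PO4": 0.5, "POz": 0.6, "O1": 0.25, "O2": 0.25,
    },
    "temporal": {
        "T7": 1.0, "T8": 1.0, "C5": 0.7, "C6": 0.7,
        "FT7": 0.6, "FT8": 0.6, "TP7": 0.6, "TP8": 0.6,
        "C3": 0.35, "C4": 0.35, "F7": 0.3, "F8": 0.3,
    },
    "ocular": {
        "vEOG": 1.0, "hEOG": 0.55,
        "Fp1": 0.7, "Fp2": 0.7, "Fpz": 0.7, "AF3": 0.45, "AF4": 0.45,
        "F7": 0.3, "F3": 0.25, "Fz": 0.22, "F4": 0.25, "F8": 0.3,
        "Cz": 0.08, "C3": 0.06, "C4": 0.06,
    },
}


@dataclass(frozen=True)
class ErpComponent:
    """A Gaussian-windowed ERP bump.

    Parameters
    ----------
    peak_latency
        Peak time in ms relative to stimulus onset; may be negative for
        pre-stimulus components.
    width
        Full width at half maximum in ms.
    amplitude
        Signed peak amplitude in µV at the topography's maximum channel.
    topography
        Name of a scalp distribution in :data:`TOPOGRAPHIES`, or an explicit
        channel -> weight mapping.
    """

    peak_latency: float
    width: float
    amplitude: float
    topography: str | dict[str, float] = "central"
    name: str = ""

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("component width must be positive")

    def topo_vector(self, channels: tuple[str, ...]) -> np.ndarray:
        weights = (
            TOPOGRAPHIES[self.topography]
            if isinstance(self.topography, str)
            else self.topography
        )
        v = np.array([weights.get(ch, 0.0) for ch in channels], float)
        m = np.abs(v).max()
        if m == 0:
            raise ValueError(
                "topography has no nonzero weight on the requested montage"
            )
        return v / m


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def render_component(
    component: ErpComponent,
    time_axis: np.ndarray,
    channels: tuple[str, ...],
) -> np.ndarray:
    """Render one component on a time axis (ms) as a channels x time array.

    The waveform is ``amplitude * exp(-(t - peak)^2 / (2 sigma^2))`` scaled
    by the max-abs-normalized topography, so the peak over channels and time
    equals ``amplitude``. Axes that only partially cover the bump clip it.
    """
    sigma = component.width * _FWHM_TO_SIGMA
    bump = component.amplitude * np.exp(
        -0.5 * ((np.asarray(time_axis, float) - component.peak_latency) / sigma) ** 2
    )
    return np.outer(component.topo_vector(channels), bump)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject ERP component sets and trial-to-trial variability.

    ``components_common`` is evoked by every stimulus (the standard
    auditory response); ``components_target`` only by the attended
    stimulus itself. ``components_neighbor`` is the attention-spillover
    response evoked by the same-group neighbours of a target, scaled by
    ``neighbor_gains[d - 1]`` at within-group distance d — the
    sequential-condition confusion structure in which stimuli adjacent to
    the target elicit target-like activity.
    """

    components_common: tuple[ErpComponent, ...]
    components_target: tuple[ErpComponent, ...]
    components_neighbor: tuple[ErpComponent, ...] = ()
    neighbor_gains: tuple[float, ...] = ()
    latency_jitter: float = 15.0  # ms, sd of per-event latency shift
    amplitude_jitter: float = 0.15  # relative sd of per-event gain
    anticipation_jitter: float = 0.0  # ms, half-width of a uniform common
    # latency shift of all class-discriminative (non-common) components,
    # drawn once per iteration: the user's anticipation of the known
    # target time runs early or late as a whole, so the target's response
    # and the target-like responses of its neighbours shift coherently.
    # Bounded (uniform) because the preceding stimulus re-anchors the
    # user's timing within one SOA.
    anticipation_scope: str = "iteration"  # "iteration": a fresh shift per
    # iteration; "trial": one persistent shift for the whole trial (a user
    # who consistently mis-times a given letter)

    def __post_init__(self):
        if (self.latency_jitter < 0 or self.amplitude_jitter < 0
                or self.anticipation_jitter < 0):
            raise ValueError("jitter scales must be >= 0")
        if self.anticipation_scope not in ("iteration", "trial"):
            raise ValueError("anticipation_scope must be 'iteration' or 'trial'")


def _scaled(components: tuple[ErpComponent, ...], gain: float) -> tuple[ErpComponent, ...]:
    return tuple(replace(c, amplitude=c.amplitude * gain) for c in components)


COMMON_RESPONSE = (
    ErpComponent(100.0, 80.0, -1.0, "frontocentral", "N1"),
    ErpComponent(200.0, 110.0, 0.8, "central", "P2"),
)

ODDBALL_TARGET = (
    ErpComponent(200.0, 110.0, -2.0, "frontocentral", "N200"),
    ErpComponent(400.0, 300.0, 4.0, "centroparietal", "P300"),
)

#: the slow anticipatory negativity of the sequential condition
SEQUENTIAL_NEGATIVITY = ErpComponent(
    -50.0, 200.0, -3.0, "central", "pre-stimulus negativity"
)
#: a weak late target-confirmation positivity, specific to the target
#: itself (its same-group neighbours share the negativity but not this)
SEQUENTIAL_LATE_CUE = ErpComponent(
    600.0, 150.0, 0.8, "frontocentral", "late confirmation positivity"
)

SEQUENTIAL_TARGET = (SEQUENTIAL_NEGATIVITY, SEQUENTIAL_LATE_CUE)
SEQUENTIAL_NEIGHBOR = (SEQUENTIAL_NEGATIVITY,)


def default_profile(condition: str, neighbor_gain: float | None = None) -> SubjectProfile:
    """Condition-appropriate default component sets.

    For condition C the default ``neighbor_gain`` of 0.5 gives the
    pre-/post-target stimuli an attenuated copy of the anticipatory
    negativity, emulating the target/neighbour confusion seen with
    sequential stimuli. Oddball conditions (A/B, random order) default to
    no neighbour response.
    """
    if condition in ("A", "B"):
        gains = () if neighbor_gain is None else (neighbor_gain,)
        return SubjectProfile(
            components_common=COMMON_RESPONSE,
            components_target=ODDBALL_TARGET,
            components_neighbor=ODDBALL_TARGET,
            neighbor_gains=gains,
            latency_jitter=15.0,
        )
    if condition == "C":
        gain = 0.5 if neighbor_gain is None else neighbor_gain
        # anticipatory components are temporally sloppier than stimulus-
        # locked oddball responses, and anticipation of the known target
        # time runs early or late coherently within an iteration
        return SubjectProfile(
            components_common=COMMON_RESPONSE,
            components_target=SEQUENTIAL_TARGET,
            components_neighbor=SEQUENTIAL_NEIGHBOR,
            neighbor_gains=(gain,),
            latency_jitter=50.0,
            anticipation_jitter=100.0,
        )
    raise ValueError(f"unknown condition {condition!r}")


def confusion_profile(
    run_gains: tuple[float, ...] = (1.0, 1.0),
    latency_jitter: float = 30.0,
    anticipation_jitter: float = 150.0,
) -> SubjectProfile:
    """A sequential-condition profile with strong neighbour confusion.

    The attention-spillover negativity extends at full strength over the
    same-group neighbours (default: distances 1 and 2 on both sides), so
    the target and its neighbours are nearly indistinguishable from their
    own epochs alone; only the weak late confirmation positivity and the
    sequence context identify the target. This is the structure under
    which a plain per-epoch pipeline confuses the target with its
    neighbours and the sequential meta-classifier recovers it.
    """
    return SubjectProfile(
        components_common=COMMON_RESPONSE,
        components_target=SEQUENTIAL_TARGET,
        components_neighbor=SEQUENTIAL_NEIGHBOR,
        neighbor_gains=run_gains,
        latency_jitter=latency_jitter,
        anticipation_jitter=anticipation_jitter,
    )


@dataclass
class RecordingEvent:
    """A stimulus event placed on the recording's sample axis."""

    sample: int
    trial: int
    onset_ms: float  # within-trial onset
    symbol: str
    group: str
    iteration: int
    is_target: bool
    is_pretarget: bool
    is_posttarget: bool
    trial_target: str = ""
    trial_target_group: str = ""


@dataclass
class SyntheticRecording:
    """Continuous multichannel signal with events and ground-truth parts.

    ``signal = erp + artifacts + noise`` holds exactly (float addition of
    the logged parts), which tests use to verify bookkeeping.
    """

    signal: np.ndarray  # (n_channels, n_samples), µV
    fs: float  # Hz
    channels: tuple[str, ...]
    eog_channels: tuple[str, ...]
    events: list[RecordingEvent]
    trial_starts: np.ndarray  # sample index of each trial's t=0
    erp: np.ndarray = None  # ground truth: summed ERP contributions
    artifacts: np.ndarray = None  # ground truth: injected artifacts
    noise: np.ndarray = None  # ground truth: background noise

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array(
            [i for i, ch in enumerate(self.channels) if ch not in self.eog_channels]
        )

    @property
    def eog_indices(self) -> np.ndarray:
        return np.array(
            [i for i, ch in enumerate(self.channels) if ch in self.eog_channels]
        )

    def copy(self) -> "SyntheticRecording":
        return SyntheticRecording(
            signal=self.signal.copy(),
            fs=self.fs,
            channels=self.channels,
            eog_channels=self.eog_channels,
            events=[replace(e) for e in self.events],
            trial_starts=self.trial_starts.copy(),
            erp=None if self.erp is None else self.erp.copy(),
            artifacts=None if self.artifacts is None else self.artifacts.copy(),
            noise=None if self.noise is None else self.noise.copy(),
        )

    def to_mne_raw(self):
        """Convert to an :class:`mne.io.RawArray` (µV -> V), with stim events."""
        import mne

        ch_types = [
            "eog" if ch in self.eog_channels else "eeg" for ch in self.channels
        ]
        info = mne.create_info(list(self.channels), self.fs, ch_types)
        raw = mne.io.RawArray(self.signal * 1e-6, info, verbose="error")
        return raw

    def events_dataframe(self):
        import pandas as pd

        return pd.DataFrame([vars(e) for e in self.events])


def pink_noise(
    n_channels: int,
    n_samples: int,
    fs: float,
    exponent: float,
    scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """1/f^beta noise via spectral shaping of white noise, RMS = ``scale``."""
    if scale == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms * scale


def synthesize(
    schedule: StimulusSchedule,
    profile: SubjectProfile,
    fs: float = 1000.0,
    channels: tuple[str, ...] = MONTAGE_16,
    eog_channels: tuple[str, ...] = EOG_CHANNELS,
    noise_scale: float = 4.0,
    noise_exponent: float = 1.0,
    inter_trial_gap: float = 2000.0,
    pad: float = 1200.0,
    seed: int = 0,
) -> SyntheticRecording:
    """Render a schedule into a continuous synthetic recording.

    Parameters
    ----------
    noise_scale
        RMS of the pink background noise in µV (per channel). The default
        of 4 µV against the default 3–4 µV ERP components gives mid-range
        single-trial separability, comparable to a usable ERP-BCI session.
    inter_trial_gap, pad
        Silence between trials and at the recording edges, ms; must exceed
        half the epoching window so all epochs fit.
    """
    all_channels = tuple(channels) + tuple(eog_channels)
    rng = np.random.default_rng(seed)

    soa = schedule.config.soa_group
    trial_durations = [t.duration + soa for t in schedule.trials]
    pad_samp = int(round(pad * fs / 1000.0))
    gap_samp = int(round(inter_trial_gap * fs / 1000.0))

    trial_starts = []
    cursor = pad_samp
    for dur in trial_durations:
        trial_starts.append(cursor)
        cursor += int(round(dur * fs / 1000.0)) + gap_samp
    n_samples = cursor + pad_samp
    n_ch = len(all_channels)

    erp = np.zeros((n_ch, n_samples))
    events: list[RecordingEvent] = []

    def _component_sets(ev, dist):
        """Components evoked by one event; dist = within-group distance to
        the nearest target occurrence (0 for the target itself)."""
        comps = list(profile.components_common)
        if ev.is_target:
            comps += list(profile.components_target)
        elif 1 <= dist <= len(profile.neighbor_gains):
            comps += list(
                _scaled(profile.components_neighbor,
                        profile.neighbor_gains[dist - 1])
            )
        return comps

    for trial_idx, trial in enumerate(schedule.trials):
        t0 = trial_starts[trial_idx]
        # within-group stream position of every event, and distance to the
        # nearest target occurrence in the same stream
        dist_of: dict[int, int] = {}
        for g in {e.group for e in trial.events}:
            stream = [e for e in trial.events if e.group == g]
            stream.sort(key=lambda e: e.onset)
            tgt_pos = [k for k, e in enumerate(stream) if e.is_target]
            for k, e in enumerate(stream):
                d = min((abs(k - p) for p in tgt_pos), default=10**6)
                dist_of[id(e)] = d
        n_iter = 1 + max(e.iteration for e in trial.events)
        if profile.anticipation_jitter > 0:
            if profile.anticipation_scope == "trial":
                iter_shift = np.full(
                    n_iter,
                    rng.uniform(-profile.anticipation_jitter,
                                profile.anticipation_jitter),
                )
            else:
                iter_shift = rng.uniform(
                    -profile.anticipation_jitter,
                    profile.anticipation_jitter, size=n_iter,
                )
        else:
            iter_shift = np.zeros(n_iter)
        n_common = len(profile.components_common)
        for ev in trial.events:
            sample = t0 + int(round(ev.onset * fs / 1000.0))
            events.append(
                RecordingEvent(
                    sample=sample,
                    trial=trial_idx,
                    onset_ms=ev.onset,
                    symbol=ev.symbol,
                    group=ev.group,
                    iteration=ev.iteration,
                    is_target=ev.is_target,
                    is_pretarget=ev.is_pretarget,
                    is_posttarget=ev.is_posttarget,
                    trial_target=trial.target,
                    trial_target_group=schedule.alphabet.group_of[trial.target],
                )
            )
            for ci, comp in enumerate(_component_sets(ev, dist_of[id(ev)])):
                lat = comp.peak_latency + rng.normal(0.0, profile.latency_jitter)
                if ci >= n_common:  # discriminative components only
                    lat += iter_shift[ev.iteration]
                gain = 1.0 + rng.normal(0.0, profile.amplitude_jitter)
                jittered = replace(comp, peak_latency=0.0, amplitude=comp.amplitude * gain)
                sigma = comp.width * _FWHM_TO_SIGMA
                half = int(round(3 * sigma * fs / 1000.0))
                center = sample + int(round(lat * fs / 1000.0))
                lo = max(0, center - half)
                hi = min(n_samples, center + half + 1)
                if hi <= lo:
                    continue
                t_local = (np.arange(lo, hi) - center) * 1000.0 / fs
                erp[:, lo:hi] += render_component(jittered, t_local, all_channels)

    noise = pink_noise(n_ch, n_samples, fs, noise_exponent, noise_scale, rng)
    artifacts = np.zeros((n_ch, n_samples))
    signal = erp + artifacts + noise

    return SyntheticRecording(
        signal=signal,
        fs=fs,
        channels=all_channels,
        eog_channels=tuple(eog_channels),
        events=events,
        trial_starts=np.array(trial_starts),
        erp=erp,
        artifacts=artifacts,
        noise=noise,
    )


def inject_eye_artifacts(
    recording: SyntheticRecording,
    rate: float = 4.0,
    amplitude: float = 60.0,
    p_target_locked: float = 0.5,
    width: float = 350.0,
    seed: int = 0,
) -> SyntheticRecording:
    """Add slow ocular deflections, optionally time-locked to targets.

    Artifacts are Gaussian bumps with a frontal/EOG-dominant topography. A
    fraction ``p_target_locked`` of them is centred within ±300 ms of a
    randomly chosen target onset (emulating unconscious target-correlated
    eye movements); the rest occur uniformly over the recording.

    Returns a modified copy; ground-truth arrays are updated accordingly.
    """
    if not 0.0 <= p_target_locked <= 1.0:
        raise ValueError("p_target_locked must be in [0, 1]")
    out = recording.copy()
    duration_min = out.n_samples / out.fs / 60.0
    n_art = int(round(rate * duration_min))
    if n_art == 0:
        return out
    rng = np.random.default_rng(seed)
    target_samples = np.array([e.sample for e in out.events if e.is_target])
    lock_window = int(round(0.3 * out.fs))  # ±300 ms

    comp = ErpComponent(0.0, width, amplitude, "ocular", "eye movement")
    sigma = width * _FWHM_TO_SIGMA
    half = int(round(3 * sigma * out.fs / 1000.0))

    for _ in range(n_art):
        locked = target_samples.size > 0 and rng.random() < p_target_locked
        if locked:
            center = int(rng.choice(target_samples)) + int(
                rng.integers(-lock_window, lock_window + 1)
            )
        else:
            center = int(rng.integers(0, out.n_samples))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lo = max(0, center - half)
        hi = min(out.n_samples, center + half + 1)
        if hi <= lo:
            continue
        t_local = (np.arange(lo, hi) - center) * 1000.0 / out.fs
        wave = render_component(replace(comp, amplitude=sign * amplitude), t_local, out.channels)
        out.artifacts[:, lo:hi] += wave
        out.signal[:, lo:hi] += wave
    return out
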