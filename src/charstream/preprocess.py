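"""Preprocessing: causal band-pass filtering, epoching, min–max artifact
rejection, and a pluggable ocular-artifact projection.

The pipeline order is fixed: filter -> (projection) -> epoch -> reject.
All data-dependent operators (the ocular projection) are fit on calibration
data only and then applied unchanged to unseen data, matching online use.
Filtering is causal (forward-only) and the group delay is deliberately not
compensated, as it cannot be online.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from charstream.synth import SyntheticRecording

logger = logging.getLogger(__name__)

#: default channels monitored by min-max rejection (fronto-central sites
#: pick up both ocular and movement artifacts well)
REJECTION_CHANNELS = (
    "Fp1", "Fp2", "Fpz", "F3", "Fz", "F4", "FC1", "FCz", "FC2", "C3", "Cz", "C4",
)

#: conservative / liberal min-max threshold presets, µV
REJECTION_PRESETS = {"conservative": 70.0, "liberal": 150.0}


@dataclass(frozen=True)
class FilterSpec:
    """Causal Chebyshev-II band-pass: high-pass then low-pass.

    Defaults: 0.2 Hz high-pass (order 4) followed by a 25 Hz low-pass
    (order 8), both with 40 dB stop-band attenuation (Chebyshev II has
    equiripple stop bands, so this bounds the residual DC leakage).
    """

    highpass: float = 0.2
    lowpass: float = 25.0
    hp_order: int = 4
    lp_order: int = 8
    stopband_db: float = 40.0

    def validate(self, fs: float) -> None:
        if not 0 < self.highpass < self.lowpass < fs / 2:
            raise ValueError(
                f"need 0 < highpass < lowpass < Nyquist "
                f"(got {self.highpass}, {self.lowpass}, fs={fs})"
            )

    def design(self, fs: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (sos_highpass, sos_lowpass); raises on unstable designs."""
        self.validate(fs)
        sos_hp = sps.cheby2(
            self.hp_order, self.stopband_db, self.highpass, "highpass", fs=fs,
            output="sos",
        )
        sos_lp = sps.cheby2(
            self.lp_order, self.stopband_db, self.lowpass, "lowpass", fs=fs,
            output="sos",
        )
        for name, sos, order in (("highpass", sos_hp, self.hp_order),
                                 ("lowpass", sos_lp, self.lp_order)):
            _, poles, _ = sps.sos2zpk(sos)
            if np.any(np.abs(poles) >= 1.0):
                raise ValueError(
                    f"unstable {name} design (order {order}); "
                    f"try a lower order"
                )
        return sos_hp, sos_lp


def _filter_array(data: np.ndarray, sos_hp: np.ndarray, sos_lp: np.ndarray) -> np.ndarray:
    out = sps.sosfilt(sos_hp, data, axis=-1)
    return sps.sosfilt(sos_lp, out, axis=-1)


def bandpass(recording: SyntheticRecording, spec: FilterSpec | None = None) -> SyntheticRecording:
    """Causal band-pass filter of a continuous recording (all channels).

    Ground-truth component arrays, if present, are filtered with the same
    operator so the additive decomposition of the signal is preserved.
    """
    spec = spec or FilterSpec()
    sos_hp, sos_lp = spec.design(recording.fs)
    out = recording.copy()
    out.signal = _filter_array(out.signal, sos_hp, sos_lp)
    for attr in ("erp", "artifacts", "noise"):
        part = getattr(out, attr)
        if part is not None:
            setattr(out, attr, _filter_array(part, sos_hp, sos_lp))
    return out


@dataclass
class EpochSet:
    """Events x channels x time array with labels and event metadata."""

    data: np.ndarray  # (n_events, n_channels, n_times)
    window: tuple[float, float]  # ms, [start, end)
    fs: float
    channels: tuple[str, ...]
    metadata: pd.DataFrame  # one row per event, aligned with data

    def __post_init__(self):
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must align 1:1 with epochs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time axis in ms (start-inclusive, end-exclusive)."""
        n = self.data.shape[2]
        return self.window[0] + np.arange(n) * 1000.0 / self.fs

    @property
    def labels(self) -> np.ndarray:
        """Binary target labels (1 = target)."""
        return self.metadata["is_target"].to_numpy().astype(int)

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return EpochSet(
            data=self.data[idx],
            window=self.window,
            fs=self.fs,
            channels=self.channels,
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
        )

    def channel_indices(self, names) -> np.ndarray:
        lookup = {ch: i for i, ch in enumerate(self.channels)}
        return np.array([lookup[ch] for ch in names if ch in lookup])


def epoch(
    recording: SyntheticRecording,
    window: tuple[float, float] = (-1000.0, 1000.0),
    baseline: tuple[float, float] | None = None,
    channels: tuple[str, ...] | None = None,
) -> EpochSet:
    """Cut the recording into stimulus-locked epochs.

    The window is sample-inclusive at the start and exclusive at the end;
    0 ms is the stimulus onset sample. No baseline correction is applied by
    default — in the sequential condition class-discriminative activity
    precedes the stimulus, which a pre-stimulus baseline would erase. Pass
    ``baseline=(t0, t1)`` (ms) to subtract the mean of that interval, as is
    conventional for the oddball conditions.

    Events whose window exceeds the recording are dropped with a logged
    count. EOG channels are excluded by default.
    """
    if channels is None:
        names = tuple(
            ch for ch in recording.channels if ch not in recording.eog_channels
        )
    else:
        names = tuple(channels)
    ch_idx = [recording.channels.index(ch) for ch in names]

    s0 = int(round(window[0] * recording.fs / 1000.0))
    s1 = int(round(window[1] * recording.fs / 1000.0))
    n_t = s1 - s0
    if n_t <= 0:
        raise ValueError("empty epoch window")

    rows = []
    slabs = []
    n_dropped = 0
    for ev in recording.events:
        lo, hi = ev.sample + s0, ev.sample + s1
        if lo < 0 or hi > recording.n_samples:
            n_dropped += 1
            continue
        slabs.append(recording.signal[ch_idx, lo:hi])
        rows.append(vars(ev))
    if n_dropped:
        logger.info("epoch: dropped %d out-of-bounds events", n_dropped)
    if not slabs:
        raise ValueError("no events fit inside the recording")
    data = np.stack(slabs)

    if baseline is not None:
        times = window[0] + np.arange(n_t) * 1000.0 / recording.fs
        bmask = (times >= baseline[0]) & (times < baseline[1])
        if not bmask.any():
            raise ValueError("baseline interval contains no samples")
        data = data - data[:, :, bmask].mean(axis=2, keepdims=True)

    return EpochSet(
        data=data,
        window=window,
        fs=recording.fs,
        channels=names,
        metadata=pd.DataFrame(rows),
    )


def minmax_reject(
    epochs: EpochSet,
    threshold: float = REJECTION_PRESETS["conservative"],
    channels: tuple[str, ...] | None = REJECTION_CHANNELS,
) -> tuple[EpochSet, dict]:
    """Reject epochs whose peak-to-peak amplitude exceeds a threshold.

    An epoch is removed iff max - min over the window exceeds ``threshold``
    (µV) on any of the selected channels (default: fronto-central sites;
    ``None`` = all channels). Returns the surviving epochs plus a report
    with per-class counts. Epoch content is never modified, only
    membership.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if channels is None:
        ch_idx = np.arange(len(epochs.channels))
    else:
        ch_idx = epochs.channel_indices(channels)
        if ch_idx.size == 0:
            ch_idx = np.arange(len(epochs.channels))
    ptp = epochs.data[:, ch_idx, :].max(axis=2) - epochs.data[:, ch_idx, :].min(axis=2)
    rejected = (ptp > threshold).any(axis=1)
    if rejected.all():
        raise ValueError(
            "min-max rejection removed every epoch; review the threshold "
            f"({threshold} µV)"
        )
    y = epochs.labels
    report = {
        "threshold": threshold,
        "n_total": int(epochs.n_epochs),
        "n_rejected": int(rejected.sum()),
        "n_rejected_target": int((rejected & (y == 1)).sum()),
        "n_rejected_nontarget": int((rejected & (y == 0)).sum()),
    }
    return epochs.subset(~rejected), report


@dataclass(frozen=True)
class ProjectionOperator:
    """A fixed channels x channels linear map, fit on calibration data only.

    The default backend regresses the EOG reference channels out of every
    EEG channel. Any channels x channels matrix can be supplied instead
    (e.g. an ICA-based cleaner), so the projection stage is pluggable.
    """

    matrix: np.ndarray  # (n_channels, n_channels)
    channels: tuple[str, ...]
    fit_on: str = "calibration"

    def __post_init__(self):
        n = len(self.channels)
        if self.matrix.shape != (n, n):
            raise ValueError("projection matrix must be channels x channels")


def fit_ocular_projection(
    recording: SyntheticRecording,
    eog_channels: tuple[str, ...] | None = None,
) -> ProjectionOperator:
    """Fit a regression-based ocular cleaner on a calibration recording.

    Least-squares regression coefficients of each EEG channel on the EOG
    reference channels are estimated from the continuous calibration
    signal; the operator subtracts the predicted ocular contribution from
    the EEG channels and leaves the EOG channels untouched.
    """
    eog_names = tuple(eog_channels or recording.eog_channels)
    if not eog_names:
        raise ValueError("no EOG channels available")
    chans = recording.channels
    eog_idx = [chans.index(ch) for ch in eog_names]
    eeg_idx = [i for i in range(len(chans)) if i not in eog_idx]

    eog = recording.signal[eog_idx]  # (n_eog, T)
    eeg = recording.signal[eeg_idx]
    gram = eog @ eog.T
    if np.linalg.cond(gram) > 1e10:
        raise ValueError("EOG channels are rank-deficient; cannot fit projection")
    coef = eeg @ eog.T @ np.linalg.inv(gram)  # (n_eeg, n_eog)

    mat = np.eye(len(chans))
    for r, i in enumerate(eeg_idx):
        for c, j in enumerate(eog_idx):
            mat[i, j] = -coef[r, c]
    return ProjectionOperator(matrix=mat, channels=chans)


def apply_projection(op: ProjectionOperator, recording: SyntheticRecording) -> SyntheticRecording:
    """Apply a fitted projection to a recording (returns a modified copy).

    Ground-truth arrays are transformed with the same operator to keep the
    additive decomposition valid.
    """
    if op.channels != recording.channels:
        raise ValueError("projection operator channels do not match recording")
    out = recording.copy()
    out.signal = op.matrix @ out.signal
    for attr in ("erp", "artifacts", "noise"):
        part = getattr(out, attr)
        if part is not None:
            setattr(out, attr, op.matrix @ part)
    return out
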