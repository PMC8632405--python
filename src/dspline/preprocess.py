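"""Preprocessing: segmentation, band filtering, artifact rejection,
baseline correction, and ERP component window extraction/recombination."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .data_model import ONSET_INVALID, BandDefinition, EpochSet

__all__ = [
    "ComponentWindows",
    "DEFAULT_COMPONENT_TABLE",
    "SegmentationReport",
    "RejectionReport",
    "segment_epochs",
    "bandpass_filter",
    "reject_artifacts",
    "baseline_correct",
    "component_windows",
    "extract_combine",
]

# Component latency table: name -> either a single nominal latency in ms
# (point component: symmetric window of 2*half_width+1 samples) or an
# inclusive (start_ms, end_ms) latency range.
DEFAULT_COMPONENT_TABLE = {
    "N70": 70.0,
    "P120": 120.0,
    "N170_P200": (170.0, 200.0),
    "P300": 300.0,
    "P400_700": (400.0, 700.0),
}


@dataclass(frozen=True)
class ComponentWindows:
    """Ordered half-open sample windows of the ERP components.

    ``windows`` is a list of ``(name, start_index, end_index)`` where the
    range is ``[start_index, end_index)`` in trial sample coordinates.
    """

    windows: tuple

    def __post_init__(self):
        object.__setattr__(self, "windows", tuple(
            (str(n), int(a), int(b)) for n, a, b in self.windows
        ))
        for name, a, b in self.windows:
            if a < 0 or b <= a:
                raise ValueError(f"window {name!r}: invalid range [{a}, {b})")

    @property
    def combined_length(self) -> int:
        return sum(b - a for _, a, b in self.windows)

    @property
    def names(self) -> tuple:
        return tuple(n for n, _, _ in self.windows)

    def indices(self) -> np.ndarray:
        """All selected sample indices, window by window."""
        if not self.windows:
            return np.empty(0, dtype=int)
        return np.concatenate(
            [np.arange(a, b) for _, a, b in self.windows]
        ).astype(int)

    def validate_for_length(self, n_samples: int) -> None:
        for name, a, b in self.windows:
            if b > n_samples:
                raise ValueError(
                    f"component {name!r} window [{a}, {b}) exceeds trial "
                    f"length {n_samples}"
                )


@dataclass
class SegmentationReport:
    n_events: int
    n_kept: int
    skipped: list  # (event index, sample, reason)


@dataclass
class RejectionReport:
    removed_ids: list
    kept_ids: list
    surviving_per_class: dict
    threshold_uv: float


def segment_epochs(continuous, events, pre_ms, post_ms, rate,
                   channel_names=None):
    """Cut a continuous recording into stimulus-locked trials.

    Each trial spans ``pre_ms`` before to ``post_ms`` after its event
    sample, i.e. ``T = round((pre_ms + post_ms)/1000 * rate) + 1`` samples
    with ``onset_index = round(pre_ms/1000 * rate)``. Events whose window
    does not fit in the recording are skipped with a warning and counted
    in the report.

    Returns ``(EpochSet, SegmentationReport)``.
    """
    continuous = np.asarray(continuous, dtype=np.float64)
    if continuous.ndim != 2:
        raise ValueError("continuous data must be channels x samples")
    n_ch, n_total = continuous.shape
    pre = int(round(pre_ms / 1000.0 * rate))
    post = int(round(post_ms / 1000.0 * rate))
    T = pre + post + 1

    trials, labels, skipped = [], [], []
    for i, (sample, label) in enumerate(events):
        start = sample - pre
        stop = sample + post + 1
        if start < 0 or stop > n_total:
            msg = (f"event {i + 1} at sample {sample}: window "
                   f"[{start}, {stop}) outside recording of {n_total} samples")
            warnings.warn(msg)
            skipped.append((i, sample, msg))
            continue
        trials.append(continuous[:, start:stop].copy())
        labels.append(label)

    if channel_names is None:
        channel_names = [f"ch{i + 1}" for i in range(n_ch)]
    epochs = EpochSet(
        trials=trials, labels=labels, channel_names=channel_names,
        sampling_rate=float(rate), onset_index=pre, band_tag="raw",
    )
    report = SegmentationReport(
        n_events=len(events), n_kept=len(trials), skipped=skipped,
    )
    assert not trials or epochs.n_samples == T
    return epochs, report


def bandpass_filter(epochs: EpochSet, band: BandDefinition,
                    order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass of every trial.

    The filter is applied forward-backward (``filtfilt``), preserving
    component latencies. Output ``band_tag`` is the band's name.
    """
    band.validate_for_rate(epochs.sampling_rate)
    sos = scipy.signal.butter(
        order, [band.low_hz, band.high_hz], btype="bandpass",
        fs=epochs.sampling_rate, output="sos",
    )
    # sosfiltfilt's default padding requirement
    padlen = 3 * (2 * sos.shape[0] + 1)
    if epochs.n_samples <= padlen:
        raise ValueError(
            f"trials have {epochs.n_samples} samples but the order-{order} "
            f"zero-phase filter needs more than {padlen}"
        )
    filtered = [
        scipy.signal.sosfiltfilt(sos, t, axis=1) for t in epochs.trials
    ]
    return epochs.with_trials(filtered, band_tag=band.name)


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 75.0):
    """Retain trials whose every sample lies within ``[-thr, +thr]`` (inclusive).

    Returns ``(surviving EpochSet, RejectionReport)``.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    kept, removed = [], []
    for i, trial in enumerate(epochs.trials):
        if np.max(np.abs(trial)) <= threshold_uv:
            kept.append(i)
        else:
            removed.append(i)
    surviving = epochs.subset(kept)
    per_class: dict = {}
    for lab in surviving.labels:
        per_class[lab] = per_class.get(lab, 0) + 1
    report = RejectionReport(
        removed_ids=removed, kept_ids=kept,
        surviving_per_class=per_class, threshold_uv=float(threshold_uv),
    )
    return surviving, report


def baseline_correct(epochs: EpochSet, baseline=None) -> EpochSet:
    """Subtract each channel's mean over the baseline range from the trial.

    ``baseline`` is a half-open ``(start_index, end_index)`` sample range;
    by default the pre-onset span ``(0, onset_index)``.
    """
    if baseline is None:
        baseline = (0, epochs.onset_index)
    start, stop = int(baseline[0]), int(baseline[1])
    if stop <= start:
        raise ValueError(f"empty baseline range [{start}, {stop})")
    if start < 0 or stop > epochs.onset_index:
        raise ValueError(
            f"baseline [{start}, {stop}) must lie within "
            f"[0, onset_index={epochs.onset_index}]"
        )
    corrected = [
        t - t[:, start:stop].mean(axis=1, keepdims=True)
        for t in epochs.trials
    ]
    return epochs.with_trials(corrected)


def component_windows(rate, onset_index, half_width=2,
                      table=None, n_samples=None) -> ComponentWindows:
    """Build the component sample windows from a latency table.

    Point components (scalar latency in ms) get a symmetric window of
    ``2*half_width + 1`` samples centered at the nominal latency; range
    components (``(start_ms, end_ms)``) get every sample whose latency
    falls in the inclusive ms range. Latencies are relative to stimulus
    onset; conversion is round-to-nearest sample.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if table is None:
        table = DEFAULT_COMPONENT_TABLE
    wins = []
    for name, spec in table.items():
        if np.isscalar(spec):
            center = onset_index + int(round(float(spec) / 1000.0 * rate))
            a, b = center - half_width, center + half_width + 1
        else:
            lo_ms, hi_ms = spec
            a = onset_index + int(round(float(lo_ms) / 1000.0 * rate))
            b = onset_index + int(round(float(hi_ms) / 1000.0 * rate)) + 1
        if a < 0:
            raise ValueError(f"component {name!r} starts before the trial ({a})")
        if n_samples is not None and b > n_samples:
            raise ValueError(
                f"component {name!r} window [{a}, {b}) exceeds trial length "
                f"{n_samples}"
            )
        wins.append((name, a, b))
    wins.sort(key=lambda w: w[1])
    return ComponentWindows(windows=tuple(wins))


def extract_combine(epochs: EpochSet, windows: ComponentWindows) -> EpochSet:
    """Concatenate the component window slices into a reduced trial matrix.

    Each ``N x T`` trial becomes ``N x T'`` where ``T'`` is the combined
    window length; labels and channel metadata are preserved, and
    ``onset_index`` is invalidated since the output samples are no longer
    contiguous time.
    """
    windows.validate_for_length(epochs.n_samples)
    idx = windows.indices()
    combined = [t[:, idx] for t in epochs.trials]
    return epochs.with_trials(combined, onset_index=ONSET_INVALID)
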