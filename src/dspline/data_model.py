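"""Core epoch data model.

An :class:`EpochSet` is an ordered, labeled collection of equally shaped
trial matrices (channels x samples, microvolts) plus the metadata needed
to interpret them: channel names, sampling rate, and the stimulus-onset
sample index. All pipeline stages consume and produce ``EpochSet``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EpochSet", "BandDefinition", "ONSET_INVALID", "DEFAULT_BANDS"]

#: Sentinel onset index used once trials are no longer contiguous time
#: (e.g. after component extraction/concatenation).
ONSET_INVALID = -1


@dataclass
class EpochSet:
    """Labeled collection of single-trial matrices.

    Parameters
    ----------
    trials : list of ndarray
        Each trial is an ``(n_channels, n_samples)`` float array in microvolts.
    labels : list of str
        Per-trial condition code. The label alphabet is open.
    channel_names : list of str
        One name per channel row.
    sampling_rate : float
        Sampling rate in Hz.
    onset_index : int
        0-based sample index of stimulus onset within each trial, or
        :data:`ONSET_INVALID` when trials are concatenated fragments.
    band_tag : str
        Identifier of the frequency band carried by this set.
    """

    trials: list
    labels: list
    channel_names: list
    sampling_rate: float
    onset_index: int = 0
    band_tag: str = "raw"

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, dtype=np.float64) for t in self.trials]
        self.labels = list(self.labels)
        self.channel_names = list(self.channel_names)
        self._validate()

    def _validate(self) -> None:
        if len(self.labels) != len(self.trials):
            raise ValueError(
                f"labels ({len(self.labels)}) and trials ({len(self.trials)}) "
                "must have equal length"
            )
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        n_ch = len(self.channel_names)
        for i, t in enumerate(self.trials):
            if t.ndim != 2:
                raise ValueError(f"trial {i + 1} is not a 2-D matrix (shape {t.shape})")
            if t.shape != self.trials[0].shape:
                raise ValueError(
                    f"trial {i + 1} has shape {t.shape}, expected "
                    f"{self.trials[0].shape} (all trials must share one shape)"
                )
            if n_ch and t.shape[0] != n_ch:
                raise ValueError(
                    f"trial {i + 1} has {t.shape[0]} channels but "
                    f"{n_ch} channel names were given"
                )
        if self.trials:
            T = self.trials[0].shape[1]
            if self.onset_index != ONSET_INVALID and not 0 <= self.onset_index < T:
                raise ValueError(
                    f"onset_index {self.onset_index} outside [0, {T})"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        if self.trials:
            return self.trials[0].shape[0]
        return len(self.channel_names)

    @property
    def n_samples(self) -> int:
        return self.trials[0].shape[1] if self.trials else 0

    @property
    def classes(self) -> list:
        """Distinct labels in order of first appearance."""
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def with_trials(self, trials, *, onset_index=None, band_tag=None) -> "EpochSet":
        """Copy of this set with new trial data, keeping labels/metadata."""
        return EpochSet(
            trials=trials,
            labels=list(self.labels),
            channel_names=list(self.channel_names),
            sampling_rate=self.sampling_rate,
            onset_index=self.onset_index if onset_index is None else onset_index,
            band_tag=self.band_tag if band_tag is None else band_tag,
        )

    def subset(self, indices) -> "EpochSet":
        """New EpochSet restricted to the given trial indices (in order)."""
        indices = list(indices)
        return EpochSet(
            trials=[self.trials[i] for i in indices],
            labels=[self.labels[i] for i in indices],
            channel_names=list(self.channel_names),
            sampling_rate=self.sampling_rate,
            onset_index=self.onset_index,
            band_tag=self.band_tag,
        )


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"band {self.name!r}: need 0 < low ({self.low_hz}) "
                f"< high ({self.high_hz})"
            )

    def validate_for_rate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if self.high_hz > nyq:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high_hz} Hz exceeds "
                f"Nyquist {nyq} Hz"
            )


#: Conventional band edges consistent with a 1-30 Hz broadband analysis.
DEFAULT_BANDS = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "whole": BandDefinition("whole", 1.0, 30.0),
}
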