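"""Synthetic three-condition ERP epochs with known discriminant structure.

Each trial is 1/f-colored background noise plus class-dependent component
effects: Gaussian-windowed bumps centered at the component latencies,
scaled by a fixed spatial topography. The generator also emits a
:class:`GroundTruth` (planted mean differences, analytic discriminant
directions, artifact trial ids) so recovery and rejection behavior can be
tested end to end without any recorded data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .data_model import EpochSet
from .preprocess import ComponentWindows, component_windows

__all__ = [
    "ComponentEffect",
    "SimConfig",
    "GroundTruth",
    "paper_preset",
    "small_preset",
    "generate",
    "analytic_direction",
    "default_windows",
]


@dataclass(frozen=True)
class ComponentEffect:
    """One planted ERP component.

    ``latency_ms`` is a scalar (point component, 5-sample window) or an
    inclusive ``(start_ms, end_ms)`` range. ``amplitudes`` maps class
    label to peak amplitude in microvolts. ``topography`` is a unit
    vector over channels. ``jitter_sd_ms`` is the SD of per-trial
    Gaussian latency jitter.
    """

    name: str
    latency_ms: object
    amplitudes: dict
    topography: np.ndarray
    jitter_sd_ms: float = 0.0
    carrier_hz: float = 0.0      # optional oscillatory carrier under the bump
    width_ms: float | None = None  # bump FWHM-ish span; default: window span

    def __post_init__(self):
        topo = np.asarray(self.topography, dtype=np.float64)
        nrm = np.linalg.norm(topo)
        if nrm == 0:
            raise ValueError(f"component {self.name}: zero topography")
        object.__setattr__(self, "topography", topo / nrm)
        for lab, a in self.amplitudes.items():
            if not np.isfinite(a):
                raise ValueError(f"component {self.name}: amplitude {lab}={a}")
        if self.carrier_hz and self.jitter_sd_ms:
            raise ValueError(
                f"component {self.name}: latency jitter with a carrier has "
                "no closed-form expected signal; set one of them to 0"
            )


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic epoch set."""

    n_channels: int = 60
    sampling_rate: float = 500.0
    pre_ms: float = 200.0
    post_ms: float = 800.0
    trials_per_class: int = 98
    class_labels: tuple = ("Ug", "Tg", "Sc")
    components: tuple = ()
    noise_exponent: float = 1.0
    noise_rms_uv: float = 5.0
    artifact_rate: float = 0.0
    artifact_amplitude_uv: float = 120.0
    half_width: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round((self.pre_ms + self.post_ms) / 1000.0
                         * self.sampling_rate)) + 1

    @property
    def onset_index(self) -> int:
        return int(round(self.pre_ms / 1000.0 * self.sampling_rate))

    @property
    def latency_table(self) -> dict:
        return {c.name: c.latency_ms for c in self.components}


@dataclass
class GroundTruth:
    """What was planted: signals, analytic directions, artifact trials."""

    artifact_ids: list
    class_signals: dict          # label -> N x T expected signal
    pair_mean_diff: dict         # (a, b) -> vector in component space
    pair_directions: dict        # (a, b) -> unit analytic direction


def _axis_topo(n_channels: int, idx: int, spread: int = 3) -> np.ndarray:
    """Smooth deterministic unit topography peaking near channel ``idx``."""
    x = np.arange(n_channels, dtype=np.float64)
    topo = np.exp(-0.5 * ((x - idx) / max(spread, 1e-9)) ** 2)
    return topo / np.linalg.norm(topo)


def _default_components(n_channels: int) -> tuple:
    """Five components with class-dependent amplitudes and distinct topographies."""

    def topo(frac):
        return _axis_topo(n_channels, int(frac * (n_channels - 1)),
                          spread=max(n_channels // 8, 1))

    # point components get realistic ~60-100 ms deflection widths so their
    # energy survives a 1-30 Hz band-pass; extraction windows stay narrow
    return (
        ComponentEffect("N70", 70.0, {"Ug": -15.0, "Tg": -9.0, "Sc": -4.5},
                        topo(0.15), width_ms=60.0),
        ComponentEffect("P120", 120.0, {"Ug": 9.0, "Tg": 16.5, "Sc": 6.0},
                        topo(0.35), width_ms=80.0),
        ComponentEffect("N170_P200", (170.0, 200.0),
                        {"Ug": -12.0, "Tg": -6.0, "Sc": -16.5}, topo(0.55),
                        width_ms=80.0),
        ComponentEffect("P300", 300.0, {"Ug": 18.0, "Tg": 10.5, "Sc": 6.0},
                        topo(0.75), width_ms=120.0),
        ComponentEffect("P400_700", (400.0, 700.0),
                        {"Ug": 13.5, "Tg": 7.5, "Sc": 3.0}, topo(0.9)),
    )


def paper_preset(seed: int = 0, **overrides) -> SimConfig:
    """60 channels, 500 Hz, 98 trials per condition."""
    cfg = SimConfig(n_channels=60, trials_per_class=98, seed=seed,
                    components=_default_components(60))
    return replace(cfg, **overrides) if overrides else cfg


def small_preset(seed: int = 0, **overrides) -> SimConfig:
    """8 channels, 30 trials per condition: fast enough for CI."""
    cfg = SimConfig(n_channels=8, trials_per_class=30, seed=seed,
                    noise_rms_uv=4.0, components=_default_components(8))
    return replace(cfg, **overrides) if overrides else cfg


def recovery_preset(seed: int = 0, **overrides) -> SimConfig:
    """Two-class, low-dimensional config for direction-recovery checks.

    D = 18 (2 channels x three 3-sample point windows) keeps the sample
    within-class scatter well estimated at n = 200 trials, so the fitted
    direction can be compared against the analytic noise-whitened one.
    """
    topo = [_axis_topo(2, i, spread=1) for i in (0, 1)]
    comps = (
        ComponentEffect("N70", 70.0, {"Ug": -5.0, "Sc": -1.5}, topo[0]),
        ComponentEffect("P120", 120.0, {"Ug": 3.0, "Sc": 5.0}, topo[1]),
        ComponentEffect("P300", 300.0, {"Ug": 6.0, "Sc": 2.0}, topo[0]),
    )
    cfg = SimConfig(
        n_channels=2, trials_per_class=100, class_labels=("Ug", "Sc"),
        components=comps, noise_rms_uv=1.0, half_width=1, seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def multiband_preset(seed: int = 0, **overrides) -> SimConfig:
    """Two-class config whose discriminative signal is split across bands.

    Four disjoint range components carry independent class contrasts at
    carriers inside theta, alpha and beta plus one slow (delta) envelope,
    so no single frequency band sees all of the separating information —
    the setting where feature-level band fusion should win.
    """
    n = 8

    def topo(i):
        return _axis_topo(n, i, spread=2)

    comps = (
        ComponentEffect("W_theta", (50.0, 230.0),
                        {"Ug": 4.0, "Sc": 0.0}, topo(1), carrier_hz=6.0),
        ComponentEffect("W_alpha", (240.0, 420.0),
                        {"Ug": 0.0, "Sc": 4.0}, topo(3), carrier_hz=10.0),
        ComponentEffect("W_beta", (430.0, 610.0),
                        {"Ug": 4.0, "Sc": 0.0}, topo(5), carrier_hz=20.0),
        ComponentEffect("W_delta", (620.0, 790.0),
                        {"Ug": 0.0, "Sc": 4.0}, topo(7)),
    )
    cfg = SimConfig(
        n_channels=n, trials_per_class=40, class_labels=("Ug", "Sc"),
        components=comps, noise_rms_uv=5.0, seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def default_windows(config: SimConfig) -> ComponentWindows:
    return component_windows(
        config.sampling_rate, config.onset_index,
        half_width=config.half_width, table=config.latency_table,
        n_samples=config.n_samples,
    )


# -- noise model ---------------------------------------------------------------

def _noise_shaper(config: SimConfig) -> np.ndarray:
    """Amplitude response over rfft bins giving unit-RMS 1/f noise."""
    T = config.n_samples
    freqs = np.fft.rfftfreq(T, d=1.0 / config.sampling_rate)
    h = np.zeros_like(freqs)
    h[1:] = freqs[1:] ** (-config.noise_exponent / 2.0)
    # calibrate so shaped white noise has unit RMS
    probe = np.eye(T)
    S = np.fft.irfft(h[None, :] * np.fft.rfft(probe, axis=1), n=T, axis=1)
    rms = np.sqrt(np.mean(np.sum(S ** 2, axis=0)))
    return h / rms


def _shape_noise(white: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Apply the coloring operator along the last axis."""
    T = white.shape[-1]
    return np.fft.irfft(h * np.fft.rfft(white, axis=-1), n=T, axis=-1)


def noise_time_covariance(config: SimConfig) -> np.ndarray:
    """Exact single-channel T x T covariance implied by the noise model."""
    T = config.n_samples
    h = _noise_shaper(config) * config.noise_rms_uv
    S = _shape_noise(np.eye(T), h)  # rows: operator applied to basis vectors
    # x = S^T w  =>  Cov = S^T S
    return S.T @ S


# -- signal model --------------------------------------------------------------

def _bump_params(config: SimConfig, comp: ComponentEffect,
                 windows: ComponentWindows):
    """Center (absolute sample) and SD (samples) of a component's bump."""
    for name, a, b in windows.windows:
        if name == comp.name:
            center = 0.5 * (a + b - 1)
            if comp.width_ms is not None:
                span = comp.width_ms / 1000.0 * config.sampling_rate
            else:
                span = b - a
            sigma = span / 4.0
            return center, sigma
    raise KeyError(comp.name)


def expected_class_signal(config: SimConfig, label,
                          windows: ComponentWindows) -> np.ndarray:
    """Expected N x T signal of a class (latency jitter integrated out)."""
    T = config.n_samples
    t = np.arange(T, dtype=np.float64)
    sig = np.zeros((config.n_channels, T))
    for comp in config.components:
        center, sigma = _bump_params(config, comp, windows)
        jit = comp.jitter_sd_ms / 1000.0 * config.sampling_rate
        var = sigma ** 2 + jit ** 2
        shrink = sigma / np.sqrt(var)
        bump = shrink * np.exp(-0.5 * (t - center) ** 2 / var)
        if comp.carrier_hz:
            bump = bump * np.cos(
                2.0 * np.pi * comp.carrier_hz
                * (t - center) / config.sampling_rate)
        amp = comp.amplitudes.get(label, 0.0)
        sig += amp * comp.topography[:, None] * bump[None, :]
    return sig


def generate(config: SimConfig, windows: ComponentWindows | None = None):
    """Draw an :class:`EpochSet` and its :class:`GroundTruth`.

    Deterministic under ``config.seed``. Trials are generated class by
    class in ``class_labels`` order.
    """
    rng = np.random.default_rng(config.seed)
    if windows is None:
        windows = default_windows(config)
    T = config.n_samples
    N = config.n_channels
    t = np.arange(T, dtype=np.float64)
    h = _noise_shaper(config) * config.noise_rms_uv

    trials, labels = [], []
    for label in config.class_labels:
        for _ in range(config.trials_per_class):
            noise = _shape_noise(rng.standard_normal((N, T)), h)
            sig = np.zeros((N, T))
            for comp in config.components:
                center, sigma = _bump_params(config, comp, windows)
                jit = comp.jitter_sd_ms / 1000.0 * config.sampling_rate
                c = center + (rng.normal(0.0, jit) if jit > 0 else 0.0)
                bump = np.exp(-0.5 * (t - c) ** 2 / sigma ** 2)
                if comp.carrier_hz:
                    bump = bump * np.cos(
                        2.0 * np.pi * comp.carrier_hz
                        * (t - c) / config.sampling_rate)
                amp = comp.amplitudes.get(label, 0.0)
                sig += amp * comp.topography[:, None] * bump[None, :]
            trials.append(noise + sig)
            labels.append(label)

    n = len(trials)
    n_artifact = int(round(config.artifact_rate * n))
    artifact_ids = sorted(
        int(i) for i in rng.choice(n, size=n_artifact, replace=False)
    )
    # artifacts are sustained slow excursions (not single-sample spikes)
    # so they also survive a 1-30 Hz band-pass, like real movement/EOG
    art_sigma = 0.030 * config.sampling_rate
    for i in artifact_ids:
        ch = int(rng.integers(N))
        lo = config.onset_index + int(3 * art_sigma)
        hi = T - int(3 * art_sigma)
        center = int(rng.integers(lo, max(hi, lo + 1)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        bump = np.exp(-0.5 * (t - center) ** 2 / art_sigma ** 2)
        trials[i][ch] += sign * config.artifact_amplitude_uv * bump

    epochs = EpochSet(
        trials=trials, labels=labels,
        channel_names=[f"ch{i + 1}" for i in range(N)],
        sampling_rate=config.sampling_rate,
        onset_index=config.onset_index, band_tag="raw",
    )

    class_signals = {
        lab: expected_class_signal(config, lab, windows)
        for lab in config.class_labels
    }
    idx = windows.indices()
    pair_mean_diff, pair_directions = {}, {}
    for i, a in enumerate(config.class_labels):
        for b in config.class_labels[i + 1:]:
            diff = (class_signals[a] - class_signals[b])[:, idx].reshape(-1)
            pair_mean_diff[(a, b)] = diff
            pair_directions[(a, b)] = analytic_direction(
                config, (a, b), windows,
            )

    truth = GroundTruth(
        artifact_ids=artifact_ids, class_signals=class_signals,
        pair_mean_diff=pair_mean_diff, pair_directions=pair_directions,
    )
    return epochs, truth


def analytic_direction(config: SimConfig, pair, windows: ComponentWindows):
    """Noise-whitened planted mean-difference direction in component space.

    Solves ``Sigma w = p`` where ``p`` is the expected class-mean
    difference (vectorized over the component windows, channel-major)
    and ``Sigma = I_channels (x) R`` with ``R`` the noise model's time
    covariance restricted to the selected samples. Returned unit-norm.
    Latency jitter enters the mean (smoothing) but not the covariance.
    """
    a, b = pair
    if a not in config.class_labels or b not in config.class_labels:
        raise ValueError(f"pair {pair} not in class labels {config.class_labels}")
    idx = windows.indices()
    sig_a = expected_class_signal(config, a, windows)
    sig_b = expected_class_signal(config, b, windows)
    p = (sig_a - sig_b)[:, idx]                  # N x T'
    if not np.any(p):
        warnings.warn(f"classes {a!r} and {b!r} have identical specs; "
                      "analytic direction is zero")
        return np.zeros(p.size)
    R = noise_time_covariance(config)[np.ix_(idx, idx)]
    R = R + (1e-10 * np.trace(R) / len(idx)) * np.eye(len(idx))
    w = scipy.linalg.solve(R, p.T, assume_a="pos").T    # per-channel solves
    w = w.reshape(-1)
    return w / np.linalg.norm(w)
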