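"""Synthetic datasets with the correlation structure latent-tree splits exploit.

Three generators, matching the three neighbourhood modes:

* :func:`simulate_spectra` — 1D spectra built from Lorentzian/Gaussian
  multiplets, where the presence/intensity of designated multiplets
  distinguishes two classes.  The default layout places four discriminative
  multiplets proportionally at the positions of ethanol's two multiplets
  (1.17-1.20 and 3.64-3.68 ppm) and uracil's two doublets (5.79-5.81 and
  7.53-7.56 ppm) on a 0-10 unit axis, with three non-discriminative
  distractor multiplets in between.
* :func:`simulate_cyclic_traces` — multi-channel cyclic traces (cardiac-cycle
  style) where class 1 carries an amplitude change inside a time window on
  designated channels; features are channel-major to match the cyclic
  neighbourhood construction.
* :func:`simulate_point_cloud` — per-sample jittered 3D point clouds with a
  smooth per-point signal and a contiguous discriminative region, feeding the
  spatial-consensus neighbourhood construction.

Every generator returns the data together with a ground-truth mask of the
discriminative features, so importance outputs can be scored by peak
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PeakSpec",
    "SpectrumSimConfig",
    "GroundTruth",
    "default_spectrum_config",
    "simulate_spectra",
    "simulate_cyclic_traces",
    "simulate_point_cloud",
    "add_noisy_feature",
]


@dataclass(frozen=True)
class PeakSpec:
    """One multiplet: sub-peaks centred ``spacing`` points apart.

    ``class_effect`` multiplies the amplitude for class-1 samples; 1.0 marks
    a non-discriminative (distractor) multiplet.
    """

    center: float
    width: float
    amplitude: float
    shape: str = "lorentzian"  # or "gaussian"
    class_effect: float = 1.0
    n_subpeaks: int = 1
    spacing: float = 0.0

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("peak width must be >= 1 point")
        if self.amplitude <= 0:
            raise ValueError("peak amplitude must be > 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def subpeak_centers(self) -> np.ndarray:
        offs = (np.arange(self.n_subpeaks) - (self.n_subpeaks - 1) / 2) * self.spacing
        return self.center + offs


@dataclass(frozen=True)
class GroundTruth:
    """Boolean mask of class-discriminative feature points.

    ``flank_k`` is the number of off-peak points per peak later designated as
    true negatives in the coverage evaluation.
    """

    mask: np.ndarray
    flank_k: int = 0


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Generative description of a synthetic 1D spectrum cohort."""

    n_features: int = 1000
    n_samples_per_class: int = 100
    peaks: tuple[PeakSpec, ...] = ()
    baseline_sd: float = 0.3
    peak_jitter_sd: float = 0.0
    amplitude_sd: float = 0.1  # per-sample relative scatter of each multiplet
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if self.n_samples_per_class < 1:
            raise ValueError("n_samples_per_class must be >= 1")
        if self.baseline_sd < 0 or self.peak_jitter_sd < 0 or self.amplitude_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        for p in self.peaks:
            centers = p.subpeak_centers()
            if centers.min() < 0 or centers.max() >= self.n_features:
                raise ValueError(f"peak at {p.center} lies outside [0, {self.n_features})")


def default_spectrum_config(
    n_features: int = 1000,
    n_samples_per_class: int = 100,
    rng_seed: int = 0,
    class_effect: float = 1.6,
    baseline_sd: float = 0.3,
) -> SpectrumSimConfig:
    """The default two-compound benchmark.

    Four discriminative multiplets at 11.85%, 36.6%, 58.0% and 75.45% of the
    axis (the ethanol/uracil multiplet positions scaled from a 10-unit ppm
    axis), each a triplet of Lorentzian sub-peaks (width 10, spacing 10), plus
    three distractor multiplets that carry no class signal.
    """
    pos = [0.1185, 0.366, 0.580, 0.7545]
    width = max(1.0, 10 * n_features / 1000)
    discriminative = tuple(
        PeakSpec(
            center=p * n_features,
            width=width,
            amplitude=1.0,
            class_effect=class_effect,
            n_subpeaks=3,
            spacing=10 * n_features / 1000,
        )
        for p in pos
    )
    distractors = tuple(
        PeakSpec(
            center=p * n_features,
            width=width,
            amplitude=0.8,
            n_subpeaks=2,
            spacing=12 * n_features / 1000,
        )
        for p in (0.25, 0.48, 0.88)
    )
    return SpectrumSimConfig(
        n_features=n_features,
        n_samples_per_class=n_samples_per_class,
        peaks=discriminative + distractors,
        baseline_sd=baseline_sd,
        rng_seed=rng_seed,
    )


def _peak_profile(axis: np.ndarray, center: float, width: float, shape: str) -> np.ndarray:
    u = (axis - center) / width
    if shape == "lorentzian":
        return 1.0 / (1.0 + u * u)
    return np.exp(-0.5 * u * u)


def _truth_mask(cfg: SpectrumSimConfig) -> np.ndarray:
    mask = np.zeros(cfg.n_features, dtype=bool)
    idx = np.arange(cfg.n_features)
    for p in cfg.peaks:
        if p.class_effect == 1.0:
            continue
        for c in p.subpeak_centers():
            mask |= np.abs(idx - c) <= p.width
    return mask


def simulate_spectra(cfg: SpectrumSimConfig) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Simulate a two-class spectral cohort from ``cfg``.

    Each sample is the sum of its multiplet profiles (class-1 samples scale
    discriminative multiplets by their ``class_effect``) plus i.i.d. baseline
    noise; per-sample multiplet amplitude scatter and optional centre jitter
    make in-peak points correlated the way real spectra are.  Returns
    ``(X, y, truth)`` with ``y`` holding ``n_samples_per_class`` zeros then
    ones and ``truth.mask`` marking points within one width of any
    discriminative sub-peak centre.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    n = 2 * cfg.n_samples_per_class
    y = np.repeat([0, 1], cfg.n_samples_per_class)
    axis = np.arange(cfg.n_features, dtype=float)
    X = rng.normal(0.0, cfg.baseline_sd, size=(n, cfg.n_features))
    for p in cfg.peaks:
        # per-sample multiplet-level randomness (shared by its sub-peaks)
        amp_scatter = 1.0 + cfg.amplitude_sd * rng.standard_normal(n)
        jitter = (
            cfg.peak_jitter_sd * rng.standard_normal(n)
            if cfg.peak_jitter_sd > 0
            else np.zeros(n)
        )
        effect = np.where(y == 1, p.class_effect, 1.0)
        amp = p.amplitude * effect * np.clip(amp_scatter, 0.0, None)
        for c in p.subpeak_centers():
            for s in range(n):
                X[s] += amp[s] * _peak_profile(axis, c + jitter[s], p.width, p.shape)
    truth = GroundTruth(mask=_truth_mask(cfg))
    return X, y, truth


def simulate_cyclic_traces(
    n_channels: int = 3,
    n_timepoints: int = 120,
    event_window: tuple[int, int] = (40, 60),
    n_per_class: int = 50,
    noise_sd: float = 0.3,
    seed: int = 0,
    event_channels: tuple[int, ...] = (0,),
    event_amplitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two-class cyclic multi-channel traces (cardiac-cycle style).

    All channels share one dominant deflection at 30% of the cycle whose
    amplitude and timing vary per sample, mimicking the common electrical
    source behind multi-lead recordings; class-1 samples additionally carry a
    bump of ``event_amplitude`` inside ``event_window`` on
    ``event_channels``.  Feature index = channel * n_timepoints + t, matching
    the cyclic neighbourhood indexing.  ``truth.mask`` is true exactly on the
    window features of the event channels.
    """
    lo, hi = event_window
    if not (0 <= lo < hi <= n_timepoints):
        raise ValueError("event_window must lie within the cycle")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.repeat([0, 1], n_per_class)
    t = np.arange(n_timepoints, dtype=float)
    # one dominant deflection (QRS-like) shared by all channels, whose
    # per-sample amplitude and timing vary jointly — so the same time point
    # is correlated across channels while distant time points are not
    t0 = 0.3 * n_timepoints
    width = n_timepoints / 15
    chan_amp = 1.0 / (1.0 + 0.4 * np.arange(n_channels))
    bump = np.zeros(n_timepoints)
    window = np.arange(lo, hi)
    bump[window] = np.sin(np.linspace(0.0, np.pi, hi - lo))
    X = np.empty((n, n_channels * n_timepoints))
    mask = np.zeros(n_channels * n_timepoints, dtype=bool)
    for c in event_channels:
        if event_amplitude != 0:
            mask[c * n_timepoints + window] = True
    for s in range(n):
        gain = 1.0 + 0.2 * rng.standard_normal()
        shift = 0.5 * width * rng.standard_normal()
        wave = np.exp(-0.5 * ((t - t0 - shift) / width) ** 2)
        traces = gain * chan_amp[:, None] * wave[None, :]
        if y[s] == 1:
            for c in event_channels:
                traces[c] += event_amplitude * bump
        traces += rng.normal(0.0, noise_sd, size=traces.shape)
        X[s] = traces.ravel()
    return X, y, GroundTruth(mask=mask)


def simulate_point_cloud(
    n_points: int = 60,
    n_per_class: int = 30,
    region_radius: float = 0.6,
    effect: float = 1.0,
    coord_jitter_sd: float = 0.02,
    seed: int = 0,
    noise_sd: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Two-class signals on a jittered 3D point cloud (mesh-like).

    A template cloud is drawn on the unit sphere; per-sample coordinates are
    the template plus Gaussian jitter (feeding the spatial-consensus
    neighbourhood construction).  The per-point feature value is a smooth
    random field plus noise; class-1 samples get ``effect`` added on the
    contiguous region of points within ``region_radius`` of a template point.
    Returns ``(coords_blocks, X, y, truth)`` with coords_blocks of shape
    (n_samples, n_points, 3).
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.repeat([0, 1], n_per_class)
    template = rng.standard_normal((n_points, 3))
    template /= np.linalg.norm(template, axis=1, keepdims=True)
    anchor = template[0]
    region = np.linalg.norm(template - anchor, axis=1) <= region_radius
    if effect != 0 and not region.any():
        raise ValueError("region_radius captures no points")
    coords = template[None, :, :] + rng.normal(0.0, coord_jitter_sd, size=(n, n_points, 3))
    # smooth field: value correlated with position via random linear map
    basis = rng.standard_normal((3, 1))
    X = (template @ basis).ravel()[None, :] + rng.normal(0.0, noise_sd, size=(n, n_points))
    X[y == 1] += effect * region[None, :].astype(float)[0]
    mask = region if effect != 0 else np.zeros(n_points, dtype=bool)
    return coords, X, y, GroundTruth(mask=mask)


def add_noisy_feature(
    X: np.ndarray,
    y: np.ndarray,
    index: int,
    noise_sd: float = 2.0,
    class_effect: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Replace one feature with an isolated 'important but noisy' column.

    The column carries a class offset of ``class_effect`` buried in Gaussian
    noise of ``noise_sd`` — the kind of single high-variance feature a
    single-feature splitter can latch onto, but whose local neighbourhood
    carries no coherent signal.  Returns a modified copy of X.
    """
    X = np.array(X, copy=True)
    rng = np.random.default_rng(seed)
    X[:, index] = class_effect * (np.asarray(y) == 1) + rng.normal(
        0.0, noise_sd, size=X.shape[0]
    )
    return X
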