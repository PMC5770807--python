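"""Synthetic source-space dataset generator.

Emulates the statistical structure the downstream analysis assumes: per
subject, a vertices x time x trials array for 6 stimuli x 2 sections, with
region-confined evoked effects (stimulus-specific early activity,
category-binding windows, supra-categorical late activity, monotone
repetition amplitude trends) added on i.i.d. Gaussian noise, plus an
optional spatial-leakage mixing step standing in for inverse-solution blur.

Every draw is deterministic given the configuration seed; a ground-truth
manifest records which regions, time bins and conditions carry each effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import convolve1d

from . import design
from ._rng import child_rng
from .atlas import Parcellation, build_synthetic_parcellation

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "SourceEpochs",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_subject",
    "apply_spatial_leakage",
]

EFFECT_KINDS = ("stimulus_specific", "category_binding", "supra_categorical", "repetition_trend")


@dataclass(frozen=True)
class EffectSpec:
    """One injected effect.

    kind
        ``stimulus_specific``: each stimulus gets its own random spatial
        loading, identical across sections (what a "stimulus recognizer"
        model RDM should recover).
        ``category_binding`` / ``supra_categorical``: all exemplars of
        ``category`` share one loading (plus small exemplar jitter); other
        stimuli get nothing (creates within-category similarity).
        ``repetition_trend``: a category-binding-shaped template whose
        per-trial amplitude varies linearly with the trial's sequential
        segment (1..10) within its section.
    target_regions
        region indices the effect is confined to.
    window_ms
        [start, end] of the temporal envelope (raised-cosine bump padded by
        half a time step, so every bin inside the window carries signal).
    amplitude
        peak template amplitude, in the same arbitrary units as the noise sd.
    trend_slope
        amplitude units per segment; only used by ``repetition_trend``.
    exemplar_jitter
        relative magnitude of the exemplar-specific loading perturbation for
        category-shaped effects.
    """

    kind: str
    target_regions: tuple[int, ...]
    window_ms: tuple[float, float]
    amplitude: float
    category: str = "all"
    trend_slope: float = 0.0
    exemplar_jitter: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.category not in design.CATEGORY_STIMULI:
            raise ValueError(f"unknown category {self.category!r}")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.window_ms[1] < self.window_ms[0]:
            raise ValueError("window_ms must be [start, end] with start <= end")

    @property
    def stimuli(self) -> tuple[int, ...]:
        return design.CATEGORY_STIMULI[self.category]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the simulated experiment.

    Defaults mirror the full study design the pipeline assumes: 22 subjects,
    82 regions, two sections of 80 presentations per stimulus, epochs
    -100..700 ms at 10 ms resolution. Smaller configurations are used for
    demos and tests.
    """

    n_subjects: int = 22
    n_regions: int = 82
    vertices_per_region: int | tuple[int, int] = 10
    n_trials_per_condition: int = 80
    epoch_ms: tuple[float, float] = (-100.0, 700.0)
    step_ms: float = 10.0
    noise_sd: float = 1.0
    noise_smooth_ms: float = 0.0
    leakage_width: float = 0.0
    effects: tuple[EffectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if self.step_ms <= 0:
            raise ValueError("step_ms must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for eff in self.effects:
            a, b = eff.window_ms
            if a < self.epoch_ms[0] or b > self.epoch_ms[1]:
                raise ValueError(
                    f"effect window {eff.window_ms} outside epoch {self.epoch_ms}"
                )

    @property
    def time_ms(self) -> np.ndarray:
        n = int(round((self.epoch_ms[1] - self.epoch_ms[0]) / self.step_ms)) + 1
        return self.epoch_ms[0] + self.step_ms * np.arange(n)


@dataclass
class SourceEpochs:
    """Vertices x time x trials data with per-trial condition labels."""

    data: np.ndarray  # (n_vertices, n_times, n_trials)
    time_ms: np.ndarray  # (n_times,)
    stimulus: np.ndarray  # (n_trials,) int 1..6
    section: np.ndarray  # (n_trials,) int 1..2
    presentation_order: np.ndarray  # (n_trials,) 1-based position within (stimulus, section)

    def __post_init__(self) -> None:
        v, t, n = self.data.shape
        if self.time_ms.shape != (t,):
            raise ValueError("time_ms length mismatch")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")
        for name in ("stimulus", "section", "presentation_order"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"label {name!r} length mismatch")
        for stim in np.unique(self.stimulus):
            for sec in np.unique(self.section):
                order = self.presentation_order[(self.stimulus == stim) & (self.section == sec)]
                if order.size and not np.array_equal(np.sort(order), np.arange(1, order.size + 1)):
                    raise ValueError(
                        f"presentation_order is not a permutation for condition ({stim}, {sec})"
                    )

    @property
    def group(self) -> np.ndarray:
        return np.array([design.STIMULUS_GROUP[int(s)] for s in self.stimulus])

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def condition_trials(self, stimulus: int, section: int) -> np.ndarray:
        return np.flatnonzero((self.stimulus == stimulus) & (self.section == section))


@dataclass(frozen=True)
class RealizedEffect:
    """Ground-truth record of one injected effect."""

    kind: str
    regions: tuple[int, ...]
    window_ms: tuple[float, float]
    window_bins: tuple[int, ...]  # time-bin indices with nonzero envelope
    stimuli: tuple[int, ...]
    amplitude: float
    trend_slope: float
    segment_amplitudes: tuple[float, ...]  # per 1..10 segment (trend effects)


@dataclass(frozen=True)
class GroundTruth:
    effects: tuple[RealizedEffect, ...]


@dataclass(frozen=True)
class SimulatedDataset:
    subjects: list
    parcellation: Parcellation
    ground_truth: GroundTruth
    config: SimulationConfig


def temporal_envelope(time_ms: np.ndarray, window_ms, step_ms: float) -> np.ndarray:
    """Raised-cosine bump covering ``window_ms``, half-a-bin padded.

    sin(pi * x) over the window stretched by step/2 at each edge: smooth,
    band-limited (like 24 Hz low-passed evoked data), strictly positive on
    every bin inside the window and zero outside it.
    """
    a, b = window_ms
    h = step_ms / 2.0
    span = (b - a) + 2.0 * h
    x = (time_ms - a + h) / span
    env = np.where((time_ms >= a - 1e-9) & (time_ms <= b + 1e-9), np.sin(np.pi * np.clip(x, 0, 1)), 0.0)
    return env


def _effect_loadings(eff: EffectSpec, n_verts: int, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Per-stimulus unit spatial loading over one region's vertices."""

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    loadings: dict[int, np.ndarray] = {}
    if eff.kind == "stimulus_specific":
        for s in eff.stimuli:
            loadings[s] = unit(rng.standard_normal(n_verts))
    else:
        shared = unit(rng.standard_normal(n_verts))
        for s in eff.stimuli:
            jitter = eff.exemplar_jitter * unit(rng.standard_normal(n_verts))
            loadings[s] = unit(shared + jitter)
    return loadings


def realize_ground_truth(config: SimulationConfig) -> GroundTruth:
    time_ms = config.time_ms
    realized = []
    for eff in config.effects:
        env = temporal_envelope(time_ms, eff.window_ms, config.step_ms)
        bins = tuple(int(i) for i in np.flatnonzero(env > 0))
        if eff.kind == "repetition_trend":
            segs = tuple(
                float(eff.amplitude + eff.trend_slope * s)
                for s in range(1, design.N_PSEUDO_TRIALS + 1)
            )
        else:
            segs = tuple([float(eff.amplitude)] * design.N_PSEUDO_TRIALS)
        realized.append(
            RealizedEffect(
                kind=eff.kind,
                regions=tuple(eff.target_regions),
                window_ms=tuple(eff.window_ms),
                window_bins=bins,
                stimuli=eff.stimuli,
                amplitude=eff.amplitude,
                trend_slope=eff.trend_slope,
                segment_amplitudes=segs,
            )
        )
    return GroundTruth(effects=tuple(realized))


def simulate_subject(
    config: SimulationConfig, subject: int, parcellation: Parcellation | None = None
) -> SourceEpochs:
    """Simulate one subject's epochs (deterministic in (config.seed, subject))."""
    if parcellation is None:
        parcellation = simulation_parcellation(config)
    time_ms = config.time_ms
    n_t = time_ms.size
    n_cond_trials = config.n_trials_per_condition
    n_trials = design.N_STIMULI * design.N_SECTIONS * n_cond_trials

    stimulus = np.empty(n_trials, dtype=int)
    section = np.empty(n_trials, dtype=int)
    order = np.empty(n_trials, dtype=int)
    i = 0
    rng_perm = child_rng(config.seed, "order", subject)
    for sec in (1, 2):
        for stim in range(1, design.N_STIMULI + 1):
            sl = slice(i, i + n_cond_trials)
            stimulus[sl] = stim
            section[sl] = sec
            order[sl] = rng_perm.permutation(n_cond_trials) + 1
            i += n_cond_trials

    rng_noise = child_rng(config.seed, "noise", subject)
    data = rng_noise.standard_normal((parcellation.n_vertices, n_t, n_trials)) * config.noise_sd
    if config.noise_smooth_ms > 0 and config.noise_sd > 0:
        half = max(1, int(round(config.noise_smooth_ms / config.step_ms / 2)))
        kernel = np.hanning(2 * half + 3)[1:-1]
        kernel /= np.linalg.norm(kernel)  # preserve marginal sd
        data = convolve1d(data, kernel, axis=1, mode="reflect")

    segment_id = np.empty(n_trials, dtype=int)
    for stim in range(1, design.N_STIMULI + 1):
        for sec in (1, 2):
            idx = np.flatnonzero((stimulus == stim) & (section == sec))
            segment_id[idx] = design.segment_of_position(order[idx], idx.size)

    for k, eff in enumerate(config.effects):
        env = temporal_envelope(time_ms, eff.window_ms, config.step_ms)
        rng_eff = child_rng(config.seed, "effect", k, subject)
        for region in eff.target_regions:
            verts = parcellation.vertices_of(int(region))
            loadings = _effect_loadings(eff, verts.size, rng_eff)
            for stim in eff.stimuli:
                idx = np.flatnonzero(stimulus == stim)
                if eff.kind == "repetition_trend":
                    amps = eff.amplitude + eff.trend_slope * segment_id[idx]
                else:
                    amps = np.full(idx.size, eff.amplitude)
                template = loadings[stim][:, None] * env[None, :]  # (v, t)
                data[np.ix_(verts, np.arange(n_t), idx)] += template[:, :, None] * amps[None, None, :]

    epochs = SourceEpochs(
        data=data, time_ms=time_ms, stimulus=stimulus, section=section, presentation_order=order
    )
    if config.leakage_width > 0:
        epochs = apply_spatial_leakage(epochs, parcellation, config.leakage_width)
    return epochs


def simulation_parcellation(config: SimulationConfig) -> Parcellation:
    return build_synthetic_parcellation(
        config.n_regions, config.vertices_per_region, seed=child_rng(config.seed, "parcellation")
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate all subjects; see :func:`simulate_subject` for one at a time."""
    parcellation = simulation_parcellation(config)
    subjects = [simulate_subject(config, s, parcellation) for s in range(config.n_subjects)]
    return SimulatedDataset(
        subjects=subjects,
        parcellation=parcellation,
        ground_truth=realize_ground_truth(config),
        config=config,
    )


def apply_spatial_leakage(
    epochs: SourceEpochs, parcellation: Parcellation, width: float
) -> SourceEpochs:
    """Mix vertex signals across neighbouring regions (inverse-solution blur).

    Synthetic layouts order regions on a line; each vertex becomes a
    normalized triangular-kernel mix of all vertices within ``width`` regions
    (kernel weight ``max(0, 1 - d/(width+1))`` at region distance ``d``).
    Row normalization leaves a spatially constant signal unchanged, and
    ``width=0`` is the identity.
    """
    if width < 0:
        raise ValueError("leakage width must be >= 0")
    if width == 0:
        return epochs
    region = np.asarray(parcellation.assignment)
    dist = np.abs(region[:, None] - region[None, :]).astype(float)
    kernel = np.clip(1.0 - dist / (width + 1.0), 0.0, None)
    kernel /= kernel.sum(axis=1, keepdims=True)
    v, t, n = epochs.data.shape
    mixed = (kernel @ epochs.data.reshape(v, t * n)).reshape(v, t, n)
    return replace(epochs, data=mixed)
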