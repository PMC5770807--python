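"""Repetition suppression / enhancement analysis.

Activity of a category-specific spatiotemporal pattern is tracked across a
section: trials are averaged in 10 sequential segments (presentation order),
each segment's three region component time courses are superimposed with the
classifier boundary coefficients to a single equivalent-dipole time course,
averaged over the category-specific window and the category's two exemplars,
and the absolute amplitudes are regressed on segment index. A positive slope
is repetition enhancement, a negative one repetition suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import design
from .decode import DecodingResult, RegionComponentEpochs, DEFAULT_MIN_TRIALS

__all__ = [
    "RepetitionSeries",
    "RepetitionFit",
    "project_boundary_timecourse",
    "sequential_segment_average",
    "category_boundary_weights",
    "repetition_amplitudes",
    "repetition_series",
    "repetition_regression",
]


class TooFewTrialsError(ValueError):
    """A condition fell below the minimum-trial rule and is excluded."""


def project_boundary_timecourse(scores: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Superimpose 3 component time courses with the boundary coefficients.

    ``scores``: (..., 3, n_times); ``weights``: unit-norm 3-vector. Returns
    the (..., n_times) inner-product time course (the equivalent current
    dipole's activity along the discriminant direction).
    """
    weights = np.asarray(weights, dtype=float)
    return np.einsum("...kt,k->...t", np.asarray(scores), weights)


def sequential_segment_average(
    data: np.ndarray,
    presentation_order: np.ndarray,
    n_segments: int = design.N_PSEUDO_TRIALS,
    min_trials: int = DEFAULT_MIN_TRIALS,
) -> np.ndarray:
    """Average trials in contiguous presentation-order blocks.

    ``data``: (..., n_trials); blocks have ``n // 10`` or ``n // 10 + 1``
    trials with the larger blocks first, so the first segment is the start
    of the section. Raises :class:`TooFewTrialsError` below ``min_trials``
    (the same 50-trial exclusion rule as the classification stage).
    """
    order = np.asarray(presentation_order)
    n = order.size
    if n < min_trials:
        raise TooFewTrialsError(f"{n} trials < required {min_trials}")
    ranks = np.argsort(order, kind="stable")
    sizes = design.segment_sizes(n, n_segments)
    bounds = np.cumsum(sizes)[:-1]
    blocks = np.split(ranks, bounds)
    return np.stack([np.take(data, blk, axis=-1).mean(axis=-1) for blk in blocks], axis=-1)


def category_boundary_weights(
    decoding: DecodingResult,
    region: int,
    category: str,
    window_bins: np.ndarray,
    sections: tuple[int, ...] = (1, 2),
) -> np.ndarray:
    """Boundary coefficients of a category's pattern in one region.

    Mean of the unit discriminant normals over that category's
    exemplar-versus-nonsense pairwise classifiers (entries of the requested
    sections) and over the window's time bins, renormalized to unit length.
    Each pair's normal is oriented toward the category exemplar before
    averaging.
    """
    if category not in ("face", "tool"):
        raise ValueError("category must be face or tool")
    cat_entries = [
        e for e in decoding.entries
        if design.entry_group(e) == category and design.ENTRIES[e][1] in sections
    ]
    non_entries = [
        e for e in decoding.entries
        if design.entry_group(e) == "nonsense" and design.ENTRIES[e][1] in sections
    ]
    if not cat_entries or not non_entries:
        raise ValueError(f"no retained {category}/nonsense entry pairs to average")
    normals = []
    for ce in cat_entries:
        for ne in non_entries:
            p = decoding.pair_index(ce, ne)
            w = decoding.boundary_weights[region, window_bins, p]  # (n_bins, 3)
            if ne < ce:  # pair stored as (nonsense, category): flip toward the category
                w = -w
            normals.append(w)
    mean = np.concatenate(normals, axis=0).mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm == 0:
        raise ValueError("degenerate boundary weights (zero mean normal)")
    return mean / norm


def repetition_amplitudes(
    comp: RegionComponentEpochs,
    weights: np.ndarray,
    region: int,
    category: str,
    window_ms: tuple[float, float],
    section: int = 1,
    n_segments: int = design.N_PSEUDO_TRIALS,
    min_trials: int = DEFAULT_MIN_TRIALS,
) -> np.ndarray:
    """One subject's 10 segment amplitudes for a category pattern.

    Per segment: the projected evoked response, averaged over the
    category-specific window and over the category's two exemplars, then
    the absolute value — in that order, so a pattern inverting polarity
    across exemplars averages before rectification.
    """
    a, b = window_ms
    in_window = (comp.time_ms >= a - 1e-9) & (comp.time_ms <= b + 1e-9)
    if not in_window.any():
        raise ValueError(f"window {window_ms} contains no time bins")
    per_exemplar = []
    for stim in design.CATEGORY_STIMULI[category]:
        idx = comp.condition_trials(stim, section)
        segs = sequential_segment_average(
            comp.scores[region][:, :, idx],
            comp.presentation_order[idx],
            n_segments=n_segments,
            min_trials=min_trials,
        )  # (3, n_times, n_segments)
        proj = project_boundary_timecourse(np.moveaxis(segs, -1, 0), weights)  # (n_seg, n_times)
        per_exemplar.append(proj[:, in_window].mean(axis=1))
    return np.abs(np.mean(per_exemplar, axis=0))


@dataclass
class RepetitionSeries:
    """Absolute segment amplitudes per subject for one region/category."""

    amplitudes: np.ndarray  # (n_subjects, 10); NaN rows for excluded subjects
    region: int
    category: str
    window_ms: tuple[float, float]
    excluded_subjects: list


def repetition_series(
    comps: list,
    decodings: list,
    region: int,
    category: str,
    window_ms: tuple[float, float],
    section: int = 1,
    weight_sections: tuple[int, ...] = (1, 2),
    min_trials: int = DEFAULT_MIN_TRIALS,
) -> RepetitionSeries:
    """Segment amplitudes for every subject (NaN + report when excluded)."""
    n_subjects = len(comps)
    amps = np.full((n_subjects, design.N_PSEUDO_TRIALS), np.nan)
    excluded = []
    for s, (comp, dec) in enumerate(zip(comps, decodings)):
        a, b = window_ms
        bins = np.flatnonzero((dec.time_ms >= a - 1e-9) & (dec.time_ms <= b + 1e-9))
        try:
            w = category_boundary_weights(dec, region, category, bins, sections=weight_sections)
            amps[s] = repetition_amplitudes(
                comp, w, region, category, window_ms, section=section, min_trials=min_trials
            )
        except (TooFewTrialsError, ValueError):
            excluded.append(s)
    return RepetitionSeries(
        amplitudes=amps, region=region, category=category,
        window_ms=tuple(window_ms), excluded_subjects=excluded,
    )


@dataclass
class RepetitionFit:
    """Pooled linear fit of amplitude on segment index (1..10)."""

    k: float  # slope, amplitude units per segment
    intercept: float
    F: float
    df: tuple[int, int]  # (1, n_points - 2)
    p: float


def repetition_regression(amplitudes: np.ndarray) -> RepetitionFit:
    """Pooled simple regression over all subject x segment points.

    All subjects' (segment, amplitude) points enter one regression — with 22
    subjects and 10 segments the slope F-test has (1, 218) degrees of
    freedom. NaN rows (excluded subjects) are dropped.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.ndim == 1:
        amplitudes = amplitudes[None, :]
    n_subj, n_seg = amplitudes.shape
    x = np.tile(np.arange(1, n_seg + 1), n_subj).astype(float)
    y = amplitudes.ravel()
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite points for the regression")
    fit = sps.linregress(x, y)
    df2 = x.size - 2
    if fit.stderr == 0:
        f_stat, p = np.inf, 0.0
    else:
        t = fit.slope / fit.stderr
        f_stat = t * t
        p = float(sps.f.sf(f_stat, 1, df2))
    return RepetitionFit(
        k=float(fit.slope), intercept=float(fit.intercept),
        F=float(f_stat), df=(1, int(df2)), p=p,
    )
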