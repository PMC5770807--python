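"""Region-wise component reduction, pseudo-trials and pairwise LDA decoding.

The classification stage: each region's vertex time courses are reduced to
their three leading spatial principal components; trials of each condition
are averaged into 10 pseudo-trials; and every pair of conditions is decoded
per time bin with a cross-validated two-class linear discriminant on the
3-dimensional component scores. Accuracy over held-out pseudo-trials is the
dissimilarity measure handed to the RSA stage, and the discriminant normals
("boundary weights") feed the repetition analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import design
from ._rng import child_rng
from .atlas import Parcellation
from .synth import SourceEpochs

__all__ = [
    "RegionComponentEpochs",
    "PseudoTrials",
    "DecodingResult",
    "resample_epochs",
    "extract_region_components",
    "make_pseudo_trials",
    "decode_pair_timecourse",
    "decode_all_pairs",
]

N_COMPONENTS = 3
TRAIN_SIZE = 2 * (design.N_PSEUDO_TRIALS - 1)  # 18: nine pseudo-trials per class
TEST_SIZE = 2  # one held-out pseudo-trial per class
DEFAULT_RIDGE = 1e-3
DEFAULT_MIN_TRIALS = 50


# ---------------------------------------------------------------------------
# resampling

def resample_epochs(
    epochs: SourceEpochs,
    window_ms: tuple[float, float] = (-100.0, 700.0),
    target_step_ms: float = 10.0,
) -> SourceEpochs:
    """Crop to ``window_ms`` and reduce to ``target_step_ms`` by block means.

    Non-overlapping blocks of ``target_step / input_step`` consecutive
    samples are averaged (a trailing shorter block is averaged as-is); each
    output bin is stamped with its block's first sample time. Input already
    on the target grid passes through apart from the crop. A 1 kHz epoch
    cropped to -100..700 ms yields the 81-bin, 10 ms analysis grid.
    """
    t = epochs.time_ms
    if window_ms[0] < t[0] - 1e-9 or window_ms[1] > t[-1] + 1e-9:
        raise ValueError(f"window {window_ms} outside epoch span ({t[0]}, {t[-1]})")
    steps = np.diff(t)
    step = float(steps[0])
    if not np.allclose(steps, step):
        raise ValueError("input time axis must be uniformly sampled")
    keep = (t >= window_ms[0] - 1e-9) & (t <= window_ms[1] + 1e-9)
    data = epochs.data[:, keep, :]
    t = t[keep]
    ratio = int(round(target_step_ms / step))
    if ratio < 1:
        raise ValueError("target step is finer than the input sampling")
    if ratio == 1:
        out, t_out = data, t
    else:
        n = t.size
        n_blocks = int(np.ceil(n / ratio))
        sums = np.add.reduceat(data, np.arange(0, n, ratio), axis=1)
        counts = np.diff(np.append(np.arange(0, n, ratio), n))
        out = sums / counts[None, :, None]
        t_out = t[::ratio][:n_blocks]
    return SourceEpochs(
        data=out,
        time_ms=t_out,
        stimulus=epochs.stimulus,
        section=epochs.section,
        presentation_order=epochs.presentation_order,
    )


# ---------------------------------------------------------------------------
# principal-component reduction

@dataclass
class RegionComponentEpochs:
    """Three spatial-component score time courses per region and trial.

    ``scores[r, c, t, i]`` is the c-th component score of region ``r`` at
    time bin ``t`` in trial ``i``; ``loadings[r]`` is that region's
    (n_vertices_r, 3) orthonormal spatial basis.
    """

    scores: np.ndarray  # (n_regions, 3, n_times, n_trials)
    loadings: list  # per region: (v_r, 3)
    explained_variance: np.ndarray  # (n_regions, 3) fractions, non-increasing
    time_ms: np.ndarray
    stimulus: np.ndarray
    section: np.ndarray
    presentation_order: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.scores.shape[0]

    def condition_trials(self, stimulus: int, section: int) -> np.ndarray:
        return np.flatnonzero((self.stimulus == stimulus) & (self.section == section))

    def condition_counts(self) -> dict[tuple[int, int], int]:
        return {
            (stim, sec): self.condition_trials(stim, sec).size
            for sec in (1, 2)
            for stim in range(1, design.N_STIMULI + 1)
        }


def extract_region_components(
    epochs: SourceEpochs, parcellation: Parcellation, n_components: int = N_COMPONENTS
) -> RegionComponentEpochs:
    """Fit per-region spatial PCA and project every trial onto it.

    The components are fitted once on the vertex x (time * trials) matrix of
    all trials of all conditions jointly (vertex-mean centered), so the
    classifier's feature space is one fixed spatial basis per region. Each
    component's sign is chosen so its largest-magnitude vertex loading is
    positive, making boundary weights reproducible.
    """
    v_total, n_t, n_trials = epochs.data.shape
    n_regions = parcellation.n_regions
    scores = np.empty((n_regions, n_components, n_t, n_trials))
    loadings: list[np.ndarray] = []
    ev = np.empty((n_regions, n_components))
    for r in range(n_regions):
        verts = parcellation.vertices_of(r)
        if verts.size < n_components:
            raise ValueError(
                f"region {r} has {verts.size} vertices; need >= {n_components} for the reduction"
            )
        x = epochs.data[verts].reshape(verts.size, n_t * n_trials)
        xc = x - x.mean(axis=1, keepdims=True)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        u = u[:, :n_components].copy()
        flip = np.sign(u[np.abs(u).argmax(axis=0), np.arange(n_components)])
        flip[flip == 0] = 1.0
        u *= flip
        total = float(np.sum(s**2))
        ev[r] = (s[:n_components] ** 2) / total if total > 0 else 0.0
        scores[r] = (u.T @ xc).reshape(n_components, n_t, n_trials)
        loadings.append(u)
    return RegionComponentEpochs(
        scores=scores,
        loadings=loadings,
        explained_variance=ev,
        time_ms=epochs.time_ms,
        stimulus=epochs.stimulus,
        section=epochs.section,
        presentation_order=epochs.presentation_order,
    )


# ---------------------------------------------------------------------------
# pseudo-trials

@dataclass
class PseudoTrials:
    """10 averaged pseudo-trials per retained (stimulus, section) condition."""

    entries: list  # retained entry indices (0..11), canonical order
    data: np.ndarray  # (n_entries, n_regions, 3, n_times, 10)
    group_sizes: np.ndarray  # (n_entries, 10)
    excluded: list  # entry indices dropped by the minimum-trial rule


def _random_groups(n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """A seeded random partition of ``n`` trials into 10 near-equal groups."""
    sizes = design.segment_sizes(n, design.N_PSEUDO_TRIALS)
    perm = rng.permutation(n)
    return list(np.split(perm, np.cumsum(sizes)[:-1]))


def make_pseudo_trials(
    comp: RegionComponentEpochs,
    min_trials: int = DEFAULT_MIN_TRIALS,
    seed: int | np.random.Generator = 0,
) -> PseudoTrials:
    """Average each condition's trials into 10 pseudo-trials.

    Trials are permuted (seeded) and split into 10 groups of ``n // 10`` or
    ``n // 10 + 1``; a condition with fewer than ``min_trials`` trials is
    excluded and reported rather than raising.
    """
    rng = np.random.default_rng(seed)
    entries, blocks, sizes, excluded = [], [], [], []
    for e, (stim, sec) in enumerate(design.ENTRIES):
        idx = comp.condition_trials(stim, sec)
        if idx.size < min_trials:
            excluded.append(e)
            continue
        groups = _random_groups(idx.size, rng)
        avg = np.stack([comp.scores[..., idx[g]].mean(axis=-1) for g in groups], axis=-1)
        entries.append(e)
        blocks.append(avg)
        sizes.append([g.size for g in groups])
    data = np.stack(blocks, axis=0) if blocks else np.empty((0,) + comp.scores.shape[:3] + (10,))
    return PseudoTrials(
        entries=entries, data=data, group_sizes=np.asarray(sizes, dtype=int), excluded=excluded
    )


# ---------------------------------------------------------------------------
# pairwise LDA decoding

def _averaging_matrices(n: int, n_rand: int, rng: np.random.Generator) -> np.ndarray:
    """(n_rand, 10, n) row-stochastic pseudo-trial averaging operators."""
    g = design.N_PSEUDO_TRIALS
    sizes = design.segment_sizes(n, g)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mats = np.zeros((n_rand, g, n))
    for r in range(n_rand):
        perm = rng.permutation(n)
        for k in range(g):
            mats[r, k, perm[bounds[k] : bounds[k + 1]]] = 1.0 / sizes[k]
    return mats


def decode_pair_timecourse(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_randomizations: int = 100,
    seed: int | np.random.Generator = 0,
    ridge: float = DEFAULT_RIDGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated LDA accuracy and boundary normal per time bin.

    ``scores_a`` / ``scores_b``: (3, n_times, n_trials) raw component scores
    of the two conditions. Each randomization re-draws the pseudo-trial
    composition from the raw trials and holds out one pseudo-trial per class;
    an LDA with pooled within-class covariance (ridge-regularized by
    ``ridge * trace/3``) is trained on the remaining 18 and scored on the 2
    held-out pseudo-trials. Returns ``(accuracy (n_times,), boundary
    (n_times, 3))`` where the boundary is the mean unit discriminant normal
    over randomizations, renormalized, oriented from class b toward class a.
    """
    rng = np.random.default_rng(seed)
    k, n_t, n_a = scores_a.shape
    n_b = scores_b.shape[2]
    g = design.N_PSEUDO_TRIALS
    r_n = n_randomizations

    aa = _averaging_matrices(n_a, r_n, rng)
    ab = _averaging_matrices(n_b, r_n, rng)
    pa = np.einsum("ktn,rgn->rgkt", scores_a, aa)  # (R, 10, 3, T)
    pb = np.einsum("ktn,rgn->rgkt", scores_b, ab)
    ha = rng.integers(0, g, size=r_n)
    hb = rng.integers(0, g, size=r_n)
    ma = np.ones((r_n, g))
    ma[np.arange(r_n), ha] = 0.0
    mb = np.ones((r_n, g))
    mb[np.arange(r_n), hb] = 0.0

    mu_a = np.einsum("rgkt,rg->rkt", pa, ma) / (g - 1)
    mu_b = np.einsum("rgkt,rg->rkt", pb, mb) / (g - 1)
    ca = pa - mu_a[:, None]
    cb = pb - mu_b[:, None]
    dof = TRAIN_SIZE - 2
    cov = (
        np.einsum("rgit,rgjt,rg->rijt", ca, ca, ma)
        + np.einsum("rgit,rgjt,rg->rijt", cb, cb, mb)
    ) / dof
    trace = np.einsum("riit->rt", cov) / k
    eye = np.eye(k)[None, :, :, None]
    cov = cov + (ridge * trace + 1e-12)[:, None, None, :] * eye

    delta = mu_a - mu_b  # (R, 3, T)
    cov_flat = cov.transpose(0, 3, 1, 2).reshape(r_n * n_t, k, k)
    delta_flat = delta.transpose(0, 2, 1).reshape(r_n * n_t, k)
    w = np.linalg.solve(cov_flat, delta_flat[:, :, None])[:, :, 0].reshape(r_n, n_t, k)

    mid = 0.5 * (mu_a + mu_b).transpose(0, 2, 1)  # (R, T, 3)
    xa = pa[np.arange(r_n), ha].transpose(0, 2, 1)
    xb = pb[np.arange(r_n), hb].transpose(0, 2, 1)
    score_a = np.einsum("rtk,rtk->rt", xa - mid, w)
    score_b = np.einsum("rtk,rtk->rt", xb - mid, w)
    accuracy = ((score_a > 0).sum(axis=0) + (score_b < 0).sum(axis=0)) / (2.0 * r_n)

    norms = np.linalg.norm(w, axis=-1, keepdims=True)
    w_unit = np.divide(w, norms, out=np.zeros_like(w), where=norms > 0)
    boundary = w_unit.mean(axis=0)
    bnorm = np.linalg.norm(boundary, axis=-1, keepdims=True)
    boundary = np.divide(boundary, bnorm, out=np.zeros_like(boundary), where=bnorm > 0)
    return accuracy, boundary


@dataclass
class DecodingResult:
    """All-pairs time-resolved decoding output for one subject.

    ``pairs`` lists the unordered entry pairs actually decoded (canonical
    order over retained entries); the boundary normal of pair ``(a, b)``
    points from condition b toward condition a.
    """

    accuracy: np.ndarray  # (n_regions, n_times, n_pairs)
    boundary_weights: np.ndarray  # (n_regions, n_times, n_pairs, 3)
    pairs: list  # [(entry_a, entry_b), ...]
    entries: list  # retained entry indices
    excluded: list  # excluded entry indices
    time_ms: np.ndarray
    n_randomizations: int
    _pair_index: dict = field(default=None, repr=False)

    def pair_index(self, a: int, b: int) -> int:
        if self._pair_index is None:
            object.__setattr__(self, "_pair_index", {p: i for i, p in enumerate(self.pairs)})
        key = (min(a, b), max(a, b))
        return self._pair_index[key]


def decode_all_pairs(
    comp: RegionComponentEpochs,
    min_trials: int = DEFAULT_MIN_TRIALS,
    n_randomizations: int = 100,
    seed: int = 0,
    regions: np.ndarray | None = None,
    ridge: float = DEFAULT_RIDGE,
) -> DecodingResult:
    """Decode every unordered pair of retained conditions in every region."""
    counts = comp.condition_counts()
    entries = [e for e, (stim, sec) in enumerate(design.ENTRIES) if counts[(stim, sec)] >= min_trials]
    excluded = [e for e in range(design.N_ENTRIES) if e not in entries]
    pairs = [(a, b) for (a, b) in design.ENTRY_PAIRS if a in entries and b in entries]
    region_ids = np.arange(comp.n_regions) if regions is None else np.asarray(regions)
    n_t = comp.time_ms.size
    accuracy = np.full((comp.n_regions, n_t, len(pairs)), np.nan)
    boundary = np.full((comp.n_regions, n_t, len(pairs), N_COMPONENTS), np.nan)
    trial_idx = {e: comp.condition_trials(*design.ENTRIES[e]) for e in entries}
    for p, (a, b) in enumerate(pairs):
        for r in region_ids:
            rng = child_rng(seed, "decode", int(r), a, b)
            acc, w = decode_pair_timecourse(
                comp.scores[r][:, :, trial_idx[a]],
                comp.scores[r][:, :, trial_idx[b]],
                n_randomizations=n_randomizations,
                seed=rng,
                ridge=ridge,
            )
            accuracy[r, :, p] = acc
            boundary[r, :, p] = w
    return DecodingResult(
        accuracy=accuracy,
        boundary_weights=boundary,
        pairs=pairs,
        entries=entries,
        excluded=excluded,
        time_ms=comp.time_ms,
        n_randomizations=n_randomizations,
    )
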