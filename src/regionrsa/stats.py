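"""Group-level region-time statistics.

Mass-univariate one-sample t-maps over (region, time bin) cells with
Benjamini-Hochberg FDR control pooled across the whole grid, onset
extraction, subject-resampling bootstrap tests of decodability
characteristics, a label-permutation chance distribution for raw decoding,
and Bartlett's MANOVA dimensionality test of model-map specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .decode import decode_pair_timecourse

__all__ = [
    "SignificanceMap",
    "BootstrapResult",
    "region_time_ttest",
    "fdr_mask",
    "onset_time",
    "bootstrap_characteristic",
    "permutation_chance",
    "manova_model_specificity",
]


def region_time_ttest(
    z: np.ndarray, one_sided: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t of Fisher-z values against 0 at every region-time cell.

    ``z``: (n_subjects, n_regions, n_times); NaN subject cells are skipped.
    Two-sided p by default (``one_sided=True`` tests mean > 0). Cells with
    zero variance across subjects get p = 0 if the mean differs from 0 and
    p = 1 otherwise.
    """
    z = np.asarray(z, dtype=float)
    n = np.sum(np.isfinite(z), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(z, axis=0)
        sd = np.nanstd(z, axis=0, ddof=1)
    df = n - 1
    ok = (n >= 2) & (sd > 0)
    t = np.full(mean.shape, np.nan)
    p = np.full(mean.shape, np.nan)
    se = np.where(ok, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    t[ok] = mean[ok] / se[ok]
    if one_sided:
        p[ok] = sps.t.sf(t[ok], df[ok])
    else:
        p[ok] = 2 * sps.t.sf(np.abs(t[ok]), df[ok])
    degenerate = (n >= 2) & (sd == 0)
    if np.any(degenerate):
        warnings.warn("zero-variance cells encountered in region_time_ttest", stacklevel=2)
        with np.errstate(invalid="ignore"):
            t[degenerate] = np.where(
                mean[degenerate] != 0, np.sign(mean[degenerate]) * np.inf, 0.0
            )
        p[degenerate] = np.where(mean[degenerate] != 0, 0.0, 1.0)
    return t, p


@dataclass
class SignificanceMap:
    """FDR-thresholded region-time map with per-region onsets."""

    t: np.ndarray  # (n_regions, n_times)
    p: np.ndarray
    mask: np.ndarray  # bool, True = significant
    q: float
    threshold: float  # realized BH p threshold (0 if nothing rejected)
    time_ms: np.ndarray
    onsets: dict  # region index -> onset ms (absent if never significant post-stimulus)


def fdr_mask(
    p: np.ndarray,
    q: float,
    time_ms: np.ndarray,
    t: np.ndarray | None = None,
) -> SignificanceMap:
    """Benjamini-Hochberg step-up over all finite cells of the grid jointly.

    The study's convention: q = 0.01 for stimulus-recognizer and
    category-vs-nonsense maps, q = 0.05 for one-vs-rest maps.
    """
    p = np.asarray(p, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    if finite.any():
        reject, _, _, _ = multipletests(p[finite], alpha=q, method="fdr_bh")
        mask[finite] = reject
    threshold = float(p[mask].max()) if mask.any() else 0.0
    tmap = t if t is not None else np.full(p.shape, np.nan)
    sig = SignificanceMap(
        t=tmap, p=p, mask=mask, q=q, threshold=threshold,
        time_ms=np.asarray(time_ms), onsets={},
    )
    sig.onsets = {
        r: onset for r in range(p.shape[0]) if (onset := onset_time(sig, r)) is not None
    }
    return sig


def onset_time(sig: SignificanceMap, region: int) -> float | None:
    """First significant time point strictly after stimulus onset (t > 0 ms).

    Pre-stimulus significance is ignored; None if the region never survives
    the threshold post-stimulus.
    """
    post = sig.time_ms > 0
    hits = np.flatnonzero(sig.mask[region] & post)
    return float(sig.time_ms[hits[0]]) if hits.size else None


@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    reject: bool
    samples: np.ndarray


def bootstrap_characteristic(
    values: np.ndarray, n_boot: int = 1000, seed: int | np.random.Generator = 0,
    ci: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap CI of the mean, resampling participants.

    ``reject`` is True when the 95% CI excludes 0 (the p < 0.05 criterion).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 subjects to bootstrap")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, values.size, size=(n_boot, values.size))
    samples = values[draws].mean(axis=1)
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(samples, [alpha, 1 - alpha])
    return BootstrapResult(
        estimate=float(values.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        reject=not (lo <= 0.0 <= hi),
        samples=samples,
    )


def permutation_chance(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_perm: int = 100,
    n_randomizations: int = 100,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null accuracy distribution with labels shuffled before averaging.

    Class labels are randomly reassigned to the pooled raw trials (keeping
    the class sizes) before pseudo-trial construction, then the standard
    decoder runs. Returns (n_perm, n_times) accuracies; their mean sits at
    chance (0.5).
    """
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([scores_a, scores_b], axis=2)
    n_a = scores_a.shape[2]
    n = pooled.shape[2]
    out = np.empty((n_perm, scores_a.shape[1]))
    for i in range(n_perm):
        perm = rng.permutation(n)
        acc, _ = decode_pair_timecourse(
            pooled[:, :, perm[:n_a]],
            pooled[:, :, perm[n_a:]],
            n_randomizations=n_randomizations,
            seed=rng,
        )
        out[i] = acc
    return out


def manova_model_specificity(z: np.ndarray, dim: int = 1) -> tuple[float, int, float]:
    """Bartlett's test that the model-group means span more than ``dim`` axes.

    ``z``: (n_subjects, n_areas, n_models) time-averaged, hemisphere-averaged
    Fisher-z maps. Each subject x model map is one observation; the models
    are the groups of a one-way MANOVA. The sequential dimensionality
    statistic for H0 "group means lie in a ``dim``-dimensional affine
    subspace" is

        chi2 = (n - 1 - (p + g) / 2) * sum_{i > dim} log(1 + lambda_i)

    with lambda_i the eigenvalues of W^{-1} B and df = (p - dim) *
    (g - dim - 1). With p = 41 areas, g = 3 models and dim = 1 (are the
    three means collinear?) this is the chi2(40) test. Returns
    ``(chi2, df, p)``.

    The grouping treats the three maps of one subject as independent
    observations, replicating the source analysis despite the within-subject
    dependence; interpret accordingly.
    """
    z = np.asarray(z, dtype=float)
    n_subj, n_areas, n_models = z.shape
    x = z.transpose(0, 2, 1).reshape(n_subj * n_models, n_areas)
    groups = np.tile(np.arange(n_models), n_subj)
    n, p, g = x.shape[0], n_areas, n_models
    if dim >= g - 1:
        raise ValueError("dim must be smaller than n_models - 1")

    grand = x.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for gi in range(g):
        xg = x[groups == gi]
        mg = xg.mean(axis=0)
        xc = xg - mg
        w += xc.T @ xc
        b += xg.shape[0] * np.outer(mg - grand, mg - grand)

    rank_w = np.linalg.matrix_rank(w)
    if rank_w < p:
        warnings.warn(
            "within-group scatter is rank deficient; using pseudo-inverse "
            f"(rank {rank_w} < {p} variables)",
            stacklevel=2,
        )
        eigvals = np.linalg.eigvals(np.linalg.pinv(w) @ b).real
    else:
        eigvals = sla.eigh(b, w, eigvals_only=True)
    eigvals = np.sort(np.clip(eigvals, 0, None))[::-1][: g - 1]
    chi2 = (n - 1 - (p + g) / 2.0) * np.sum(np.log1p(eigvals[dim:]))
    df = (p - dim) * (g - dim - 1)
    pval = float(sps.chi2.sf(chi2, df))
    return float(chi2), int(df), pval
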