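"""Representational dissimilarity matrices and their model correlations.

Empirical RDMs are 12 x 12 matrices of pairwise decoding accuracies over the
(stimulus, section) entries; model RDMs encode hypotheses as 0/1
dissimilarities with exclusion masks. Three model families are supported:

* ``stimulus_recognizer`` (type 1): every pair dissimilar except the same
  stimulus across sections — low-level stimulus identity.
* ``category_vs_nonsense`` (type 2): within one meaningful category and the
  nonsense group only, cross-group pairs dissimilar; same-stimulus
  cross-section pairs excluded.
* ``one_vs_rest`` (type 3): one group (face, tool, or the combined
  meaningful group) against everything else over all 12 entries, with all
  same-stimulus cross-section pairs excluded.

Empirical-model agreement is Spearman's rank correlation over the jointly
valid upper-triangle cells, Fisher-transformed for group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import design
from .decode import DecodingResult

__all__ = [
    "RDM",
    "ModelSpec",
    "MODEL_NAMES",
    "build_empirical_rdm",
    "build_model_rdm",
    "correlate_rdms",
    "fisher_z",
    "rsa_zmaps",
]


@dataclass(frozen=True)
class RDM:
    """Symmetric 12 x 12 dissimilarity matrix with a validity mask."""

    values: np.ndarray  # (12, 12)
    mask: np.ndarray  # (12, 12) bool; True = valid cell; diagonal always False

    def __post_init__(self) -> None:
        n = design.N_ENTRIES
        if self.values.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("RDM must be 12 x 12")
        if not np.allclose(self.values[self.mask], self.values.T[self.mask]):
            raise ValueError("RDM values must be symmetric on valid cells")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("RDM mask must be symmetric")
        if np.any(np.diag(self.mask)):
            raise ValueError("diagonal cells are never valid")

    def upper_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, validity) over the 66 upper-triangle cells in pair order."""
        iu = np.triu_indices(design.N_ENTRIES, k=1)
        return self.values[iu], self.mask[iu]


@dataclass(frozen=True)
class ModelSpec:
    """Which model RDM to build; ``target`` is required for types 2 and 3."""

    type: str  # stimulus_recognizer | category_vs_nonsense | one_vs_rest
    target: str | None = None  # face | tool | meaningful

    def __post_init__(self) -> None:
        if self.type == "stimulus_recognizer":
            if self.target is not None:
                raise ValueError("stimulus_recognizer takes no target")
        elif self.type == "category_vs_nonsense":
            if self.target not in ("face", "tool"):
                raise ValueError("category_vs_nonsense needs target face or tool")
        elif self.type == "one_vs_rest":
            if self.target not in ("face", "tool", "meaningful"):
                raise ValueError("one_vs_rest needs target face, tool or meaningful")
        else:
            raise ValueError(f"unknown model type {self.type!r}")


#: short names used by the CLI and pipeline configs
MODEL_NAMES: dict[str, ModelSpec] = {
    "recognizer": ModelSpec("stimulus_recognizer"),
    "face_vs_nonsense": ModelSpec("category_vs_nonsense", "face"),
    "tool_vs_nonsense": ModelSpec("category_vs_nonsense", "tool"),
    "face_specific": ModelSpec("one_vs_rest", "face"),
    "tool_specific": ModelSpec("one_vs_rest", "tool"),
    "meaningful": ModelSpec("one_vs_rest", "meaningful"),
}


def _same_stimulus_cross_section(a: int, b: int) -> bool:
    (sa, seca), (sb, secb) = design.ENTRIES[a], design.ENTRIES[b]
    return sa == sb and seca != secb


def build_model_rdm(spec: ModelSpec) -> RDM:
    """Construct a 0/1 model RDM with its exclusion mask."""
    n = design.N_ENTRIES
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    if spec.type == "stimulus_recognizer":
        for a, b in design.ENTRY_PAIRS:
            mask[a, b] = True
            values[a, b] = 0.0 if _same_stimulus_cross_section(a, b) else 1.0
    elif spec.type == "category_vs_nonsense":
        in_play = set(design.CATEGORY_STIMULI[spec.target]) | set(design.CATEGORY_STIMULI["nonsense"])
        for a, b in design.ENTRY_PAIRS:
            if design.ENTRIES[a][0] not in in_play or design.ENTRIES[b][0] not in in_play:
                continue
            if _same_stimulus_cross_section(a, b):
                continue  # excluded: same stimulus across sections
            mask[a, b] = True
            values[a, b] = 0.0 if design.entry_group(a) == design.entry_group(b) else 1.0
    else:  # one_vs_rest
        target_stimuli = set(design.CATEGORY_STIMULI[spec.target])
        for a, b in design.ENTRY_PAIRS:
            if _same_stimulus_cross_section(a, b):
                continue
            in_a = design.ENTRIES[a][0] in target_stimuli
            in_b = design.ENTRIES[b][0] in target_stimuli
            mask[a, b] = True
            values[a, b] = 1.0 if in_a != in_b else 0.0
    values = values + values.T
    mask = mask | mask.T
    return RDM(values=values, mask=mask)


def build_empirical_rdm(
    decoding: DecodingResult, region: int, time_bin: int
) -> RDM:
    """Empirical RDM at one (region, time bin) from pairwise accuracies.

    Cells of excluded conditions (and the diagonal) are masked invalid.
    """
    n = design.N_ENTRIES
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    acc = decoding.accuracy[region, time_bin]  # indexes out of range raise naturally
    for p, (a, b) in enumerate(decoding.pairs):
        values[a, b] = values[b, a] = acc[p]
        mask[a, b] = mask[b, a] = np.isfinite(acc[p])
    return RDM(values=values, mask=mask)


def correlate_rdms(empirical: RDM, model: RDM) -> float:
    """Spearman rank correlation over cells valid in both RDMs.

    Ties get average ranks. Returns NaN (propagated as missing, never zero)
    when fewer than 3 joint cells remain or the model is constant on them.
    """
    ev, evalid = empirical.upper_cells()
    mv, mvalid = model.upper_cells()
    joint = evalid & mvalid
    if joint.sum() < 3 or np.ptp(mv[joint]) == 0:
        return float("nan")
    rho, _ = sps.spearmanr(ev[joint], mv[joint])
    return float(rho)


def fisher_z(rho):
    """Variance-stabilizing Fisher transform z = atanh(rho).

    |rho| is clipped to 1 - 1e-6 so perfect correlations stay finite.
    """
    rho = np.clip(np.asarray(rho, dtype=float), -1 + 1e-6, 1 - 1e-6)
    return np.arctanh(rho)


# ---------------------------------------------------------------------------
# whole-map RSA

def _rank_correlate(block: np.ndarray, model_vals: np.ndarray) -> np.ndarray:
    """Spearman rho of ``block[..., m]`` against ``model_vals (m,)``.

    Average-rank ties on both sides; vectorized Pearson-of-ranks, identical
    to ``scipy.stats.spearmanr`` cell by cell (cross-checked in the tests).
    """
    rx = sps.rankdata(block, axis=-1)
    ry = sps.rankdata(model_vals)
    rx = rx - rx.mean(axis=-1, keepdims=True)
    ry = ry - ry.mean()
    num = np.einsum("...m,m->...", rx, ry)
    den = np.sqrt(np.einsum("...m,...m->...", rx, rx) * (ry @ ry))
    return np.divide(num, den, out=np.full(block.shape[:-1], np.nan), where=den > 0)


def rsa_zmaps(
    decoding: DecodingResult, models: dict[str, ModelSpec] | list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Fisher-z Spearman correlation maps for one subject.

    Returns ``(z, names)`` with ``z`` of shape (n_regions, n_times,
    n_models). Cells where a model has fewer than 3 jointly valid pairs are
    NaN.
    """
    if models is None:
        models = dict(MODEL_NAMES)
    elif isinstance(models, (list, tuple)):
        models = {name: MODEL_NAMES[name] for name in models}
    names = list(models)
    n_regions, n_t, _ = decoding.accuracy.shape
    z = np.full((n_regions, n_t, len(names)), np.nan)
    pair_arr = np.array(decoding.pairs)
    for m, name in enumerate(names):
        model = build_model_rdm(models[name])
        valid = np.array([model.mask[a, b] for a, b in pair_arr], dtype=bool)
        use = np.flatnonzero(valid)
        mvals = model.values[pair_arr[use, 0], pair_arr[use, 1]]
        if use.size < 3 or np.ptp(mvals) == 0:
            continue
        block = decoding.accuracy[:, :, use]
        rho = _rank_correlate(block, mvals)
        rho[~np.all(np.isfinite(block), axis=-1)] = np.nan
        z[:, :, m] = np.where(np.isfinite(rho), fisher_z(rho), np.nan)
    return z, names
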