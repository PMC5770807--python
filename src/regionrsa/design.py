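"""Experimental-design constants shared across the pipeline.

Six bitonal stimuli in three groups (two faces, two tools, two nonsense
images), each shown in two merged sections of up to 80 presentations. A
condition is a (stimulus, section) pair; the 12 conditions are the entries of
every representational dissimilarity matrix.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

N_STIMULI = 6
N_SECTIONS = 2
N_PSEUDO_TRIALS = 10

#: stimulus id (1-based) -> group
STIMULUS_GROUP = {1: "face", 2: "face", 3: "tool", 4: "tool", 5: "nonsense", 6: "nonsense"}

GROUPS = ("face", "tool", "nonsense")

#: stimuli belonging to each category keyword an effect or model may use
CATEGORY_STIMULI = {
    "face": (1, 2),
    "tool": (3, 4),
    "nonsense": (5, 6),
    "meaningful": (1, 2, 3, 4),
    "all": (1, 2, 3, 4, 5, 6),
}

#: canonical RSA entry order: stimuli 1..6 of section 1, then of section 2
ENTRIES: tuple[tuple[int, int], ...] = tuple(
    (stim, section) for section in (1, 2) for stim in range(1, N_STIMULI + 1)
)
N_ENTRIES = len(ENTRIES)  # 12

#: all unordered entry pairs in canonical order (66 of them)
ENTRY_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(N_ENTRIES), 2))


def entry_index(stimulus: int, section: int) -> int:
    """Canonical index (0..11) of condition (stimulus 1..6, section 1..2)."""
    if not (1 <= stimulus <= N_STIMULI and section in (1, 2)):
        raise ValueError(f"invalid condition ({stimulus}, {section})")
    return (section - 1) * N_STIMULI + (stimulus - 1)


def entry_group(entry: int) -> str:
    return STIMULUS_GROUP[ENTRIES[entry][0]]


def segment_sizes(n_trials: int, n_segments: int = N_PSEUDO_TRIALS) -> np.ndarray:
    """Near-equal block sizes for splitting ``n_trials`` into ``n_segments``.

    Sizes are ``n // s`` or ``n // s + 1`` with the larger blocks first, so
    e.g. 73 trials give three blocks of 8 followed by seven of 7. Used both
    for random pseudo-trial averaging and for sequential repetition segments.
    """
    if n_trials < n_segments:
        raise ValueError(f"cannot split {n_trials} trials into {n_segments} segments")
    base, extra = divmod(n_trials, n_segments)
    return np.array([base + 1] * extra + [base] * (n_segments - extra))


def segment_of_position(position: np.ndarray, n_trials: int, n_segments: int = N_PSEUDO_TRIALS) -> np.ndarray:
    """Map 1-based within-section presentation positions to 1-based segment ids."""
    sizes = segment_sizes(n_trials, n_segments)
    edges = np.cumsum(sizes)
    return np.searchsorted(edges, np.asarray(position) - 1, side="right") + 1
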