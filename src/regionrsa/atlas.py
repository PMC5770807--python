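"""Cortical parcellation bookkeeping.

The analysis operates on a whole-cortex parcellation of 82 regions (41 named
areas, modified from the Destrieux scheme, duplicated over hemispheres). The
canonical table ships with the package as a TSV resource; vertex-level
parcellations for synthetic layouts are built here as contiguous blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _importlib_resources

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "RegionTable",
    "Parcellation",
    "load_region_table",
    "build_synthetic_parcellation",
]


@dataclass(frozen=True)
class Region:
    """A named cortical region with its hemisphere and MNI seed (mm)."""

    name: str
    alias: str
    hemisphere: str  # "left" | "right"
    mni_seed: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere!r}")
        if not np.all(np.isfinite(self.mni_seed)):
            raise ValueError(f"non-finite MNI seed for {self.alias}")

    @property
    def label(self) -> str:
        """Short label in the field's convention, e.g. ``leIPS`` / ``rIPS``."""
        prefix = "le" if self.hemisphere == "left" else "r"
        return prefix + self.alias


@dataclass(frozen=True)
class RegionTable:
    """Ordered table of regions; (alias, hemisphere) is unique."""

    regions: tuple[Region, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        idx = {}
        for i, r in enumerate(self.regions):
            key = (r.alias, r.hemisphere)
            if key in idx:
                raise ValueError(f"duplicate region {key}")
            idx[key] = i
        object.__setattr__(self, "_index", idx)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    @property
    def aliases(self) -> list[str]:
        """Distinct aliases in canonical order (one per hemisphere pair)."""
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.alias, None)
        return list(seen)

    def index_of(self, alias: str, hemisphere: str) -> int:
        return self._index[(alias, hemisphere)]

    def lookup(self, alias: str, hemisphere: str = "right") -> Region:
        return self.regions[self.index_of(alias, hemisphere)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.regions],
                "alias": [r.alias for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "mni_x": [r.mni_seed[0] for r in self.regions],
                "mni_y": [r.mni_seed[1] for r in self.regions],
                "mni_z": [r.mni_seed[2] for r in self.regions],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionTable":
        regions = tuple(
            Region(
                name=row["name"],
                alias=row["alias"],
                hemisphere=row["hemisphere"],
                mni_seed=(float(row["mni_x"]), float(row["mni_y"]), float(row["mni_z"])),
            )
            for _, row in df.iterrows()
        )
        return cls(regions=regions)

    @classmethod
    def from_tsv(cls, path) -> "RegionTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class Parcellation:
    """Vertex -> region assignment.

    ``assignment[v]`` is the region index of vertex ``v``. Every region must
    own at least 3 vertices so that three spatial components can be extracted.
    """

    n_vertices: int
    assignment: np.ndarray  # (n_vertices,) int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment)
        if a.shape != (self.n_vertices,):
            raise ValueError("assignment length must equal n_vertices")
        counts = np.bincount(a)
        if counts.min(initial=3) < 3:
            bad = int(np.argmin(counts))
            raise ValueError(f"region {bad} has fewer than 3 vertices")

    @property
    def n_regions(self) -> int:
        return int(self.assignment.max()) + 1

    def vertices_of(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == region)


def load_region_table() -> RegionTable:
    """Load the canonical 82-region table packaged with the library.

    Order is the canonical one used by every region-indexed array in this
    package: the 41 printed areas in order, each as (left, right) hemisphere
    pair, so hemisphere-averaging to 41 areas is ``values.reshape(41, 2)``.
    """
    ref = _importlib_resources.files("regionrsa") / "resources" / "regions.tsv"
    try:
        with _importlib_resources.as_file(ref) as path:
            table = RegionTable.from_tsv(path)
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover
        raise RuntimeError("packaged region table missing or unreadable") from exc
    if len(table) != 82:
        raise RuntimeError(f"packaged region table corrupt: {len(table)} rows, expected 82")
    return table


def build_synthetic_parcellation(
    n_regions: int,
    vertices_per_region: int | tuple[int, int],
    seed: int | np.random.Generator = 0,
) -> Parcellation:
    """Contiguous-block parcellation for simulated layouts.

    ``vertices_per_region`` may be a fixed count or an inclusive ``(lo, hi)``
    range sampled per region; either way every region gets >= 3 vertices.
    Deterministic given the seed.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    if np.isscalar(vertices_per_region):
        counts = np.full(n_regions, int(vertices_per_region))
    else:
        lo, hi = vertices_per_region
        counts = rng.integers(int(lo), int(hi) + 1, size=n_regions)
    if counts.min() < 3:
        raise ValueError("vertices_per_region must be >= 3")
    assignment = np.repeat(np.arange(n_regions), counts)
    return Parcellation(n_vertices=int(counts.sum()), assignment=assignment)
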