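"""HDF5 dataset container.

Schema (version 1)::

    /time_ms                      (n_times,) float, ms
    /parcellation/assignment      (n_vertices,) int, vertex -> region
    /subjects/s<idx>/data         (n_vertices, n_times, n_trials) float
    /subjects/s<idx>/labels/stimulus            (n_trials,) int 1..6
    /subjects/s<idx>/labels/section             (n_trials,) int 1..2
    /subjects/s<idx>/labels/presentation_order  (n_trials,) int, 1-based
    attrs: schema_version, ground_truth (JSON, optional)
"""

from __future__ import annotations

import dataclasses
import json

import h5py

from .atlas import Parcellation
from .synth import GroundTruth, RealizedEffect, SourceEpochs

SCHEMA_VERSION = 1

__all__ = ["SchemaError", "write_dataset", "read_dataset"]


class SchemaError(ValueError):
    """The container does not conform to the documented schema."""


def write_dataset(
    path,
    subjects: list,
    parcellation: Parcellation,
    ground_truth: GroundTruth | None = None,
) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.create_dataset("time_ms", data=subjects[0].time_ms)
        fh.create_dataset("parcellation/assignment", data=parcellation.assignment)
        for i, ep in enumerate(subjects):
            grp = fh.create_group(f"subjects/s{i:03d}")
            grp.create_dataset("data", data=ep.data)
            lab = grp.create_group("labels")
            lab.create_dataset("stimulus", data=ep.stimulus)
            lab.create_dataset("section", data=ep.section)
            lab.create_dataset("presentation_order", data=ep.presentation_order)
        if ground_truth is not None:
            fh.attrs["ground_truth"] = json.dumps(
                [dataclasses.asdict(e) for e in ground_truth.effects]
            )


def _require(node, key: str):
    if key not in node:
        raise SchemaError(f"dataset is missing required field {node.name}/{key}")
    return node[key]


def read_dataset(path) -> tuple[list, Parcellation, GroundTruth | None]:
    """Materialize (subjects, parcellation, ground_truth-or-None)."""
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema_version {version!r}")
        time_ms = _require(fh, "time_ms")[()]
        parc_grp = _require(fh, "parcellation")
        assignment = _require(parc_grp, "assignment")[()]
        subj_grp = _require(fh, "subjects")
        subjects = []
        for name in sorted(subj_grp):
            grp = subj_grp[name]
            data = _require(grp, "data")[()]
            labels = _require(grp, "labels")
            subjects.append(
                SourceEpochs(
                    data=data,
                    time_ms=time_ms,
                    stimulus=_require(labels, "stimulus")[()],
                    section=_require(labels, "section")[()],
                    presentation_order=_require(labels, "presentation_order")[()],
                )
            )
        gt = None
        if "ground_truth" in fh.attrs:
            effects = tuple(
                RealizedEffect(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in record.items()
                    }
                )
                for record in json.loads(fh.attrs["ground_truth"])
            )
            gt = GroundTruth(effects=effects)
    parcellation = Parcellation(n_vertices=assignment.size, assignment=assignment)
    return subjects, parcellation, gt
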