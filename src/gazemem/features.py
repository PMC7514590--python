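"""Cross-level feature vectors from Multilevel Entropy Maps.

A feature set is named after the segment sizes it combines, e.g.
``set128_256_512``.  The finest size X defines the elements: each map
contributes ``nemr / X`` elements, the i-th covering samples
``(i-1)*X+1 .. i*X``.  The element's feature vector stacks the ApEn of
its own finest-level window with the ApEn of the *ancestor* windows
containing it at each coarser requested level — for size S that is
segment ``ceil(i*X / S)``.  The class label of an element is simply its
index i, so a classifier predicting the label is localising a time
window within the eye-movement series.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .mem import MemSpec, MultilevelEntropyMap

__all__ = [
    "FeatureSetSpec",
    "FeatureDataset",
    "build_features",
    "element_cells",
    "PAPER_FEATURE_SETS",
]

#: The ten canonical feature-set names (finest-to-coarsest sizes).
PAPER_FEATURE_SETS = (
    "set64",
    "set128",
    "set256",
    "set512",
    "set64_128",
    "set128_256",
    "set256_512",
    "set64_128_256",
    "set128_256_512",
    "set64_128_256_512",
)


@dataclass(frozen=True)
class FeatureSetSpec:
    """An ordered combination of MEM segment sizes."""

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.sizes:
            raise FormatError("feature set needs at least one segment size")
        if list(self.sizes) != sorted(set(self.sizes)):
            raise FormatError(
                f"segment sizes must be strictly increasing, got {self.sizes}"
            )
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))

    @classmethod
    def from_name(cls, name: str) -> "FeatureSetSpec":
        """Parse a name like ``set128_256_512``."""
        m = re.fullmatch(r"set(\d+(?:_\d+)*)", name)
        if not m:
            raise FormatError(f"not a feature-set name: {name!r}")
        return cls(tuple(int(s) for s in m.group(1).split("_")))

    @property
    def name(self) -> str:
        return "set" + "_".join(str(s) for s in self.sizes)

    @property
    def finest_size(self) -> int:
        return self.sizes[0]

    @property
    def dim(self) -> int:
        return len(self.sizes)

    def n_elements(self, mem_spec: MemSpec) -> int:
        """Elements per map = number of classes: nemr / finest size."""
        self.validate_against(mem_spec)
        return mem_spec.nemr // self.finest_size

    def validate_against(self, mem_spec: MemSpec) -> None:
        for s in self.sizes:
            mem_spec.level_for_size(s)  # raises if absent


def element_cells(
    spec: FeatureSetSpec, mem_spec: MemSpec, element: int
) -> list[tuple[int, int]]:
    """(level, segment) cells making up one element's feature vector.

    ``element`` is 1-based.  For each requested size S the cell is the
    window at that level containing the element's time span:
    segment ``ceil(element * X / S)`` where X is the finest size.
    """
    n_el = spec.n_elements(mem_spec)
    if not 1 <= element <= n_el:
        raise DataError(f"element {element} out of range 1..{n_el}")
    x = spec.finest_size
    return [
        (mem_spec.level_for_size(s), math.ceil(element * x / s))
        for s in spec.sizes
    ]


@dataclass
class FeatureDataset:
    """Labeled feature vectors ready for classification.

    One row per (map, element): ``X[i]`` is the feature vector, ``y[i]``
    the class label (the element's finest-level segment index, 1-based)
    and ``groups[i]`` the participant-session key used to form
    cross-validation folds.  ``meta`` carries provenance columns.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    meta: pd.DataFrame
    spec: FeatureSetSpec
    mem_spec: MemSpec

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        self.groups = np.asarray(self.groups)
        if not (len(self.X) == len(self.y) == len(self.groups) == len(self.meta)):
            raise DataError("feature dataset arrays must share length")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_classes(self) -> int:
        return self.spec.n_elements(self.mem_spec)

    def class_range(self, label: int) -> str:
        """Sample span of a class, e.g. label 2 of size 128 -> '129-256'."""
        x = self.spec.finest_size
        return f"{(label - 1) * x + 1}-{label * x}"

    @property
    def class_ranges(self) -> dict[int, str]:
        return {c: self.class_range(c) for c in range(1, self.n_classes + 1)}

    def subset(self, idx: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            X=self.X[idx],
            y=self.y[idx],
            groups=self.groups[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            spec=self.spec,
            mem_spec=self.mem_spec,
        )


def build_features(
    maps: Sequence[MultilevelEntropyMap],
    spec: FeatureSetSpec | str,
    mem_spec: Optional[MemSpec] = None,
) -> FeatureDataset:
    """Assemble a feature dataset from a collection of MEMs.

    All maps must share one :class:`MemSpec`, and every requested
    segment size must be a level of that spec.
    """
    if isinstance(spec, str):
        spec = FeatureSetSpec.from_name(spec)
    if not maps:
        raise DataError("no maps supplied")
    mspec = mem_spec or maps[0].spec
    if any(m.spec != mspec for m in maps):
        raise DataError("all maps must share one MemSpec")
    spec.validate_against(mspec)

    n_el = spec.n_elements(mspec)
    cells = [element_cells(spec, mspec, i) for i in range(1, n_el + 1)]

    rows, labels, groups, meta = [], [], [], []
    for m in maps:
        pid = str(m.provenance.get("participant_id", ""))
        sid = str(m.provenance.get("session_id", ""))
        stim = m.provenance.get("stimulus_index", -1)
        for i in range(1, n_el + 1):
            rows.append([m.cell(l, s) for l, s in cells[i - 1]])
            labels.append(i)
            groups.append(f"{pid}/{sid}")
            meta.append(
                {
                    "participant_id": pid,
                    "session_id": sid,
                    "stimulus_index": stim,
                    "element": i,
                }
            )
    return FeatureDataset(
        X=np.asarray(rows, dtype=float),
        y=np.asarray(labels, dtype=int),
        groups=np.asarray(groups),
        meta=pd.DataFrame(meta),
        spec=spec,
        mem_spec=mspec,
    )
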