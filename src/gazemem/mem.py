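"""The Multilevel Entropy Map (MEM).

A velocity series of length ``nemr`` is covered by a dyadic grid of
contiguous, non-overlapping segments: level 1 uses windows of ``nss``
samples, and each higher level doubles the window, so level ``l`` has
``nemr / (nss * 2**(l-1))`` segments.  Approximate entropy is computed
independently in every cell, giving a triangular time-scale picture of
signal regularity — the same grid a dyadic wavelet decomposition uses,
but carrying entropies rather than filter coefficients.

Levels and segments are numbered from 1, so ``MEM(l, s)`` is the
``s``-th window at level ``l``, matching the notation used in reports
and serialized files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .entropy import ApEnParams, apen_auto
from .errors import DataError
from .preprocess import EMSeries

__all__ = [
    "MemSpec",
    "MultilevelEntropyMap",
    "build_mem",
    "average_mems",
    "render_mem",
    "value_band",
    "BANDS",
]


@dataclass(frozen=True)
class MemSpec:
    """Geometry of a Multilevel Entropy Map.

    ``nemr`` is the series length, ``nss`` the finest (level-1) segment
    size and ``levels`` the number of dyadic levels; full coverage
    requires ``nemr == nss * 2**(levels-1)``.
    """

    nemr: int = 2048
    nss: int = 64
    levels: int = 6

    def __post_init__(self) -> None:
        if self.nss < 1 or self.levels < 1:
            raise DataError("nss and levels must be positive")
        if self.nemr != self.nss * 2 ** (self.levels - 1):
            raise DataError(
                f"nemr={self.nemr} must equal nss*2**(levels-1)="
                f"{self.nss * 2 ** (self.levels - 1)}"
            )

    def segment_size(self, level: int) -> int:
        """Window length at a 1-based level."""
        self._check_level(level)
        return self.nss * 2 ** (level - 1)

    def n_segments(self, level: int) -> int:
        """Number of windows at a 1-based level."""
        return self.nemr // self.segment_size(level)

    def level_for_size(self, size: int) -> int:
        """The level whose windows have the given length."""
        for level in range(1, self.levels + 1):
            if self.segment_size(level) == size:
                return level
        raise DataError(f"no MEM level has segment size {size}")

    @property
    def total_cells(self) -> int:
        return sum(self.n_segments(l) for l in range(1, self.levels + 1))

    def _check_level(self, level: int) -> None:
        if not 1 <= level <= self.levels:
            raise DataError(
                f"level {level} out of range 1..{self.levels}"
            )


@dataclass
class MultilevelEntropyMap:
    """ApEn values on the dyadic grid, with per-cell degeneracy flags.

    ``values[l-1][s-1]`` holds ``MEM(l, s)``; ``degenerate`` marks cells
    whose segment had zero variance (assigned ApEn 0).  ``provenance``
    records which series the map came from, or ``{"kind": "averaged"}``
    and the like for derived maps.
    """

    spec: MemSpec
    values: list[np.ndarray]
    degenerate: list[np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.values) != self.spec.levels:
            raise DataError("one value array per level required")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        self.degenerate = [np.asarray(d, dtype=bool) for d in self.degenerate]
        for level in range(1, self.spec.levels + 1):
            n = self.spec.n_segments(level)
            if self.values[level - 1].shape != (n,):
                raise DataError(
                    f"level {level} must have {n} cells, got "
                    f"{self.values[level - 1].shape}"
                )
            if self.degenerate[level - 1].shape != (n,):
                raise DataError(f"level {level} degeneracy flags malformed")
            if not np.all(np.isfinite(self.values[level - 1])):
                raise DataError(f"non-finite cell at level {level}")

    def cell(self, level: int, segment: int) -> float:
        """MEM(level, segment) with 1-based indices."""
        self.spec._check_level(level)
        n = self.spec.n_segments(level)
        if not 1 <= segment <= n:
            raise DataError(
                f"segment {segment} out of range 1..{n} at level {level}"
            )
        return float(self.values[level - 1][segment - 1])

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spec": {
                "nemr": self.spec.nemr,
                "nss": self.spec.nss,
                "levels": self.spec.levels,
            },
            "indexing": "levels and segments are 1-based",
            "provenance": self.provenance,
            "levels": [v.tolist() for v in self.values],
            "degenerate": [d.tolist() for d in self.degenerate],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultilevelEntropyMap":
        spec = MemSpec(**d["spec"])
        return cls(
            spec=spec,
            values=[np.asarray(v) for v in d["levels"]],
            degenerate=[np.asarray(x, dtype=bool) for x in d["degenerate"]],
            provenance=d.get("provenance", {}),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "MultilevelEntropyMap":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table: one row per cell with its sample window."""
        rows = []
        for level in range(1, self.spec.levels + 1):
            w = self.spec.segment_size(level)
            for seg in range(1, self.spec.n_segments(level) + 1):
                rows.append(
                    {
                        "level": level,
                        "segment": seg,
                        "start_sample": (seg - 1) * w + 1,
                        "end_sample": seg * w,
                        "apen": self.values[level - 1][seg - 1],
                        "degenerate": bool(self.degenerate[level - 1][seg - 1]),
                    }
                )
        return pd.DataFrame(rows)

    def save_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_mem(
    series: Union[EMSeries, np.ndarray],
    spec: MemSpec = MemSpec(),
    params: ApEnParams = ApEnParams(),
    provenance: Optional[dict] = None,
) -> MultilevelEntropyMap:
    """Compute the MEM of one velocity series.

    Each cell is ``apen_auto`` of the corresponding contiguous window
    ``v[(s-1)*w : s*w]`` with ``w = nss * 2**(l-1)``.  Under the global
    r policy the tolerance of every cell derives from the SD of the full
    series instead of each window's own.
    """
    if isinstance(series, EMSeries):
        v = series.v
        prov = {
            "participant_id": series.participant_id,
            "session_id": series.session_id,
            "stimulus_index": series.stimulus_index,
        }
    else:
        v = np.asarray(series, dtype=float)
        prov = {}
    if provenance is not None:
        prov = dict(provenance)
    if v.size != spec.nemr:
        raise DataError(
            f"series length {v.size} does not match spec nemr={spec.nemr}"
        )
    global_sd = float(np.std(v, ddof=1)) if params.r_policy == "global" else None

    values, flags = [], []
    for level in range(1, spec.levels + 1):
        w = spec.segment_size(level)
        nseg = spec.n_segments(level)
        vals = np.empty(nseg)
        degen = np.empty(nseg, dtype=bool)
        for seg in range(nseg):
            vals[seg], degen[seg] = apen_auto(
                v[seg * w : (seg + 1) * w], params, global_sd=global_sd
            )
        values.append(vals)
        flags.append(degen)
    return MultilevelEntropyMap(spec, values, flags, prov)


def average_mems(
    maps: Sequence[MultilevelEntropyMap],
    ddof: int = 1,
    exclude_degenerate: bool = False,
) -> tuple[MultilevelEntropyMap, MultilevelEntropyMap]:
    """Cellwise mean and SD across maps sharing one spec.

    Degenerate cells contribute their 0 value by default; with
    ``exclude_degenerate`` they are dropped from each cell's sample
    (a cell degenerate in every map falls back to 0).  Returns
    ``(mean_map, sd_map)``; a mean cell is flagged degenerate only if it
    was degenerate in every input map.
    """
    if not maps:
        raise DataError("cannot average an empty list of maps")
    spec = maps[0].spec
    if any(m.spec != spec for m in maps):
        raise DataError("all maps must share one MemSpec")
    n_eff_min = 1 + ddof
    mean_vals, sd_vals, mean_flags, zero_flags = [], [], [], []
    for level in range(1, spec.levels + 1):
        stack = np.stack([m.values[level - 1] for m in maps])
        degen = np.stack([m.degenerate[level - 1] for m in maps])
        if exclude_degenerate:
            ok = ~degen
            counts = ok.sum(axis=0)
            safe = np.maximum(counts, 1)
            mean = np.where(counts > 0, (stack * ok).sum(axis=0) / safe, 0.0)
            centered = np.where(ok, stack - mean, 0.0)
            var_n = np.maximum(counts - ddof, 1)
            sd = np.where(
                counts >= n_eff_min,
                np.sqrt((centered**2).sum(axis=0) / var_n),
                0.0,
            )
        else:
            mean = stack.mean(axis=0)
            sd = stack.std(axis=0, ddof=ddof) if len(maps) > ddof else np.zeros_like(mean)
        mean_vals.append(mean)
        sd_vals.append(sd)
        mean_flags.append(degen.all(axis=0))
        zero_flags.append(np.zeros_like(mean, dtype=bool))
    mean_map = MultilevelEntropyMap(
        spec, mean_vals, mean_flags, {"kind": "averaged", "n_maps": len(maps)}
    )
    sd_map = MultilevelEntropyMap(
        spec, sd_vals, zero_flags, {"kind": "cellwise_sd", "n_maps": len(maps)}
    )
    return mean_map, sd_map


#: Rendering palette: left-closed/right-open entropy bands.
BANDS = [
    (-np.inf, 0.4, "green", "#4daf4a"),
    (0.4, 0.5, "brown", "#a65628"),
    (0.5, 0.6, "blue", "#377eb8"),
    (0.6, 0.7, "light violet", "#c6a4e0"),
    (0.7, 0.8, "light burgundy", "#c76b79"),
    (0.8, 0.9, "light gray", "#cccccc"),
    (0.9, 1.0, "dark gray", "#777777"),
    (1.0, np.inf, "red", "#e41a1c"),
]


def value_band(value: float) -> str:
    """Name of the colour band an entropy value falls into."""
    for lo, hi, name, _ in BANDS:
        if lo <= value < hi:
            return name
    raise DataError(f"cannot band non-finite value {value}")


def _band_color(value: float) -> str:
    for lo, hi, _, color in BANDS:
        if lo <= value < hi:
            return color
    return "#ffffff"


def render_mem(mem: MultilevelEntropyMap, path: str | Path) -> None:
    """Render a map as a coloured grid image plus numeric CSV/JSON.

    The figure is written to ``path`` (extension selects PNG/SVG); the
    numeric map is written alongside with ``.csv`` and ``.json``
    suffixes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    path = Path(path)
    spec = mem.spec
    fig, ax = plt.subplots(
        figsize=(max(8.0, spec.n_segments(1) * 0.45), spec.levels * 0.8)
    )
    for level in range(1, spec.levels + 1):
        nseg = spec.n_segments(level)
        width = 1.0 / nseg
        ypos = spec.levels - level  # level 1 on top
        for seg in range(1, nseg + 1):
            val = mem.cell(level, seg)
            ax.add_patch(
                Rectangle(
                    ((seg - 1) * width, ypos),
                    width,
                    1.0,
                    facecolor=_band_color(val),
                    edgecolor="black",
                    linewidth=0.5,
                )
            )
            if nseg <= 32:
                ax.text(
                    (seg - 0.5) * width,
                    ypos + 0.5,
                    f"{val:.2f}",
                    ha="center",
                    va="center",
                    fontsize=7 if nseg > 16 else 9,
                )
        ax.text(
            -0.01,
            ypos + 0.5,
            f"{spec.segment_size(level)}",
            ha="right",
            va="center",
            fontsize=9,
        )
    ax.set_xlim(-0.06, 1)
    ax.set_ylim(0, spec.levels)
    ax.axis("off")
    ax.set_title("Multilevel Entropy Map", fontsize=11)
    try:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    except OSError as exc:
        raise DataError(f"cannot write rendering to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    mem.save_csv(path.with_suffix(".csv"))
    mem.save_json(path.with_suffix(".json"))
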