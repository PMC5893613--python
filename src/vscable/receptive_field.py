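"""Receptive-field vector maps: normalization, comparison, magnitude stats.

A receptive field (RF) is a map over discrete visual-field locations; each
location carries a 2-D response vector whose direction is the local preferred
direction (LPD) and whose magnitude is the local motion sensitivity (LMS).
The fly's visual field is discretized into a fixed shared grid (50 locations
in the source experiments), so RFs are compared location-id by location-id.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReceptiveField",
    "MagnitudeStats",
    "normalize",
    "difference_index",
    "magnitude_stats",
    "read_rf_csv",
    "write_rf_csv",
]


@dataclass(frozen=True)
class ReceptiveField:
    """A vector map over visual-field locations.

    ``vectors`` is (n, 2): horizontal (x) and vertical (y) response
    components in normalized response units. Azimuth/elevation are carried as
    metadata; all comparisons match locations by ``location_ids``.
    """

    location_ids: np.ndarray
    azimuth_deg: np.ndarray
    elevation_deg: np.ndarray
    vectors: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "location_ids", np.asarray(self.location_ids, dtype=int))
        object.__setattr__(self, "azimuth_deg", np.asarray(self.azimuth_deg, dtype=float))
        object.__setattr__(self, "elevation_deg", np.asarray(self.elevation_deg, dtype=float))
        object.__setattr__(self, "vectors", np.asarray(self.vectors, dtype=float))
        n = len(self.location_ids)
        if n < 1:
            raise ValueError("receptive field needs at least one location")
        if len(set(self.location_ids.tolist())) != n:
            raise ValueError("duplicate location ids")
        if self.vectors.shape != (n, 2):
            raise ValueError(f"vectors must be ({n}, 2), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite response vectors")

    @property
    def n_locations(self) -> int:
        return len(self.location_ids)

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    @property
    def is_normalized(self) -> bool:
        mags = self.magnitudes()
        return bool(abs(mags.max() - 1.0) <= 1e-9)

    def sorted_by_id(self) -> "ReceptiveField":
        order = np.argsort(self.location_ids)
        return replace(
            self,
            location_ids=self.location_ids[order],
            azimuth_deg=self.azimuth_deg[order],
            elevation_deg=self.elevation_deg[order],
            vectors=self.vectors[order],
        )

    def with_vectors(self, vectors: np.ndarray, label: str | None = None) -> "ReceptiveField":
        return replace(
            self,
            vectors=np.asarray(vectors, dtype=float),
            source_label=self.source_label if label is None else label,
        )


def normalize(rf: ReceptiveField) -> ReceptiveField:
    """Scale so the longest vector has length 1; directions are unchanged.

    All fields are normalized this way before integration or comparison,
    which amounts to assuming the maximal responses of different branchlets
    are equal.
    """
    mags = rf.magnitudes()
    peak = mags.max()
    if peak == 0:
        raise ValueError("all-zero receptive field cannot be normalized")
    return rf.with_vectors(rf.vectors / peak)


def _align(u: ReceptiveField, w: ReceptiveField) -> tuple[np.ndarray, np.ndarray]:
    su, sw = set(u.location_ids.tolist()), set(w.location_ids.tolist())
    if su != sw:
        missing = sorted(su.symmetric_difference(sw))
        raise ValueError(f"mismatched location sets; unmatched ids: {missing}")
    return u.sorted_by_id().vectors, w.sorted_by_id().vectors


def difference_index(u: ReceptiveField, w: ReceptiveField) -> float:
    """Mean Euclidean distance between corresponding vectors of two RFs.

    DI = (1/n) Σ_i sqrt((U_ix - W_ix)² + (U_iy - W_iy)²). Zero for identical
    fields; at most 2 for normalized fields (opposed unit-vector maps).
    """
    vu, vw = _align(u, w)
    return float(np.mean(np.linalg.norm(vu - vw, axis=1)))


@dataclass(frozen=True)
class MagnitudeStats:
    """Counts of vector magnitudes above/below thresholds (strict
    inequalities, matching 'larger than' / 'less than')."""

    magnitudes: np.ndarray

    @property
    def n(self) -> int:
        return len(self.magnitudes)

    def count_above(self, t: float) -> int:
        return int(np.sum(self.magnitudes > t))

    def frac_above(self, t: float) -> float:
        return self.count_above(t) / self.n

    def count_below(self, t: float) -> int:
        return int(np.sum(self.magnitudes < t))

    def frac_below(self, t: float) -> float:
        return self.count_below(t) / self.n

    def summary(self, thresholds: Sequence[float]) -> dict:
        return {
            "n": self.n,
            "thresholds": {
                str(t): {
                    "count_above": self.count_above(t),
                    "frac_above": self.frac_above(t),
                    "count_below": self.count_below(t),
                    "frac_below": self.frac_below(t),
                }
                for t in thresholds
            },
        }


def magnitude_stats(rf: ReceptiveField) -> MagnitudeStats:
    """Magnitude statistics of a (normalized) receptive field."""
    return MagnitudeStats(magnitudes=rf.magnitudes())


# ---------------------------------------------------------------------------
# Tabular I/O: CSV with columns
# source_label, location_id, azimuth_deg, elevation_deg, vx, vy
# ---------------------------------------------------------------------------

_RF_COLUMNS = ["source_label", "location_id", "azimuth_deg", "elevation_deg", "vx", "vy"]


def write_rf_csv(rfs: Iterable[ReceptiveField], path: str | Path) -> None:
    frames = []
    for rf in rfs:
        frames.append(
            pd.DataFrame(
                {
                    "source_label": rf.source_label,
                    "location_id": rf.location_ids,
                    "azimuth_deg": rf.azimuth_deg,
                    "elevation_deg": rf.elevation_deg,
                    "vx": rf.vectors[:, 0],
                    "vy": rf.vectors[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_rf_csv(path: str | Path) -> dict[str, ReceptiveField]:
    """Read one or many receptive fields keyed by ``source_label``."""
    df = pd.read_csv(path)
    missing = [c for c in _RF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[str, ReceptiveField] = {}
    for label, grp in df.groupby("source_label", sort=False):
        out[str(label)] = ReceptiveField(
            location_ids=grp["location_id"].to_numpy(),
            azimuth_deg=grp["azimuth_deg"].to_numpy(),
            elevation_deg=grp["elevation_deg"].to_numpy(),
            vectors=grp[["vx", "vy"]].to_numpy(),
            source_label=str(label),
        )
    return out
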