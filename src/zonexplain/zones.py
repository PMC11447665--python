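"""Spectral-zone partitions.

A zone is a contiguous wavenumber interval treated as one interpretable
feature.  Zones are delimited by the valleys between detected peaks — either
of a single spectrum (local explanation) or of a dataset's mean spectrum
(global explanation) — or supplied by the user from domain knowledge.  Every
ZoneSet is a true partition of the grid: contiguous, non-overlapping, and
jointly covering all points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .spectra import SpectraSet, Spectrum

__all__ = [
    "Zone",
    "ZoneSet",
    "detect_extrema",
    "zones_from_valleys",
    "local_zones",
    "global_zones",
    "load_user_zones",
    "write_zones",
]

#: detection pipelines merge zones narrower than this many grid points
MIN_ZONE_POINTS = 3


@dataclass(frozen=True)
class Zone:
    """A contiguous interval on the grid: wavenumbers [lo, hi], indices [start, end)."""

    lo: float
    hi: float
    start: int
    end: int

    def __post_init__(self) -> None:
        # single-point zones (lo == hi) can arise from adversarial valley
        # placements; detection pipelines merge them away
        if not (self.lo <= self.hi and self.start < self.end):
            raise ValueError(f"degenerate zone {self}")

    @property
    def n_points(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return f"{self.lo:g}–{self.hi:g} cm⁻¹"

    def contains(self, wavenumber: float) -> bool:
        return self.lo <= wavenumber <= self.hi


@dataclass
class ZoneSet:
    """An ordered partition of the grid into zones.

    Invariants (checked on construction): zone k ends where zone k+1 starts,
    the first zone starts at index 0, the last ends at n_points, and each
    zone's (lo, hi) equals (grid[start], grid[end-1]).
    """

    zones: list[Zone]
    grid: np.ndarray
    provenance: str = "user"  # local | global | user
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.zones:
            raise ValueError("ZoneSet needs at least one zone")
        self.grid = np.asarray(self.grid, dtype=float)
        n = self.grid.size
        if self.zones[0].start != 0 or self.zones[-1].end != n:
            raise ValueError("zones do not cover the grid")
        for k, z in enumerate(self.zones):
            if k and z.start != self.zones[k - 1].end:
                raise ValueError(
                    f"zones {k - 1} and {k} are not contiguous "
                    f"({self.zones[k - 1].end} != {z.start})"
                )
            if z.lo != self.grid[z.start] or z.hi != self.grid[z.end - 1]:
                raise ValueError(f"zone {k} wavenumbers disagree with its indices")

    def __len__(self) -> int:
        return len(self.zones)

    def __iter__(self):
        return iter(self.zones)

    def __getitem__(self, k: int) -> Zone:
        return self.zones[k]

    @property
    def labels(self) -> list[str]:
        return [z.label for z in self.zones]

    def point_to_zone(self) -> np.ndarray:
        """Zone index of every grid point."""
        out = np.empty(self.grid.size, dtype=int)
        for k, z in enumerate(self.zones):
            out[z.start : z.end] = k
        return out

    def zone_means(self, X: np.ndarray) -> np.ndarray:
        """Per-zone mean intensity for each row of an (n, n_points) matrix."""
        X = np.atleast_2d(X)
        return np.column_stack(
            [X[:, z.start : z.end].mean(axis=1) for z in self.zones]
        )


def _zones_from_boundaries(grid: np.ndarray, bounds: list[int], provenance: str,
                           params: dict | None = None) -> ZoneSet:
    """Build a ZoneSet from interior boundary indices (each begins a zone)."""
    edges = [0, *bounds, grid.size]
    zones = [
        Zone(lo=float(grid[a]), hi=float(grid[b - 1]), start=a, end=b)
        for a, b in zip(edges[:-1], edges[1:])
    ]
    return ZoneSet(zones=zones, grid=grid, provenance=provenance,
                   params=params or {})


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd point count")
    if window == 1:
        return y
    return uniform_filter1d(y, size=window, mode="nearest")


def detect_extrema(
    s: Spectrum,
    smooth_window: int = 5,
    min_prominence: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Find peak and valley positions (cm^-1) of a spectrum.

    The spectrum is smoothed by a centered moving average of ``smooth_window``
    points, peaks are local maxima whose prominence exceeds
    ``min_prominence * (max - min)`` of the smoothed trace, and valleys are
    the minima between consecutive retained peaks.  Positions are reported on
    the original grid, so detection is invariant to uniform intensity scaling.
    """
    if not 0 <= min_prominence < 1:
        raise ValueError("min_prominence must lie in [0, 1)")
    if s.n_points < smooth_window:
        raise ValueError(
            f"spectrum has {s.n_points} points, fewer than smooth_window="
            f"{smooth_window}"
        )
    y = _smooth(s.intensities, smooth_window)
    span = float(y.max() - y.min())
    if span == 0.0:
        return np.empty(0), np.empty(0)
    peak_idx, _ = find_peaks(y, prominence=min_prominence * span)
    valley_idx = []
    for a, b in zip(peak_idx[:-1], peak_idx[1:]):
        valley_idx.append(a + 1 + int(np.argmin(y[a + 1 : b])))
    return s.grid[peak_idx], s.grid[np.asarray(valley_idx, dtype=int)]


def zones_from_valleys(s: Spectrum, valleys: np.ndarray) -> ZoneSet:
    """Partition the grid at valley positions: k valleys give k+1 zones.

    Each valley index begins the zone to its right (half-open convention).
    """
    valleys = np.asarray(valleys, dtype=float)
    if valleys.size == 0:
        return _zones_from_boundaries(s.grid, [], provenance="local")
    if np.any(np.diff(valleys) <= 0):
        raise ValueError("valley positions must be strictly increasing (no duplicates)")
    if valleys[0] <= s.grid[0] or valleys[-1] >= s.grid[-1]:
        raise ValueError("valleys must lie strictly inside the grid range")
    idx = [int(np.argmin(np.abs(s.grid - v))) for v in valleys]
    if len(set(idx)) != len(idx) or 0 in idx or s.grid.size in idx:
        raise ValueError("valleys snap to duplicate or boundary grid indices")
    return _zones_from_boundaries(s.grid, sorted(idx), provenance="local")


def _merge_narrow(zs: ZoneSet, min_points: int = MIN_ZONE_POINTS,
                  intensities: np.ndarray | None = None) -> ZoneSet:
    """Merge zones narrower than ``min_points`` into a neighbor.

    The neighbor across the boundary with the lower intensity absorbs the
    narrow zone (falling back to the narrower neighbor without intensities).
    """
    bounds = [z.start for z in zs.zones[1:]]
    changed = True
    while changed and bounds:
        changed = False
        edges = [0, *bounds, zs.grid.size]
        for k in range(len(edges) - 1):
            if edges[k + 1] - edges[k] < min_points:
                # drop the boundary whose shared intensity is lower
                left_b = edges[k] if k > 0 else None
                right_b = edges[k + 1] if k + 1 < len(edges) - 1 else None
                if left_b is None:
                    drop = right_b
                elif right_b is None:
                    drop = left_b
                elif intensities is not None:
                    drop = left_b if intensities[left_b] <= intensities[right_b] else right_b
                else:
                    drop = left_b
                bounds.remove(drop)
                changed = True
                break
    return _zones_from_boundaries(zs.grid, bounds, zs.provenance, zs.params)


def local_zones(
    s: Spectrum, smooth_window: int = 5, min_prominence: float = 0.01
) -> ZoneSet:
    """Detect extrema of one spectrum and partition the grid at its valleys."""
    _, valleys = detect_extrema(s, smooth_window, min_prominence)
    zs = zones_from_valleys(s, valleys)
    zs = _merge_narrow(zs, intensities=s.intensities)
    zs.provenance = "local"
    zs.params = {"smooth_window": smooth_window, "min_prominence": min_prominence}
    return zs


def global_zones(
    ds: SpectraSet, smooth_window: int = 5, min_prominence: float = 0.01
) -> ZoneSet:
    """Zones of the dataset's pointwise mean spectrum (global understanding)."""
    if ds.n_spectra == 0:
        raise ValueError("dataset is empty")
    mean = ds.mean_spectrum()
    zs = local_zones(mean, smooth_window, min_prominence)
    zs.provenance = "global"
    return zs


def load_user_zones(path: str | Path, grid: np.ndarray) -> ZoneSet:
    """Load user-declared zones (rows of lo,hi in cm^-1) and complete the partition.

    Declared intervals are snapped to the nearest grid indices; gaps between
    them become "background" zones so the partition invariant holds.
    Overlapping declarations are an error.
    """
    grid = np.asarray(grid, dtype=float)
    df = pd.read_csv(path, comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    if "lo" not in cols or "hi" not in cols:
        raise ValueError(f"{path}: zone file needs columns lo,hi")
    rows = sorted(
        (float(r[cols["lo"]]), float(r[cols["hi"]])) for _, r in df.iterrows()
    )
    spans: list[tuple[int, int]] = []
    for lo, hi in rows:
        if lo >= hi:
            raise ValueError(f"zone ({lo:g}, {hi:g}) is empty or inverted")
        a = int(np.argmin(np.abs(grid - lo)))
        b = int(np.argmin(np.abs(grid - hi))) + 1  # half-open
        if spans and a < spans[-1][1]:
            plo, phi = grid[spans[-1][0]], grid[spans[-1][1] - 1]
            raise ValueError(
                f"zones overlap: ({lo:g}, {hi:g}) intersects ({plo:g}, {phi:g})"
            )
        spans.append((a, b))
    bounds: list[int] = []
    for a, b in spans:
        for edge in (a, b):
            if 0 < edge < grid.size and edge not in bounds:
                bounds.append(edge)
    zs = _zones_from_boundaries(grid, sorted(bounds), provenance="user",
                                params={"source": str(path)})
    return zs


def write_zones(zs: ZoneSet, path: str | Path) -> None:
    """Write a ZoneSet as delimited text with provenance metadata comments."""
    with open(path, "w") as fh:
        fh.write(f"# provenance={zs.provenance}\n")
        for k, v in zs.params.items():
            fh.write(f"# {k}={v}\n")
        fh.write("lo,hi\n")
        for z in zs.zones:
            fh.write(f"{z.lo:g},{z.hi:g}\n")
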