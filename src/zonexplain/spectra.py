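"""Core spectral data types, delimited-text I/O, and the model-adapter contract.

A :class:`Spectrum` is a single intensity trace on an ascending wavenumber
grid (cm^-1); a :class:`SpectraSet` is a stack of such traces sharing one
grid, with optional class labels and batch (bottle) identifiers.  A
:class:`ModelAdapter` wraps an opaque classifier ``f`` — a batch of intensity
vectors in, an ``n x n_classes`` probability matrix out — which is the only
thing the explainers ever see of the user's model.

The interchange format is wide delimited text: first column ``wavenumber``,
one column per spectrum.  Spectra on mismatched grids are rejected rather
than silently resampled; call :func:`resample` explicitly so that zone
indices mean the same thing across a dataset.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraSet",
    "ModelAdapter",
    "read_spectra",
    "write_spectra",
    "read_labels",
    "write_labels",
    "resample",
    "expected_value",
]

_DELIMITERS = ",\t;"


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("wavenumber grid must be a 1-D array with >= 2 points")
    if not np.all(np.isfinite(grid)):
        raise ValueError("wavenumber grid contains non-finite values")
    diffs = np.diff(grid)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 1
        raise ValueError(
            f"grid not ascending: wavenumber at row {row + 1} "
            f"({grid[row]:g}) does not exceed row {row} ({grid[row - 1]:g})"
        )
    return grid


@dataclass(frozen=True)
class Spectrum:
    """One intensity trace on an ascending wavenumber grid.

    Parameters
    ----------
    grid : array of float
        Strictly increasing wavenumbers in cm^-1.
    intensities : array of float
        Arbitrary-unit intensities, same length as ``grid``, no NaN.
    id : str
        Text label for the spectrum.
    """

    grid: np.ndarray
    intensities: np.ndarray
    id: str = "spectrum"

    def __post_init__(self) -> None:
        grid = _check_grid(self.grid)
        intens = np.asarray(self.intensities, dtype=float)
        if intens.shape != grid.shape:
            raise ValueError(
                f"intensities length {intens.size} != grid length {grid.size}"
            )
        if not np.all(np.isfinite(intens)):
            raise ValueError(f"spectrum {self.id!r} contains non-finite intensities")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "intensities", intens)

    @property
    def n_points(self) -> int:
        return self.grid.size


@dataclass
class SpectraSet:
    """A stack of spectra on one shared grid with aligned metadata.

    ``labels`` holds the class per row and ``batches`` the bottle/batch id
    per row; either may be ``None`` for unlabeled data.
    """

    grid: np.ndarray
    matrix: np.ndarray
    ids: list[str] = field(default_factory=list)
    labels: list[str] | None = None
    batches: list[str] | None = None

    def __post_init__(self) -> None:
        self.grid = _check_grid(self.grid)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.grid.size:
            raise ValueError(
                f"matrix shape {self.matrix.shape} incompatible with grid of "
                f"{self.grid.size} points"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("intensity matrix contains non-finite values")
        n = self.matrix.shape[0]
        if not self.ids:
            self.ids = [f"s{i}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError("ids do not align with matrix rows")
        for name, meta in (("labels", self.labels), ("batches", self.batches)):
            if meta is not None and len(meta) != n:
                raise ValueError(f"{name} do not align with matrix rows")

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.size

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[i], id=self.ids[i])

    def mean_spectrum(self, id: str = "mean") -> Spectrum:
        return Spectrum(self.grid, self.matrix.mean(axis=0), id=id)

    def subset(self, rows: Sequence[int]) -> "SpectraSet":
        rows = list(rows)
        return SpectraSet(
            grid=self.grid,
            matrix=self.matrix[rows],
            ids=[self.ids[i] for i in rows],
            labels=None if self.labels is None else [self.labels[i] for i in rows],
            batches=None if self.batches is None else [self.batches[i] for i in rows],
        )

    def by_class(self, label: str) -> "SpectraSet":
        if self.labels is None:
            raise ValueError("dataset has no class labels")
        rows = [i for i, lab in enumerate(self.labels) if lab == label]
        if not rows:
            raise ValueError(f"no spectra labeled {label!r}")
        return self.subset(rows)

    @property
    def classes(self) -> list[str]:
        if self.labels is None:
            return []
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        return list(seen)


@dataclass
class ModelAdapter:
    """The opaque model ``f`` seen by every explainer.

    ``predict_fn`` maps an ``(n, n_points)`` float array of intensities on
    ``grid`` to an ``(n, n_classes)`` probability matrix.  With
    ``strict=True`` (the default for real classifiers) each output row must
    be a probability simplex to within 1e-6; analytic toy models that emit
    raw scores set ``strict=False``.
    """

    predict_fn: Callable[[np.ndarray], np.ndarray]
    class_names: list[str]
    grid: np.ndarray | None = None
    strict: bool = True

    def __post_init__(self) -> None:
        if self.grid is not None:
            self.grid = _check_grid(self.grid)
        if not self.class_names:
            raise ValueError("class_names must be non-empty")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown class {name!r}; known classes: {self.class_names}"
            ) from None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.grid is not None and X.shape[1] != self.grid.size:
            raise ValueError(
                f"model expects {self.grid.size} points, got {X.shape[1]}"
            )
        out = np.asarray(self.predict_fn(X), dtype=float)
        if out.ndim != 2 or out.shape != (X.shape[0], self.n_classes):
            raise ValueError(
                f"model returned shape {out.shape}, expected "
                f"({X.shape[0]}, {self.n_classes})"
            )
        if self.strict:
            sums = out.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6) or np.any(out < -1e-9):
                raise ValueError("model output rows are not probability simplices")
        return out

    __call__ = predict


# ---------------------------------------------------------------------------
# I/O


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(65536)
    try:
        return csv.Sniffer().sniff(sample, delimiters=_DELIMITERS).delimiter
    except csv.Error:
        return ","


def read_spectra(path: str | Path, label_path: str | Path | None = None) -> SpectraSet:
    """Read a wide-format spectra file (and optional label table).

    First column is the wavenumber axis; every remaining column is one
    spectrum, named by its header.  The label file maps spectrum id to
    ``class`` and ``batch``.  Non-monotone wavenumbers and unmatched label
    ids are hard errors with row/column context.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    # round_trip parser: bit-exact write→read identity for %.17g output
    df = pd.read_csv(path, sep=delim, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a wavenumber column plus >= 1 spectrum")
    bad = df.columns[df.isna().any()]
    if len(bad):
        raise ValueError(f"{path}: missing values in columns {list(bad)}")
    grid = df.iloc[:, 0].to_numpy(dtype=float)
    try:
        grid = _check_grid(grid)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
    ids = [str(c) for c in df.columns[1:]]
    matrix = df.iloc[:, 1:].to_numpy(dtype=float).T

    labels = batches = None
    if label_path is not None:
        labels_by_id, batches_by_id = read_labels(label_path)
        missing = [i for i in ids if i not in labels_by_id]
        extra = [i for i in labels_by_id if i not in ids]
        if missing or extra:
            raise ValueError(
                f"label/column mismatch: spectra without labels {missing[:10]}, "
                f"labels without spectra {extra[:10]}"
            )
        labels = [labels_by_id[i] for i in ids]
        batches = [batches_by_id[i] for i in ids]
    return SpectraSet(grid=grid, matrix=matrix, ids=ids, labels=labels, batches=batches)


def read_labels(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a label table with columns id, class, batch."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for req in ("id", "class"):
        if req not in cols:
            raise ValueError(f"{path}: label file needs a {req!r} column")
    ids = df[cols["id"]].tolist()
    labels = dict(zip(ids, df[cols["class"]].tolist()))
    if "batch" in cols:
        batches = dict(zip(ids, df[cols["batch"]].astype(str).tolist()))
    else:
        batches = {i: "0" for i in ids}
    return labels, batches


def write_spectra(ds: SpectraSet, path: str | Path, delimiter: str = ",") -> None:
    """Write a SpectraSet as wide delimited text, full precision (round-trips)."""
    df = pd.DataFrame(ds.matrix.T, columns=ds.ids)
    df.insert(0, "wavenumber", ds.grid)
    # %.17g round-trips IEEE doubles bit-exactly through text
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def write_labels(ds: SpectraSet, path: str | Path, delimiter: str = ",") -> None:
    if ds.labels is None:
        raise ValueError("dataset has no labels to write")
    batches = ds.batches if ds.batches is not None else ["0"] * ds.n_spectra
    pd.DataFrame({"id": ds.ids, "class": ds.labels, "batch": batches}).to_csv(
        path, sep=delimiter, index=False
    )


# ---------------------------------------------------------------------------
# grid alignment and reference statistics


def resample(s: Spectrum, target_grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target_grid``.

    Values at grid points shared with the source grid are preserved exactly;
    any point outside the source range is an error (no extrapolation).
    """
    target = _check_grid(np.asarray(target_grid, dtype=float))
    if target[0] < s.grid[0] or target[-1] > s.grid[-1]:
        raise ValueError(
            f"target grid [{target[0]:g}, {target[-1]:g}] extends beyond source "
            f"range [{s.grid[0]:g}, {s.grid[-1]:g}]; extrapolation is not supported"
        )
    values = np.interp(target, s.grid, s.intensities)
    return Spectrum(target, values, id=s.id)


def expected_value(
    model: ModelAdapter, reference: SpectraSet, class_index: int
) -> float:
    """Mean model output E[f(x)] for one class over a reference set."""
    if reference.n_spectra == 0:
        raise ValueError("reference set is empty")
    probs = model.predict(reference.matrix)
    if not 0 <= class_index < probs.shape[1]:
        raise IndexError(f"class_index {class_index} out of range")
    return float(probs[:, class_index].mean())
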