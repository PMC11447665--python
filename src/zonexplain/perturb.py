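"""Group perturbations: build the perturbation set Z by replacing or
transforming whole spectral zones.

Three generation strategies are supported, chosen by data availability:

``dataset_substitution``
    masked zones are replaced from a reference dataset (or by zeros / the
    pointwise reference mean),
``transform_augmented``
    masked zones are substituted from a reference spectrum after a smoothing
    or sharpening transform, widening the diversity of a thin dataset,
``input_augmented``
    no dataset at all — masked zones of the input itself are transformed.

Whatever the strategy, every perturbed spectrum equals the original
bit-exactly on every retained (mask = 1) zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .spectra import SpectraSet, Spectrum
from .zones import Zone, ZoneSet

__all__ = [
    "PerturbationSpec",
    "PerturbationSet",
    "replace_zones",
    "transform_zone",
    "build_perturbation_set",
    "draw_masks",
]

STRATEGIES = ("dataset_substitution", "transform_augmented", "input_augmented")
BASELINES = ("zero", "reference_mean", "reference_sample")


@dataclass(frozen=True)
class PerturbationSpec:
    """How to build a perturbation set.

    ``n_samples`` perturbed spectra are generated with zone masks drawn
    uniformly over non-trivial binary vectors (the all-ones mask is excluded
    as uninformative; the all-zeros mask anchors the baseline).  ``seed`` is
    mandatory because every strategy is stochastic.  ``smooth_width`` (odd
    points) and ``sharpen_strength`` parameterize the transform strategies.
    """

    strategy: str = "dataset_substitution"
    baseline: str = "reference_mean"
    n_samples: int = 100
    seed: int = 0
    smooth_width: int = 9
    sharpen_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; one of {STRATEGIES}")
        if self.baseline not in BASELINES:
            raise ValueError(f"unknown baseline {self.baseline!r}; one of {BASELINES}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory for stochastic perturbation")


@dataclass
class PerturbationSet:
    """The perturbed spectra Z with their binary zone masks."""

    samples: np.ndarray  # (n_samples, n_points)
    masks: np.ndarray  # (n_samples, n_zones), 1 = zone retained from x
    source: PerturbationSpec = field(default_factory=PerturbationSpec)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def to_spectra(self, grid: np.ndarray) -> SpectraSet:
        """Export as a SpectraSet for inspection in the wide text format."""
        return SpectraSet(grid=grid, matrix=self.samples,
                          ids=[f"z{i}" for i in range(self.n_samples)])


def _require_reference(reference: SpectraSet | None, baseline: str) -> SpectraSet:
    if reference is None:
        raise ValueError(f"baseline {baseline!r} requires a reference SpectraSet")
    return reference


def replace_zones(
    x: Spectrum,
    zs: ZoneSet,
    mask: np.ndarray,
    baseline: str = "reference_mean",
    reference: SpectraSet | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Replace the masked-out zones of ``x``.

    Zones with mask 1 are copied from ``x`` bit-exactly; zones with mask 0
    are filled with zeros, the pointwise reference mean restricted to the
    zone, or the corresponding zone of one reference spectrum drawn
    uniformly (one donor per call).
    """
    mask = np.asarray(mask)
    if mask.size != len(zs):
        raise ValueError(f"mask length {mask.size} != zone count {len(zs)}")
    out = x.intensities.copy()
    replaced = [z for z, m in zip(zs, mask) if not m]
    if not replaced:
        return out
    if baseline == "zero":
        filler = np.zeros(x.n_points)
    elif baseline == "reference_mean":
        ref = _require_reference(reference, baseline)
        filler = ref.matrix.mean(axis=0)
    elif baseline == "reference_sample":
        ref = _require_reference(reference, baseline)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        filler = ref.matrix[int(rng.integers(ref.n_spectra))]
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    for z in replaced:
        out[z.start : z.end] = filler[z.start : z.end]
    return out


def transform_zone(
    x: Spectrum, z: Zone, kind: str, strength: float
) -> np.ndarray:
    """Smooth or sharpen one zone of ``x``, leaving the rest untouched.

    ``smooth``: centered moving average of ``strength`` points inside the
    zone.  ``sharpen``: unsharp masking, ``x + strength * (x - smoothed x)``
    inside the zone.
    """
    if strength <= 0:
        raise ValueError("strength must be > 0")
    out = x.intensities.copy()
    seg = x.intensities[z.start : z.end]
    if kind == "smooth":
        width = int(strength)
        if width % 2 == 0:
            width += 1
        if z.n_points < width:
            raise ValueError(
                f"zone {z.label} has {z.n_points} points, narrower than "
                f"smoothing width {width}"
            )
        out[z.start : z.end] = uniform_filter1d(seg, size=width, mode="nearest")
    elif kind == "sharpen":
        width = 5 if z.n_points >= 5 else (z.n_points | 1)
        smoothed = uniform_filter1d(seg, size=width, mode="nearest")
        out[z.start : z.end] = seg + strength * (seg - smoothed)
    else:
        raise ValueError(f"unknown transform kind {kind!r} (smooth | sharpen)")
    return out


def draw_masks(n_zones: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Draw masks uniformly over binary vectors excluding all-ones."""
    if n_zones < 1:
        raise ValueError("need at least one zone")
    masks = np.empty((n_samples, n_zones), dtype=np.int8)
    for i in range(n_samples):
        while True:
            m = rng.integers(0, 2, size=n_zones, dtype=np.int8)
            if not m.all():
                masks[i] = m
                break
    return masks


def build_perturbation_set(
    x: Spectrum,
    zs: ZoneSet,
    spec: PerturbationSpec,
    reference: SpectraSet | None = None,
) -> PerturbationSet:
    """Generate ``spec.n_samples`` perturbed spectra of ``x`` with zone masks."""
    needs_ref = spec.strategy == "transform_augmented" or (
        spec.strategy == "dataset_substitution" and spec.baseline != "zero"
    )
    if needs_ref:
        ref = _require_reference(reference, spec.strategy)
        if ref.n_points != x.n_points or not np.array_equal(ref.grid, x.grid):
            raise ValueError("reference grid does not match the instance grid")
    rng = np.random.default_rng(spec.seed)
    masks = draw_masks(len(zs), spec.n_samples, rng)
    samples = np.empty((spec.n_samples, x.n_points))
    for i, mask in enumerate(masks):
        if spec.strategy == "dataset_substitution":
            samples[i] = replace_zones(x, zs, mask, spec.baseline, reference, rng)
        elif spec.strategy == "transform_augmented":
            donor_row = reference.matrix[int(rng.integers(reference.n_spectra))]
            donor = Spectrum(x.grid, donor_row, id="donor")
            zi = donor_row.copy()
            for z, m in zip(zs, mask):
                if not m:
                    kind = "smooth" if rng.random() < 0.5 else "sharpen"
                    strength = (spec.smooth_width if kind == "smooth"
                                else spec.sharpen_strength)
                    if kind == "smooth" and z.n_points < spec.smooth_width:
                        kind, strength = "sharpen", spec.sharpen_strength
                    zi[z.start : z.end] = transform_zone(donor, z, kind, strength)[
                        z.start : z.end
                    ]
            out = x.intensities.copy()
            for z, m in zip(zs, mask):
                if not m:
                    out[z.start : z.end] = zi[z.start : z.end]
            samples[i] = out
        else:  # input_augmented
            out = x.intensities.copy()
            for z, m in zip(zs, mask):
                if not m:
                    kind = "smooth" if rng.random() < 0.5 else "sharpen"
                    strength = (spec.smooth_width if kind == "smooth"
                                else spec.sharpen_strength)
                    if kind == "smooth" and z.n_points < spec.smooth_width:
                        kind, strength = "sharpen", spec.sharpen_strength
                    out[z.start : z.end] = transform_zone(x, z, kind, strength)[
                        z.start : z.end
                    ]
            samples[i] = out
    return PerturbationSet(samples=samples, masks=masks, source=spec)
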