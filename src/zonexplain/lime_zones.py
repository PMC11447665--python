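"""Zone-based LIME: a weighted sparse linear surrogate over zone masks.

The surrogate g operates on the binary zone representation of a perturbed
spectrum z (1 = zone retained from x, 0 = replaced/transformed) and is fit
by minimizing the proximity-weighted squared loss

    sum_z pi_x(z) * (f(z) - g(mask(z)))^2

subject to a hard sparsity cap of K nonzero coefficients, enforced by greedy
forward selection followed by weighted least squares on the selected zones.
Proximity pi_x(z) = exp(-d^2 / width^2) with d the fraction of zones
replaced, so pi_x(x) = 1 and weight decays with distance from x.

Unlike Shapley values, LIME coefficients are *not* additive feature
attributions: they do not decompose the path from the expected output to the
prediction, and waterfall rendering of a LIME Attribution is refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .perturb import PerturbationSpec, build_perturbation_set
from .shap_zones import Attribution
from .spectra import ModelAdapter, SpectraSet, Spectrum
from .zones import ZoneSet

__all__ = ["ProximityKernel", "SurrogateFit", "proximity", "zone_lime_explain"]

DEFAULT_KERNEL_WIDTH = 0.25
DEFAULT_K = 10


@dataclass(frozen=True)
class ProximityKernel:
    """Exponential kernel on the replaced-zone fraction.

    d(x, z) = (# mask zeros) / n_zones, weight = exp(-d^2 / width^2):
    1 at the instance itself, strictly decreasing in d.
    """

    width: float = DEFAULT_KERNEL_WIDTH

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("kernel width must be > 0")

    def __call__(self, mask: np.ndarray) -> float:
        return proximity(mask, self.width)


def proximity(mask: np.ndarray, width: float) -> float:
    """Weight of one perturbation: exp(-(replaced fraction)^2 / width^2)."""
    if width <= 0:
        raise ValueError("kernel width must be > 0")
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    d = float(np.count_nonzero(mask == 0)) / mask.size
    return float(np.exp(-(d**2) / width**2))


@dataclass
class SurrogateFit:
    """Diagnostics of the fitted sparse linear surrogate."""

    coefficients: np.ndarray
    intercept: float
    kernel_width: float
    n_samples: int
    sparsity_cap: int
    fidelity: float  # weighted R^2 of g against f on the perturbation sample
    seed: int
    selected: list[int] | None = None


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted least squares with intercept; returns (coef, residual SS)."""
    sw = np.sqrt(w)
    A = np.column_stack([np.ones(len(y)), X]) * sw[:, None]
    b = y * sw
    coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError("rank deficient")
    rss = float(np.sum((A @ coef - b) ** 2))
    return coef, rss


def zone_lime_explain(
    model: ModelAdapter,
    x: Spectrum,
    zs: ZoneSet,
    spec: PerturbationSpec | None = None,
    K: int = DEFAULT_K,
    kernel_width: float = DEFAULT_KERNEL_WIDTH,
    class_index: int = 0,
    seed: int = 0,
    reference: SpectraSet | None = None,
) -> tuple[Attribution, SurrogateFit]:
    """Fit the zone LIME surrogate around ``x`` and return its coefficients.

    Masks and perturbed spectra come from :func:`build_perturbation_set`;
    at least ``5 * n_zones`` samples are recommended.  The returned
    Attribution carries the coefficients (zero for unselected zones) with
    ``base_value`` holding the surrogate intercept; by contract these
    coefficients do not satisfy the additive path from base to prediction.
    """
    n = len(zs)
    if spec is None:
        spec = PerturbationSpec(n_samples=max(5 * n, 50), seed=seed)
    pset = build_perturbation_set(x, zs, spec, reference)
    y = model.predict(pset.samples)[:, class_index]
    w = np.array([proximity(m, kernel_width) for m in pset.masks])
    M = pset.masks.astype(float)

    K = min(K, n)
    if np.allclose(y, y[0]):
        # constant model: intercept only, all coefficients zero
        coef_full = np.zeros(n)
        intercept = float(y[0])
        fidelity = 1.0
        selected: list[int] = []
    else:
        selected = _forward_select(M, y, w, K)
        try:
            coef_sel, rss = _wls(M[:, selected], y, w)
        except np.linalg.LinAlgError:
            raise ValueError(
                "design matrix is rank deficient after selection; "
                "increase n_samples"
            ) from None
        intercept = float(coef_sel[0])
        coef_full = np.zeros(n)
        coef_full[selected] = coef_sel[1:]
        ybar = float(np.average(y, weights=w))
        tss = float(np.sum(w * (y - ybar) ** 2))
        fidelity = 1.0 - rss / tss if tss > 0 else 1.0

    prediction = float(model.predict(x.intensities[None, :])[0, class_index])
    att = Attribution(
        zone_set=zs,
        values=coef_full,
        base_value=intercept,
        prediction=prediction,
        class_index=class_index,
        method="lime",
        n_evaluations=pset.n_samples + 1,
        seed=spec.seed,
        class_name=model.class_names[class_index],
        instance_id=x.id,
    )
    fit = SurrogateFit(
        coefficients=coef_full,
        intercept=intercept,
        kernel_width=kernel_width,
        n_samples=pset.n_samples,
        sparsity_cap=K,
        fidelity=fidelity,
        seed=spec.seed,
        selected=sorted(selected),
    )
    return att, fit


def _forward_select(M: np.ndarray, y: np.ndarray, w: np.ndarray, K: int) -> list[int]:
    """Greedy forward selection of K columns minimizing weighted RSS."""
    n = M.shape[1]
    selected: list[int] = []
    remaining = list(range(n))
    for _ in range(K):
        best, best_rss = None, np.inf
        for j in remaining:
            cols = selected + [j]
            try:
                _, rss = _wls(M[:, cols], y, w)
            except np.linalg.LinAlgError:
                continue
            if rss < best_rss - 1e-15:
                best, best_rss = j, rss
        if best is None:
            break
        selected.append(best)
        remaining.remove(best)
    if not selected:
        raise ValueError(
            "forward selection found no usable zone; increase n_samples"
        )
    return selected
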