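"""Zone-level Shapley values.

A coalition S is a subset of zones retained from the explained spectrum x;
zones outside S are replaced per the chosen baseline (zero, pointwise
reference mean, or a sampled reference spectrum's zone).  The value of a
coalition is the model's class probability for the resulting spectrum.  The
Shapley value of zone i is then the classic weighted average of its marginal
contributions

    phi_i = sum_{S subseteq B \\ {i}} |S|! (n-|S|-1)! / n! * [v(S u {i}) - v(S)]

computed by full 2^n enumeration for small zone counts
(:func:`exact_zone_shap`) or by Monte-Carlo permutation sampling for large
(:func:`sampling_zone_shap`).  Model calls are batched and memoized by
coalition bitmask, so an identical coalition is never evaluated twice.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .perturb import replace_zones
from .spectra import ModelAdapter, SpectraSet, Spectrum
from .zones import Zone, ZoneSet

__all__ = [
    "Attribution",
    "CoalitionGame",
    "exact_zone_shap",
    "sampling_zone_shap",
    "explain_dataset",
    "DEFAULT_EXACT_CAP",
    "DEFAULT_N_DRAWS",
]

DEFAULT_EXACT_CAP = 20
DEFAULT_N_DRAWS = 5000
_BATCH = 2048


@dataclass
class Attribution:
    """Per-zone contributions for one instance and one class.

    ``base_value`` is the model output on the empty coalition (every zone
    replaced by the baseline) — the start of the waterfall path; it estimates
    the expected model output, which is also stored as ``expected_value``
    when a reference set was designated.  For SHAP methods the efficiency
    axiom ties everything together: sum(values) = prediction - base_value
    (exactly for exact enumeration, within sampling error otherwise).  LIME
    coefficients do not satisfy that path; see the lime module.
    """

    zone_set: ZoneSet
    values: np.ndarray
    base_value: float
    prediction: float
    class_index: int
    method: str  # exact_shap | sampling_shap | lime
    n_evaluations: int = 0
    seed: int | None = None
    stderr: np.ndarray | None = None
    expected_value: float | None = None
    class_name: str | None = None
    instance_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.zone_set):
            raise ValueError("one value per zone required")

    def to_document(self) -> dict:
        doc = {
            "method": self.method,
            "class_index": int(self.class_index),
            "class_name": None if self.class_name is None else str(self.class_name),
            "instance_id": None if self.instance_id is None else str(self.instance_id),
            "base_value": _sig(self.base_value),
            "prediction": _sig(self.prediction),
            "expected_value": None if self.expected_value is None
            else _sig(self.expected_value),
            "n_evaluations": int(self.n_evaluations),
            "seed": self.seed,
            "zones": [
                {"lo": z.lo, "hi": z.hi, "value": _sig(v)}
                for z, v in zip(self.zone_set, self.values)
            ],
        }
        if self.stderr is not None:
            for row, se in zip(doc["zones"], self.stderr):
                row["stderr"] = _sig(float(se))
        if self.method == "lime":
            doc["note"] = (
                "LIME coefficients are not additive feature attributions: they "
                "do not decompose the path from base_value to prediction."
            )
        return doc

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_document(), fh, sort_keys=False,
                           allow_unicode=True)


def _sig(v: float, digits: int = 6) -> float:
    """Round to 6 significant digits for serialized output."""
    if v == 0 or not math.isfinite(v):
        return float(v)
    return float(f"{v:.{digits}g}")


class CoalitionGame:
    """The set function v(S) behind zone SHAP, with bitmask memoization.

    A coalition is encoded as an integer bitmask (bit i set = zone i retained
    from x).  For the ``reference_sample`` baseline one donor spectrum is
    drawn up front so v is a well-defined deterministic function.
    """

    def __init__(
        self,
        model: ModelAdapter,
        x: Spectrum,
        zs: ZoneSet,
        baseline: str,
        reference: SpectraSet | None,
        class_index: int,
        seed: int | None = None,
    ) -> None:
        self.model = model
        self.x = x
        self.zs = zs
        self.baseline = baseline
        self.reference = reference
        self.class_index = class_index
        self._cache: dict[int, float] = {}
        self.n_evaluations = 0
        rng = np.random.default_rng(seed)
        self._donor_rng = np.random.default_rng(int(rng.integers(2**31)))
        # freeze the donor for reference_sample so v(S) is deterministic
        self._frozen_seed = int(rng.integers(2**31))

    def spectrum_for(self, bitmask: int) -> np.ndarray:
        mask = np.array(
            [(bitmask >> i) & 1 for i in range(len(self.zs))], dtype=np.int8
        )
        return replace_zones(
            self.x, self.zs, mask, self.baseline, self.reference,
            seed=self._frozen_seed,
        )

    def evaluate(self, bitmasks: list[int]) -> np.ndarray:
        """v(S) for a batch of coalitions, memoized and chunk-batched."""
        todo = sorted({b for b in bitmasks if b not in self._cache})
        for lo in range(0, len(todo), _BATCH):
            chunk = todo[lo : lo + _BATCH]
            X = np.stack([self.spectrum_for(b) for b in chunk])
            probs = self.model.predict(X)[:, self.class_index]
            for b, p in zip(chunk, probs):
                self._cache[b] = float(p)
            self.n_evaluations += len(chunk)
        return np.array([self._cache[b] for b in bitmasks])

    def value(self, bitmask: int) -> float:
        return float(self.evaluate([bitmask])[0])


def _shapley_weights(n: int) -> np.ndarray:
    """w[s] = s! (n-s-1)! / n! for coalition sizes s = 0..n-1."""
    return np.array(
        [math.factorial(s) * math.factorial(n - s - 1) / math.factorial(n)
         for s in range(n)]
    )


def exact_zone_shap(
    model: ModelAdapter,
    x: Spectrum,
    zs: ZoneSet,
    baseline: str = "reference_mean",
    reference: SpectraSet | None = None,
    class_index: int = 0,
    seed: int | None = None,
    cap: int = DEFAULT_EXACT_CAP,
) -> Attribution:
    """Exact zone Shapley values by full coalition enumeration.

    Enumerates all 2^n coalitions, so the zone count must not exceed ``cap``
    (default 20).  The efficiency axiom holds exactly:
    sum(phi) == v(full) - v(empty).
    """
    n = len(zs)
    if n > cap:
        raise ValueError(
            f"{n} zones exceed the exact-enumeration cap ({cap}); "
            "use sampling_zone_shap instead"
        )
    game = CoalitionGame(model, x, zs, baseline, reference, class_index, seed)
    all_masks = list(range(2**n))
    v = game.evaluate(all_masks)
    w = _shapley_weights(n)
    sizes = np.array([bin(b).count("1") for b in all_masks])
    phi = np.zeros(n)
    for i in range(n):
        bit = 1 << i
        without = np.array([b for b in all_masks if not b & bit])
        s = sizes[without]
        phi[i] = float(np.sum(w[s] * (v[without | bit] - v[without])))
    full, empty = (2**n) - 1, 0
    return Attribution(
        zone_set=zs,
        values=phi,
        base_value=float(v[empty]),
        prediction=float(v[full]),
        class_index=class_index,
        method="exact_shap",
        n_evaluations=game.n_evaluations,
        seed=seed,
        class_name=model.class_names[class_index],
        instance_id=x.id,
    )


def sampling_zone_shap(
    model: ModelAdapter,
    x: Spectrum,
    zs: ZoneSet,
    baseline: str = "reference_mean",
    reference: SpectraSet | None = None,
    class_index: int = 0,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
) -> Attribution:
    """Monte-Carlo zone Shapley values by permutation sampling.

    Each of ``n_draws`` uniform random zone permutations contributes, for
    every zone, the marginal contribution of adding that zone to the
    coalition of zones preceding it.  The per-zone averages are unbiased
    estimates of the exact Shapley values and are reported with standard
    errors (std of the marginals / sqrt(n_draws)).
    """
    n = len(zs)
    if n_draws < 2 * n:
        raise ValueError(f"n_draws must be >= 2 * zone count ({2 * n})")
    game = CoalitionGame(model, x, zs, baseline, reference, class_index, seed)
    rng = np.random.default_rng(seed)
    sums = np.zeros(n)
    sumsq = np.zeros(n)
    full = (2**n) - 1
    for _ in range(n_draws):
        perm = rng.permutation(n)
        masks = [0]
        b = 0
        for z in perm:
            b |= 1 << int(z)
            masks.append(b)
        v = game.evaluate(masks)
        marg = np.diff(v)
        sums[perm] += marg
        sumsq[perm] += marg**2
    phi = sums / n_draws
    var = np.maximum(sumsq / n_draws - phi**2, 0.0)
    stderr = np.sqrt(var / n_draws)
    return Attribution(
        zone_set=zs,
        values=phi,
        base_value=game.value(0),
        prediction=game.value(full),
        class_index=class_index,
        method="sampling_shap",
        n_evaluations=game.n_evaluations,
        seed=seed,
        stderr=stderr,
        class_name=model.class_names[class_index],
        instance_id=x.id,
    )


def explain_dataset(
    model: ModelAdapter,
    ds: SpectraSet,
    zs: ZoneSet,
    baseline: str = "reference_mean",
    reference: SpectraSet | None = None,
    class_index: int = 0,
    method: str = "sampling_shap",
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
) -> list[Attribution]:
    """One Attribution per dataset row, deterministic given ``seed``.

    Every spectrum gets its own child seed derived from ``seed`` and the
    spectrum id (so permuting dataset rows permutes the results and nothing
    else), while the designated reference — hence the base value — is shared.
    """
    if not np.array_equal(ds.grid, zs.grid):
        raise ValueError("dataset grid does not match the zone grid")
    ref = reference if reference is not None else ds
    out = []
    for i in range(ds.n_spectra):
        x = ds.spectrum(i)
        entropy = [seed, zlib.crc32(x.id.encode())]
        child_seed = int(
            np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31)
        )
        if method == "exact_shap":
            att = exact_zone_shap(model, x, zs, baseline, ref, class_index,
                                  seed=child_seed)
        elif method == "sampling_shap":
            att = sampling_zone_shap(model, x, zs, baseline, ref, class_index,
                                     n_draws=n_draws, seed=child_seed)
        else:
            raise ValueError(f"unknown SHAP method {method!r}")
        out.append(att)
    return out
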