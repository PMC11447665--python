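"""Synthetic Raman-oil datasets and analytic models with known attributions.

The generator emulates an edible-oil discrimination study: eight oil classes,
each measured from several independent bottles with ten spectra per bottle,
on a 400–3100 cm^-1 grid.  Class identity is encoded through the relative
amplitudes of nine characteristic lipid Raman bands (C–C aliphatic stretch at
760 cm^-1, trans C=C/C–H at 972, cis =CH in-plane deformation at 1265,
CH2 twist at 1302, CH2 scissoring at 1440, O–CH3 symmetric deformation at
1460, cis C=C stretch at 1656, ester C=O stretch at 1745, and the CH stretch
shoulder at 2843 cm^-1).  Bottle-to-bottle variability is a multiplicative
amplitude jitter per bottle; each measurement adds i.i.d. noise and a smooth
low-order polynomial baseline, and every spectrum is max-normalized.

The module also provides analytic models: :func:`toy_zone_model` exposes a
classifier whose ground-truth zone attributions are known in closed form,
and :func:`stand_in_classifier` trains a small multinomial logistic model on
zone-mean features to stand in for a deep spectral classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .spectra import ModelAdapter, SpectraSet, Spectrum
from .zones import ZoneSet, global_zones

__all__ = [
    "BAND_POSITIONS",
    "BAND_ASSIGNMENTS",
    "BandLibrary",
    "ClassProfile",
    "default_grid",
    "default_profiles",
    "generate_spectrum",
    "generate_dataset",
    "toy_zone_model",
    "stand_in_classifier",
]

#: characteristic lipid band positions (cm^-1)
BAND_POSITIONS = (760.0, 972.0, 1265.0, 1302.0, 1440.0, 1460.0, 1656.0,
                  1745.0, 2843.0)
BAND_ASSIGNMENTS = (
    "ν(C–C) aliphatic",
    "trans C=C / C–H bend",
    "δ(=C–H) cis in-plane",
    "τ(CH2) twist",
    "δ(CH2) scissoring",
    "δ(CH3) of –O–CH3",
    "ν(C=C) cis",
    "ν(C=O) ester",
    "ν(C–H) stretch shoulder",
)


@dataclass(frozen=True)
class BandLibrary:
    """Band positions with their vibrational assignments."""

    bands: tuple[tuple[float, str], ...] = tuple(
        zip(BAND_POSITIONS, BAND_ASSIGNMENTS)
    )

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.bands])

    def check_grid(self, grid: np.ndarray) -> None:
        pos = self.positions
        if pos.min() < grid[0] or pos.max() > grid[-1]:
            raise ValueError(
                f"band positions [{pos.min():g}, {pos.max():g}] outside grid "
                f"[{grid[0]:g}, {grid[-1]:g}]"
            )


@dataclass(frozen=True)
class ClassProfile:
    """Spectral recipe for one oil class.

    ``amplitudes`` maps band position to mean amplitude (arbitrary units,
    >= 0); ``bottle_cv`` is the coefficient of variation of the per-bottle
    multiplicative amplitude jitter, ``sigma`` the Gaussian bandwidth in
    cm^-1, ``noise`` the i.i.d. noise standard deviation relative to the
    max-normalized spectrum, and ``baseline_amp`` the amplitude of the smooth
    polynomial baseline drift.
    """

    name: str
    amplitudes: dict[float, float]
    bottle_cv: float = 0.08
    sigma: float = 10.0
    noise: float = 0.003
    baseline_amp: float = 0.03

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError(f"{self.name}: band amplitudes must be >= 0")
        if self.noise < 0 or self.bottle_cv < 0:
            raise ValueError(f"{self.name}: noise and bottle_cv must be >= 0")


def default_grid(lo: float = 400.0, hi: float = 3100.0, step: float = 2.0) -> np.ndarray:
    """Default wavenumber axis: 400–3100 cm^-1 at 2 cm^-1 (1351 points)."""
    return np.arange(lo, hi + step / 2, step)


# Relative band amplitudes per oil class, stylized by fatty-acid makeup:
# unsaturated oils carry strong cis C=C (1265/1656), coconut is dominated by
# saturated CH2 bands (1302/1440) with a strong ester carbonyl, and seed oils
# get a δ(CH3) shoulder at 1460.
_PROFILE_TABLE: dict[str, dict[float, float]] = {
    #                 760    972   1265   1302   1440   1460   1656   1745   2843
    "olive":       {760: .30, 972: .10, 1265: .45, 1302: .55, 1440: .90, 1460: .15, 1656: .75, 1745: .30, 2843: .85},
    "sunflower":   {760: .25, 972: .15, 1265: .60, 1302: .45, 1440: .85, 1460: .20, 1656: .85, 1745: .35, 2843: .80},
    "canola":      {760: .28, 972: .12, 1265: .55, 1302: .50, 1440: .88, 1460: .18, 1656: .80, 1745: .32, 2843: .82},
    "sesame":      {760: .40, 972: .18, 1265: .50, 1302: .48, 1440: .80, 1460: .35, 1656: .78, 1745: .40, 2843: .78},
    "peanut":      {760: .33, 972: .14, 1265: .48, 1302: .52, 1440: .86, 1460: .28, 1656: .70, 1745: .38, 2843: .80},
    "grape_seed":  {760: .22, 972: .20, 1265: .65, 1302: .42, 1440: .82, 1460: .25, 1656: .90, 1745: .36, 2843: .76},
    "linseed":     {760: .20, 972: .25, 1265: .75, 1302: .40, 1440: .78, 1460: .22, 1656: 1.0, 1745: .34, 2843: .74},
    "coconut":     {760: .45, 972: .08, 1265: .15, 1302: .70, 1440: 1.0, 1460: .30, 1656: .20, 1745: .55, 2843: .90},
}

# classes reported as more batch-variable get a larger bottle jitter
_HIGH_VARIABILITY = {"coconut", "grape_seed", "peanut", "sesame"}


def default_profiles(noise: float = 0.003, bottle_cv: float = 0.08) -> list[ClassProfile]:
    """The eight stylized oil-class profiles."""
    out = []
    for name, amps in _PROFILE_TABLE.items():
        cv = bottle_cv * 2 if name in _HIGH_VARIABILITY else bottle_cv
        out.append(ClassProfile(name=name, amplitudes=dict(amps),
                                bottle_cv=cv, noise=noise))
    return out


def generate_spectrum(
    profile: ClassProfile,
    bottle_seed: int,
    measurement_seed: int,
    grid: np.ndarray | None = None,
    id: str | None = None,
) -> Spectrum:
    """One synthetic spectrum: jittered Gaussian bands + baseline + noise.

    The bottle seed fixes the multiplicative amplitude jitter shared by all
    measurements of a bottle; the measurement seed fixes baseline and noise.
    The result is max-normalized (unless identically zero) and deterministic
    in the two seeds.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    positions = np.array(sorted(profile.amplitudes))
    if positions.size and (positions.min() < grid[0] or positions.max() > grid[-1]):
        raise ValueError("band position outside the grid range")
    bottle_rng = np.random.default_rng(bottle_seed)
    meas_rng = np.random.default_rng(measurement_seed)
    y = np.zeros_like(grid)
    for pos in positions:
        amp = profile.amplitudes[pos]
        jitter = 1.0 + profile.bottle_cv * bottle_rng.standard_normal()
        amp = max(amp * jitter, 0.0)
        y += amp * np.exp(-0.5 * ((grid - pos) / profile.sigma) ** 2)
    if profile.baseline_amp > 0:
        # smooth quadratic drift with random coefficients per measurement
        t = (grid - grid[0]) / (grid[-1] - grid[0])
        c = meas_rng.uniform(-1, 1, size=3)
        y += profile.baseline_amp * (c[0] + c[1] * t + c[2] * t**2)
    if profile.noise > 0:
        y += profile.noise * meas_rng.standard_normal(grid.size)
    peak = np.max(np.abs(y))
    if peak > 0:
        y = y / peak
    return Spectrum(grid, y, id=id or f"{profile.name}")


def generate_dataset(
    profiles: list[ClassProfile] | None = None,
    bottles_train: int = 4,
    bottles_test: int = 3,
    repeats: int = 10,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> tuple[SpectraSet, SpectraSet]:
    """Train/test SpectraSets emulating the bottle-split study design.

    With the defaults (8 classes x 4 train + 3 test bottles x 10 repeats)
    this yields 320 training and 240 testing spectra.  Bottles are
    independent between splits; labels carry the class, batches the bottle
    id.
    """
    profiles = default_profiles() if profiles is None else profiles
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names in profiles")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    root = np.random.SeedSequence(seed)
    splits = {}
    bottle_counter = {"train": 0, "test": 0}
    children = iter(root.spawn(len(profiles) * (bottles_train + bottles_test)))
    for split, n_bottles in (("train", bottles_train), ("test", bottles_test)):
        rows, ids, labels, batches = [], [], [], []
        for p in profiles:
            for b in range(n_bottles):
                child = next(children)
                states = child.generate_state(repeats + 1) % (2**31)
                bseed = int(states[0])
                bottle_id = f"{p.name}_{split}_b{b}"
                for r in range(repeats):
                    s = generate_spectrum(
                        p, bottle_seed=bseed, measurement_seed=int(states[r + 1]),
                        grid=grid, id=f"{bottle_id}_m{r}",
                    )
                    rows.append(s.intensities)
                    ids.append(s.id)
                    labels.append(p.name)
                    batches.append(bottle_id)
        splits[split] = SpectraSet(
            grid=grid, matrix=np.stack(rows), ids=ids, labels=labels,
            batches=batches,
        )
    return splits["train"], splits["test"]


def toy_zone_model(
    weights: np.ndarray,
    zs: ZoneSet,
    link: str = "identity",
    intercepts: np.ndarray | None = None,
) -> ModelAdapter:
    """An analytic model on per-zone mean intensities with known attributions.

    ``identity``: single score column w . zone_means(x) + b — under a zero
    baseline its exact zone Shapley values are w_i * mean_i(x) in closed
    form.  ``softmax``: rows of ``weights`` (n_classes x n_zones) feed a
    softmax, giving a proper probability simplex.
    """
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if not np.all(np.isfinite(W)):
        raise ValueError("weights must be finite")
    if W.shape[1] != len(zs):
        raise ValueError(f"{W.shape[1]} weights for {len(zs)} zones")
    b = np.zeros(W.shape[0]) if intercepts is None else np.asarray(intercepts, float)

    if link == "identity":
        if W.shape[0] != 1:
            raise ValueError("identity link takes a single weight vector")

        def predict(X: np.ndarray) -> np.ndarray:
            return (zs.zone_means(X) @ W.T + b).reshape(-1, 1)

        return ModelAdapter(predict_fn=predict, class_names=["score"],
                            grid=zs.grid, strict=False)
    if link == "softmax":

        def predict(X: np.ndarray) -> np.ndarray:
            scores = zs.zone_means(X) @ W.T + b
            scores -= scores.max(axis=1, keepdims=True)
            e = np.exp(scores)
            return e / e.sum(axis=1, keepdims=True)

        names = [f"class{i}" for i in range(W.shape[0])]
        return ModelAdapter(predict_fn=predict, class_names=names,
                            grid=zs.grid, strict=True)
    raise ValueError(f"unknown link {link!r} (identity | softmax)")


def stand_in_classifier(
    train: SpectraSet,
    seed: int = 0,
    zs: ZoneSet | None = None,
) -> ModelAdapter:
    """Multinomial logistic classifier on zone-mean features.

    A small deterministic probabilistic classifier wrapped in the
    ModelAdapter contract, reproducible from ``seed``.  Zones default to the
    global zones of the training set.
    """
    if train.labels is None or len(set(train.labels)) < 2:
        raise ValueError("stand-in classifier needs >= 2 labeled classes")
    zones = zs if zs is not None else global_zones(train)
    X = zones.zone_means(train.matrix)
    clf = make_pipeline(
        StandardScaler(),
        LogisticRegression(max_iter=5000, C=100.0, random_state=seed),
    )
    clf.fit(X, train.labels)
    classes = [str(c) for c in clf.classes_]

    def predict(batch: np.ndarray) -> np.ndarray:
        return clf.predict_proba(zones.zone_means(batch))

    adapter = ModelAdapter(predict_fn=predict, class_names=classes,
                           grid=train.grid, strict=True)
    adapter.zones = zones  # convenience: the featurization partition
    return adapter
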