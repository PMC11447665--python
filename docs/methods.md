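# Methods

## The problem

Post-hoc explainers such as SHAP and LIME probe a trained classifier by
perturbing inputs and watching the output move. Applied channel-by-channel to
a 1-D vibrational spectrum, this is doubly unsatisfying: replacing a single
wavenumber intensity with zero (or a dataset value) produces a spectrum no
instrument could record, and neighboring channels of one Raman band routinely
receive large attributions of opposite sign, which has no physical reading.
`zonexplain` instead treats contiguous *spectral zones* as the unit of
explanation: the axis is partitioned into intervals, perturbations act on
whole zones, and the attribution of a zone summarizes the joint effect of all
its channels on the model's class probability.

The model under explanation is opaque: a `ModelAdapter` is any callable
mapping a batch of intensity vectors on a declared grid to a row-stochastic
class-probability matrix. Explanations are computed on the probability
scale, not logits.

## Zone detection

Zones are delimited by the valleys between peaks. The spectrum (or, for a
global partition, the dataset's pointwise mean spectrum) is smoothed by a
centered moving average (`smooth_window`, default 5 points — the derivative
criterion for extrema is stated for noiseless curves, so light smoothing
stabilizes it against measurement noise); peaks are local maxima whose
prominence exceeds `min_prominence × (max − min)` of the smoothed trace
(default 0.01, a permissive threshold that keeps shoulder bands); the valley
between two consecutive retained peaks is the interior minimum between them.
k valleys give k+1 zones under a half-open index convention `[start, end)` —
a boundary valley belongs to the zone on its right — and zones narrower than
3 grid points are merged into the neighbor across the lower-intensity
boundary, so no zone degenerates into a near-singleton coalition. Because
the prominence threshold is relative, detection is invariant to uniform
intensity scaling, and raising the threshold can only remove peaks.

User-defined zones (rows of `lo,hi` in cm⁻¹) are snapped to the nearest grid
indices; gaps between declared intervals are auto-filled with background
zones so that every `ZoneSet` is a true partition — contiguity, disjointness
and full coverage are constructor invariants, not conventions.

## Group perturbations

A perturbed spectrum `z` keeps a random subset of zones from the instance
`x` (its binary mask) and replaces the rest. Replacement baselines follow
the three standard readings of "excluding" a feature from a network input:
zeros, the pointwise mean of a reference set, or the corresponding zone of a
single reference spectrum drawn uniformly (one donor per sample — a
nearest-donor search over all reference spectra would be quadratic in the
dataset and is deliberately not implemented). The default baseline is the
reference mean: zero-replacement creates exactly the physically unrealistic
cliff edges that motivate zone analysis in the first place.

When the reference data are thin or absent, two transform strategies
substitute smoothed or unsharp-masked (`x + s·(x − smoothed x)`) zone
content, from a reference donor (`transform_augmented`) or from the instance
itself (`input_augmented`). Masks are drawn uniformly over binary vectors
excluding all-ones (which is just `x` again); the all-zeros mask is allowed
because it anchors the baseline. Whatever the strategy, a retained zone is
copied bit-exactly — the test suite enforces this identity over a thousand
random masks, because any leakage across zone boundaries silently corrupts
every attribution downstream.

## Zone Shapley values

A coalition S ⊆ B of zones keeps its content from `x`; its value v(S) is the
model's class probability for the resulting spectrum. Zone i's attribution
is the Shapley value

φᵢ = Σ_{S ⊆ B∖{i}} |S|!(n−|S|−1)!/n! · [v(S∪{i}) − v(S)].

`exact_zone_shap` enumerates all 2ⁿ coalitions (capped at n = 20) with model
calls batched and memoized by coalition bitmask — one model evaluation per
distinct coalition, ever. Efficiency (Σφ = v(B) − v(∅)), symmetry and the
dummy axiom then hold to numerical precision and are asserted at 1e−9.

For larger n, `sampling_zone_shap` uses permutation sampling: each of N
draws is a uniform random zone ordering, and each zone contributes the
marginal gain of joining the coalition of zones preceding it. The per-zone
averages are unbiased for the exact values, satisfy efficiency in
expectation, and come with standard errors (marginal std / √N). Permutation
sampling was chosen over independent subset draws because it is unbiased
without reweighting and respects efficiency; the default N = 5000 puts the
estimates within 4 standard errors of exact enumeration on 6–10-zone test
problems. With the `reference_sample` baseline the donor is frozen per
explain call so that v is a well-defined function of the coalition.

`base_value` on an `Attribution` is v(∅) — the model output with every zone
replaced — which is what the efficiency identity and the waterfall plot
telescope against. The expected model output over a designated reference
set (by default the training split, since no canonical choice exists) is
computed separately by `expected_value` and stored alongside; under the
reference-mean baseline the two are close but not identical (f of the mean
spectrum versus the mean of f).

## Zone LIME

The surrogate g is linear in the binary mask and fit by minimizing the
proximity-weighted squared loss Σ_z π_x(z)(f(z) − g(mask(z)))². The
proximity kernel is exp(−d²/width²) with d the fraction of replaced zones
(width default 0.25, so perturbations with more than ~half their zones
replaced carry little weight); the kernel form is an implementation choice —
only its qualitative shape (1 at x, decreasing in d) is dictated by the
method. Sparsity is a hard cap K (default 10), enforced by greedy forward
selection on weighted residual sum of squares followed by a weighted
least-squares refit on the selected zones; unselected zones get coefficient
exactly 0. The fit reports a weighted R² ("fidelity"): 1.0 means f is
mask-linear in the sample, and on such models the coefficients reproduce the
ground truth to 1e−6 with K = n.

LIME coefficients are *not* additive attributions — they do not decompose
f(x) − E[f(x)] — so the serialized document carries an explicit note and the
waterfall renderer refuses LIME input rather than drawing a misleading path.
Because the perturbation sample is random, different seeds give (slightly)
different coefficients; all entry points therefore require a seed and log it.

## Explanation views

*Waterfall*: top-k zones by |φ| (ties broken by lower wavenumber, so plots
are deterministic), remaining zones summed into one remainder row; the rows
telescope exactly from `base_value` to the prediction. *Relevance
coefficients*: one signed bar per zone across the axis. *Saliency map*: each
grid point carries its zone's φ normalized by max|φ| to [−1, 1] — piecewise
constant with breakpoints exactly at zone boundaries; an all-zero
attribution maps to zero rather than dividing by zero. *Beeswarm summary*:
per-zone attribution distributions over a dataset, ordered by mean |φ|,
colored by the zone's mean intensity min-max normalized across the dataset
(a degenerate constant-intensity zone maps to color 0 by convention — such
zones are legitimate, e.g. signal-free baseline regions).

## Synthetic data

No measured spectra ship with the package; the generator emulates an
edible-oil discrimination study so every component is testable end to end.
Eight oil classes are encoded as relative amplitudes of nine characteristic
lipid bands (760, 972, 1265, 1302, 1440, 1460, 1656, 1745, 2843 cm⁻¹):
highly unsaturated oils (linseed, grape seed) carry strong cis C=C signals
at 1265/1656 cm⁻¹, coconut is dominated by saturated CH₂ bands and the
ester carbonyl, seed oils get a δ(CH₃) shoulder at 1460 cm⁻¹. Band shapes
are Gaussian (σ = 10 cm⁻¹; Lorentzian/Voigt profiles are a deferred
refinement) on a 400–3100 cm⁻¹ grid at 2 cm⁻¹. A bottle is a multiplicative
amplitude jitter shared by its measurements (CV 0.08, doubled for the four
classes described as batch-variable); each measurement adds a random
quadratic baseline drift (amplitude 0.03) and i.i.d. noise (σ 0.003 of the
normalized maximum), and spectra are max-normalized. The default design —
8 classes × (4 training + 3 testing bottles) × 10 spectra — yields the
320/240 split, with bottles independent between splits.

What the generator does **not** emulate: cosmic-ray spikes, detector
etaloning, wavenumber miscalibration, fluorescence backgrounds beyond a
quadratic, or realistic inter-class amplitude tables (the profiles are
stylized). Tests passing on these data show the machinery is correct — not
that any particular real oil model is faithful.

Two analytic models close the loop: `toy_zone_model` is (identity or
softmax) linear in per-zone mean intensities, so its exact attributions are
known in closed form (identity link, zero baseline: φᵢ = wᵢ·meanᵢ(x)); and
`stand_in_classifier` is a multinomial logistic model on standardized
zone-mean features standing in for a deep spectral classifier. At the
default noise/bottle-variability settings its held-out accuracy is ~0.7 —
deliberately in the regime of a realistically hard task — while at low
noise (σ 0.001, bottle CV 0.02) it exceeds 0.9, which is the configuration
the accuracy test asserts.

## Numerical and design notes

- Spectra files are written with `%.17g` and parsed with the round-trip
  float parser, so write→read is bit-exact; derived exports (attribution
  documents, plot tables) round to 6 significant digits.
- Mismatched grids are always an error; `resample` (linear interpolation,
  no extrapolation) must be called explicitly.
- Every stochastic component takes a mandatory seed; dataset-level
  explanation derives per-spectrum seeds from the master seed and the
  spectrum id, so permuting rows permutes results and nothing else. Each
  CLI run writes a resolved-config YAML sufficient to reproduce it.
- Problem sizes in the test and acceptance runs (100-point grids, 3–10
  zones, N = 5000 permutations, 150–200 draws in pipeline checks) were
  chosen so the full validation completes in seconds on one CPU while still
  exercising every code path at meaningful precision.

## Known limitations

- Exact enumeration is O(2ⁿ) and capped at 20 zones; beyond that only the
  sampling estimator is available (no Owen/antithetic variance reduction).
- No gradient-based explainer: the model contract is a black-box predict
  function, so backpropagation-style attribution is out of reach by design.
- Zone detection assumes peaks-over-baseline structure; spectra without
  clear valleys (broad overlapping envelopes) will yield few, wide zones —
  user-defined zones are the intended escape hatch.
- Shapley interaction indices, ridge/elastic-net LIME variants, and
  interactive/force plots are not implemented.
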