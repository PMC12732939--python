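# Methods

This note records the models, numerical choices and design decisions
behind `nirselect`, and what the synthetic benchmark does and does not
establish about behaviour on real spectra.

## PLS1 engine

The regression core is NIPALS PLS1 with deflation of X only. For
column-centred E₀ = X − x̄ and centred response y − ȳ, each component k
takes the weight w_k ∝ E_{k−1}ᵀ(y − ȳ) (unit norm), score t_k = E_{k−1}w_k,
X-loading p_k = E_{k−1}ᵀt_k/t_kᵀt_k, y-loading q_k = (y − ȳ)ᵀt_k/t_kᵀt_k,
and deflates E_k = E_{k−1} − t_k p_kᵀ. The collapsed coefficient vector is
b = W(PᵀW)⁻¹q, so prediction is ŷ = ȳ + (X − x̄)b. Scores are mutually
orthogonal, and at A = min(n−1, p) on full-column-rank X the predictions
coincide with ordinary least squares — both properties are asserted in
tests, the latter also against scikit-learn's NIPALS as an independent
implementation. If the covariance of the deflated X with y falls below
1e−13 the iteration stops early and the model records the effective
component count; this happens only on (near-)degenerate inputs.

The inner loop is deliberately lean (no allocation-heavy helpers): the
optimizer evaluates tens of thousands of candidate channel subsets, each
requiring a fresh fit per cross-validation repeat.

## Figures of merit

RMSECV pools squared validation residuals over all MCCV repeats before
taking the root (one global mean, not a mean of per-repeat RMSEs), which
makes it invariant to repeat order and weights every held-out prediction
equally. R² is computed on the prediction set as 1 − SS_res/SS_tot — the
form that can go negative — rather than a squared correlation, because it
is the stricter check and pairs naturally with RMSEP.

## Partitioning

Kennard–Stone is the deterministic greedy maximin: seed with the most
distant pair (Euclidean, on whatever matrix is handed in — i.e. after any
per-sample pretreatment), then repeatedly add the sample with the largest
minimum distance to the selected set. Ties break to the lowest sample
index. The calibration size is round(fraction·n) half-away-from-zero,
which maps two-thirds of 100/310/72 samples to 67/207/48. MCCV draws
round(fraction·n) calibration indices without replacement, independently
per repeat, reproducibly from the plan's seed.

## Pretreatments

- **SNV**: per-spectrum centring and scaling with the (n−1)-denominator
  standard deviation (idempotent either way; the sample form is the
  dominant convention). Constant spectra are an error, named by sample.
- **MSC**: per-spectrum regression x ≈ a + b·ref and correction
  (x − a)/b. The reference defaults to the mean spectrum of the
  *calibration* partition and is then applied to both partitions —
  leakage-free; the reference choice is applied identically everywhere.
- **Savitzky–Golay derivatives**: order 1 or 2, default window 11 /
  polynomial order 2, boundary windows handled by polynomial fit
  (`mode="interp"`), so the output keeps the full channel count and
  selector masks stay aligned with the wavelength axis.

Per-sample transforms (SNV, derivatives) commute with the sample split
and are applied before it; MSC needs a training reference and is applied
after.

## Comparator selectors

All three append-or-permute schemes fix n_lv at the value chosen once on
the full spectrum.

- **UVE** appends p i.i.d. uniform noise channels scaled by 1e−10 (small
  enough not to perturb the fit, nonzero so coefficients exist),
  estimates per-channel stability mean(b)/sd(b) over leave-one-out
  refits, and keeps real channels whose |stability| exceeds the noise
  channels' maximum. Leave-one-out coefficient estimates are strongly
  correlated, which inflates all stabilities; the comparison against the
  noise channels' own inflated maximum is what keeps the cut meaningful.
- **MC-UVE** replaces leave-one-out by n_mc random subsamples (default
  500 at fraction 0.8), which stabilises the stability estimates; a
  top-k keep rule is available for when a fixed model size is wanted.
- **Randomization test**: observed coefficients vs a null from refits on
  permuted responses, p_j = (1 + #{|b_perm| ≥ |b_obs|})/(n_perm + 1)
  (the add-one form is exact for permutation nulls and makes 1/(n_perm+1)
  the smallest attainable p). Defaults n_perm = 499, α = 0.05.

An empty selection raises rather than silently falling back: a model with
zero channels is a configuration error, not a result.

## DBWO

The optimizer follows the canonical beluga-whale update equations
(balance factor B_f = B₀(1 − T/2T_max); sine/cosine exploration toward a
random peer; exploitation toward the incumbent best with Levy term
C₁·LF·(x_r − x), C₁ = 2r(1 − T/T_max); whale fall x_new = r₅x − r₆x_r + r₇·X_step
with X_step = (u − l)·exp(−C₂T/T_max), C₂ = 2·W_f·pop, applied to whales
with B_f ≤ W_f, W_f decaying linearly 0.1 → 0.05). Positions are clamped
to [−6, 6], which covers the effective range of all three transfer
functions.

**Discretization.** The sigmoid rule resamples bit_j ~ Bernoulli(σ(x_j))
from the position itself. For the V-shaped rules the flip probability is
read off the *move*, (x_new − x_old)/s with the granularity scale
s = `tf_step_scale` (default 24, twice the bound width), not off the raw
position: position coordinates live in [−6, 6] where |tanh| ≈ 1, so a
position-based V-rule would flip essentially every bit every move and
degenerate into random mask resampling. Normalising the step instead
gives a proposal that flips a few percent of channels and dies out as a
whale converges — the incumbent-preserving behaviour that makes V-shaped
transfers settle faster and end lower than the S-shaped rule, which is
also the ranking the benchmark sweep reproduces. At the default scale a
typical mid-run move flips roughly 5–10 % of a 200-channel mask.

**Acceptance and fitness.** Each whale's proposal is accepted only if its
fitness (MCCV RMSECV of a PLS model restricted to the mask, fixed n_lv,
one shared split plan so all comparisons are paired) does not worsen;
the best-so-far curve is therefore monotone non-increasing and asserted
as such on every run. A mask with fewer than n_lv active channels gets
random channels switched on up to n_lv (minimum-selection guard), keeping
the fitness total. Fitness values are cached by mask, so re-evaluations
of an unchanged mask are free. There is no variable-count penalty in the
fitness; parsimony emerges from the search.

**Defaults** pop_size 30 and max_iter 500 suit production runs; the test
and acceptance sweeps use pop 20 / 100 iterations on the 200-channel
benchmark, which is enough for the qualitative comparisons while keeping
a full 10-seed sweep around a minute.

n_lv is fixed at the full-spectrum optimum rather than re-selected per
candidate subset — re-selection inside the fitness would multiply cost by
max_lv and blur the paired comparison between masks.

## Synthetic benchmark

`generate` builds Beer–Lambert mixtures: per-component pure spectra as
sums of Gaussian bands, concentrations uniform in `conc_range`
(independent across components, keeping the design full-rank), an
optional fixed matrix background, then per-sample affine scatter
x ← a + b·x (a ~ U(−baseline_amp, +baseline_amp), b ~ N(1, scatter_slope_sd) —
exactly the distortion model MSC inverts) and additive channel noise.
The response is the target component's concentration, and channels within
two band widths of its band centres form the ground-truth informative
mask (a scoring convention, not a claim about real spectra).

`planted_band_benchmark` is the canonical fixture: 60 samples × 200
channels, one narrow analyte band (15 informative channels) overlapped by
two broad interferents whose channels a good model also needs, plus five
strong narrow nuisance absorbers elsewhere. The nuisance components
dominate the spectral variance while carrying no response information;
with n_lv fixed at 7 the full-spectrum model must spend latent variables
on them, which is the regime in which discarding channels genuinely
improves prediction. An earlier all-broad-band design was discarded after
pilot runs showed the full spectrum to be effectively optimal there
(redundant channels average noise away), leaving selection nothing to
gain. The pilot that fixed the final design also fixed the benchmark
pipeline: no pretreatment (chemical variation, not scatter, dominates at
these artifact magnitudes), n_lv = 7, fitness plan of 10 MCCV repeats at
fraction 0.8.

What passing the benchmark shows: the optimizer finds masks that beat the
full spectrum out of sample, concentrates on the analyte band (recall of
the informative channels well above the ≈0.45 chance level of its mask
size), behaves deterministically per seed, and ranks V2 ≤ sigmoid on
final RMSECV. What it does not show: behaviour under instrument drift,
non-Gaussian band shapes, wavelength-dependent noise, reference-value
error, or the channel counts/error magnitudes of any real dataset —
real-data results must be established on real data, for which the CSV
reader and the `compare` workbench are the intended route.

## Degenerate inputs and tie-breaks

- Wavelength grids: inclusive arithmetic sequence; a partial final step
  is dropped; single-channel grids are legal.
- LV selection: smallest count within 1e−12 of the curve minimum
  (parsimony tie-break).
- Kennard–Stone ties: lowest index (via row-major argmax).
- Duplicate spectra: legal; the tie rule resolves the seed pair.
- Constant response, constant spectra, NaN cells, empty selections and
  infeasible n_lv all raise with the offending sample/channel named where
  applicable.

## Known limitations

- PLS1 only (single response); no PLS2, SIMPLS or kernel variants.
- The BWO update equations come from the canonical description of the
  algorithm; other formulations exist and would change trajectories,
  though not the interface or the invariants asserted here.
- UVE's leave-one-out stability is noisy below ~35–40 samples; MC-UVE is
  the recommended variant for small n (that is its point).
- The randomization test controls per-channel type-I error, not the
  family-wise or false-discovery rate.
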