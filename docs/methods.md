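# Methods

## The problem

A one-dimensional expression profile pairs positions x along the
anterior–posterior (AP) axis of an embryo, in percent egg length (%EL),
with fluorescence intensities in arbitrary units (AU). For an
anteriorly-produced morphogen such as Bicoid, the
synthesis–diffusion–degradation (SDD) model at steady state gives

    B(x) = A · exp(−x / λ),

where A is the anterior amplitude and λ the length constant. Substituting
m(x) = A·e^(−x/λ) into the reaction–diffusion balance
∂m/∂t = D ∂²m/∂x² − m/τ_p + S with ∂m/∂t = 0 and no source away from the
anterior yields λ = √(D·τ_p) (`steady_state_length_constant`). Measured
profiles superimpose strong position-dependent noise on this curve; the
task is to recover the smooth signal from one noisy profile at a time.

All extractors return a `SignalExtraction` satisfying
`signal + residual == observed` element-wise. For forecasting-style models
(ARIMA, ARFIMA, ETS, NN) the "signal" is defined as the in-sample one-step
fitted values; positions with no usable prediction (the first d values
after integer differencing, the burn-in prefix of the fractional filter,
the first p lags of the NN) are fitted by the observed values, so the
identity holds everywhere and those points contribute their raw noise to
any error score — a deliberate, conservative convention.

## Extractors

**SSA** (`ssa` module). The series y_1..y_N is embedded into the L×K
Hankel trajectory matrix (K = N − L + 1) whose columns are the L-lagged
vectors; the SVD X = Σ √λ_i U_i V_iᵀ splits it into rank-one elementary
matrices; a group of eigentriples is mapped back to a series by averaging
anti-diagonals (hankelization). The trend group defaults to the first
eigentriple alone (`n_components=1`): for a profile that is a decaying
exponential plus structureless noise the leading eigentriple carries the
trend, and for a noiseless exponential — Hankel rank exactly 1 — it is
exact to numerical precision. The window length defaults to L = ⌊N/2⌋,
the standard separability-maximizing choice; it is exposed everywhere.
Singular values below 1e−11 of the largest are treated as zero.
Separability is diagnosed with the w-correlation, the weighted correlation
whose weight at point i is its anti-diagonal multiplicity
min(i, L, K, N−i+1).

**SDD benchmark** (`sdd` module). Two fitters. `anterior_efold` (the
default benchmark): A is the observed intensity at the anterior-most
position; λ is the distance to the first position where intensity drops to
A/e, linearly interpolated between the bracketing grid points; with
multiple crossings the first from the anterior wins. This reproduces the
classical read-off and deliberately inherits the noise of the anterior
point and of the crossing neighbourhood. `least_squares`: nonlinear least
squares on A·exp(−(x − x_anterior)/λ), initialized from the log-linear
regression of ln y⁺ on x (non-positive intensities excluded from the
initialization only). Both fitters use x measured from the anterior-most
position of the (possibly cropped) profile, so A always means the
amplitude at the profile's own anterior; both recover (A, λ) exactly on
noiseless data whose grid contains the 1/e crossing.

**Auto-ARIMA** (`baselines.fit_arima_auto`). The differencing order d is
chosen by repeating a stationarity test (KPSS by default, ADF selectable)
on successive differences, capped at d = 2. Orders (p, q) and the constant
are selected by minimizing AIC = −2 log L + 2(p + q + k), k = 1 iff a
constant is fit, with a stepwise neighbourhood search from starting points
(2,2), (0,0), (1,0), (0,1) — bounded by max_p = max_q = 5. Seasonal terms
are disabled (a spatial series has no season). Candidate fits whose
one-step predictions are non-finite or exceed 10× the data range are
rejected as numerically diverged. Likelihood optimization is statsmodels'
state-space ARIMA.

**Stepwise ARFIMA** (`baselines.fit_arfima`). (1) d is estimated from an
ARFIMA(2, d, 0) profile likelihood: for each candidate d the demeaned
series is fractionally differenced — (1−B)^d truncated at t = 0, with
coefficients π_k = π_{k−1}(k−1−d)/k — and an AR(2) is fit by Yule–Walker,
whose stationarity guarantee forces d alone to absorb any remaining
nonstationarity. (2) The series is fractionally differenced with that d.
(3) An ARMA(p, q) is selected on the differenced series by the automatic
AIC search. (4) d is re-estimated jointly with the selected orders by
profiling the exact ARMA likelihood over d. d is searched over [0, 0.5],
the stationary long-memory range used by the reference automatic scheme;
widening the range makes d poorly identified against the free AR
polynomial (a spurious negative-d mode trades off against AR mass).
Because the truncated filter carries the start of the series for ~1/d
points, a burn-in prefix of min(10, N/10) points is excluded from both
profile likelihoods and fitted by the observed values in the extraction.

**ETS** (`baselines.fit_ets`). Enumerates additive/multiplicative error ×
{no trend, additive trend, damped additive trend}, no seasonality;
smoothing parameters and initial states by maximum likelihood
(statsmodels ETS); best model by AIC. Multiplicative error requires a
strictly positive series and is dropped otherwise.

**NN autoregression** (`baselines.fit_nn_autoregression`). A feed-forward
network regresses y_t on its p lags: logistic hidden activations
ψ(u) = 1/(1+e^(−u)), linear output. Defaults: p is the AIC-optimal linear
AR order capped at 8; two hidden layers of sizes (k, ⌈k/2⌉) with
k = ⌈(p+1)/2⌉ — small relative to the ~100-point profiles to limit
overfitting. Inputs and target are standardized; training (scikit-learn
MLP, L-BFGS, max 200 iterations) restarts from 25 seeded random
initializations and the signal is the mean of the restarts' in-sample
predictions, which suppresses the variance of any badly initialized net.

## The simulation study

`SimulationSpec` defaults: A = 255 AU (an 8-bit-like intensity ceiling),
λ = 20 %EL (the scale commonly reported for Bicoid), N = 101 equally
spaced points on 0–100 %EL, three equal-width noise segments with standard
deviations (8, 12, 8) AU — noisier mid-embryo, emulating position-dependent
measurement noise — 1000 replicates nominally, seed 42. Noise is zero-mean
Gaussian, applied to the full grid before any cropping, and never clipped
(negative intensities are allowed so the noise stays exactly Gaussian).
Each replicate's draw is determined by (seed, rep_index) alone, so
replicates are order-independent and reproducible. Every extractor sees
the same noisy series per replicate (common random numbers), which
sharpens the paired comparisons; a method failing on more than 1% of
replicates aborts the study, isolated failures drop that replicate for all
methods so alignment is preserved.

Scoring: RMSE, MAE, MAPE of the extracted signal against the noise-free
truth; RRMSE = RMSE(alternate)/RMSE(SDD benchmark) summarized as a ratio
of replicate means (a mean of per-replicate ratios is selectable);
improvement percentage (1 − RRMSE)·100; two-sided two-sample Wilcoxon
rank-sum tests on the per-replicate RMSE samples, exact at small n,
reported raw with no multiple-testing correction. If the benchmark RMSE is
numerically zero (a noiseless study) RRMSE is undefined and flagged
instead of divided.

The shipped studies and the reproduction script use 100 replicates rather
than 1000: the summary means are stable to well under the differences of
interest at that size, and the study completes in minutes on one CPU (the
ARIMA/ARFIMA searches and the 25 NN restarts dominate).

**What the generator does and does not emulate.** It reproduces the shape,
scale and segment-wise heteroscedasticity of gradient profiles, but real
nuclear data have per-nucleus scatter (duplicate positions, handled by
averaging on load), intensity-dependent and spatially correlated noise,
embryo-to-embryo variation in A and λ, and deviations from a single
exponential. Results on the generator therefore demonstrate correctness
and relative behaviour of the extractors under a known truth, not their
absolute performance on measured embryos.

**Regime dependence of the benchmark comparison.** How badly the naive
anterior-e-fold fit loses depends on the noise-to-signal ratio. At the
default conditions the relative noise is only ~3–5% of the anterior
amplitude and the gradient's slope at the 1/e crossing (A/(λe) ≈ 4.7
AU/%EL) dwarfs the local noise, so the parametric read-off stays fairly
accurate (mean RMSE ≈ 3.3) — global curve fitters (SSA ≈ 1.5, ETS ≈ 1.8)
beat it, but one-step smoothers cannot: their error is bounded below by a
sizable fraction of the noise s.d. (~9.5 AU pooled), leaving ARIMA (≈ 6.6),
NN (≈ 5.3) and ARFIMA (≈ 9.2) above the benchmark. With noise a large
fraction of the local signal — as in highly volatile measured profiles —
the e-fold crossing collapses toward the anterior and the benchmark
degrades to a near-deterministic large error while the smoothers' errors
stay noise-proportional, inverting that ordering. SSA's advantage (lowest
mean RMSE, narrowest min–max spread, |w-correlation| of signal vs residual
~2·10⁻³) is robust across the regimes we examined.

## Numerical choices and degenerate inputs

- Duplicate positions on load are averaged (with a warning); rows with
  non-finite intensities are dropped and logged; nothing is imputed.
- Profiles must have N ≥ 3 strictly increasing positions; SSA needs
  2 ≤ L ≤ N − 1; ARIMA needs N ≥ 10, ARFIMA N ≥ 30, diagnostics N ≥ 20.
- CSVs are written at full float precision and parsed with round-trip
  float conversion, so write→read is bit-exact.
- The AP window crop (default 20–80 %EL, the standard analysis window for
  measured embryos) is inclusive on both boundaries and idempotent.
- Ljung–Box uses lag min(10, N/5) by default; ADF uses AIC lag selection.
- Wilcoxon p-values switch from the exact null distribution to the normal
  approximation per scipy's standard rule (small n, no ties → exact).

## Known limitations

- ARFIMA is structurally mismatched to strongly trending profiles: with d
  capped at the stationary range and a stationarity-enforced ARMA, its
  extraction barely improves on the raw series at the default conditions —
  consistent with fractional models targeting slowly-decaying stationary
  memory, not deterministic trends.
- The NN's hidden-layer sizes and lag order are heuristics; no
  architecture search is performed beyond the linear-AR lag selection.
- Only the AP axis is modelled; two-dimensional (AP×DV) profiles, image
  quantification, and time-dependent solutions of the reaction–diffusion
  equation are out of scope.
- The anterior-e-fold fitter requires the profile to actually cross A/e;
  profiles truncated before the crossing raise an error rather than
  extrapolate.
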