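# gradsig

Signal extraction for noisy one-dimensional morphogen expression profiles,
built around the Bicoid (Bcd) gradient in the early *Drosophila* embryo.

A Bcd profile is a sequence of fluorescence intensities along the
anterior–posterior (AP) axis, in percent egg length (%EL). At steady state
the synthesis–diffusion–degradation (SDD) model predicts an exponential
gradient

    B(x) = A · exp(−x / λ),        λ = √(D · τ_p)

with amplitude *A* at the anterior pole and length constant *λ* set by the
diffusion constant *D* and protein lifetime *τ_p*. Measured profiles are
this curve buried in strong, heteroscedastic measurement noise, and the
classical way of "extracting the signal" — reading *A* off the anterior
intensity and *λ* off the position where intensity first drops to *A*/e —
inherits that noise directly.

`gradsig` implements and benchmarks six extractors on the same profiles:

- **SSA** — basic singular spectrum analysis: embed the series into an
  L×K Hankel trajectory matrix, take its SVD, keep the leading
  eigentriple(s) as trend, and map back by diagonal averaging
  (hankelization). Nonparametric; a noiseless exponential has Hankel rank 1,
  so the first eigentriple recovers it exactly.
- **SDD** — the exponential benchmark, via the anterior-1/e-crossing rule
  (default) or nonlinear least squares.
- **ARIMA** — automatic order selection: KPSS-chosen differencing, stepwise
  AIC search over (p, q) and the constant; the in-sample one-step fitted
  values are the signal.
- **ARFIMA** — stepwise fractional differencing: estimate d from an
  ARFIMA(2, d, 0) profile likelihood over the stationary range [0, 0.5],
  fractionally difference, select an ARMA by AIC, jointly re-estimate d.
- **ETS** — exponential-smoothing state space, enumerating error/trend
  variants by maximum likelihood and AIC.
- **NN** — feed-forward neural autoregression on lagged intensities
  (logistic hidden layers, linear output), averaging the in-sample
  predictions of 25 randomly initialized restarts.

A Monte-Carlo study generates noisy replicates of a known exponential
truth (zero-mean Gaussian noise whose standard deviation differs between
segments of the axis), scores every extractor by RMSE/MAE/MAPE against the
truth, summarizes with RRMSE = RMSE(alternate)/RMSE(SDD) — values below 1
mean the alternate beats the benchmark — and compares RMSE samples with
two-sample Wilcoxon tests. Residual diagnostics (ADF, Ljung–Box) and
signal–noise correlations (Pearson/Kendall/Spearman, plus SSA's weighted
w-correlation) assess how cleanly signal and noise separate.

## Worked example

```python
from gradsig import (SimulationSpec, generate_replicate, extract_signal_ssa,
                     extract_signal_sdd, rmse, w_correlation)

spec = SimulationSpec(n_reps=1, seed=7)      # A=255, lambda=20 %EL, sigmas (8,12,8)
truth, noisy = generate_replicate(spec, 0)

ssa = extract_signal_ssa(noisy)              # first eigentriple = trend
sdd = extract_signal_sdd(noisy, "anterior_efold")

print(f"raw observations : RMSE vs truth = {rmse(noisy.intensities, truth.intensities):.2f}")
print(f"SSA extraction   : RMSE vs truth = {rmse(ssa.signal, truth.intensities):.2f}")
print(f"SDD benchmark    : RMSE vs truth = {rmse(sdd.signal, truth.intensities):.2f}"
      f"  (A = {sdd.meta['amplitude_A']:.1f}, lambda = {sdd.meta['lambda_']:.1f} %EL)")
wc = w_correlation(ssa.signal, ssa.residual, ssa.meta["window_length_L"])
print(f"SSA signal-noise w-correlation = {wc:.4f}")
```

prints

```
raw observations : RMSE vs truth = 8.27
SSA extraction   : RMSE vs truth = 2.03
SDD benchmark    : RMSE vs truth = 6.76  (A = 255.0, lambda = 17.7 %EL)
SSA signal-noise w-correlation = 0.0024
```

SSA cuts the error of the raw profile by a factor of four where the naive
SDD fit barely improves on it — the anterior read-off absorbed the noise at
x = 0 and the 1/e crossing landed 2.3 %EL early. The near-zero
w-correlation says the extracted trend and its residual are almost
w-orthogonal, i.e. the separation is clean.

## Command line

```sh
gradsig simulate  --reps 5 --out sim/                 # dump (truth, noisy) CSV pairs
gradsig extract   --method ssa --in sim/rep0.csv --out rep0_ssa.csv
gradsig run-study --methods ssa,sdd,arima,arfima,ets,nn --reps 100 --seed 42 --out study/
gradsig report    --study study/ --out tables/
```

`run-study` writes a summary table (model, rmse, mape, mae, rrmse, min,
max), the per-replicate RMSE matrix, Wilcoxon p-values, and a JSON manifest
that reproduces the run exactly. Measured FlyEx-style profiles can be read
with `read_profile(..., dialect="flyex_like")` and cropped to the standard
20–80 %EL analysis window with `crop_to_ap_window`; no external data is
bundled or required.

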