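# naphl — alpha-power transformed lifetime distributions

`naphl` is a statistical library for a distribution-generating transform
that adds one shape parameter to any baseline lifetime law, and for its
half-logistic special case, the **NAP-HL distribution**. It is aimed at
reliability engineers and biostatisticians who fit flexible two-parameter
lifetime models to positive, right-skewed data and want to benchmark the
classical estimation criteria against each other.

## The model

Given a baseline CDF `H(x)`, the transform produces a new CDF

```
F(x) = (α^{1 − H(x)^α} − α) / (1 − α),      α > 0,  α ≠ 1,
```

with `F = H` recovered continuously as α → 1. Taking the half-logistic
baseline `H(x) = (1 − e^{−θx}) / (1 + e^{−θx})` on x > 0 gives the NAP-HL
distribution with shape α and rate θ (a pure inverse scale:
`X(α, θ) ~ X(α, 1)/θ`). The shape parameter moves skewness, tail weight
and the hazard-rate profile (increasing, decreasing or bathtub) while
keeping the model at two parameters.

The package provides:

* `family` — the generic transform, its density factor and algebraic
  inverse (quantiles / inverse-transform sampling for any baseline);
* `distribution` — `NapHL` with pdf/cdf/survival/hazard functions,
  quantiles, seeded sampling, quadrature moments, incomplete moments,
  mean residual life and waiting time, Rényi and Tsallis entropies, order
  statistics, and the exponential-mixture series expansion as an analytic
  cross-check;
* `estimation` — seven criteria (MLE, CVME, MPSE, OLSE, WLSE, ADE,
  RTADE) over a common multi-start Nelder–Mead driver in log-parameter
  space;
* `gof` — log-likelihood, AIC/BIC, Anderson–Darling `A*`, Cramér–von
  Mises `W*`, Kolmogorov–Smirnov distance with exact p-value;
* `competitors` — six half-logistic generalisations (OFHL, KHL, EHL,
  MoHL, HL, PoHL) with derived closed-form CDFs and MLE fitting;
* `simulate` — a seeded Monte Carlo harness reporting AB/MSE/MRE per
  (parameter set, sample size, method) cell;
* `datasets` — two bundled benchmark datasets (20 component failure
  times; 76 Kevlar 373/epoxy fatigue lives) and descriptive statistics;
* a `naphl` command-line tool (`fit`, `compare`, `simulate`, `describe`,
  `sample`).

## Worked example

```python
import naphl

d = naphl.NapHL(alpha=1.1, theta=0.6)
s = d.moment_summary()
print(f"mean {s.mu1:.4f}  var {s.variance:.4f}  skew {s.skewness:.4f}  "
      f"kurt {s.kurtosis:.4f}  mode {s.mode:.4f}")

met = naphl.load_dataset("metrology").values
res = naphl.fit(met, "MLE")
rep = naphl.gof_report(met, res.model().cdf, res.loglik, 2)
print(f"alpha={res.alpha:.4f} theta={res.theta:.4f} loglik={res.loglik:.4f}")
print(f"AIC={rep.aic:.4f} KS={rep.ks:.4f} p={rep.ks_pvalue:.4f}")
```

prints

```
mean 2.3934  var 3.8168  skew 1.5197  kurt 6.5289  mode 0.6715
alpha=0.6169 theta=7.1682 loglik=17.2517
AIC=-30.5033 KS=0.0835 p=0.9969
```

The first line is the quadrature moment summary at (α, θ) = (1.1, 0.6):
a right-skewed density (skewness 1.52, kurtosis 6.53) with mode well
below the mean. The fit lines show the maximum-likelihood estimate on
the 20 failure times with its goodness-of-fit report: the tiny K-S
distance (0.0835, p ≈ 0.997) says the fitted CDF tracks the empirical
one closely.

From the shell, the model comparison on the same data ranks all seven
models by AIC with the NAP-HL model first:

```sh
$ naphl compare metrology.csv
 model  alpha   gamma      AIC    K-S  p-value
NAP-HL 0.6169  7.1682 -30.5033 0.0835   0.9969
   EHL 0.6774  6.7704 -30.4152 0.0943   0.9867
  OFHL 0.3083 21.1333 -30.3970 0.1335   0.8227
   ...
```

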