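# irtmiss

Missing item responses are endemic in low-stakes educational assessments:
students omit items they cannot or do not want to answer, and they run out
of time at the end of a test. How those missing responses are treated when
test data are scaled with an item response model — scored as wrong, scored
as partially correct, ignored, modeled jointly with a response propensity,
or multiply imputed — changes the estimated ability distributions, and with
them group (e.g., country) means and rankings.

`irtmiss` is an analysis package for studying these treatments under a
controlled, fully specified data-generating process. It is aimed at
psychometricians and methodologists who want to compare missing-data
treatments for the two-parameter logistic (2PL) model without depending on
any proprietary assessment database.

## The models

Item responses follow the 2PL,

    P(X_pi = 1 | theta_p) = psi(a_i (theta_p - b_i)),

with logistic cdf psi, discriminations a_i, difficulties b_i, and ability
theta_p ~ N(0, 1). Response indicators R_pi (1 = observed) follow the
Mislevy–Wu missingness model

    P(R_pi = 1 | X_pi, theta_p, xi_p) = psi(xi_p - beta_i - delta_i X_pi),

where xi_p is a latent response propensity, bivariate-normal with theta_p.
The shift delta_i lets missingness depend on the (possibly unobserved)
response itself:

* `delta = 0` — latent ignorability: missingness depends only on xi
  (models MO1/MO2; MO1 additionally fixes Cor(theta, xi) = 0);
* `delta -> -inf` (operationally −10) — only incorrect responses can be
  missing, which is exactly what scoring missing responses as wrong
  assumes (models MW/UW);
* a free common (MM1) or item-format-specific (MM2) delta nests both.

Within the administered design, (X, R) is a three-category variable
(observed-wrong / observed-right / missing) whose category probabilities
the joint estimator maximizes over a 21 × 21 Gauss-type quadrature.
Treatments are compared by generating data under known truth, fitting
each treatment, linking estimated item parameters to the true ones with
Haberman linking (log-mean-mean for two groups), and reading off the bias
of the linked mean and SD against the truth (0, 1). Multi-group linking,
the reporting metric (pooled mean 500, SD 100), BIC/GHP model comparison
and balanced-repeated-replication standard errors support a synthetic
multi-country analysis.

## Worked example

`analysis/02_fit_treatments_single_dataset.py` generates one dataset at
delta = −2 with 20% missing responses (a regime where *neither* scoring
as wrong nor latent ignorability is correct) and applies the seven study
treatments:

```
dataset: N=1500, I=20, realized missing rate 0.201, calibrated beta -0.969
model  linked_mean  linked_sd   loglik  seconds     BIC    GHP
   CD      -0.0483     1.0422 -16296.7      0.0     NaN    NaN
   UW      -0.2120     1.0324 -16639.5      0.1     NaN    NaN
   UO       0.3201     0.9420 -12999.3      0.0     NaN    NaN
  MO2       0.2808     0.9544 -26457.8      1.0 53369.0 0.2947
  MM1      -0.0603     1.0430 -26445.1      4.1 53351.0 0.2945
  IF1       0.3307     0.9452 -81512.8     13.0     NaN    NaN
  IF2       0.2977     0.9578 -81650.4     14.5     NaN    NaN
```

Truth is mean 0, SD 1. The complete-data fit (CD) and the correctly
specified Mislevy–Wu model (MM1) sit near the truth; scoring missing as
wrong (UW) biases the mean down by ~0.2 SD; ignoring missingness (UO),
the latent-ignorable model (MO2) and the FCS imputations (IF1/IF2)
bias it up by ~0.3 SD. MM1 also wins the model comparison (lower BIC;
the GHP gap to MO2 is below the 0.001 notability threshold on a single
dataset of this size). The other drivers produce the calibration table
(`01`), a desk-scale bias/RMSE table over the design (`03`), and the
multi-group linking + BRR demonstration (`04`); each writes its table
under `results/`.

A CLI wraps the same library calls, e.g.

```bash
irtmiss simulate --n 1500 --items 20 --delta -1 --missing 0.2 --seed 1 --out scratch/demo
irtmiss fit --model MM1 --data scratch/demo/responses.csv --items scratch/demo/items.csv --out scratch/mm1.json
```

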