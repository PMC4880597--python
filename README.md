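# axondist

Which probability distribution actually describes axon diameters?

Axon diameters within a white-matter tract such as the corpus callosum are
non-negative, right-skewed and heavy-tailed. Microstructure models — both
for direct electron-microscopy morphometry and for indirect inference from
diffusion-weighted MRI (e.g. AxCaliber-style approaches) — need a parametric
distribution for them, and the gamma distribution is the conventional pick.
`axondist` makes that choice an empirical question: it fits sixteen candidate
families to per-axon diameter samples by maximum likelihood, ranks them with
the finite-sample-corrected Akaike information criterion, localizes each
family's misfit across the diameter range, and tests whether rankings are
consistent across regions and specimens. On corpus-callosum data the
generalized extreme value family wins decisively and the gamma family's
misfit is significant — a result this package lets you reproduce, audit and
apply to your own measurements.

## The method

For a diameter sample x₁…xₙ (μm) and each family f(x; θ) the package
maximizes the log-likelihood ln L(θ) = Σᵢ ln f(xᵢ; θ) — in closed form for
the normal, log-normal, exponential and Rayleigh families, otherwise by
Nelder–Mead on a constraint-transformed parameter space from method-of-
moments starts with seeded jittered restarts. Families are scored with

    AICc = 2k − 2 ln L + 2k(k+1)/(n − k − 1),

where k is the number of estimated parameters (lower is better; BIC and the
negative log-likelihood are reported alongside and, on these data, give the
same ordering). Fit quality is profiled as F̂(x) − Fₙ(x), the fitted CDF
minus the empirical CDF, across the observed diameter range. Rank
consistency across m datasets × k families is tested with Friedman's
χ²_F = [12/(mk(k+1))] Σⱼ Rⱼ² − 3m(k+1) and Nemenyi's post-hoc critical
difference CD = q_α √(k(k+1)/(6m)).

The sixteen families: Birnbaum–Saunders, exponential, extreme value
(minimum-type Gumbel), gamma, generalized extreme value, generalized Pareto,
inverse Gaussian, log-logistic, log-normal, logistic, Nakagami, normal,
Rayleigh, Rician, t location-scale, Weibull.

## Worked example

Generate a corpus-callosum-like synthetic dataset (generalized extreme
value, location 0.45 μm, scale 0.15 μm, shape 0.2; regions genu/body/
splenium with 7680/5260/7188 axons, truncated to the 0.03–3.09 μm
measurement range), summarize it, and rank all sixteen families:

```bash
axondist simulate --preset --seed 1 --out sim.csv
axondist stats sim.csv
axondist rank sim.csv --seed 1 --restarts 2   # pooled + per-region tables
```

`stats` prints (pooled row; values in μm):

```json
"whole": {"n": 20128, "mean": 0.574, "sd": 0.262,
          "min": 0.149, "max": 3.070, "median": 0.510}
```

— right-skewed (median < mean), at the scale of real corpus-callosum
morphometry. The ranking (abridged) comes back as:

```
                   family  rank  k         aicc
generalized_extreme_value     1  3 -8495.1
             log_logistic     2  2 -7377.9
               log_normal     3  2 -7184.0
         inverse_gaussian     4  2 -7122.8
        birnbaum_saunders     5  2 -6994.9
                    gamma     6  2 -4918.2
                      ...
              exponential    15  1 17892.2
            extreme_value    16  2 21981.2
```

The generating family is recovered at rank 1; the two-parameter log-domain
families (log-logistic, log-normal, inverse Gaussian, Birnbaum–Saunders)
cluster next; gamma trails them by ~2000 AICc units despite having the same
number of parameters; and the minimum-type extreme value family — the wrong
skew direction entirely — is last. In Python the same pipeline is three
calls: `generate_dataset`, `fit_and_rank`, `cdf_error_profile`.

Test whether family choice matters across the seven packaged cross-species
datasets (two human specimens × three callosal regions, one macaque region;
six families each):

```bash
axondist compare-regions
```

```json
"friedman": {"statistic": 29.61, "df": 5, "p_value": 1.76e-05}
```

with the Nemenyi table flagging generalized extreme value vs gamma (mean
rank difference 5.0 > critical difference 2.85 at α = 0.05) as significant:
gamma fits significantly worse wherever it has been ranked.

To analyze your own measurements, supply a CSV with a `diameter_um` column
(optional `region`, `specimen`) to `stats`, `fit` and `rank`, or a
one-diameter-per-line file with `--headerless`.

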