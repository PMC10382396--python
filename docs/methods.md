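# Methods

## The consensus score

For a trait reported by $\bar{M}$ of the study's $M$ centres with q-values
$q_i$ and standardised effect sizes $\rho_i$,

$$
s = \frac{\sum_i q_i \sqrt{|\rho_i|}}{\bar{M}^2\,\hat{q}\sqrt{\hat{\rho}}}
    \times \max\!\left(\frac{M}{2}, \bar{M}\right)
  \quad\text{if } \bar{M} P > c, \qquad s = 1 \text{ otherwise},
$$

with the directionality penalty $P = |\sum_i \mathrm{Sign}(\rho_i)|/\bar{M}$
($\mathrm{Sign}(0)=0$). The score compares the observed q-value/effect-size
mass against what $\bar{M}$ centres would produce if every one sat exactly
at the expected values $\hat{q}$ and $\hat{\rho}$; $-\log_{10} s > 0$
declares consensus. The square root compresses effect sizes so that a few
very large $|\rho_i|$ cannot dominate ($\sqrt{x} > x$ for $x<1$,
$\sqrt{x}\le x$ for $x\ge 1$).

Decision classes, in the order they are checked:

1. `INSUFFICIENT_CENTRES` — $\bar{M} \le c$: too few centres report the
   trait for a score to be meaningful (score unset).
2. `INSUFFICIENT_INFO` — the gate $\bar{M}P \le c$ fails: effect
   directions cancel, $s = 1$ by definition.
3. `CONSENSUS` / `NO_CONSENSUS` — from the sign of $-\log_{10} s$; for a
   consensus the direction of dimorphism is the sign of the unweighted mean
   effect size.

Numerical choices:

- **Log base.** $-\log s$ is reported base-10; base 10 makes the score and
  its reported negative log internally consistent with how such tables
  round (e.g. $-\log_{10} 0.45 = 0.35$ to two decimals).
- **Gate arithmetic.** $\bar{M}P$ equals the integer
  $|\sum_i \mathrm{Sign}(\rho_i)|$, so the gate is evaluated as an integer
  comparison with $c$ and cannot be perturbed by floating-point noise.
- **Minimum-centre rule.** Scoring requires *more than* $c$ centres
  ($\bar{M} \ge 4$ at the default $c=3$). Sources describing this family
  of rules are ambiguous between "more than 3" and "at least 3"; the
  stricter reading is used, so 3-centre traits are classified
  `INSUFFICIENT_CENTRES`.
- **Gate variable.** The gate uses $\bar{M}$ (centres actually reporting
  the trait), not the study-wide $M$; in multi-trait studies $M$ enters
  only through $\max(M/2, \bar{M})$. The implementation requires
  $\bar{M} \le M$.
- **q-value clamping.** q-values are probabilities; inputs are clamped to
  $[0,1]$.
- **Zero effects.** $\rho_i = 0$ contributes zero to both numerator and
  penalty; a trait where every centre reports $\rho_i=0$ fails the gate.
- **Degenerate score 0.** If the gate passes but every $q_i = 0$ (possible
  only with artificially exact zeros), the score is floored at the smallest
  positive double so that $-\log_{10}$ stays finite.
- Scores are kept at full precision internally and in CSV output;
  rounding (default 2 decimals) applies only to the printed report.

**Parameters.** $c$ (default 3) is the minimum net number of
direction-agreeing centres; $\hat{q}$ (default 0.05) the expected q-value
at the usual 5% FDR level; $\hat{\rho}$ (default 0.5, dimensionless
standardised units) a moderate expected effect size. These defaults suit
high-throughput screens; `calibrate_rho_hat` estimates $\hat{\rho}$
empirically as the 10% trimmed mean of observed $|\rho_i|$ (trimming
$\lfloor 0.1 n \rfloor$ values from each tail), which is how a field-wide
expected effect size can be set from previous data.

## Per-centre model

Within each centre × trait group, raw values are z-scored
($x \mapsto (x-\mu)/\sigma$, sample SD with $n-1$), pooling both sexes —
the group is indexed by centre only, so standardisation removes
centre-level location/scale shifts (different analysers, units, kits)
while preserving the within-centre sex contrast. Standardisation uses the
sample SD to match the pooled-variance convention of Cohen's d.

The sex effect is then estimated from

`value_std ~ intercept + sex + body_weight_centred`, batch (test date) as a
random intercept (statsmodels `MixedLM`, REML).

- **Effect size.** $d = \beta_{sex} / \sqrt{\sigma^2_{batch} +
  \sigma^2_{resid}}$: the covariate-adjusted male–female difference in
  units of the total residual SD (batch + within-batch). With one batch
  and constant body weight this is exactly the two-sample Cohen's d, and
  the sex-term p-value is exactly the pooled two-sample t-test p-value.
  Computing d from the model coefficient (rather than marginally) keeps it
  consistent with the adjusted p-value; in balanced data the two agree
  closely.
- **Standard error.** The usual large-sample form
  $\mathrm{se}(d) = \sqrt{(n_m+n_f)/(n_m n_f) + d^2/(2(n_m+n_f))}$,
  needed only to feed the meta-analysis baseline.
- **Fallback.** With fewer than 3 distinct batches, or when the mixed fit
  is singular/non-convergent, an OLS fit of the same fixed effects is used
  and a warning logged. Constant body weight drops the covariate (it would
  make the design singular).
- **Missing body weight** drops the animal from the fit (logged count):
  the covariate is part of the model, so imputing silently would change
  the estimand.
- An optional "IMPC mode" pre-filter requires a minimum of 50 animals per
  sex per centre before a centre contributes a result (off by default).

## Multiplicity

Benjamini–Hochberg q-values (statsmodels `fdr_bh`). The correction family
is configurable because the right family is a design choice: the default
`per_centre` corrects each centre across its own traits (each centre's
test battery is one family); `global` pools all centre × trait tests.

## Baselines

- **All-centres-agree**: consensus iff every centre has $q < \alpha$
  (default 0.05) and all effect signs agree. Deliberately ignores any
  minimum-centre rule — that is the naive criterion the score improves on.
- **Random-effects meta-analysis**: DerSimonian–Laird.
  $w_i = 1/se_i^2$, $Q = \sum w_i (y_i - \bar{y}_{FE})^2$,
  $\tau^2 = \max\{0, (Q - (k-1)) / (\sum w_i - \sum w_i^2/\sum w_i)\}$,
  pooled effect with weights $1/(se_i^2+\tau^2)$, two-sided normal test,
  heterogeneity $p$ from $\chi^2_{k-1}(Q)$. DL is the closed-form
  method-of-moments estimator; REML (the default of some meta-analysis
  software) can give slightly different $\tau^2$, which matters little for
  the comparison role the baseline plays here. Both the pooled-effect p and
  the heterogeneity p are reported, as either can be the quantity of
  interest. A single study passes through with $\tau^2=0$ and undefined
  (NaN) heterogeneity p.

## Synthetic data generator

`generate(SimulationConfig)` emulates a multicentre wild-type haematology
screen. For centre $c$, trait $t$, animal $j$:

$$
\text{value} = o_c + s_c\big(d_{ct}\,\sigma_{ref}\,\mathbb{1}[male]
 + \beta_{bw}(bw_j - \overline{bw}) + b_{c,t,\text{batch}(j)} + e_j\big)
$$

with $b \sim N(0, \sigma_b^2)$ shared within a batch,
$e \sim N(0, \sigma_e^2)$, and
$\sigma_{ref} = \sqrt{\sigma_b^2+\sigma_e^2}$, so the population
standardised sex difference net of the covariate equals `true_d` exactly —
the ground truth the estimator is tested against.

Defaults (the study conditions the tests use): 11 centres, 22
haematology-like traits with standardised sex effects spanning roughly
−0.9 to +1.25 (counts male-higher, cell-volume/haemoglobin indices
female-higher, as in real screens), 50 animals per sex per centre, 10
batches, batch SD 0.25 and residual SD 1 (trait units before centre
scaling), body weight $N(31, 3^2)$ g for males and $N(25, 3^2)$ g for
females with slope 0.01 standardised units/g, centre offsets $N(0, 2^2)$
and scales $U(0.7, 1.3)$ drawn once per centre (seeded). `true_d` may be a
per-centre vector, which is how the scenario presets S1–S6 (full
agreement, 2-vs-2 splits, borderline cases, opposite significant
directions, mixed patterns) induce between-centre disagreement — always
through the data, never by injecting p-values.

What the generator does *not* emulate: heavy-tailed or contaminated noise,
temporal drift within centre, litter/strain substructure, missingness
mechanisms, or correlated traits. Tests passing on this generator show the
pipeline recovers known effects under the model's own assumptions
(Gaussian, linear, batch-exchangeable); they do not certify behaviour on
real data violating them.

## Operating characteristics (computed by the test suite)

With 6 centres and 100 animals/sex on a single trait, over 100 simulated
replicates: a true standardised effect of 0.8 yields consensus in ≥95% of
replicates, and a true null effect in ≤10% (both the sign gate and the
large null q-values protect). Replicate counts (100–200) and sizes were
chosen to keep each Monte-Carlo check to seconds while leaving wide
margins around the thresholds. Estimator recovery: the mean estimated
effect over 200 replicates at $n=100$/sex is within 0.05 of the true
value, with the full generator (batches, body weight, centre shifts)
active.

## Known limitations

- The score has no finite-sample null distribution attached; $-\log_{10}s$
  is an evidence scale, not a calibrated p-value. Scores near 1 are
  genuinely ambiguous.
- The mixed model assumes Gaussian residuals and a random batch intercept;
  count-like traits with strong skew may need transformation upstream.
- `INSUFFICIENT_INFO` vs `NO_CONSENSUS` both yield $s=1$ on the boundary;
  they are distinguished by which branch produced the 1 (gate vs
  cancellation), since the score value alone cannot tell them apart.
- The FDR family is a configuration choice; per-centre and global
  corrections can classify borderline traits differently.
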