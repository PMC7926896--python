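# Methods

## Design and data model

The analysis targets a two-group qPCR experiment: `n = 4` fish per group
(control vs. acutely air-exposed), four brain regions dissected per fish,
26 genes per region, 3 technical replicates per well. All statistics are
run independently per brain region, since the biology (and the reporting
convention the pipeline mirrors) treats regions as separate tissues;
nothing pools regions into one model.

Measurements are threshold cycles (Ct): one PCR cycle equals a factor
`E` (amplification efficiency) in template amount, so Ct is a negative
log-expression scale. `E` defaults to 2.0, the standard assumption for a
validated SYBR assay; it is a parameter, not an estimate — the pipeline
performs no dilution-series efficiency estimation.

## Synthetic data generator

Because data of this kind are typically not deposited, the generator is
first-class: it produces Ct tables with the exact design above plus a
ground-truth record, so recovery can be verified.

The measurement model is additive on the Ct scale:

    ct = baseline(gene, region) - gamma(animal) - x * effect_log2 / log2(E)
         - bio_noise(animal, region, gene) + tech_noise(replicate)

* `baseline(gene, region)`: drawn once per config from U(18, 30) cycles
  and then fixed, giving a realistic spread of expression levels without
  per-run variation. Reference candidates get one region-constant
  baseline — a reference gene is by definition expressed uniformly
  across tissue — while target baselines vary by region.
* `gamma(animal) ~ N(0, 0.3)` cycles models RNA input / RT-yield
  differences that shift all genes of an animal together; reference
  normalization removes it downstream.
* `effect_log2(gene, region)`: injected log2 fold changes. The defaults
  mirror the qualitative pattern of acute-stress studies in fish
  (immediate-early-gene induction in the telencephalon, opposite
  crf1/crf2 shifts relative to crh-bp, pomc effects in optic tectum and
  rhombencephalon, gabaa/serotr shifts), with magnitudes 1.5–2 log2
  units, the size of the larger effects such studies report. Reference
  candidates carry zero effect everywhere.
* Biological noise: SD 0.5 cycles per (animal, region, gene) for
  targets. Among the 8 reference candidates, the stable trio
  (bactin, eIF4E, ef) gets SD 0.05 and the remaining candidates SD 0.35,
  emulating the usual outcome that only part of a candidate panel is
  truly stable; the stability ranking therefore recovers that trio by
  construction rather than by chance.
* Technical noise: SD 0.2 cycles per replicate, typical replicate
  scatter for a well-run plate.
* Undetected wells (probability `missing_rate`, default 0) are recorded
  as missing, not censored at cycle 40; missingness exercises the
  pipeline's drop rules.

What the generator does **not** emulate: melt curves, per-assay primer
efficiencies, inter-plate calibration, heavy-tailed outliers,
gene–gene expression correlation beyond the shared animal effect, and
region-correlated effects. Passing tests therefore demonstrate the
statistics are implemented correctly under the assumed Gaussian additive
model — not that real brain qPCR data satisfy that model.

## Reference-gene stability

`M_j` is the mean over partners `k` of the SD across samples of
`log2(q_j / q_k)`; iterative exclusion removes the largest-M gene and
recomputes until 3 remain (the selected count is fixed at three; the
pairwise-variation `V(n/n+1)` stopping rule is not implemented).
Relative quantities for stability are computed per gene as
`E^(gene mean Ct - sample Ct)`; any per-gene positive rescaling is
irrelevant because M is ratio-based (a tested invariant). Ties in M
break lexicographically for determinism. Samples missing either gene of
a pair are dropped pairwise with a minimum of 3 complete pairs.
Selection is per dataset by default (one reference set for all regions);
per-region re-selection is available via a flag.

## Normalization

Delta-Ct is control-group mean minus sample Ct, so up-regulation gives
positive delta-Ct and RQ > 1. The normalization factor is computed per
sample as the geometric mean of that sample's reference RQs — the
standard reading of the geometric-mean workflow; a per-group variant
(one factor per biological group) is available behind a flag since the
verbal description of such workflows is often ambiguous. The log
transform is log2 (qPCR fold-change convention; base configurable).
Group SD/SEM are computed on the log scale; the reported geometric mean
is the back-transformed log mean.

Replicate QC: replicate SD above 0.5 cycles flags the well in the QC
log (it is not dropped — with n = 4 animals, discarding data costs more
than it saves).

## Two-group tests and bootstrap

Both Mann–Whitney conventions are always reported: the exact two-sided p
(full enumeration with midranks, p = min(1, 2 × smaller tail) — at 4 vs 4
complete separation this is 2/70 = 0.029) and the tie-corrected normal
approximation without continuity correction (0.021 at the same
configuration). Published small-n qPCR analyses mix the two conventions,
so parity with both avoids chasing which column a given table used.
No multiplicity correction is layered on these tests; the hierarchical
model is the pipeline's answer to multiplicity. Significance is two-sided
at alpha = 0.05.

Gene-pair ratios are tested on the log scale (difference of log
normalized expressions); a raw positive quotient could not produce the
negative interval bounds these analyses report. BCa intervals follow
Efron: z0 from the proportion of bootstrap statistics below the observed
value (ties counted half), acceleration from jackknife skewness,
endpoints read from the bootstrap quantiles at the adjusted levels;
B = 2000, per-group independent resampling, seeds recorded. A constant
sample returns the degenerate interval.

## Hierarchical model

One model per region: `y_ij ~ N(alpha_j + beta_j x_i + gamma_i, s^2)`
with zero-centred Gaussian random effects for gene intercepts,
gene-specific group differences and animal effects. No global intercept
or global treatment term is included: y is centred by construction
(delta-Ct against the control mean), so the zero-centred effects are
proper, and a global treatment effect would fight the exchangeable
`beta_j` prior for the same variance.

Priors: inverse-gamma(0.001, 0.001) on all four variances, giving fully
conjugate Gibbs updates (the sampler is dependency-free and auditable:
every conditional is a closed-form Gaussian or inverse-gamma, and the
coefficient conditionals are verified against an independent
precision-matrix derivation in the tests). A half-normal(0, 5) prior on
the SDs is available as a sensitivity switch via a random-walk
Metropolis step on log sigma. Defaults: 4 chains × 4000 iterations, half
warmup; split-R̂ and ESS are computed per scalar parameter (arviz), and
any R̂ > 1.01 or ESS < 100 flags the fit prominently rather than
failing it.

Summaries per gene: posterior mean of `beta_j` (the point estimate), its
posterior SD (reported in the SEM position of the summary table — it is
the posterior-summary pair to the point estimate), the central 95%
credible interval (empirical 2.5/97.5% quantiles), and the posterior
probability `Pr(beta_j > 0 | y)` — chosen as the "posterior p" because
it co-varies with the sign of the point estimate the way published
summary tables of this form do; a posterior-predictive tail-area
alternative would require a declared discrepancy statistic and is not
the default. Posterior predictive checks simulate replicate datasets
from evenly spaced retained draws and compare observed vs. replicated
quantiles (QQ-style band).

With the treatment indicator absent, `beta_j` carries no likelihood
weight and its chain reproduces the prior balance (posterior p ≈ 0.5);
because the IG(0.001, 0.001) hyperprior is heavy-tailed, the
unidentified variance then wanders across scales — expected behaviour,
covered by a test, and harmless in identified fits.

## PCA

Correlation-matrix PCA (centre + scale) is the default because the
"cos² sums to one per variable" identity holds exactly in that
convention; covariance PCA is a flag. Variable coordinates are
eigenvector × sqrt(eigenvalue) (correlation of gene with component);
cos² is the squared coordinate normalised per gene. With n = 8 samples,
components beyond min(n − 1, p) are reported as exactly zero variance.
Component signs are fixed (largest-magnitude loading positive).
Zero-variance genes raise an error naming the gene; inside the pipeline
that subset is skipped with a warning so degenerate (e.g. noise-free
null) datasets still run. Group ellipses are normal-theory ellipses of
the Dim1/Dim2 score cloud (mean, covariance, chi-square radius); with
n = 4 per group they are flagged descriptive-only.

The shipped gene subsets are the immediate-early, HPI-axis and
neurotransmitter panels plus the final marker-candidate subset
(gabaa, crfr1, crfr2, mr, egr-1, 5-ht-r, c-fos); arbitrary subsets are
accepted.

## Numerical and scale choices

* Exact Mann–Whitney enumeration is capped at 2 × 10⁶ assignments;
  beyond that the asymptotic test is the intended tool.
* The mean statistic has a vectorised bootstrap path; other statistics
  go through a generic per-resample loop.
* Pipeline seeds: one user seed fans out deterministically to named
  sub-seeds (bootstrap, per-region Gibbs, per-region posterior
  predictive), all recorded in the report.
* Simulation sizes in the verification suite (100 recovery fits at
  2 chains × 2000 iterations, 40 sparse-effect fits, 500 bootstrap
  coverage replications, 200 bias seeds) were chosen to give binomial /
  Monte-Carlo error comfortably inside the asserted bands.

## Known limitations

* The Gaussian likelihood has no robust-t alternative; gross outliers
  inflate `s^2`.
* Exchangeability of the vectorised sampler holds distributionally but
  not draw-for-draw under gene relabelling (a permuted dataset consumes
  the chain's random numbers in permuted order).
* Per-region reference re-selection is supported but unstudied here;
  with n = 4 per group the stability ranking itself is noisy.
* The hierarchical model shares one residual variance across genes;
  strongly heteroscedastic panels (e.g. references vs. targets) show up
  in the posterior predictive QQ band rather than being modelled.
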