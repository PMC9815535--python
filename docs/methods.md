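# Methods

## The classification model

The core procedure is a control-anchored, per-parameter cutoff rule with a
k-of-m aggregation. For every behavioral parameter and every time point,
the cutoff is the concurrent control group's sample mean ± one sample
standard deviation (denominator n − 1; the controls are a sample, not the
population), taken in the parameter's pathological direction. An animal is
flagged on a parameter when its value lies *strictly* beyond the cutoff;
a value exactly at the cutoff is not flagged. An animal flagged on at
least k = 4 of the m = 7 profile parameters at the post-trauma time point
is classified *affected*; all other classifiable animals are *unaffected*.
Controls are classified too, against cutoffs computed from the full control
group (plug-in cutoffs): their self-classification rate is the empirical
false-positive rate of the rule. A leave-one-out option rescoring each
control against cutoffs computed from the remaining controls is available
(`leave_one_out=True`); it removes the animal's own pull on the mean/SD and
therefore yields a slightly *higher* self-flag rate than the plug-in
default.

Treatment response is classified only for animals that were affected
pre-treatment, against cutoffs recomputed from the concurrent controls at
the post-treatment time point. Two operationalizations of "recovery" are
implemented:

* `post_count` (default): responder iff fewer than k parameters are flagged
  post-treatment — the animal no longer meets the affected criterion.
* `recovered_count`: responder iff at least k of the m post-treatment
  parameters are unflagged.

For m = 7 and k = 4 the two are logically equivalent (flag count < 4 ⟺
≥ 4 unflagged), so the choice only matters for custom k/m. `post_count` is
the default because the second built-in profile swaps two parameters
between time points, which makes strict animal-relative per-parameter
recovery matching undefined for those two parameters.

### Directions

The source procedure states the flag rule only as "beyond the cutoff in
either direction, per parameter"; the shipped per-parameter directions are
inferred from which tail the affected groups occupy in the published group
contrasts: exploration measures (total/arm distances, open-arm and
center times, social preference index) are `low_is_affected`; freezing
times, closed-arm time and the anxiety index are `high_is_affected`. The
social preference index is the one parameter not covered by that published
pattern sentence; it ships as `low_is_affected` (impaired social
recognition lowers the index). Any direction can be overridden in a custom
`ProfileDefinition`, and `two_sided` is available per parameter.

### Known discrepancies in the published counts

The source report gives "~65.6%" affected alongside figure counts of 64/93
(68.8%), an "unaffected" percentage (34.6%) that makes the pair sum to
more than 100%, and a post-treatment control affected rate (18.5%) that is
not an integer fraction of n = 16. No computation in this package targets
those numbers; the reproducible quantities are the Fisher p-values and the
count-consistent rates (57% = 41/72, 49% = 26/53, 63% = 22/35, 12.5% =
2/16).

## Statistics

* **Fisher exact test** (scipy implementation) for 2×2 classification
  tables, two-sided by the minimum-likelihood rule: the p-value sums the
  point probabilities of all tables with the observed margins whose
  hypergeometric probability does not exceed the observed one. The test
  suite verifies it against an independent exact-rational enumeration
  oracle. The reported odds ratio is the sample ad/bc.
* **Normality-gated group comparison**: Shapiro–Wilk on every group at
  α = 0.05; the parametric branch (one-way ANOVA) is taken only when *all*
  groups pass, otherwise Kruskal–Wallis. Post-hoc tests run only when the
  omnibus p < α: Bonferroni-adjusted pairwise t tests pooling the ANOVA
  mean-square error on the parametric branch, Dunn's test on the
  nonparametric branch. Dunn's test is implemented in-package (pooled
  mid-ranks, tie-corrected variance N(N+1)/12 − Σ(t³−t)/(12(N−1)),
  two-sided normal p, Bonferroni over all pairs); the adjustment method is
  recorded in the result's audit trail. It is validated against a
  hand-computed rank example and the identity z² = Kruskal–Wallis H for two
  groups. No variance-homogeneity test is applied. A constant group is
  treated as failing the normality gate (a point mass has no normal fit).
* **Proportion summaries** report raw and rounded percentages over
  classifiable animals only, with Wilson 95% intervals; zero classifiable
  animals yield undefined (NaN) percentages rather than 0.

## Derived measures

Anxiety index = 100·(closed-arm time + center time)/total session time;
preference index = 100·(t_unfamiliar − t_familiar)/(t_unfamiliar +
t_familiar). Both are scale-invariant in their time inputs. Densitometry:
band optical density is background-corrected by *subtraction* (not
division) and divided by the same lane's background-subtracted GAPDH
signal, then scaled by the control-group mean so control values average 1
by construction; the subtractive reading is the package's documented choice
— it is the only reading under which the loading-control step is a ratio of
like quantities. Electrophysiology protocol responses are summarized as
100·mean(protocol responses)/mean(baseline responses); values below 100
indicate inhibition. Raw-to-index derivation happens at CSV ingestion when
raw columns are present; precomputed index columns are accepted as-is and
never overwritten.

## Synthetic cohorts

The generator emulates exactly the structure the classifier assumes: the
control population is multivariate Gaussian over the profile parameters
with an equicorrelation ρ (the seven measures are correlated readouts of a
single latent anxiety construct; one ρ keeps the model analyzable), and a
latent affected fraction of the exposed group is shifted by δ control-SDs
in each parameter's pathological direction. Post-treatment, a latent
responder fraction of affected animals reverts to the control distribution
(complete reversion by default; `partial_reversion` retains a configurable
fraction of the shift) while non-responders keep their full shift.

Defaults mirror the study conditions where these are stated — 16 controls,
93 exposed animals, about two thirds affected and just under half
responding — and are otherwise round numbers chosen once: δ = 2 SD, shift
on 5 of 7 parameters (so the 4-of-7 boundary is exercised, not just
saturated cases), ρ = 0.2, and per-parameter control means/SDs on the
scales typical of 5-minute rodent tests (the source reports no
distributional summaries, so these are acknowledged round-number choices).
For a profile that swaps parameters between time points, the shifted
subset is drawn from the post-trauma list and topped back up from the
swapped-in parameters so the affected load is comparable across time
points.

What the generator does **not** emulate: non-Gaussian (skewed, bounded,
zero-inflated) real behavioral distributions, heteroscedasticity between
groups, partial or parameter-specific treatment effects beyond the single
reversion fraction, litter/batch structure, or any raw trajectory/bout
data. Passing recovery tests therefore shows the pipeline is correct under
its own assumptions — not that the 1-SD/4-of-7 rule is optimal for real
cohorts.

## Numerical choices and degenerate inputs

* Flags use strict inequalities; ties at the cutoff are never flagged.
* A zero control SD collapses the cutoff to the mean and emits a
  `DegenerateCutoffWarning`; classification proceeds (strictness then means
  only values beyond the mean can flag).
* Records missing any active parameter are retained, labelled
  `unclassifiable`, and excluded from percentages — silent imputation would
  fabricate flags.
* Fewer than 2 complete control records at a time point is an error; there
  is no fallback cutoff.
* Parameter names are canonicalized (case-fold, whitespace/hyphens →
  underscores) at ingestion; reports echo canonical names.
* Percentages are rounded half-to-even at the integer reporting precision;
  raw fractions are always retained in the machine-readable report.

## Validation properties exercised by the test suite

* Classification equals a brute-force reimplementation on random small
  cohorts, and is invariant under per-parameter affine rescaling.
* Raising k or the SD multiplier is monotone (never creates new flags).
* On an infinite homogeneous Gaussian population scored against its true
  mean/SD with one-sided cutoffs and independent parameters, the
  per-parameter flag rate is Φ(−1) ≈ 0.1587 and the affected rate the
  binomial tail P(Bin(7, Φ(−1)) ≥ 4) ≈ 0.0148. With finite plug-in
  control anchors the rate is exactly computable via the internally
  studentized residual (r²·n/(n−1)² ~ Beta(½, (n−2)/2)): 0.014929 at
  n = 16 — a real but small inflation that Monte-Carlo at a few thousand
  animals cannot resolve, which is why the test asserts the strict
  inequality on the exact rate and checks the simulated rate against it
  within 3 SE.
* The gated comparison pipeline's null rejection rate at α = 0.05 stays
  within 0.05 ± 0.015 over 2,000 replicates.

Problem sizes in the default suite (10⁵-animal Monte-Carlo, 20-seed
recovery at 250 animals per cohort, 2,000 null replicates, 1,000
brute-force cohorts) were chosen so the whole suite completes in well under
a minute on one CPU while keeping every stochastic check at ≥ 3-SE
resolution.

## Limitations

The package implements the published rule, deliberately without
improvements: no multivariate or latent-class classification, no
repeated-measures or mixed-effects statistics, no variance-homogeneity
gating, and no ingestion of raw tracking exports. The 1-SD cutoff and the
4-of-7 threshold are conventions of the source procedure, not estimates;
their false-positive behavior is characterized (see above) but not tuned.
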