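# Methods

This note documents the statistical models, conventions and numerical
choices behind `uropep`, in the spirit of a package methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Data model

A CE-MS urine peptide profile is a peak list: per peptide a calibrated
monoisotopic mass (Da, analysis window 800–20,000), a CE migration time
(min) and a normalized ion-count amplitude. A cohort is a dense
samples × peptides matrix in which 0 encodes non-detection. Zero inflation
is treated as informative signal throughout: zeros enter rank statistics as
exact ties at the minimum, are included in activity means, and are
preserved (never imputed or rescaled) by normalization. Clinical metadata
carry a group label that maps to an ordinal disease grade — 2 for HCC, 1
for liver cirrhosis, 0 for everything else (normal, NAFLD, NASH without
cirrhosis) — following the grading used for monotone-trend marker
selection. The mapping is fixed but overridable.

## Calibration and normalization

*Mass*: one global ordinary-least-squares fit of reference on observed mass
applied to all peptides. *Migration time*: a nearest-neighbour, tricube-
weighted local linear fit (span = fraction of reference points per local
fit, default 0.5; span ≥ 1 or < 3 references degrade to the global fit)
whose resulting mapping is forced monotone non-decreasing by a running
maximum in observed-time order.

*Amplitude normalization* corrects per-sample dilution and analytical
response against a panel of ubiquitously detected internal-standard
peptides with known reference amplitudes. For each sample, ln(observed
amplitude) of the detected standards is regressed on ln(reference
amplitude); the inverse of the fitted mapping is applied to every non-zero
amplitude. Regression is in natural-log space because dilution is
multiplicative. Two modes: `global` (plain OLS; exactly idempotent, and a
refit of the standards after normalization returns slope 1/intercept 0 by
construction) and `local` (tricube-weighted local linear fit, default span
0.5, inverted by interpolation along the monotonized curve with linear
end-segment extrapolation). The identities of the standards and the local
bandwidth are not canonical — they are user-supplied configuration, with
the synthetic generator able to emit a 29-standard panel for testing. A
sample must detect at least `min_detected` standards (default 15, a
majority of 29); fewer is an error naming the sample, not a silent skip.

## Two-step marker selection

Step 1 tests each peptide with a two-sided Wilcoxon rank-sum (Mann–Whitney
U) of HCC vs all non-HCC samples, mid-ranks for ties, exact null
enumeration when both groups have ≤ 10 observations and no ties, otherwise
the normal approximation with tie correction (the heavy zero ties make the
correction material). p-values are Benjamini–Hochberg adjusted across all
tested peptides; survivors require adjusted p < 0.05.

Step 2 computes, for the step-1 survivors only, the Spearman correlation of
amplitude with the ordinal grade (Pearson correlation of mid-ranks; exact
permutation p for n ≤ 7 by default — the threshold is configuration, the
t approximation takes over beyond it). These p-values are BH-adjusted
*within the survivors* (the nested reading of the published procedure),
and a marker must have adjusted p < 0.05 and |ρ| strictly > 0.3.
Constant-amplitude peptides have undefined ρ and are flagged and excluded.
The detection-frequency filter (keep peptides detected in ≥ 20% of samples,
≥ on the exact fraction) is a separate operation applied before selection
in the discovery pipeline.

Thresholds: ≥ for frequency ("at least 20%"), strict > for |ρ|, strict <
for both adjusted-p cutoffs.

## Classifier

The panel classifier is a soft-margin C-SVC with RBF kernel
K(u,v) = exp(−γ‖u−v‖²) and fixed hyperparameters C = 2.2691, γ = 0.0764,
stopping tolerance 0.001 (no tuning is performed; the values are part of
the published model definition). Class imbalance is handled by per-class
penalties C_k = C·n_total/(2 n_k) — the exact weighting of the original
software is unpublished; this balanced heuristic is the package's choice
and is switchable off. Features are ln(1+amplitude), standardized by
training-set mean/SD (refit per cross-validation fold); a `raw` mode exists
for sensitivity analysis. The membership score is the signed SVM decision
value, oriented positive toward HCC; no probability calibration is applied,
so a stored decision threshold is only meaningful for the configuration it
was computed under, and the Youden threshold is recomputed whenever the
model is retrained. "Total cross-validation" is implemented as
leave-one-out, tractable at these cohort sizes.

ROC: AUC is the Mann–Whitney concordance with tie correction; its 95% CI
uses DeLong's structural-components estimator (the exact binomial
machinery applies to sensitivity and specificity, which get Clopper–Pearson
intervals). The decision rule is positive iff score ≥ threshold. The Youden
threshold maximizes J = sensitivity + specificity − 1 over midpoints of
adjacent sorted unique scores, ties broken toward the lower threshold
(higher sensitivity); a degenerate all-equal score vector returns that
score with J = 0. Covariate adjustment refits a binomial logistic
regression of case status on (score, age, sex) and compares adjusted vs
unadjusted AUC with the paired DeLong test; detected separation falls back
to a ridge-stabilized fit and is flagged.

## Protease activity

Each sequenced peptide yields two cleavage sites in Schechter–Berger
notation: the N-terminal site takes P4–P1 from the protein flank and
P1′–P4′ from the peptide start, the C-terminal site symmetrically. Sites at
protein termini (empty flank) do not exist and never match. Hydroxyproline
(`p`) and oxidized methionine (`m`) are upper-cased before matching —
specificity rules are defined on unmodified residues. A protease is
associated with a peptide if any existing site matches any of its rules; a
peptide matching at both termini counts once, because activities aggregate
per-peptide intensities. Live cleavage-database services are out of scope;
the package ships (a) the curated association map of the bundled marker
panel and (b) a generic positional rule-table format (allowed-residue sets
per P4…P4′ with `*` wildcards; truncated positions near protein termini
fail non-wildcard constraints) so users can bring their own specificity
data. The bundled demonstration rule file is synthetic, not curated biology.

Activity(sample, protease) = arithmetic mean of the sample's substrate
amplitudes, zeros included — this keeps the estimator linear, so the group
mean of per-sample activities equals the substrate-average of per-group
peptide means, an identity the tests exploit. Fold change = mean case
activity / mean control activity (controls = all non-HCC), with two-sided
Mann–Whitney U p-values BH-adjusted across proteases; a zero control mean
leaves the fold change undefined and flagged. Per-patient averaging is the
default (pooled peptide means agree with it only on complete data).

QC: monoisotopic masses are recomputed from standard residue masses
(+15.994915 Da for `p`/`m`); the default agreement tolerance against
experimental TOF masses is configurable (the bundled experimental masses
deviate by up to ~80 ppm, one outlier excepted — see Limitations). Peptide
charge at the CE operating pH of 2 is 1 (N-terminal amine) plus one per
K/R/H; a regression of CE time on charge and ln(mass) flags annotations
with externally studentized residuals beyond 3 SD as likely false sequence
assignments.

## Survival

Kaplan–Meier product-limit curves with right-censoring; same-time deaths
are counted before censorings. The log-rank test is the Mantel–Haenszel
statistic over pooled event times with the standard discrete tie
increments. The primary hazard-ratio estimator is the O/E form
HR = (O_A/E_A)/(O_B/E_B) with CI exp(ln HR ± 1.96√(1/E_A + 1/E_B)) — chosen
because it derives from the same log-rank table as the test; a
single-covariate Cox fit is provided as an independent cross-check.
Administrative censoring at the 500-day follow-up horizon converts later
events into censorings at the horizon.

## Synthetic cohorts

The generator emulates the zero-inflated amplitude structure of CE-MS urine
profiles: detection is Bernoulli(f) per peptide/sample, detected amplitudes
are log-normal (the published analysis operates on ln intensities, and
amplitude noise is multiplicative). Marker peptides are moment-matched to
the bundled panel's per-group mean m, SD s and detection frequency f.
Because the printed m, s cover *all* samples while f is listed separately,
the generator first converts to detected-subpopulation moments
(m_d = m/f, s_d² = (s² + m²)/f − m_d², floored at a 5% CV), then matches
σ² = ln(1 + s_d²/m_d²), μ = ln m_d − σ²/2. The all-sample convention is the
default because a printed cell of mean 0 (SD 3) at 4% frequency is only
consistent with zeros included; `means_are="detected"` switches the
convention. Printed means of 0 with positive frequency are rounding
artifacts and are floored at 0.5 ion counts (half the printing unit) before
matching.

Background peptides are pure nulls — identical parameters in every group
(frequency uniform on [0.2, 0.95], ln-mean normal around ln 100, σ uniform
on [0.6, 1.4]) — so selection specificity is directly measurable. Default
group sizes are the discovery phase's 9/9/8/25/18; ages are truncated
normals fit to the published per-group mean and range (SD = range/4), sex
is Bernoulli from the published counts. Survival is exponential with
baseline rate ln 2/500 per day (median survival at the horizon) times
HR^flag for test-positive subjects, censored at 500 days. A single integer
seed drives one `numpy` Generator; identical seeds give bit-identical
cohorts, and a per-sample multiplicative dilution utility supports the
normalization tests.

What the generator does **not** emulate: between-peptide correlation (real
collagen fragments co-vary strongly), batch and instrument drift, heavy
tails or discreteness of ion counts, and any coupling between covariates
and peptide amplitudes. Passing recovery tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
field performance on real cohorts.

## Numerical choices and degenerate inputs

Exact-vs-asymptotic switching: rank-sum exact path at n ≤ 10 per group
without ties; Spearman exact permutation at n ≤ 7 (5040 permutations
enumerated; the 10! ≈ 3.6 M cost of larger exact enumerations is not worth
it when the t approximation is already accurate there). BH adjustment is
the step-up formula with capping at 1. Standardization guards zero-variance
features by unit SD. The local-regression inverse collapses flat curve
segments (< 1e-12 rise) before interpolation and errors on non-increasing
global fits. Youden candidates are midpoints only; ROC operating points add
∓∞ sentinels. The log-rank path warns and returns (χ² = 0, p = 1) when no
events exist; the O/E hazard ratio requires ≥ 1 event and positive expected
counts per group. Hazard-ratio seeds are offset by a fixed constant from
the cohort seed so amplitude and survival draws are independent streams.

## Problem sizes

The test suite and acceptance script run at the study's own scale:
discovery cohorts of 69 samples with 31 planted markers and up to 500
background nulls, validation cohorts of 126 samples, 50-seed recovery
ensembles, 500-seed log-rank calibration at 100/arm and hazard-ratio
recovery at 500/arm — sizes chosen so every simulation remains a
desk-scale computation while keeping Monte-Carlo error well below the
decision margins of the checks.

## Known limitations

- The recovery rate of the two-step selection on cohorts moment-matched to
  the bundled panel statistics is substantially below 31/31: the printed
  per-group summary moments constrain the generating distribution only up
  to second moments, and for markers whose frequency contrast exceeds their
  mean contrast the implied detected-amplitude distributions separate far
  less than the original data evidently did (the printed single-peptide
  AUCs and adjusted p-values are not jointly consistent under any
  zero-inflated log-normal at these group sizes). Recovery counts reported
  by the acceptance script should be read with that in mind.
- One bundled sequenced peptide (id 11725) has a printed experimental mass
  0.90 Da above the theoretical mass of its printed sequence — no standard
  modification explains the offset; it is shipped as printed and fails a
  100 ppm mass check that all other sequenced peptides pass.
- The curated substrate map covers only the marker panel's sequenced
  peptides; genome-wide protease inference requires user-supplied rules.
- Validation-cohort covariate adjustment refits on the validation samples
  (mirroring the published analysis); a fit-on-training mode is available
  through the library API by scoring with `adjust_covariates` on any
  cohort.
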