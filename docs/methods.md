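# Methods

This note documents the models, parameter choices, numerical details and
limitations behind `paleoherd`. Empirical claims below are the ones the
test suite and `scripts/acceptance.py` compute; nothing else is asserted.

## Seasonal cosine model

Intra-tooth δ18O sequences are modelled as

δ18O_m(x) = A·cos(2π·(x − x0)/X) + M

with x the distance (mm) from the enamel–root junction (ERJ), A the
half-amplitude (‰), X the period (mm of crown formed per annual cycle),
x0 the delay (the δ18O maximum sits at x = x0 mod X) and M the mean (‰).
The model assumes steady crown extension, a single annual cycle in the
drinking-water signal and no time-averaging of the drilled samples; real
enamel maturation smooths and attenuates the input signal, which the
model does not invert.

### Fitting

For a fixed period X the model is linear in the harmonic coefficients
(a, b) of a·cos(2πx/X) + b·sin(2πx/X) + M, so the fitter solves that
least-squares problem exactly on a period grid (default 16–60 mm in 2 mm
steps — spanning the plausible Caprine molar range), then refines the
best three starts jointly over (a, b, X, M) with bounded nonlinear least
squares (X ∈ [4, max(200, 4·span)] mm, tolerances 1e-15). Under this
parameterisation the phase solution is global for each candidate period,
which removes phase-aliasing local minima; multi-starting is only needed
in X. The canonical form reports A = √(a²+b²) > 0 (using
A·cosθ = −A·cos(θ+π)) and x0 reduced modulo X into [0, X). Fit quality
is the Pearson r between observed and fitted values, computed on all
samples. Degenerate (constant) sequences get r = 0 and near-zero A.

An independent check used in the tests and the acceptance script is a
dense brute-force grid over (X, x0) (177 periods × 200 phases) with an
exact linear solve for (A, M) at each grid point; the two routes agree
on simulated noisy teeth to within 0.02 cycles in x0/X and 0.5 mm in X.

### Acceptance rules

A fit is accepted iff, in order, none of the following fires:

1. **missing_ERJ** — the sequence was flagged as lacking a locatable
   enamel–root junction (an input flag; it cannot be inferred from the
   numbers).
2. **no_sinusoid** — A below an absolute floor (default 0.5‰, well
   under observed intra-tooth amplitudes but above analytical noise) or
   below 2× the residual standard deviation. This operationalises "very
   low amplitude / no sinusoidal pattern", which is listed as a
   rejection cause without a formula; both constants are configurable.
3. **no_clear_maximum** — no interior sample's fitted value lies within
   5% of the full fitted range of the fitted maximum M + A
   (configurable fraction). Monotone partial cycles from heavily worn
   crowns fail here.
4. **low_r** — r < 0.92.
5. **short_period** — X < 16.0 mm.

Thresholds are inclusive: r = 0.92 and X = 16.0 exactly are accepted
(the r rule is stated with "≥"; the period rule rejects "below 16.0",
i.e. strictly less). Fewer than four usable samples is an input error,
distinct from rejection.

### Birth season

The normalised position of the δ18O maximum, x0/X mod 1, indexes the
season of birth. For upper sheep M3s the ratio is corrected by +0.073
of a cycle (a reported upper-vs-lower M3 offset of about one month); no
correction exists for goats or for M2s, so none is applied. Reference
x0/X ranges from modern herds of known birth season are study-specific
and shipped empty — users supply them as CSV (species, tooth, jaw, lo,
hi, label); intervals may wrap past 1 → 0. An estimate matching no bin
is labelled "unassigned".

## ZooMS classification

Markers are carried exactly as printed, as average masses, and matched
within a ±0.2 Da default tolerance (typical MALDI-ToF fingerprint
precision; configurable — no tolerance is stated for the original
visual identifications). Matching is nearest-wins and one-to-one
between marker masses and observed peaks; intensities are ignored.

Decision rules:

* A COL1α2 757 variant calls Ovis or Capra; both variants matched →
  composite Ovis/Capra. The +16 oxidation pairs count as one marker
  each, matched if either mass is present.
* COL1α2 375 (1154/2028/2044) alone flags the Caprine composite only —
  it does not separate sheep from goat.
* Gazelle/deer calls count matched masses from the union
  {1182, 2056, 2072, 1532, 3227, 2216} against a requirement of 3
  (configurable), resolved by the species-specific markers (3227 →
  Gazella, 2216 → Cervus). The requirement is capped per species at the
  number of masses the reference holds for that species: the deer
  reference contains the single printed mass 2216, and a rule demanding
  more markers than the reference contains could never fire. Partial or
  conflicting evidence degrades to Gazella/Cervus.
* Nesotragus and Rupicapra share the Ovis marker set but fall outside
  the study region; they are excluded from assignable labels.

## Diet thresholds

Enamel cutoffs per taxon group (e\*: ruminants +14.1‰, cattle/cervids
+14.5‰, suids +13.95‰ — the midpoint of the reported +13.3…+14.6 range):

* derived triple: (plant_avg + Suess + e\*, plant_max + e\*,
  canopy_plant + e\*) = (−10.4, −8.7, −14.1)‰ for ruminants, from
  baselines −26.0 (modern global C3 mean, +1.5‰ Suess correction),
  −22.8 (local archaeological C3 maximum, no Suess correction needed)
  and −28.2‰ (archaeological canopy);
* as-published ruminant triple: (−10.7, −9.0, −14.5)‰.

The two disagree by 0.3–0.4‰ and the source does not explain the
difference; both are carried, the discrepancy is reported on the cutoff
object, and classification defaults to the as-published values where
they exist (ruminants) and the derived arithmetic otherwise.
Classification: δ13C ≤ canopy cutoff → canopy_C3; ≤ maximum-C3 cutoff →
pure_C3 (the basis field records whether the stricter average-based
cutoff was also cleared); above → C4_contribution. Decreasing δ13C can
never move a classification toward C4 (tested).

Collagen: expectations for a 100% C3 diet are plant_avg + 1.5 + 5 =
−19.5‰ and plant_max + 5 = −17.8‰; values above the maximum-based
expectation indicate a C4 component. Quality control accepts atomic
C:N = (%C/12.011)/(%N/14.007) in the inclusive window [3.2, 3.62]
(atomic, the field convention for the ~2.9–3.6 range; mass vs atomic is
not specified in the source and atomic is assumed). A two-endmember C4
mixing fraction is exposed as an explicitly diagnostic extra; the
decision procedure proper only classifies.

## Assemblage statistics

Shares are 100·count/denominator rounded to one decimal (matching the
reporting style); the denominator is either all counts or the
identified subset. Chi-square uniformity uses expected counts total/k.
The group-comparison flow tests normality (Shapiro–Wilk) on pooled
residuals from the group means by default — per-group testing is
available but the pooled choice matches how omnibus assumptions are
usually screened at these sample sizes — then variance homogeneity
(Levene); one-way ANOVA if both pass at α = 0.05, otherwise
Kruskal–Wallis. Groups with one value are dropped with a warning.
All-identical data return the boundary result (statistic 0, p = 1) on
the nonparametric branch. α = 0.05 throughout; no multiple-testing
correction is applied, matching the original analysis. ZooMS-derived
counts and morphological NISP are kept in separate tables and never
summed, since fingerprint counts correlate with body size in fragmented
assemblages.

## Synthetic data

The generators emulate the statistical structure of the excavated
material, not its biology:

* **Tooth sequences** — δ18O(x) = attenuation·A·cos(2π(x−x0)/X) + M +
  Gaussian noise, with x0 = birth_phase·X. Defaults are the study
  conditions: A = 2.5‰ and M = −5.5‰ (sequences spanning roughly −10 to
  −1‰), X = 30 mm, 10 samples at 3 mm spacing (~124/14 ≈ 9 samples per
  tooth in the original sampling), noise 0.3‰ (the total analytical
  uncertainty). Attenuation is a single multiplicative damping factor —
  the simplest mechanism producing the attenuated patterns seen in worn
  teeth — not a maturation convolution; no quantitative attenuation
  value is reported for worn teeth, and 0.7 is this package's
  illustrative choice where one is needed. Wear truncation removes mm
  from the occlusal (high-x) end. Crown-formation month windows
  (M2 ≈ months 1–12, M3 ≈ months 9–22 in sheep) are carried as
  documented constants; the simulator equates the truth ratio with
  birth_phase directly, which is the scale on which recovery is tested.
* **Spectra** — the taxon's full marker-mass profile with Gaussian m/z
  jitter, independent per-mass dropout, and decoy peaks uniform on
  800–3500 Da but never within 2 Da of any true marker mass.
* **Assemblages** — independent multinomial draws per horizon; the
  default taxon profile (Caprine 0.934, Bos 0.024, other 0.042) mirrors
  a Caprine-dominated assemblage.
* **Collagen series** — Gaussian δ15N per horizon mean (a monotone mean
  sequence produces the diachronic-trend scenario), Gaussian δ13C, %C
  uniform on the observed 39–44% range and %N back-computed so C:N
  always lands in the accepted window.

What passing tests show — and what they do not: parameter recovery,
classifier round trips and test calibration hold under these idealised
generating processes. Real enamel adds time-averaging and maturation
overprinting, real spectra add baseline, adducts and contaminant peaks,
and real assemblages are not multinomial across horizons; none of those
effects are simulated, so the tests validate the decision machinery,
not the field accuracy of the underlying proxies.

## Problem sizes and numerics

Monte-Carlo checks use 200 simulated teeth (fit-oracle agreement and
birth-phase recovery), 500 noisy goat spectra (classifier robustness),
and 1000 null simulations (type-I calibration of the group flow) — large
enough for stable rates at the tolerances tested while keeping the whole
suite quick on a single core. Noiseless cosine recovery is exact to
better than 1e-6 relative error; acceptance-rule boundaries are
inclusive; duplicate peaks are defined as masses within 0.01 Da; float
cutoff arithmetic is rounded to 6 decimals to keep printed thresholds
exact.

## Known limitations

* No inverse modelling of enamel maturation (attenuation is not
  deconvolved), no Bayesian/MCMC fitting, no δ13C sequence modelling
  beyond summaries.
* The marker database contains only the printed masses; taxa whose full
  fingerprints require unpublished markers (notably deer) are
  identified from their single printed diagnostic mass.
* Reference birth-season bins ship empty; season labels depend entirely
  on user-supplied modern reference data.
* Diet classification is threshold-based; it does not estimate %C4
  beyond the clearly-labelled diagnostic mixing fraction.
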