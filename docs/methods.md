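# Methods

## The selection model

An individual hare is sampled together with a botanical inventory of the
10-ha circular plot around its sampling location; the inventory's
proportions a_i describe the forage available to that animal, the
stomach content's proportions u_i describe what it ate during the
preceding activity period. Manly's alpha,

    α_i = (u_i / a_i) / Σ_j (u_j / a_j),

is the normalised use/availability ratio over the m items available to
the individual. Under a foraging process in which the probability of
taking item i is proportional to w_i · a_i (preference weight times
availability), α is exactly the maximum-likelihood-style estimator of
the normalised weights w_i / Σ w_j — which is why the synthetic
generator (below) uses that process. Chesson's electivity

    ε_i = (m·α_i − 1) / ((m − 2)·α_i + 1)

rescales α onto [−1, +1] so that individuals with different m are
comparable: ε = 0 at the neutral α = 1/m, ε = +1 iff α = 1, ε = −1 iff
α = 0 (m ≥ 2). The source literature for this index exists in several
algebraic variants; the exact form used is exported as
`EPSILON_FORMULA` and written into every run manifest so a substitution
would be visible in the output, not just in the code.

Four item schemes share the machinery. For **plant taxa**, use and
availability are the stomach's and the plot's botanical proportions over
the union of taxa. **Plant groups** pool taxa through the packaged
five-group table before the index is computed; pooling happens on the
raw vectors, and the zero-availability policy is applied at group level,
so a used taxon missing from a plot still counts toward a group that is
available through other members. For the **DM** and **FA** schemes the
five crude fractions (ash, carbohydrates, fat, fibre, protein) and seven
fatty acids (C14:0, C16:0, C16:1, C18:0, C18:1, LA, ALA) are treated as
"food items" on a simplex: use is the stomach assay renormalised to
proportions, availability is the availability-weighted mean composition
of the plot. Treating chemical components as items on the renormalised
simplex is an interpretive choice of this package (nothing in the index
itself forces a particular normalisation); it is the only choice that
puts use and availability on the same scale, and it fixes m = 5 and
m = 7 for the two chemical schemes.

## Availability and gross energy

The chemical availability of a plot is the pooled-sample mix: for DM
component c, avail_c = Σ_t a_t·dm_t(c) / Σ_t a_t·Σ_c' dm_t(c'), i.e. the
proportions obtained by mixing the taxa's mg/g profiles with the
botanical weights; FA availability is the analogous weighted mean of the
FA simplexes, renormalised. The computation is invariant to uniform
rescaling of the weights, so cover-, frequency- or biomass-flavoured
availability scores work equally as long as they are used consistently;
callers wanting biomass weighting can fold standing biomass into the
weights themselves.

Gross energy is the coefficient-weighted sum Σ_c (dm_c/1000)·k_c in
kJ/g. The default coefficients (fat 39.8, protein 23.9, carbohydrates
17.5, fibre 18.8, ash 0 kJ/g) are generic combustion values for forage
analysis and are **not** calibrated to any particular laboratory; they
are a required, overridable config entry precisely because published
analyses typically cite an external calibration that is not reproduced
here. `paired_energy_summary` is a deliberately plain descriptive
replacement for a mixed-model paired test: means, SEs and a bootstrap CI
of the mean within-hare difference, with no season/year adjustment.

## Bootstrap inference

The statistic bootstrapped is the mean ε across contributing hares (the
mean is what CI dot-plots of this kind display; a median option is not
offered). B = 1000 resamples of size n with replacement; the BCa
interval uses

* bias correction z0 = Φ⁻¹((#{boot < observed} + ½·#{boot = observed})/B)
  — ties counted half so z0 stays finite on discrete data, and the
  fraction clipped to [1/(2B), 1 − 1/(2B)];
* acceleration a = Σ d_i³ / (6 (Σ d_i²)^{3/2}) from jackknife deviations
  d_i = mean(jack) − jack_i, with a = 0 when the denominator vanishes;
* adjusted percentiles Φ(z0 + (z0 + z_α)/(1 − a(z0 + z_α))), read off
  the empirical bootstrap-mean distribution with linear interpolation
  between order statistics (numpy's default quantile rule, fixed for
  bit-reproducibility).

An all-identical sample yields the degenerate interval [v, v] with a
warning. Selection is classified by the same-sign rule: preference iff
the lower bound exceeds 0, avoidance iff the upper bound is below 0; a
bound exactly at zero carries no sign and classifies as "none".

Eligibility: an item is bootstrapped when ≥ min_n (default 7) hares
contribute. "Contributing" defaults to use > 0 — the item appears in the
hare's diet — matching the convention of reporting n as the number of
animals selecting the item; the alternative reading (every hare with the
item available) is available as `eligibility_basis: available`. The same
contributing set supplies the bootstrapped values. The eligibility rule
is applied per stratum (season, sex, age, or the unstratified "all");
combinations failing it are reported with the reason, not silently
dropped.

Reproducibility: each (scheme, item, stratum) gets its own random
substream derived from the master seed and a stable blake2b hash, so
adding or removing one item never perturbs another item's interval, and
identical config + seed reproduce byte-identical output tables.

Small-sample behaviour worth knowing: BCa percentile-type intervals for
a mean undercover at small n by O(1/n). In this package's own
Monte-Carlo checks the measured coverage for a Gaussian mean at n = 30,
B = 1000 is ≈ 0.91 (and scipy's independent BCa implementation measures
the same under identical conditions), rising to ≈ 0.95 by n = 100. At
the default min_n = 7, intervals are to be read as approximate;
significance calls near the boundary deserve scepticism.

## Zero availability and degenerate cases

Manly's alpha is undefined for an item used but absent from the plot.
Default policy `drop_renormalise`: such items are removed and use is
renormalised (logged); a hare whose entire diet is dropped is excluded
from that scheme. Alternative `floor`: availability is set to a small
`floor_value` (default 1e-6), which keeps the item but drives its ε
toward +1 — use it only to flag such cases, not to interpret the value.
A hare with m < 2 available items is excluded from that scheme (ε is
undefined at m = 1), with the reason logged.

Input hygiene: proportion vectors whose raw sum falls in [0.98, 1.02]
are renormalised (rounded field tables); anything outside that band is
rejected as a data error naming the individual. All categorical
vocabularies (seasons, sexes, age classes, groups, components) are
closed; unknown labels are rejected, never coerced. Ages must be
categorical — eye-lens masses are not accepted, because ageing is
outside this package's scope. Taxon names are matched case-insensitively
after whitespace collapsing. The two dual-membership crop species in the
plant-group table (Fagopyrum esculentum, Pisum sativum) require a
context tag (`volunteer`/`intertillage`, `crop`/`intertillage`) at
lookup; an untagged lookup is an error rather than a guess.

## The synthetic generator

`simulate_dataset` draws, per hare: availabilities from a symmetric
Dirichlet (concentration 4 per taxon — plots differ noticeably but no
taxon is routinely absent), coverage uniform on [0.6, 1.0] (so the 75%
filter removes roughly a third of animals, the order observed in
boundary-heavy field designs), and a diet of 200 multinomial bites with
p_i ∝ w_i·a_i. The default flora is a 10-taxon pool spanning four of the
five groups, with crude-composition templates in which energy-dense seed
crops are fat/protein-rich and fibre-poor while leafy forage is fibrous
and ALA-rich — the gradient the analysis is designed to detect. The
stomach assay is the use-weighted template mix perturbed by Dirichlet
noise with concentration 2500, i.e. a ~5% coefficient of variation on
major components, the order of routine proximate/chromatographic assays;
noise larger than this is not merely unrealistic, it visibly biases ε of
trace components downward (ε is concave in α, so symmetric noise in use
translates into negative bias — a caution that applies to real data
too). The emitted composition table is the noise-free template: it plays
the ground-truth role the availability step assumes, and a shared
table-level error would not average out across hares.

Presets: `neutral` (w ≡ 1; expected use equals availability, all ε
centred on 0), `fat_seeker` (w = rank of template fat content, the
energy maximiser), `taxa_selector` (w = 10 on Beta vulgaris, Medicago
sativa and Glycine max against 1 elsewhere). Default size 15 hares per
season × 4 seasons.

What passing tests on these data do **not** show about real field data:
no spatial autocorrelation between neighbouring plots, no phenology
within a season, no digestion-rate distortion of stomach proportions, no
observer error in the botanical inventory, and availability is never
exactly zero for a taxon in the pool (the zero-availability machinery is
exercised by constructed cases instead).

## Problem sizes and numerical choices

The statistical test batteries use 500 simulated neutral datasets for
null calibration (the fraction of item flags at the 95% level stays
within the Monte-Carlo allowance ≤ 10%), 200 taxa_selector datasets for
power and weight recovery (mean alpha within 0.02 of w/Σw), 2000
replicates for bootstrap coverage, and 1000 random instances against an
exact rational-arithmetic oracle for alpha. These sizes keep each
property estimable with modest Monte-Carlo error while the whole suite
runs in well under a minute per battery on one core. All randomness
flows from explicit seeds; alpha/ε identities hold to 1e-12, proportion
sums to 1e-9 after validation.

## Known limitations

* The electivity of chemical components inherits the renormalised-simplex
  interpretation; mg/g-scale alternatives would give different numbers.
* Finite stomach samples bias α away from extreme values by O(1/bites);
  with very small diets (few distinct bites) rare items drift toward
  apparent avoidance.
* BCa undercoverage at small n (above) makes borderline significance
  calls at n near 7 optimistic.
* No mixed-effects modelling, model averaging or post-hoc seasonal
  contrasts are provided; strata are analysed marginally with the same
  eligibility rule per stratum.
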