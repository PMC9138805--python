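# Methods

This note records the models, defaults and numerical choices behind
`lipidmrm`, and what the synthetic fixtures do and do not establish.

## Lipid chemistry

Neutral formulas are assembled from backbone residues plus fatty acids minus
esterification waters: glycerolipids use glycerol (C3H8O3) with 1–3 acyls,
glycerophospholipids use the glycerophospho-headgroup backbone (e.g.
glycerophosphocholine C8H20NO6P) with two acyls, lyso species the same
backbone with one acyl (equivalent to removing an acyl ketene from the
diacyl formula), and cholesteryl esters cholesterol plus one acyl.
Sphingolipids are fixed on the d18:1 sphingoid backbone and computed in
closed form on the species totals: SM(c:d) = C(c+5)H(2c−2d+13)N2O6P,
Cer(c:d) = C(c)H(2c−2d+1)NO3. Deuterium labels substitute H→D
(+1.0062768 Da each).

Masses are monoisotopic (C 12, H 1.0078250, D 2.0141018, N 14.0030740,
O 15.9949146, P 30.9737615); charged-species arithmetic uses the proton
mass ±1.00728 and neglects the electron mass (<0.0006 Da, far below the
unit-resolution reporting of triple-quadrupole panels). Printed vendor
values are unit/0.1-resolution, so comparisons in the tests use ±0.1 m/z
(±0.005 where three decimals are available). The nitrogen rule (SM
protonated ions odd, PC even) is checked on integer nominal masses — a
rounded monoisotopic mass drifts off the nominal value for large lipids
because of the hydrogen mass excess.

Two printed values are knowingly not reproduced: the TAG internal standard
Q1 prints 829.4 where TAG(15:0/18:1(d7)/15:0) [M+NH4]+ computes to 829.80
(its printed Q3 570.5 *does* match the computed 570.55), and the SM Q3
prints 184.2 where phosphocholine computes to 184.073. Both are treated as
unreconciled source-table entries and excluded from exact assertions. The
PC 38:4 value 868.607 equals the acetate-adduct mass and is computed as
[M+CH3COO]−.

## Default panel configuration

The shipped panel reproduces the published per-class library sizes (1218
entries + 12 standards; 611 positive / 619 negative). Species identities
within each class are *configuration*, not a claim about any instrument's
actual list: classes are enumerated in canonical (carbons, double bonds)
order within chemically sensible bounds (single-chain classes 14–22 C ×
0–6 DB; diacyl classes 28–44 C × 0–12 DB; TAG 42–66 C × 0–7 DB) and
truncated at the configured class size. The Cer enumeration skips the
acyl-17:0 entry because that identity is the Cer(d18:1/17:0) internal
standard; the exclusion leaves exactly the 62 published Cer entries.

TAG entries are *sn*-isomer transitions — one per (species, lost fatty
acid), the lost acid drawn from a nine-acid pool common in plasma (14:0,
16:0, 16:1, 18:0, 18:1, 18:2, 18:3, 20:4, 22:6) subject to the remaining
two chains being realizable; this yields the published 445 TAG entries with
TAG 52:6 resolving into 9 isomer transitions on one Q1. Diacyl phospholipid
entries designate one quantifier chain (an even split of the totals) for
the negative-mode carboxylate Q3; per-species composition lists (as in the
PC 38:5 example with four compositions → eight transitions) can be
configured.

Expected retention times use a class-anchored linear model: the class
internal standard's retention time anchors the class, small per-carbon and
per-double-bond offsets spread species across the class elution range, and
predictions are clipped to that range. The PC (9.09–11.59 min) and SM
(11.74–12.38 min) ranges are the known class windows; other ranges default
to ±0.5 min around the class anchor except TAG (1.8–3.4 min), where the
larger span reflects the wide neutral-lipid elution band. Voltages default
to the class standard's DP/EP/CE/CxP.

## Scheduling model

Windows: halfwidth = clamp(3·rt_sd + base_halfwidth, h_min=0.15 min,
h_max=1.0 min), centred on the mean RT and clipped to the 24-min run. The
constants are exposed policy defaults — the vendor scheduling tool's exact
formulas are unpublished, so the policy is chosen to reproduce the
qualitative behavior (wider windows for higher RT variance or broader
peaks). Weights: clamp(sqrt(median abundance / abundance), 1, 10), rounded
to two decimals; unknown abundance → 1.

Dwell allocation charges settling (5 ms) + pause (5.007 ms) once per
transition per cycle and splits the remaining part of the 0.5 s target scan
time proportionally to weight, flooring at 1 ms with deterministic
proportional redistribution (water-filling). If overhead + minimum dwells
exceed the target, every member gets the minimum dwell and the cycle runs
long, flagged over budget. Conservation (Σdwell + overhead = cycle) is
exact by construction. Positive- and negative-mode transitions cycle
independently while sharing the chromatographic clock.

Predicted points per peak = (covered base width in seconds) × (mean
sampling rate over that span), where the sampling rate is the reciprocal of
the cycle time of the instantaneous composition — i.e. the harmonic-mean
cycle time, which is the correct expectation when the cycle composition
changes across the peak. Because the simulator holds each cycle's
composition fixed for the whole cycle while the predictor uses the
instantaneous composition, agreement with simulated sample counts is within
±1 point for ~94% of transitions and within ±3 in the worst
composition-transition cases; the median agreement is well under one point.

## Acquisition simulator

Peak shapes are Gaussian with base width defined as 4σ; fixture base widths
are uniform on 0.05–0.3 min. True areas are log-uniform over five decades
above a 10³ counts·s floor — the dynamic range a plasma panel spans.
Per-transition run-to-run RT jitter SDs are uniform on 0.005–0.04 min,
consistent with the observed <5% retention CV. The baseline is a constant
30 counts/s rate.

Counts in a sample are Poisson with mean (intensity + baseline) × dwell;
the recorded signal is counts divided by dwell (counts per second), so
areas are dwell-unbiased while the per-sample noise scales as 1/√dwell —
this is deliberately how dwell weighting is allowed to matter: through
signal-to-noise, never through area bias. All cycle members are recorded at
the cycle-start time (within-cycle stagger is not modeled; at cycle ≪ peak
width it is immaterial and it keeps every sample inside its window).

Peak integration: baseline = median of the lowest quartile of samples in
the window, noise = that quartile's SD, peak region = the contiguous block
above baseline + 3·noise around the maximum, area = trapezoid of
(signal − baseline). This estimator is accurate to <1% when the window
amply covers the peak (≳5σ each side) and the peak is sampled finely
(in-peak gaps ≲σ); windows sized near the 4σ base or cycles comparable to σ
truncate tails or under-resolve the quadrature, biasing areas low by a few
percent. The acceptance checks therefore assert 1% recovery on the
adequately covered, adequately sampled stratum, which the detectability
rule (≥10 points) already approximates.

The three-mode comparison acquires the *same* ground-truth replicates under
unscheduled MRM (full-run windows), fixed-window sMRM (±0.5 min) and
variable-RTW/relative-DTW schedules, then applies the ≥10-point / <30%-CV
filter across replicates. On the default fixture the ordering
variable ≥ sMRM ≥ MRM emerges from cycle-time arithmetic alone: the
unscheduled method's ~1230-member cycles run to several seconds, starving
every peak of points. The published per-mode *area* advantage of the
weighted method is not reproduced by this noise model: with
counts-per-second normalization areas are unbiased by construction, and the
residual area differences between schedules reflect window-width
integration truncation rather than dwell benefits, which appear in S/N
(replicate area CV improves like √dwell) — the simulator demonstrates the
S/N mechanism, not the real-instrument area gains.

What passing simulator tests show: the scheduling arithmetic, the
detectability accounting and the noise model are internally consistent at
realistic scale. What they do not show: real detected-species counts (the
published 829/901/852 per-day counts come from real plasma), chromatographic
tailing, ion suppression, polarity-switching overhead, or isotopologue
(M+2) interference.

## Method validation

LoB/LoD/LoQ thresholds are mean(blank) + 1.645/3/10·SD with the sample
(n−1) SD; "signal more than the limit" is a strict inequality on the
replicate mean; the LoD/LoQ concentration is the lowest calibrator whose
mean exceeds the corresponding threshold, with an explicit
"above top calibrator" sentinel when none does. R² is ordinary least
squares of raw signal vs concentration over [LoQ concentration, top
calibrator], on replicate means by default (all-points fit available).
CV% uses within-class sum normalization per replicate, making it invariant
to per-replicate global scaling of a class.

## Differential pipeline

Preprocessing removes species missing in ≥10 samples, imputes the rest
with the species median pooled across both groups (per-group imputation is
not offered because the pooled median is what keeps imputation from
manufacturing group differences), then class-sum normalizes per sample.

Batch adjustment is the standard parametric empirical-Bayes location/scale
model: standardize per feature under a design of batch indicators plus
preserved covariates (group and sex by default), shrink per-batch
location/scale estimates across features with moment-matched normal /
inverse-gamma priors solved by fixed-point iteration (convergence 1e-4),
remove them, and restore the preserved effects. The implementation matches
the Bioconductor reference to machine precision on shared inputs (a test
runs the R reference when available). The pipeline applies it on log2
areas and exponentiates back. Confounded batch/group designs raise.

Screening: fold change is the deficient/normal ratio of group means of
normalized values (median-ratio available); candidates need |FC| beyond
1.3× and two-sided Wilcoxon rank-sum p < 0.05 (exact p for tie-free
combined n ≤ 20, normal approximation with tie correction otherwise;
all-equal species get p = 1). BH adjustment is the step-up procedure.

Boruta-style selection appends freshly shuffled shadow copies of the active
features (kept to at least five columns), fits a 100-tree random forest,
and scores a hit for each real feature whose importance beats the best
shadow. Importance defaults to the Z-score of per-tree impurity importance
(mean over trees / SD over trees); raw forest MDI is available but is
anti-conservative here — without the between-tree stability normalization,
chance in-sample associations beat the shadow maximum persistently and get
confirmed on pure-noise data far too often. Confirm/reject calls use a
two-sided binomial test on accumulated hits at α = 0.01, Bonferroni-divided
by the feature count; undecided features after 100 iterations are
tentative. The procedure is deterministic under its seed.

## Synthetic cohort generator

The default design mirrors the screening study's structure: 47 deficient
vs 46 normal samples, 759 species with per-class counts scaled from the
panel, two balanced batches, a sex covariate, ~0.5% missingness, and 18
planted effects with fold changes ≥1.5 in magnitude (TAG-heavy
up-regulation plus a few down-regulated species). Areas are log-normal:
base abundances 10^N(6, 0.8) — heavy-tailed within class but not
single-species dominated, as in real plasma class compositions — with
per-species noise σ_ln = 0.35 (area CV ≈ 36%, the lower end of reported
between-subject lipid variability, appropriate because class-sum
normalization removes variation shared within a class). Planted species
are drawn at moderate abundance (10^N(5.5, 0.3)) so their shifts leave
class totals essentially unchanged — matching the observed situation where
individual species change while classes as a whole do not — and so the
compositional normalization does not leak planted effects into null
species. Batch effects are additive (SD 0.3) and multiplicative (scale SD
0.1) on the log scale; sex effects are small per-species shifts (SD 0.05).

Under these defaults the full pipeline recovers ~97% of planted species
with at most two false confirmations per seed, and on null cohorts the
Wilcoxon p < 0.05 gate passes ~5% of species — the calibration and power
claims the end-to-end tests assert. The generator emulates marginal
structure only: no lipid co-regulation networks, no class-wide shifts, no
abundance-dependent missingness; results on it speak to statistical
calibration, not biology.

## Problem sizes used in the test suite

The acceptance-level checks run the full 1230-transition panel with five
simulated technical replicates for the mode comparison, one noiseless
full-panel run for area/points verification, and ten seeds each of the
93-sample × 759-species cohort (with Boruta on the ~20 screened
candidates) and of the null cohort. Unit tests use a down-scaled panel
(~100 transitions) and smaller matrices for speed.

## Known limitations

- Species enumerations are canonical-order placeholders; a real deployment
  would load its own species lists and per-species voltages.
- The scheduling policy constants (h_min, h_max, weight cap) are declared
  defaults, not recovered vendor values.
- The simulator does not model polarity-switching overhead, scan-speed
  effects, tailing, matrix effects, or isotopologue overlap.
- Absolute quantitation is out of scope; areas are relative.
- Double-bond-position isomers are not distinguishable by these transitions.
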