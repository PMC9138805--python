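# lipidmrm

A toolkit for building and evaluating high-throughput *scheduled* multiple
reaction monitoring (MRM) lipidomics methods on triple-quadrupole
instruments. It is aimed at mass-spectrometry method developers and
computational lipidomics researchers who want to design large targeted
panels (1000+ lipid species in a single 24-minute LC run), reason about
retention-time-window scheduling and dwell-time allocation under a fixed
cycle-time budget, and validate the resulting method statistically.

## What it does

**Transition library generation.** Monoisotopic m/z computation for 17 lipid
classes (SM, Cer, CE, MAG, DAG, TAG, PA, PC/LPC, PE/LPE, PG/LPG, PI/LPI,
PS/LPS) with the class-appropriate adducts — [M+H]⁺ for sphingolipids,
[M+NH₄]⁺ for neutral lipids, [M−H]⁻ for phospholipids and [M+CH₃COO]⁻ for
(L)PC — and class-appropriate product ions: head-group fragments
(phosphocholine 184.073, sphingoid 264.269, cholestadienyl 369.352),
fatty-acyl carboxylate anions for phospholipids, and *sn*-position-resolving
neutral-loss transitions for TAG/DAG, where Q3 is the precursor minus one
fatty acid (RCOOH) and NH₃. The shipped default panel reproduces the
published per-class accounting: 1218 species plus 12 deuterated internal
standards, 611 positive- and 619 negative-mode transitions.

**Scheduling.** Variable retention-time windows — halfwidth
`clamp(3·rt_sd + base_halfwidth, h_min, h_max)`, wider for analytes with
higher run-to-run drift or broader peaks — and relative dwell-time weights
`clamp(sqrt(median_abundance / abundance), 1, 10)`, larger for low-abundance
analytes. Per cycle, the 0.5 s target scan time minus per-transition
overhead (5 ms settling + 5.007 ms pause) is split across concurrent
transitions proportionally to weight, with a 1 ms dwell floor; when overhead
alone exceeds the budget the cycle is flagged over budget. Exact time
conservation holds: Σdwell + overhead = cycle time.

**Acquisition simulation.** A synthetic plasma-like fixture (class-clustered
retention times, Gaussian peaks 0.05–0.3 min wide, abundances spanning five
decades, run-to-run RT jitter) is acquired cycle by cycle under three
schedules — unscheduled MRM, fixed-window sMRM, and variable-RTW/relative-DTW
— with Poisson shot noise scaled by dwell time, so dwell weighting buys
signal-to-noise without biasing areas. A detectability filter (present in
all technical replicates with ≥10 points per peak and area CV < 30%)
reproduces the characteristic ordering: variable-RTW/DTW ≥ sMRM ≥ MRM.

**Method validation.** LoB/LoD/LoQ from blank statistics
(mean + 1.645/3/10 SD), LoD/LoQ concentrations read off serial-dilution
series, linearity (R²), spike recovery, and per-species CV% after
within-class sum normalization.

**Differential screening.** The two-group pipeline: missing-value filtering
(≥10 missing samples drops a species) and median imputation, class-sum
normalization, ComBat-style empirical-Bayes batch adjustment (verified
against the Bioconductor reference), two-sided Wilcoxon rank-sum + 1.3-fold
screening, Benjamini–Hochberg adjustment, and Boruta-style random-forest
feature selection with shadow probes. A seed-deterministic synthetic cohort
generator (47 vs 46 samples, 759 species, planted fold changes, batch and
sex effects) supports end-to-end power/calibration testing.

## Worked example

```python
from lipidmrm import (default_library, library_summary, parse_species, FattyAcyl,
                      precursor_mz, product_mz_neutral_loss_fa, allocate_dwell,
                      CycleBudget, compare_modes)

lib = default_library()
s = library_summary(lib)
print(f"library: {s['n_species']} species + {s['n_standards']} standards "
      f"= {s['n_transitions']} transitions "
      f"({s['per_mode']['positive']} positive / {s['per_mode']['negative']} negative)")

species = parse_species("TAG 52:6")
print(f"TAG 52:6 [M+NH4]+  Q1 = {precursor_mz(species):.2f}")
for fa in (FattyAcyl(16, 0), FattyAcyl(18, 1), FattyAcyl(22, 6)):
    print(f"  loss of FA {fa}: Q3 = {product_mz_neutral_loss_fa(species, fa):.2f}")

dwell, cycle, over = allocate_dwell([1, 1, 2], CycleBudget())
print(f"dwell for weights (1,1,2): {dwell.round(2)} ms, cycle {cycle:.0f} ms")

report = compare_modes(lib, n_replicates=5, seed=1)
print("detected species (5 replicates, >=10 points, CV<30%):",
      report.detected_counts)
```

prints

```
library: 1218 species + 12 standards = 1230 transitions (611 positive / 619 negative)
TAG 52:6 [M+NH4]+  Q1 = 868.74
  loss of FA 16:0: Q3 = 595.47
  loss of FA 18:1: Q3 = 569.46
  loss of FA 22:6: Q3 = 523.47
dwell for weights (1,1,2): [117.49 117.49 234.99] ms, cycle 500 ms
detected species (5 replicates, >=10 points, CV<30%): {'mrm': 0, 'smrm': 269, 'advanced': 470}
```

Reading the numbers: TAG 52:6 keeps one precursor (Q1 868.74, the ammonium
adduct) while each *sn*-position isomer gets its own diagnostic product ion —
losing palmitate (16:0) leaves 595.47, losing oleate (18:1) leaves 569.46,
and so on, which is what lets the method count TAG isomers in one run. The
dwell split shows the weight-2 member receiving twice the dwell of its
weight-1 partners with the 0.5 s cycle budget conserved exactly. In the
three-mode comparison, the unscheduled method's cycle time balloons to
several seconds (too few points across each peak to pass the ≥10-point
filter), fixed windows recover a few hundred species, and the variable-
window/weighted schedule recovers the most — the ordering the scheduled
approach is designed to produce.

A CLI mirrors the library: `lipidmrm build-library`, `schedule`, `simulate`,
`validate`, `diff` (see `lipidmrm --help`).

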