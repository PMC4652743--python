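# Methods

`emulsim` couples a ground-truth generator for droplet single-cell cultures
with the quantitation machinery used to analyse them: limiting-dilution
digital PCR fitting, Hartigan's dip test of unimodality, GAPDH-gated
per-cell normalisation, and fold-change calls with Mann-Whitney
significance. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what a passing test does and does not
establish.

## The simulated world

### Encapsulation

Cells are loaded into `n_droplets` droplets of volume `droplet_volume_nl`
(default 5.9 nl) with i.i.d. Poisson occupancy at `mean_cells_per_droplet`
(default 0.1, the statistically dilute regime that keeps co-encapsulation
rare: ~4.8% of occupied droplets hold ≥2 cells). Empty droplets are kept —
they matter for gating. One cell in a droplet of volume *V* nl experiences
an effective culture concentration of `1e6/V` cells/ml (~170,000 cells/ml at
5.9 nl), independent of how dilute the cell suspension was.

### Colony growth

Each cell divides when its generation time elapses; generation times are
normal with mean `doubling_time_h` (default 20 h, a lymphoblast rate giving
2–4 divisions by days 2–3) and coefficient of variation `division_cv`
(default 0.1, which reproduces the synchronous 1/2/4/8-cell colony-size
peaks). The droplet supports `capacity_cells_per_nl x volume` cells
(default 2.5 cells/nl ≈ 14 cells at 5.9 nl, ≈ 8 at 3.4 nl); a colony at
capacity stops dividing, and from the next day is non-viable and loses 40%
of its cells per day — the nutrient-exhaustion collapse seen in small
droplets.

### Transcription

hTERT expression is bursty and variant-exclusive. Each cell carries one
dominant splice variant, drawn for founders in proportion to the configured
burst rates and inherited at division. A cell is either burst-on or off:
founders start on with probability `1 − exp(−R)` (R = summed burst rates,
default 0.24 → ~21% of single cells, under the 25% ceiling), off cells
ignite at the same rate each day, and the state persists for the short
culture window and is inherited. This slow-off telegraph is what sustains
abundance bimodality through division: colonies are essentially all-on or
all-off, and the on-fraction grows towards a balanced mixture by day 2.

Burst output is negative-binomial with mean `burst_size_mean` (70
molecules) and shape `burst_size_shape` (10; tight enough that the high
mode survives the readout noise). Off-state variants leak Poisson baseline
transcription, `baseline_mean` (0.6) molecules per cell in total, split
across variants in proportion to their burst rates — so leakage does not
break single-variant dominance, yet non-bursting colonies remain
low-but-positive (the low mode of the bimodal histograms). The default
rates {a+/b+: 0.01, a−/b+: 0.01, a+/b−: 0.20, a−/b−: 0.02} pin the expected
per-cell copy numbers at ≈ 0.7 / 0.7 / 12.5 / 1.4, matching the
dilution-series estimates.

hTR and GAPDH are high-copy and independent of hTERT: per-cell Poisson
counts around a lognormal cell-to-cell mean (hTR 2000 ± CV 0.5, GAPDH 1000
± CV 0.3). Per-cell hTR therefore converges to the population mean as
colonies grow (variance ∝ 1/cells), while hTERT bimodality persists.

### Curcumin

Sub-lethal exposure is modelled as three effects from `onset_day`
(default 2): both α− variants switch to constitutive expression in every
cell at `alpha_minus_fold` (default 300) times their pre-onset per-cell
mean; division desynchronises (`division_cv_multiplier` 3); and growth rate
scales by `growth_rate_multiplier` (default 1.0 — the sub-lethal dose does
not change growth significantly). Constitutive induction (rather than
scaling burst sizes) is deliberate: it reproduces both the >100-fold rise
in mean α− abundance and the disappearance of the low-abundance population
(loss of bimodality); scaling bursts alone would sharpen bimodality
instead. The measured day-1→day-2 fold change tracks `alpha_minus_fold` by
construction of the anchor.

The ~3-fold GAPDH drift reported between days is *not* emulated: any
rank-shifting 3-fold drift at the simulated sample sizes would be
Mann-Whitney significant at P ≤ 0.01, contradicting the required
non-significant GAPDH call; in this world GAPDH is stable and its
non-significance comes from the fold-change rule.

### Readout

Each molecule is reverse-transcribed and detected with probability
`detection_prob` (0.5); a target is positive iff ≥1 molecule is detected.
Detected molecules yield a peak of area `detected x area_per_molecule`
(100) with unit-mean lognormal noise (`area_noise_cv` 0.3). Peaks are
emitted in the CE export format (sample, dye, size, height, area) plus one
ROX size-standard row per sample; amplicon sizes are synthetic defaults
(the real sizes were never published) with the β deletion 182 bp and the α
deletion 36 bp shorter than full length, tolerance ±1 bp.

What the generator does **not** emulate: PCR efficiency curves and
amplification competition, cross-run CE normalisation, droplet volume
variation, mRNA degradation dynamics (bimodality is produced purely by the
burst mechanism), and the GAPDH day drift. A green end-to-end test
establishes that the analysis pipeline recovers the patterns this stated
world produces, not that the world is complete.

## Quantitation machinery

### Limiting-dilution fitting

Positive-reaction frequencies follow the Poisson zero class
`p(d) = 1 − exp(−λd)`. `fit_lambda` minimises the unweighted squared error
over λ ≥ 0 by bounded scalar minimisation (`xatol` 1e-10; upper bracket
50/min(d), past which the model saturates in double precision); a weighted
option (1/SE²) exists but is off by default. All-zero series return λ=0;
fully positive series are flagged as lower bounds (λ=∞). The Poisson error
of a frequency is `sqrt(k)/n` with a one-count floor `1/n` at k=0.
Goodness of fit is a parametric bootstrap: resimulate binomial counts at
the fitted λ, refit, and compare residual sums of squares. The default
ladder is nine 2-fold dilutions (1…1/256) with 18 reactions per point; at
the three published abundance regimes (12.5, 1.4, 0.16 copies/cell) the
mean estimate is within a few percent of truth.

### Dip statistic

The dip is the minimal sup-norm distance between the empirical CDF and any
unimodal CDF (convex left of the mode, concave right, an atom permitted at
the mode — without the atom, tied samples are handled wrongly). It is
computed exactly by bisection on the band halfwidth: at halfwidth `d` the
ecdf constrains a candidate CDF to per-value tolerance bands, and a
unimodal candidate exists iff for some mode placement a nondecreasing
convex function threads the left bands and a concave one the right bands,
joined monotonically. Feasibility is decided in O(m²) by a forward dynamic
program propagating the minimal attainable value and sharpest slope lower
bound of any convex in-band function (mirrored for the concave side); the
monotone join across the mode is checked explicitly — it genuinely binds
on well-separated bimodal samples. Numba accelerates the inner loops when
available; a pure-Python fallback keeps results identical. Tolerances are
scale-relative (1e-12·n), and the bisection brackets to 1e-13·n, so values
are accurate to ~1e-12; sub-1e-3 spacing between distinct sample values is
numerically ill-conditioned for any method and is avoided in the oracle
comparisons. The implementation was validated against an exhaustive
LP formulation (every mode placement solved as a linear program) and
reproduces the published uniform-null quantile table at n=100 (95th
percentile ≈ 0.043).

P-values bootstrap from Uniform(0,1), the least-favourable unimodal null:
`p = (1 + #{D_b ≥ D})/(B + 1)`, B default 2000. A precomputed null can be
shared across many tests of equal n — equivalent in distribution and much
cheaper for calibration studies. Dip inputs in the pipeline are per-cell
normalised abundances on the linear scale, **excluding zero-abundance
colonies**: the atom at zero plus the single-molecule detection quantum
(~100 area units) would otherwise register as a second mode even for
burst-free data.

### Colony statistics

Only samples with a GAPDH peak count as successful live-cell assays; areas
are then divided by the microscopy cell count. Fold change between days is
the ratio of arithmetic means of normalised areas (the quantity plotted in
the source analyses; a geometric option was considered and rejected as it
discards zeros). Significance requires both Mann-Whitney P ≤ 0.01
(exact enumeration when the pooled sample is ≤20 without ties, else the
tie-corrected normal approximation) and fold change >2 or <0.5; a zero
day-1 mean leaves the fold change undefined and uncalled. Growth rates are
`ln(cells_final/cells_0)/days` per colony, compared between conditions by
Welch's t-test (unequal variances assumed; identical degenerate groups
return p=1). Cross-target correlation is the squared Pearson coefficient,
with `nan` as the undefined sentinel for zero-variance input.

## Determinism

All stochastic operations consume a `numpy.random.Generator`; a run derives
per-stage streams from the single master seed via seed sequences, so every
output (including the report bundle) is byte-identical across reruns, and
the config hash in file names excludes only the output location.
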