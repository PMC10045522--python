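# Methods

## Germination indices

A replicate is a dish of `S` sown seeds scored at strictly increasing times
`t_i` (days; day 1 = first scoring, so irregular monitoring is supported),
yielding newly germinated counts `n_i`. Definitions are in the README table.
Conventions that are genuinely open and the choices made here:

* **Censoring.** Seeds not germinated by the end of the test enter G and PV
  (through the sown total) but are excluded from MGT, MGR, CVG, U and Z,
  which are statistics of the germinated fraction only. This is the standard
  right-censoring convention for these indices.
* **Peak value** uses the *cumulative* germinated count divided by elapsed
  time, maximized over observation days. This bounds PV by the number of
  seeds per replicate, which is the magnitude such tables report.
* **Degenerate cases.** With no germination, MGT/MGR/CVG are reported as a
  not-defined marker (`None` in code, `n.d.` in tables), while U = 0 (N ≤ 1)
  and Z = 0 (N < 2); a fully synchronous replicate has U = 0 and Z = 1.
  Reporting 0 rather than n.d. for U and Z keeps the summary of an all-zero
  treatment numeric (0 ± 0).
* **Entropy base.** U is Shannon entropy in bits (log₂), the convention of
  the germination-measurement literature; the base is an argument.
* **Summaries.** Indices are computed per replicate, then averaged. The
  printed treatment-level MGR therefore need not equal the reciprocal of the
  printed MGT — each replicate satisfies MGR·MGT = 1 and CVG = 100·MGR
  exactly, but the mean of reciprocals is not the reciprocal of the mean.
  Dispersion is the sample SD (n−1) by default; SEM is available via
  `dispersion="sem"`. Comparisons against the control use a two-sided
  equal-variance Student t-test at α = 0.05.

## ROS assays

**DCF fluorimetry.** Readings are single-cycle fluorimeter outputs (RFU).
The dye-only negative control's fluorescence is subtracted from every
reading of the batch; negative nets are preserved and flagged, not clipped,
because they diagnose blank drift. No kinetic slope fitting is attempted.

**FOX-1.** The calibration is an ordinary least-squares line of A560 on
standard H₂O₂ concentration (0, 1.25, 2.50, 5 µM), intercept free: the 0 µM
standard is a measured reagent blank with nonzero colour, and forcing the
line through the origin would bias every inverse prediction. A fit with
R² < 0.98 logs a warning but is returned. Inverse prediction is
`c = (A560 − b)/m`; negative predictions are clipped to 0 µM with a flag
(concentrations cannot be negative, and keeping the row valid preserves the
downstream ANOVA design), and predictions outside the standards' range are
flagged extrapolated. The analysis unit is the per-seed measurement (five
single-seed replicates per sample).

## qPCR (X0 method)

Ct values are linearised before any averaging: `X0 = (1+E)^(−Ct)`, defined
up to an arbitrary multiplicative constant that cancels in all relative
quantities. Efficiency defaults to 1 (perfect doubling) and can be set per
gene. Technical replicates are averaged on the Ct scale before conversion
(geometric averaging on the X0 scale; the arithmetic-X0 alternative is
available via `tech_average="x0"`). Targets are normalized by the geometric
mean of the reference-gene X0 values — the standard multi-reference
practice — and treatment means are divided by the control mean, so the
control's relative expression is 1 by construction. Undetermined Ct wells
are dropped with a logged warning, never imputed.

## Statistical layer

* **ANOVA.** Two-way fixed-effects OLS with interaction when every cell has
  replication, dropping to additive when cells lack replication; empty cells
  raise a degenerate-design error. Type-II sums of squares.
* **Tukey–Kramer.** Pairwise comparisons on group means using the pooled
  within-group variance and the studentized-range distribution with the
  Kramer unequal-n correction `SE = sqrt(MSE/2 · (1/nᵢ + 1/nⱼ))`; this is
  the only familywise correction applied. The compact letter display uses
  the insert-and-absorb procedure: start from one letter set holding all
  groups, split every set containing both members of each significant pair,
  absorb subsets, and assign letters with groups ordered by descending mean
  (ties by label). The display satisfies the biconditional "two groups share
  a letter iff their comparison is non-significant".
* **Pearson.** Pairwise-complete observations, p-values from the t-transform
  of r with n−2 df, reported raw (no multiplicity adjustment). Zero-variance
  columns yield NaN correlations with a logged warning.
* **PCA.** Features are z-scored per column (correlation-matrix PCA — the
  inputs mix %, days, µM and RFU), rows with missing cells dropped listwise,
  constant columns removed with a warning, then SVD. Sign convention: the
  largest-magnitude loading of each component is positive, making reruns
  deterministic. Explained-variance fractions are non-increasing and sum
  to 1.

## Synthetic-data generator

The generator is phenomenological, not mechanistic: it emulates the
*statistical* structure of the measurements, not ROS chemistry or priming
physiology.

* **Germination.** Each seed independently germinates with probability
  `p_germ`; germinating seeds draw a latent continuous day from a gamma
  distribution (unimodal, positive support) with mean `mgt_true` and SD
  `dispersion`, rounded to the nearest monitoring day (floor day 1). Latent
  days past the monitoring window are silently censored, exactly as an
  unobserved seed in a real test. `expected_mgt()` gives the analytic mean
  of the discretized, window-truncated day distribution — the
  censoring-adjusted truth that pipeline MGT estimates converge to.
  `dispersion = 0` is the synchronous point-mass limit (Z = 1).
* **Assays.** Standards follow the true calibration line (slope 0.10 AU/µM,
  intercept 0.05 AU, measurement noise SD 0.005 AU); per-seed true [ROOH]
  and net RFU are lognormal around treatment means with CV 0.10, so signals
  stay positive and variability scales with the mean.
* **qPCR.** A true fold F shifts the target Ct by `−log₍₁₊E₎(F)` cycles from
  the control baseline (26 cycles; references at 21); references wobble per
  sample with SD 0.10 cycles, biological samples with SD 0.15, and every
  well gets technical noise of SD 0.10 across triplicate reactions.
* **Study-condition defaults.** 20 seeds × 3 replicates; daily monitoring
  for 3 days (soybean), 5 (wheat), 6 (tomato). The `paper_like` templates
  encode the qualitative design: HS germinates not at all and carries the
  highest ROS; HP treatments germinate faster and more synchronously than
  CTRL and carry the lowest ROS; ROS-turnover genes are upregulated at
  imbibition and after dry-back (catalases strongest, Rboh genes mildest,
  with MnSOD not yet up at imbibition and APX2 back down after dry-back).
  ROS and expression effect sizes are order-of-magnitude placeholders chosen
  once to reproduce those orderings; they are not measured values.
* **Determinism.** All randomness flows through one seeded
  `numpy.random.Generator` per scenario; a fixed seed reproduces output
  files byte-for-byte.

Because the generator shares none of real data's nuisance structure —
plate effects, between-lot heterogeneity, non-gamma germination-day shapes,
DCF photo-oxidation drift — passing recovery tests demonstrates the
pipeline's numerics and its statistical calibration under the assumed model,
not the assays' field performance.

## Pipeline

Stages (germination → ROS → qPCR → join → statistics) are independently
runnable; the replicate-level feature table is the only cross-stage
contract. Assay and qPCR sample ids are `<treatment>_<k>`, and the trailing
integer joins them to germination replicates. Outputs are plain CSV plus a
JSON manifest (config, package version, SHA-256 digests of inputs); reruns
with identical inputs are byte-identical. Plots are deliberately not
emitted — tables are the source of record.

## Problem sizes used in validation

The test suite exercises: 1000 random time courses against brute-force pair
enumeration and direct entropy summation; 200 seeded calibration fits at
noise SD 0.005 AU; 200 seeded qPCR recoveries at technical SD 0.2 cycles;
1000 null two-way layouts (3×2, 3 per cell) for the interaction p-value
uniformity check; 1000 replicate dishes for MGT recovery; and 200 seeded
assay runs for the group-ordering check.

## Known limitations

* Amplification efficiencies default to 1; with real dilution-series
  estimates they should be set per gene.
* The second ANOVA factor is a generic interface (any column can serve);
  the pipeline's default lettering factor is treatment.
* The FOX-1 calibration is assumed linear over 0–5 µM; curvature at higher
  concentrations is out of range and only flagged via extrapolation.
* Seedling biometry is ingested only as numbers; no image analysis.
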