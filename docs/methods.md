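# Methods

## Scope and measurement model

The package starts at integrated transition peak areas (the boundary where
acquisition software hands off) and ends at publication-shaped comparison
tables. It models a single-surrogate-peptide QTAP design: one proteotypic
peptide per target protein, 3–4 MRM transitions per peptide, each acquired
in a light (endogenous) and heavy (stable-isotope-labelled internal
standard) channel.

Per transition, the quantitative value is
`(light area / heavy area) · spike_fmol / load_μg` in fmol/μg total
protein; protein expression is the *arithmetic* mean of the per-transition
values (no intensity weighting — the averaging rule this implements is an
unweighted average). A transition contributes only when **both** channels
are detected: the isotope ratio is undefined otherwise. What "detected"
means is left to the upstream integration step; the simulator realizes it
as a hard area floor.

Quantification status per (sample, peptide):

- `quantified` — 3 or 4 contributing transitions; expression is their mean;
- `ULQ` — 2 or fewer; the cell carries the protein's LLOQ bound and is
  excluded from all downstream statistics.

The LLOQ of a protein is the lowest level of a labelled-peptide dilution
series yielding 3–4 detected transitions; a non-monotone series (a
qualifying level below a failing one) warns but still returns the lowest
qualifying level, since the rule is defined on the lowest concentration.
LLOQ bounds are configured per protein and used only for rendering ULQ
sentinels (`<0.15 (ULQ)`).

Multi-peptide protein inference is deliberately out of scope; a
peptide-to-protein map that is not 1:1 is rejected as a configuration
error.

## Statistical layer

**t-tests.** The group comparison is the unpaired two-sided Student's
t-test with pooled variance. The pooled form (not Welch) is the default
because recomputing the published table p-values from their printed
`(mean, SD, n)` summaries reproduces the printed values under pooling
(e.g. 0.008 for LAT1, 0.009 → "0.01" for ASCT1) while Welch degrees of
freedom do not. The raw-data and summary-statistic forms share one code
path, so their equivalence is exact by construction; tests cross-check both
against `scipy.stats.ttest_ind`. No multiple-testing correction is applied
across proteins, matching the analysis the tables report.

**Outlier screen.** The original analysis names a proprietary
robust-outlier routine (ROUT) without parameters. We implement a documented
univariate variant: location = median; scale = the 68.27th percentile of
absolute residuals (the robust analogue of one SD) with an `n/(n−1)`
small-sample correction; each point's t-ratio `|residual|/RSDR` is
converted to a two-sided p on `n−1` df, points are ranked from most extreme
inward, and the largest prefix passing the Benjamini–Hochberg condition
`p(k) ≤ Q·k/n` is flagged. Default Q = 1%; `Q = 0` flags nothing. On clean
normal data at n = 6 the false-flag rate measures well under 5% of
datasets. Removed sample ids are recorded in every test result and in the
run manifest. Whether the published p-values were computed before or after
outlier removal is not stated in the source analysis; the pipeline makes
the choice explicit (`rout_q`, default 0.01, `None` disables).

**Normality.** Shapiro–Wilk with pass ⇔ p ≥ 0.05; constant input returns a
degenerate-input marker rather than a verdict.

**Power and sample size.** Exact noncentral-t power for the two-sided
two-sample design: `λ = |δ| / (s_p √(2/n))` with `s_p = √((s₁²+s₂²)/2)`,
df = 2n−2, `power = P(|T′(df, λ)| > t_crit)`. The minimum per-group n is
found by incrementing from 2. Pooling the two SDs this way reproduces the
study's documented design choice of 6 observations per group from the
anchoring effect size (0.12 ± 0.040 vs 0.37 ± 0.18 fmol/μg, α = 0.05,
power 0.80). An independent Monte-Carlo simulation of the test
(`simulated_power`) agrees with the analytic power to < 0.01 at 10⁵
replicates and serves as the cross-check route.

**Fold ratios** are treatment/control on group means of quantified cells,
carried at full precision and rounded to 2 significant figures only at the
report layer. A zero control mean yields an undefined-ratio marker (NaN).

## Reporting layer

Comparison rows render `mean ± SD` per group, the ratio, p at 2 significant
figures, and `<bound (ULQ)` sentinels; ratio and p are suppressed whenever
either group has no quantified cells. Machine-readable JSON retains
unrounded values, and a written matrix re-reads to identical flags and
values.

**Purity assessment.** Microvessel enrichment is the ratio of the luminal
endothelial marker's microvessel mean to its whole-tissue mean; when the
tissue side is ULQ the ratio against the ULQ bound is reported as a lower
bound (e.g. 2.7 fmol/μg vs < 0.03 → ≥ 90-fold enrichment). The abluminal
plasma-membrane marker is compared between study groups (pooled t) to
check that membrane-fraction recovery does not differ.

**Cross-model comparison.** Between-model expression ratios are computed
separately for the disease groups and the control groups; a side is flagged
beyond a fold threshold (default 2, the dashed-line convention of
between-model scatter displays). Both sides flagged in the same direction →
interspecies difference (or age-dependent when the compared control groups
differ in age — that category requires explicit age metadata and is
otherwise unreachable); disease side flagged without the control side, or
directions opposed → model-specific; any side without a ratio (ULQ/NQ) →
not-comparable. The classification is invariant under swapping the two
models.

## Companion assays

**Amino acids.** `level = (analyte area / IS area) / normalizer`, with the
normalizer made explicit (mg wet tissue for brain, μL for plasma) so the
ratio's units are auditable. Percent-of-control sets the control-group mean
to 100 per analyte. Between-group percent change defaults to the ratio of
group means (the alternative, mean of per-sample ratios, is available);
which of the two the original analysis used is not stated. The
method-acceptance gate is RSD ≤ 15% (inclusive) on ≥ 3 QC replicates.
Enantiomers are not distinguished; analytes are single named species.

**qPCR.** Efficiency-corrected ΔΔCt:
`ΔCt = Ct_target − Ct_housekeeping`, `ΔΔCt = ΔCt − mean ΔCt(calibrator)`,
`fold = E^(−ΔΔCt)` with per-gene efficiency E ∈ (1, 2] defaulting to 2.0 —
exactly the classic `2^(−ΔΔCt)` at the default, since the normalization
method behind the published figures is cited only indirectly. Group tests
run on linear folds (matching mean ± SD bar displays), with a log2 option.
Folds are invariant to any per-sample global Ct shift.

## Synthetic-data generator

The generator emulates the measurement structure, not the instrument:

- **Noise.** Areas are positive and right-skewed, so both layers are
  multiplicative log-normal with unit mean; a CV maps to the log-scale
  sigma via `σ² = ln(1 + CV²)`. Biological variation is one draw per
  (sample, protein) — default CV 0.3; technical variation one draw per
  transition and channel — default CV 0.1. The source tables report only
  total SDs (typically 30–60% CV at n = 6), not a variance decomposition;
  the split is a free parameter documented in `SimConfig`, with defaults
  chosen so that simulated group SDs land on the published scale.
- **Detection.** A hard area floor applied independently per transition
  reproduces the "only two or one transition(s)" failure mode; with the
  default load (50 μg), response factor and transition fractions the
  implied noiseless LLOQ is 0.01–0.1 fmol/μg, the range of the published
  per-protein bounds (0.015–0.15).
- **Scale.** True abundances default to the published per-group means
  (≈ 0.02–50 fmol/μg) via `refdata.sim_config_from_published`; spike
  10 fmol and load 50 μg per digest.
- **Designs.** n = 6/6 for microvessels, 14/12 for cortex, 9/9 amino-acid
  panels with percent effects of 13–39%, qPCR panels of 6 control / 7
  disease samples with Ct noise SD 0.2 cycles and inductions of 2.5–4×.

What passing tests on synthetic data do **not** show: robustness to
chromatographic interference, retention-time drift, between-batch effects,
non-log-normal heavy-tailed contamination, or correlated transition noise —
none of which the generator models. The noiseless round-trip (generate →
quantify recovers truth to 1e-12 relative error) validates the arithmetic,
and the noisy Monte-Carlo checks validate operating characteristics
(ratio recovery, type-I error ≈ 5%) under the stated noise model only.

## Numerical choices and problem sizes

- Determinism: every generator takes a seed; equal (seed, config) yields
  byte-identical CSV output, and the pipeline bundle is byte-identical
  across repeated runs (the manifest contains no timestamps).
- Degenerate inputs: identical groups give t = 0, p = 1; zero pooled SD
  with unequal means gives p = 0; a detected pair with zero heavy area is a
  data-integrity error (missing internal standard), not a silent infinity.
- Monte-Carlo problem sizes were chosen to keep the default suite fast
  while leaving comfortable margins: 200 replicate studies for effect
  recovery, 1000 for type-I error, 10⁵ simulated tests for the power
  cross-check, 200–500 replicates for the companion-assay recoveries.
- Ties in the outlier screen are broken by original index (stable sort);
  `q = 0` short-circuits to no flags.

## Known limitations

- Single peptide per protein; no protein-level inference from multiple
  peptides.
- The outlier screen is a documented stand-in for an undocumented
  proprietary routine; flags can differ from that routine's output in edge
  cases.
- Printed summary tables round to 2 significant figures; a few published
  ratio cells were evidently computed from unrounded means and differ in
  the last digit from ratios of the printed means — recomputation can only
  match the self-consistent rows.
- The amino-acid stage is relative quantification only; no calibration
  curves, hence no absolute concentrations.
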