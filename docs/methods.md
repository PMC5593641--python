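# Methods

This note documents the statistical models implemented in `celldx`, the
defaults they ship with, the synthetic data they are validated on, and the
design decisions taken where more than one reasonable choice existed.

## Data model

The unit of observation is one imaged cell nucleus. A cell table carries
identity columns (`cell_id`, `patient_id`, `phase`, `frame_id`), the tissue
compartment of the imaging frame (`E` pure epithelium, `E+s` epithelium with
a minor stromal border, `ES` mixed, `S` pure stroma, `NA` for cultured
cells), tissue-level labels inherited by every cell of a specimen
(`path_category` ∈ {B, ASAP, AC, LAC, StageII, StageIII, unknown};
`gleason_group` ∈ {B, G33, G34, G43, unknown}), and one nonnegative
fluorescence intensity per marker on a 12-bit scale (0–4095). Tables are CSV
with a JSON provenance sidecar; CSV parsing must keep the literal token
`NA` (cultured cells have no compartment), so default NA-handling is
disabled on read.

Cell-level truth is inherited from tissue: cells from benign tissue are
"normal", all others "aberrant". This is the central supervision assumption
of the whole approach — individual cell states are unobservable, and every
accuracy figure must be read conditional on it.

**Log transform.** Channel intensities are strongly right-skewed; every
stage operates on natural-log intensities, ln(max(v, floor)). Zero and
sub-floor intensities are clamped to a configurable positive floor (default
1 intensity unit) rather than dropped, because the aggregation stage reports
cell counts and dropping cells would silently change denominators. Clamped
cells are flagged. How the original pipeline handled zero or saturated
intensities is not documented anywhere we could follow, so this is a package
decision.

## Synthetic cohorts

No raw per-cell intensities from the motivating study are deposited, so the
generator is a first-class module, and everything the test suite and the
acceptance script claim is a claim about cohorts drawn from it.

Within each (pathological class × compartment) stratum, log intensities are
multivariate normal — i.e. intensities are log-normal, matching the observed
skew — with:

* baseline (benign epithelium) log-means `(6.8, 5.5, 6.2, 5.9)` for
  (DAPI, AMACR, 5mC, 5hmC), i.e. geometric means ≈ 900/245/490/365 on the
  12-bit scale; per-channel log-SD 0.5 with pairwise correlation 0.3;
* a cancer effect vector in log units, Panel I `(+0.35, +0.5, −0.8, −0.6)`:
  DNA content and AMACR rise, both epigenetic cytosine modifications fall;
  Panel II `(+0.35, −0.5, +0.6, −0.6, +0.7)` for
  (DAPI, SAFB, H3K9me3, H3K27me3, nAR);
* a severity multiplier per class (B 0, ASAP 0.3, AC 1.0, LAC 1.3,
  StageII 1.5, StageIII 1.8) and a compartment attenuation (E 1.0, E+s 0.7,
  ES 0.35, S 0.0) — in pure stroma the class effect vanishes, reflecting the
  absence of marker covariation with disease in that compartment.

Only the effect *directions* are empirically grounded; the magnitudes,
variances and correlations are package defaults chosen once to give a
realistic, imperfectly separable problem (epithelial two-class AUC ≈ 0.95 at
the default scale). Cohorts are organised as patients × phases × cells with
deterministic largest-remainder allocation of cells to strata; default sizes
(5 patients × 2 phases × 2,000 cells) deliberately scale the ~139,000-cell
study design down to desk scale, with the epithelial share (13%) and the
benign share of epithelium (21%) mirroring the study proportions. Values
above 4095 are clipped to the ceiling and flagged. Fixed seeds give
byte-identical tables.

What the generator does **not** emulate: within-patient clustering beyond
the class/compartment strata, spatial structure, frame-level batch effects,
segmentation errors, and any marginal/multivariate effect discordance (e.g.
a marker whose marginal direction flips sign in the joint model). Passing
tests therefore demonstrate correctness of the machinery and calibration
under the stated generative assumptions, not clinical performance.

A second generator (`generate_logistic_table`) draws predictors multivariate
normal directly on the log scale and the outcome Bernoulli under an exact
logistic law. It exists for parameter-recovery calibration, where the
generating model must be exactly the fitted model; generating raw
intensities and re-logging would add ceiling-clipping distortion that the
recovery statement does not account for.

## PCA exploration

Components are eigenvectors of the sample correlation matrix by default
(covariance optional); with ≤ 5 markers a direct symmetric
eigendecomposition is exact and cheap. Standardization is the default
because channels sit on different intensity scales. Signs are fixed by
making the largest-magnitude loading of each component positive, and
eigenvalue ties keep the stable marker order, so results are deterministic.
Stratified reports fit one PCA per compartment / pathological category /
Gleason group (strata under 3 cells are skipped with a warning) and export a
tidy PC1/PC2 scatter table.

## Logistic stage

Maximum likelihood by IRLS (Newton–Raphson), intercept initialised at the
empirical logit. Convergence when the maximum absolute score is < 1e-8 or
the relative log-likelihood change is < 1e-10; `cov_beta` is the inverse
observed information at the optimum. Quasi-complete separation is detected
(coefficient norm exceeding 100 on the log-odds scale, or a singular
information matrix) and raised as an explicit error — no ridge fallback —
because silently penalised estimates would not be comparable to
conventional ML coefficient tables. Cluster-robust standard errors are *not*
computed: cells within a patient are treated as independent, mirroring the
convention of the reports this package reproduces; SEs should be read as
conditional on that caveat.

Reporting uses the delta method: OR = exp(β), SE(OR) = OR·SE(β),
z = β/SE(β), CI = exp(β ± 1.959964·SE(β)) with the exact normal 97.5th
percentile so that printed intervals reconstruct to full precision. The
reporter accepts printed (OR, SE) pairs and inverts the same identities,
which is how published tables are checked: re-derived z agrees with printed
z to one unit in the second decimal (the printed inputs are themselves
rounded to 7 significant digits, so exact half-unit agreement is not
attainable in general), and CI bounds to ~1e-5 relative.

The cutoff scan evaluates sensitivity, specificity and percent correctly
classified ((TP+TN)/N) at cutoffs 0.00–1.00 in steps of 0.05 (21 rows;
"aberrant" when probability ≥ cutoff, making sensitivity nonincreasing and
specificity nondecreasing in the cutoff). The generic selector maximises
the Youden index (ties → smallest cutoff); 0.75 (epithelial-only) and 0.9
(all-cells) ship as named presets for the two model variants. AUC is the
rank-based Mann–Whitney statistic with average ranks (ties count ½), and is
banded qualitatively: 0.5 none, (0.7, 0.8] acceptable, (0.8, 0.9] excellent,
(0.9, 1] outstanding. The published rules leave (0.5, 0.7] undefined; the
package labels it "poor" and [0, 0.5) "worse-than-chance" as documented
extensions.

## k-NN stage

Multiclass staging/grading by k-nearest neighbors (default k = 5) under
Mahalanobis distance. The metric uses the pooled, class-agnostic covariance
of the reference log intensities — one metric per model, the standard
Mahalanobis-k-NN reading; per-class metrics are a different estimator and
are out of scope. References are capped at 30,000 cells by seeded
class-stratified proportional subsampling (largest-remainder rounding, each
class within one cell of proportionality). Neighbor search whitens queries
and references by the Cholesky factor of Σ⁻¹ (after which Mahalanobis is
Euclidean) and scans exhaustively in chunks; with ≤ 30,000 references and
≤ 5 markers no tree index is warranted. Determinism: distance ties break by
reference order (stable sort); a tie in the plurality vote returns ABSTAIN
rather than an arbitrary label — abstention is the package's model of
"unclassifiable" cells, which the original analysis reports but never
defines. With k = 1 the abstain rate is zero by construction. Accuracy is
reported over classified cells, with the abstain rate alongside, never
folded in. A singular or near-singular pooled covariance (condition number
> 1e12) is an error suggesting jitter or marker removal.

## Tissue aggregation

The largest-share fuzzy rule: fractions of each class among a specimen's
classified cells are the diagnosis probabilities; the majority class is the
diagnosis. Abstained cells are excluded from the denominator but always
reported. Zero classified cells gives an explicit `indeterminate` status,
not an exception. Exact ties resolve toward the more severe class under
B < ASAP < AC < LAC < StageII < StageIII (or B < G33 < G34 < G43) and are
flagged — a conservative-toward-malignancy package decision for a case the
rule itself leaves undefined. Display percentages round half-away-from-zero
to two decimals while machine outputs keep full precision; published
composition tables contain at least one cell inconsistent with any single
rounding rule, so table-exact reproduction of every printed percentage is
explicitly not a goal. A deterministic probabilistic cutoff on the aberrant
fraction (for a hard call instead of a probability) is exposed as
configuration but has no default, as no validated threshold exists.

## Pipeline

`run_pipeline` chains simulate/ingest → log transform → optional compartment
restriction (the epithelial-only vs all-cells model variants) → patient-level
development/validation split → logistic scoring (scan, cutoff, ROC/band) →
k-NN staging → aggregation, writing every intermediate as CSV/JSON. The
single global seed expands into per-stage seeds as
`stage_seed(i) = (seed·1000 + i) mod 2³¹`, so any stage can be rerun in
isolation; the config hash and per-stage row counts are logged as the audit
trail. Reruns with identical config are bit-identical (`report.digest()`).

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script: study-like
cohorts of 2,000–20,000 cells; parameter recovery at n = 50,000 over 10
seeds (each coefficient within 3 fitted SEs, ≥ 9/10 seeds); AUC/k-NN oracle
equivalence at 30–2,000 cells; null-cohort calibration over 20 seeded
end-to-end runs (mean validation AUC within 0.5 ± 0.05). These sizes were
chosen as the package's own desk-scale defaults; all are configurable
upward. Tolerances: IRLS as above; eigendecomposition agreement with an
independent eigensolver at 1e-8; whitening-vs-quadratic-form Mahalanobis
agreement at 1e-10; AUC-vs-concordance agreement exact to 1e-12.

## Known limitations

* Cell truth is inherited from tissue labels; per-cell accuracy is only as
  meaningful as that assumption.
* SEs ignore within-patient correlation (see above).
* The fraction-as-probability reading of compositions is a convention, not
  a calibrated posterior.
* The synthetic generator's effect magnitudes are stipulated, so absolute
  synthetic performance numbers (AUC, k-NN accuracy) characterise the
  machinery under the default scenario, not any tissue dataset.
* No image processing: the package begins at the per-cell intensity table.
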