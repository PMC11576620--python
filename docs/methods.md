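# Methods

## Scope and model

The package compares proteome *groups* — named sets of protein sequences,
each protein optionally carrying one per-residue disorder score track in
[0, 1] per predictor — along four axes: amino-acid composition, per-protein
disorder summaries, whole-protein binary order/disorder classification,
and expression-weighted pool summaries.  Trained disorder predictors are
treated strictly as data sources; the package never attempts to reproduce
their scores and ships only a clearly-labelled geometric baseline
predictor for self-contained runs.

## Composition profiling

For residue x, enrichment of a query set Q against a background set B is
the fractional difference (C_x(Q) − C_x(B)) / C_x(B), where C_x is the
pooled relative frequency over all residues of all proteins in the set.
The statistic is scale-free: duplicating every protein leaves it
unchanged.

Uncertainty is estimated by a **protein-level bootstrap**: proteins are the
independent sampling units, so each iteration resamples proteins with
replacement within Q and within B (each at its original size) and
recomputes the statistic.  The per-residue standard deviation over
iterations is the reported error bar.  Significance uses a two-sided
sign-crossing test with an add-one correction,

    p = min(1, 2·(k + 1)/(B + 1)),

where k is the number of iterations on the opposite side of zero from the
observed value and B the iteration count — the +1 avoids exactly-zero
p-values at finite B.  Defaults: 10,000 iterations, α = 0.05; the seed is
mandatory.  A percentile-interval test would be an equally defensible
choice; the crossing test was chosen because it reads directly off the
bootstrap sample and degrades gracefully at small B.

No background composition is bundled: the reference background used in
lens/zonule work (a culled PDB subset) is not redistributable from here,
so backgrounds are always supplied by the caller as FASTA or a frequency
table.  Residues with zero background frequency but nonzero query
frequency are reported as +∞ and flagged `undefined`, excluded from
significance calls.

## Per-protein metrics and the cutoff grid

* ADS = mean of the track; PPDR = fraction of residues **strictly above**
  0.5 (configurable to ≥ for sensitivity analyses).
* MDP = per-residue mean across predictors; since all tracks of one
  protein share its length, ADS(MDP) equals the mean of the per-predictor
  ADS values exactly (asserted to 1e−12 in tests).
* Grid: ADS bins [0, 0.15), [0.15, 0.5), [0.5, 1]; PPDR bins [0, 10%),
  [10%, 30%), [30%, 100%].  Lower bins are half-open, the top bin is
  closed below.
* The two axes can disagree.  Two combination modes are provided:
  `strict_and` (highly disordered only when both axes agree; otherwise the
  less-disordered axis wins) and `lenient_or` (the more-disordered axis
  wins).  **Default: `lenient_or`** — the convention under which published
  highly-disordered counts in this line of work were evidently produced —
  and every report records the mode used.  Both modes are monotone in
  each axis.

## CH-CDF classification

ΔCH = ⟨R⟩ − (m·⟨H⟩ + b), with ⟨R⟩ the mean absolute net charge
(K, R positive; D, E negative; H neutral; no pH model) and ⟨H⟩ the
Kyte–Doolittle hydropathy min–max rescaled to [0, 1] and averaged over
sliding windows (default width 5).  Defaults m = 2.785, b = −1.151 — the
literature-standard boundary line in ⟨R⟩–⟨H⟩ space.  ΔCH > 0 predicts
disorder.

ΔCDF is the mean signed elevation of the protein's score CDF — at each
boundary threshold x, the fraction of residues with score ≤ x — above a
boundary curve.  ΔCDF > 0 predicts order.  The bundled 7-point boundary
table is **synthetic** (a diagonal offset; see
`src/idproteome/data/boundary_default.yaml`): no calibrated boundary for a
specific predictor is redistributable here, and the package's own tests
depend only on sign and geometry properties, never on the default
constants.  Users analysing real predictor output should substitute the
predictor's published boundary.

Quadrants follow the sign table Q1 (ΔCH<0, ΔCDF>0), Q2 (ΔCH<0, ΔCDF<0),
Q3 (ΔCH>0, ΔCDF<0), Q4 (ΔCH>0, ΔCDF>0).  Exact zeros are measure-zero but
must be deterministic: ΔCH = 0 joins the disordered side, ΔCDF = 0 the
ordered side, and ties are logged.

The baseline predictor reuses the CH geometry per residue: windowed mean
scaled hydropathy h and windowed mean absolute net charge q (centered
window, shrunk at the termini) give a margin (m·h + b) − q, negated and
passed through a logistic (gain 3 by default) so charged/hydrophilic
regions score above 0.5. It is a qualitative stand-in with the right sign
behaviour, not a trained model, and is named `baseline` in all outputs.

## Group statistics

* One-way ANOVA is computed from explicit sums of squares
  (F = MS_between/MS_within, p from the F distribution), returning the
  degrees of freedom alongside the statistic; the scipy reference
  implementation serves as a cross-check in the tests, not as the
  implementation.
* Tukey HSD uses the studentized-range procedure with the Tukey–Kramer
  unequal-n adjustment (statsmodels), since the motivating group sizes
  differ by a factor of 3–4.
* Chi-squared is plain Pearson (no Yates correction; the tables of
  interest are larger than 2×2), dof = (r−1)(c−1), expected counts from
  the margins.  Tiers or quadrants that are empty in every group carry no
  information and are dropped before the test (the count tables
  themselves are always emitted in full).
* The pool score is Σ wᵢ·ADSᵢ(MDP)/Σ wᵢ over proteins with positive
  abundance wᵢ; a positive-abundance protein without an MDP ADS is an
  error, zero-abundance proteins may lack one.  The score is invariant
  under abundance rescaling and bounded by the pool's ADS range.
* No multiple-testing correction is applied across the per-predictor
  metrics, matching the practice the pipeline reports on; p-values are
  stored at full precision and any "<0.01"-style bucketing is display
  layer only.

## Synthetic data: what it emulates, what it does not

The generator produces (i) sequences i.i.d. per residue from a baseline
composition (uniform 1/20 unless a table is supplied) reweighted by
per-residue multiplicative biases, lengths uniform in a range (default
50–500, minimum 30); (ii) tracks whose protein-level mean is drawn from a
Beta distribution re-parameterized by (mean, concentration) — specified
via the more intuitive (mean, SD), default SD 0.15 — with additive
moving-average Gaussian residue noise (default SD 0.15, correlation
length 10) clipped to [0, 1]; (iii) log-normal expression pools,
optionally exponentially tilted (weights ∝ exp(λ·ADS), λ solved by
Brent's method) so a pool's weighted mean ADS hits a stated target.

Defaults mirror the motivating study's conditions: groups of 926/261/279
proteins, six pseudo-predictors at the published per-group mean ADS
values, four pools at mean donor ages 38.5/50.5/60.0/38.5 years with
target scores 0.323/0.310/0.353/0.310.

What this does **not** emulate: real sequence families (crystallins,
fibrillins), domain architecture, residue-order structure within
sequences, correlations between composition and disorder, or heavy-tailed
abundance structure beyond log-normal.  Passing recovery tests therefore
demonstrates that the *analysis machinery* is correct and calibrated under
known ground truth — not that any biological conclusion transfers.

Clipping tracks to [0, 1] biases recovered ADS slightly toward the
interior when means sit near the boundaries; at the default noise levels
the bias is well inside the ±0.01 recovery tolerance asserted in tests.

## Numerical and degenerate-input choices

* Track/sequence length mismatch is an error, never a truncation.
* Residue indices are 1-based in files, 0-based internally; contiguity
  1..L is verified on load.
* Ambiguous residues: policy `drop_ambiguous` (default, logged),
  `strict`, or `map_to_nearest` (B→N, Z→Q, U→C, O→K, X dropped).
* ANOVA with zero variance both within and between groups raises
  (F undefined); zero within-group variance alone yields F = ∞, p = 0.
* Proteins in a FASTA with no track are listed in a sidecar table and
  excluded from disorder stages — drops are always explicit.
* The whole pipeline is byte-deterministic under fixed config and seed;
  synthetic sub-streams are derived from the master seed plus a CRC of the
  task name, so any piece regenerates identically in isolation.

## Validation problem sizes

The package's own validation experiments use: 500 null replicates
(3 × 200 proteins, tracks 30–40 residues) for ANOVA type-I calibration;
100 replicates at group sizes 926/261/279 for power at the published ADS
means; 2 × 420 proteins of 240–260 residues (≥10⁵ residues per set, 2,000
bootstrap iterations) for composition-bias recovery; and a 150-protein
group with six pseudo-predictors for pool-score construction.  These
sizes were chosen to make Monte-Carlo error small relative to the bands
being checked while keeping the default suite fast.

## Known limitations

* The bundled CDF boundary is synthetic; quadrant *counts* on real data
  are only meaningful with a predictor-matched calibrated boundary.
* The bootstrap p-value is Monte-Carlo-discrete; at B iterations its
  resolution is 2/(B+1).
* The baseline predictor has no notion of secondary-structure propensity
  beyond hydropathy/charge and should not be used for per-protein claims,
  only for exercising the pipeline.
* Composition profiles treat proteins as independent; paralog-rich
  proteomes violate this silently.
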